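"""Design the 120-index set and pick a balanced 96-index working subset.

Builds the 256-word quaternary (8,4) code, shifts it by the reference
offset word W=(1,2,2,3,3,0,0,0) modulo 4, maps to DNA, and keeps the
sequences with no base triplet anywhere and no identical duplet at either
end.  The survivors keep the code's minimum pairwise distance of 4.
"""

from hamdex import (
    DEFAULT_OFFSET,
    balance_report,
    build_quaternary_code,
    design_indices,
    select_subset,
)

codebook = build_quaternary_code()
print(f"codebook: {len(codebook)} words, construction {codebook.construction_id!r}")

indexset = design_indices(codebook, DEFAULT_OFFSET)
rep = balance_report(indexset)
print(f"W={DEFAULT_OFFSET}: {len(indexset)} indices survive the filters")
print(f"min pairwise distance: {indexset.min_distance()}")
print(f"balance imbalance: {rep.imbalance:.1f} (0 means every base appears "
      f"equally often at every position)")

working = select_subset(indexset, 96, seed=0)
wrep = balance_report(working)
print(f"96-index working set: imbalance {wrep.imbalance:.1f}, "
      f"min distance {working.min_distance()}")
print("first five indices:", ", ".join(working.indices[:5]))
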