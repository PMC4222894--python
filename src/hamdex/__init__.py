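"""hamdex: error-correcting DNA sample indices and dual-index demultiplexing.

Designs sets of 8-base sequencing indices from a quaternary Hamming (8,4)
code (256 words, minimum pairwise distance 4), filtered for homopolymer
safety and per-position nucleotide balance; decodes observed index reads
with single-error correction and double-error detection; and demultiplexes
dual-indexed FASTQ runs against a sample sheet, supporting up to 96 x 96
sample pairs.
"""

from .code import (
    Codebook,
    build_binary_hamming84,
    build_quaternary_code,
    hamming_distance,
)
from .design import (
    DEFAULT_NUCLEOTIDE_MAP,
    BalanceReport,
    IndexSet,
    OffsetResult,
    apply_offset,
    balance_report,
    design_indices,
    from_dna,
    passes_constraints,
    search_offsets,
    select_subset,
    to_dna,
)
from .decode import (
    DecodeResult,
    Decoder,
    ErrorAudit,
    audit_errors,
    decode,
    decode_with_quality,
    distance_histogram,
)
from .demux import (
    DemuxPolicy,
    DemuxStats,
    ReadRecord,
    SampleSheet,
    demux_run,
    parse_sample_sheet,
    read_run,
)
from .sim import ErrorProfile, evaluate_demux, generate_run, simulate_records

__version__ = "0.1.0"

#: The offset word used for the shipped 120-index design.
DEFAULT_OFFSET = (1, 2, 2, 3, 3, 0, 0, 0)


def default_index_set(k: int | None = None, seed: int = 0) -> IndexSet:
    """Build the shipped design: 120 indices, optionally a balanced k-subset.

    Uses the default bit-plane code, offset W = (1,2,2,3,3,0,0,0) and the
    default nucleotide map; ``default_index_set(96)`` returns the 96-index
    working set.
    """
    full = design_indices(build_quaternary_code(), DEFAULT_OFFSET)
    if k is None:
        return full
    return select_subset(full, k, seed=seed)
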