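"""Index-set design: offset transform, DNA mapping, filters, balance, search.

The raw quaternary code contains many length-3 homopolymers once read as DNA.
The design procedure therefore adds a fixed offset word W (modulo 4, position
by position) to every code word — a translation that preserves all pairwise
Hamming distances — maps to DNA, and discards sequences with a run of three
identical bases anywhere or an identical duplet at either end.  Varying W
trades off the number of surviving indices against per-position nucleotide
balance; `search_offsets` sweeps all 4^8 = 65,536 offsets exhaustively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .code import Codebook, QuaternaryWord, hamming_distance

__all__ = [
    "DEFAULT_NUCLEOTIDE_MAP",
    "IndexSet",
    "BalanceReport",
    "OffsetResult",
    "apply_offset",
    "to_dna",
    "from_dna",
    "passes_constraints",
    "design_indices",
    "balance_report",
    "search_offsets",
    "select_subset",
]

WORD_LENGTH = 8
BASES = "ACGT"

#: Default bijection {0,1,2,3} -> {A,C,G,T}: symbol i maps to position i.
DEFAULT_NUCLEOTIDE_MAP = "ACGT"


def _check_map(nucleotide_map: str) -> str:
    if sorted(nucleotide_map) != list(BASES):
        raise ValueError(
            f"nucleotide map must be a permutation of ACGT, got {nucleotide_map!r}"
        )
    return nucleotide_map


def _check_word(word: Sequence[int], name: str = "word") -> tuple[int, ...]:
    w = tuple(int(x) for x in word)
    if len(w) != WORD_LENGTH or any(x not in (0, 1, 2, 3) for x in w):
        raise ValueError(f"{name} must be 8 symbols in {{0,1,2,3}}, got {word!r}")
    return w


def apply_offset(word: QuaternaryWord, offset: Sequence[int]) -> QuaternaryWord:
    """Add the offset word position-wise, modulo 4.

    Translation by a fixed offset is a distance-preserving bijection of the
    symbol space, so the offset code inherits the codebook's minimum distance.
    """
    w = _check_word(word)
    off = _check_word(offset, "offset")
    return tuple((a + b) % 4 for a, b in zip(w, off))


def to_dna(word: QuaternaryWord, nucleotide_map: str = DEFAULT_NUCLEOTIDE_MAP) -> str:
    """Map a quaternary word to an 8-base DNA string."""
    m = _check_map(nucleotide_map)
    return "".join(m[x] for x in _check_word(word))


def from_dna(seq: str, nucleotide_map: str = DEFAULT_NUCLEOTIDE_MAP) -> QuaternaryWord:
    """Invert `to_dna` for a given map."""
    m = _check_map(nucleotide_map)
    try:
        return tuple(m.index(b) for b in seq)
    except ValueError:
        raise ValueError(f"non-ACGT character in {seq!r}") from None


def passes_constraints(seq: str) -> tuple[bool, list[str]]:
    """Check the homopolymer rules on an 8-base index candidate.

    Rule ``triplet``: no run of >= 3 identical consecutive bases anywhere.
    Rule ``end_duplet``: the first two bases differ and the last two bases
    differ.  Returns ``(ok, violated_rules)``.
    """
    if len(seq) != WORD_LENGTH or any(b not in BASES for b in seq):
        raise ValueError(f"expected an 8-base ACGT string, got {seq!r}")
    violations = []
    if any(seq[i] == seq[i + 1] == seq[i + 2] for i in range(WORD_LENGTH - 2)):
        violations.append("triplet")
    if seq[0] == seq[1] or seq[-2] == seq[-1]:
        violations.append("end_duplet")
    return not violations, violations


@dataclass(frozen=True)
class IndexSet:
    """An ordered set of designed 8-base DNA indices with provenance.

    ``provenance`` carries, per index, the source code word and the offset /
    map that produced it, so a designed set can be audited back to the code.
    """

    indices: tuple[str, ...]
    set_id: str = "indexset"
    source_words: tuple[QuaternaryWord, ...] | None = None
    offset: tuple[int, ...] | None = None
    nucleotide_map: str | None = None

    def __post_init__(self):
        seen = set()
        for s in self.indices:
            if len(s) != WORD_LENGTH or any(b not in BASES for b in s):
                raise ValueError(f"invalid index sequence {s!r}")
            if s in seen:
                raise ValueError(f"duplicate index {s!r}")
            seen.add(s)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def index_ids(self) -> list[str]:
        return [f"{self.set_id}_{i + 1:03d}" for i in range(len(self.indices))]

    def min_distance(self) -> int:
        return min(
            hamming_distance(a, b)
            for a, b in itertools.combinations(self.indices, 2)
        )

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        off = ",".join(map(str, self.offset)) if self.offset else ""
        with open(path, "w") as fh:
            fh.write("index_id\tsequence\tsource_word\toffset\tmap\n")
            for i, (iid, seq) in enumerate(zip(self.index_ids(), self.indices)):
                src = (
                    ",".join(map(str, self.source_words[i]))
                    if self.source_words
                    else ""
                )
                fh.write(
                    f"{iid}\t{seq}\t{src}\t{off}\t{self.nucleotide_map or ''}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, set_id: str | None = None) -> "IndexSet":
        indices, sources, offset, nmap = [], [], None, None
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {name: i for i, name in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                indices.append(parts[cols["sequence"]])
                if parts[cols.get("source_word", -1)]:
                    sources.append(
                        tuple(int(x) for x in parts[cols["source_word"]].split(","))
                    )
                if "offset" in cols and parts[cols["offset"]]:
                    offset = tuple(int(x) for x in parts[cols["offset"]].split(","))
                if "map" in cols and parts[cols["map"]]:
                    nmap = parts[cols["map"]]
        return cls(
            indices=tuple(indices),
            set_id=set_id or Path(path).stem,
            source_words=tuple(sources) if len(sources) == len(indices) else None,
            offset=offset,
            nucleotide_map=nmap,
        )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iid, seq in zip(self.index_ids(), self.indices):
                fh.write(f">{iid}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path: str | Path, set_id: str | None = None) -> "IndexSet":
        from Bio import SeqIO

        indices = tuple(str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta"))
        return cls(indices=indices, set_id=set_id or Path(path).stem)


@dataclass(frozen=True)
class BalanceReport:
    """Per-position nucleotide usage of an index set.

    ``counts[p, b]`` is the number of indices carrying base ``BASES[b]`` at
    position ``p``.  ``imbalance`` is the sum over all 32 position-base cells
    of the squared deviation from the uniform expectation n/4; it is zero
    exactly when every base occurs equally often at every position.
    """

    counts: np.ndarray
    n_indices: int

    @property
    def imbalance(self) -> float:
        expected = self.n_indices / 4.0
        return float(((self.counts - expected) ** 2).sum())

    @property
    def max_cell_deviation(self) -> float:
        return float(np.abs(self.counts - self.n_indices / 4.0).max())


def balance_report(indexset: IndexSet | Sequence[str]) -> BalanceReport:
    """Count base usage per position and score the imbalance."""
    seqs = list(indexset)
    if not seqs:
        raise ValueError("empty index set")
    counts = np.zeros((WORD_LENGTH, 4), dtype=np.int64)
    for s in seqs:
        for p, b in enumerate(s):
            counts[p, BASES.index(b)] += 1
    return BalanceReport(counts=counts, n_indices=len(seqs))


def design_indices(
    codebook: Codebook,
    offset: Sequence[int],
    nucleotide_map: str = DEFAULT_NUCLEOTIDE_MAP,
    set_id: str | None = None,
) -> IndexSet:
    """Offset the codebook, map to DNA, and keep the filter survivors.

    Preserves codebook order.  The surviving set inherits the codebook's
    minimum distance (>= 4 for the default construction) because both the
    offset translation and the base mapping preserve Hamming distances and
    filtering only removes words.
    """
    off = _check_word(offset, "offset")
    indices, sources = [], []
    for word in codebook.words:
        seq = to_dna(apply_offset(word, off), nucleotide_map)
        ok, _ = passes_constraints(seq)
        if ok:
            indices.append(seq)
            sources.append(word)
    return IndexSet(
        indices=tuple(indices),
        set_id=set_id or "design_W" + "".join(map(str, off)),
        source_words=tuple(sources),
        offset=off,
        nucleotide_map=nucleotide_map,
    )


@dataclass(frozen=True)
class OffsetResult:
    offset: tuple[int, ...]
    count: int
    imbalance: float


def _codebook_array(codebook: Codebook) -> np.ndarray:
    return np.array(codebook.words, dtype=np.uint8)


def _survivor_mask(offset_words: np.ndarray, code: np.ndarray) -> np.ndarray:
    """Vectorised filter over (n_offsets, 256, 8) offset words.

    Base-equality patterns do not depend on the nucleotide map, so the rules
    are evaluated directly on the quaternary symbols.
    """
    shifted = (code[None, :, :] + offset_words[:, None, :]) % 4
    eq = shifted[..., :-1] == shifted[..., 1:]          # adjacent equal
    run3 = (eq[..., :-1] & eq[..., 1:]).any(axis=-1)    # any run >= 3
    end = eq[..., 0] | eq[..., -1]                      # duplet at either end
    return ~(run3 | end)


def search_offsets(
    codebook: Codebook,
    nucleotide_map: str = DEFAULT_NUCLEOTIDE_MAP,
    min_count: int = 0,
    balance_tolerance: float | None = None,
    chunk: int = 4096,
) -> list[OffsetResult]:
    """Exhaustively evaluate all 4^8 = 65,536 offset words.

    Returns offsets whose surviving-index count is >= ``min_count`` (and, if
    ``balance_tolerance`` is given, whose per-cell deviation from uniform
    balance is within it), ranked by count descending, imbalance ascending,
    then lexicographic offset — fully deterministic.
    """
    _check_map(nucleotide_map)
    code = _codebook_array(codebook)
    all_offsets = np.array(
        list(itertools.product(range(4), repeat=WORD_LENGTH)), dtype=np.uint8
    )
    results: list[OffsetResult] = []
    for start in range(0, len(all_offsets), chunk):
        block = all_offsets[start : start + chunk]
        mask = _survivor_mask(block, code)
        counts = mask.sum(axis=1)
        for i in np.flatnonzero(counts >= min_count):
            shifted = (code + block[i]) % 4
            survivors = shifted[mask[i]]
            # per-position symbol counts; imbalance is map-invariant
            n = survivors.shape[0]
            cell = np.stack(
                [(survivors == s).sum(axis=0) for s in range(4)], axis=1
            )
            imb = float(((cell - n / 4.0) ** 2).sum())
            if balance_tolerance is not None:
                if np.abs(cell - n / 4.0).max() > balance_tolerance:
                    continue
            results.append(
                OffsetResult(tuple(int(x) for x in block[i]), int(counts[i]), imb)
            )
    results.sort(key=lambda r: (-r.count, r.imbalance, r.offset))
    return results


def select_subset(indexset: IndexSet, k: int, seed: int = 0) -> IndexSet:
    """Pick ``k`` indices minimising balance imbalance by greedy swapping.

    Starts from the first ``k`` indices in codebook order and repeatedly
    applies the single in/out swap that most reduces the imbalance until no
    improving swap exists.  Deterministic: ``seed`` only breaks exact ties in
    swap scores (via a seeded tiny jitter on tie ordering, not on scores).
    """
    n = len(indexset)
    if k > n:
        raise ValueError(f"cannot select {k} from {n} indices")
    if k == n:
        return indexset
    seqs = list(indexset.indices)
    enc = np.array([[BASES.index(b) for b in s] for s in seqs], dtype=np.int64)
    onehot = np.zeros((n, WORD_LENGTH, 4), dtype=np.int64)
    for i in range(n):
        onehot[i, np.arange(WORD_LENGTH), enc[i]] = 1

    rng = np.random.default_rng(seed)
    tie_rank = rng.permutation(n * n)  # deterministic tie order over swap ids

    chosen = list(range(k))
    excluded = list(range(k, n))
    counts = onehot[chosen].sum(axis=0)
    expected = k / 4.0

    def imb(c: np.ndarray) -> float:
        return float(((c - expected) ** 2).sum())

    current = imb(counts)
    improved = True
    while improved:
        improved = False
        best = (0.0, 0, None)  # (gain, tie_rank, (ci, ei))
        for ci, i_out in enumerate(chosen):
            base = counts - onehot[i_out]
            for ei, i_in in enumerate(excluded):
                gain = current - imb(base + onehot[i_in])
                if gain > 1e-12:
                    rank = tie_rank[i_out * n + i_in]
                    if gain > best[0] + 1e-12 or (
                        abs(gain - best[0]) <= 1e-12 and rank < best[1]
                    ):
                        best = (gain, rank, (ci, ei))
        if best[2] is not None:
            ci, ei = best[2]
            i_out, i_in = chosen[ci], excluded[ei]
            chosen[ci], excluded[ei] = i_in, i_out
            counts = counts - onehot[i_out] + onehot[i_in]
            current = imb(counts)
            improved = True

    chosen_sorted = sorted(chosen)
    return IndexSet(
        indices=tuple(seqs[i] for i in chosen_sorted),
        set_id=f"{indexset.set_id}_k{k}",
        source_words=(
            tuple(indexset.source_words[i] for i in chosen_sorted)
            if indexset.source_words
            else None
        ),
        offset=indexset.offset,
        nucleotide_map=indexset.nucleotide_map,
    )
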