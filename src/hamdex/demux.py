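"""Dual-index demultiplexing of FASTQ runs.

Each read carries two 8-base index reads (i7 and i5).  Both are decoded
independently against their index sets with single-error correction and the
quality policy; a read is assigned to a sample exactly when both decode
successfully and the decoded (i7, i5) pair is present in the sample sheet.
With two indices at minimum distance 4 each, sample identity is protected by
an effective pair distance of 8.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .decode import Decoder, DecodeResult
from .design import IndexSet
from . import fastq

__all__ = [
    "SampleSheet",
    "ReadRecord",
    "DemuxStats",
    "DemuxPolicy",
    "parse_sample_sheet",
    "read_run",
    "demux_run",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNDETERMINED_REASONS = ("low_quality", "index1_fail", "index2_fail", "pair_not_in_sheet")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SampleSheet:
    """Mapping from (i7, i5) index pairs to unique sample identifiers."""

    samples: tuple[tuple[str, str, str], ...]  # (sample_id, i7, i5)

    def __post_init__(self):
        ids = [s for s, _, _ in self.samples]
        pairs = [(a, b) for _, a, b in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample sheet")
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (i7, i5) pair in sample sheet")
        for sid, i7, i5 in self.samples:
            for seq in (i7, i5):
                if len(seq) != 8 or any(b not in "ACGT" for b in seq):
                    raise ValueError(
                        f"sample {sid!r}: index {seq!r} is not an 8-base ACGT string"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def pair_to_sample(self) -> dict[tuple[str, str], str]:
        return {(i7, i5): sid for sid, i7, i5 in self.samples}

    def sample_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.samples]

    def validate_against(self, i7set: IndexSet, i5set: IndexSet) -> None:
        """Require every sheet index to be a member of its designed set."""
        i7s, i5s = set(i7set.indices), set(i5set.indices)
        for sid, i7, i5 in self.samples:
            if i7 not in i7s:
                raise ValueError(f"sample {sid!r}: i7 {i7} not in index set")
            if i5 not in i5s:
                raise ValueError(f"sample {sid!r}: i5 {i5} not in index set")


def parse_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV sample sheet with header sample_id,i7,i5."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "i7", "i5"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"sample sheet must have columns {sorted(required)}, got {list(df.columns)}"
        )
    rows = tuple(
        (str(r.sample_id), str(r.i7).upper(), str(r.i5).upper())
        for r in df.itertuples()
    )
    return SampleSheet(samples=rows)


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: str  # Phred+33 string
    index1_seq: str
    index1_quals: str
    index2_seq: str
    index2_quals: str
    sequence2: str | None = None  # R2 for paired-end runs
    qualities2: str | None = None


@dataclass
class DemuxStats:
    """Read-count bookkeeping for one demultiplexing run.

    per_sample[sid] = {"exact_both": ..., "corrected_any": ..., "total": ...};
    undetermined counts are keyed by the first applicable failure reason.
    """

    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    undetermined: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in UNDETERMINED_REASONS}
    )
    total_reads: int = 0

    @property
    def assigned_reads(self) -> int:
        return sum(c["total"] for c in self.per_sample.values())

    @property
    def undetermined_reads(self) -> int:
        return sum(self.undetermined.values())

    def conserves_counts(self) -> bool:
        return self.assigned_reads + self.undetermined_reads == self.total_reads

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "assigned_reads": self.assigned_reads,
            "undetermined_reads": self.undetermined_reads,
            "per_sample": self.per_sample,
            "undetermined_by_reason": self.undetermined,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\ttotal\texact_both\tcorrected_any\n")
            for sid, c in self.per_sample.items():
                fh.write(f"{sid}\t{c['total']}\t{c['exact_both']}\t{c['corrected_any']}\n")
            for reason, count in self.undetermined.items():
                fh.write(f"undetermined:{reason}\t{count}\t\t\n")


_HEADER_INDEX_RE = re.compile(r"[012]:[YN]:\d+:([ACGTN]+)\+([ACGTN]+)$")


def read_run(
    r1: str | Path,
    i1: str | Path | None = None,
    i2: str | Path | None = None,
    r2: str | Path | None = None,
    indexes_in_header: bool = False,
) -> Iterator[ReadRecord]:
    """Stream a dual-indexed run as ReadRecord objects.

    Index reads come either from separate I1/I2 FASTQ files synchronized by
    record order (default) or, with ``indexes_in_header``, from the comment
    field of the R1 header (``1:N:0:INDEX1+INDEX2`` dialect); in the latter
    case index qualities are unavailable and treated as maximal.
    """
    r1_iter = fastq.read_fastq(r1)
    r2_iter = fastq.read_fastq(r2) if r2 else None

    if indexes_in_header:
        for n, (title, seq, qual) in enumerate(r1_iter):
            m = _HEADER_INDEX_RE.search(title)
            if not m:
                raise ValueError(
                    f"record {n} in {r1}: header {title!r} carries no INDEX1+INDEX2 field"
                )
            idx1, idx2 = m.group(1), m.group(2)
            hi = fastq.phred_to_string([40] * len(idx1))
            rec2 = next(r2_iter) if r2_iter else None
            yield ReadRecord(
                read_id=title.split()[0],
                sequence=seq,
                qualities=qual,
                index1_seq=idx1,
                index1_quals=hi,
                index2_seq=idx2,
                index2_quals=fastq.phred_to_string([40] * len(idx2)),
                sequence2=rec2[1] if rec2 else None,
                qualities2=rec2[2] if rec2 else None,
            )
        return

    if i1 is None or i2 is None:
        raise ValueError("i1 and i2 FASTQ paths are required unless indexes_in_header")
    i1_iter = fastq.read_fastq(i1)
    i2_iter = fastq.read_fastq(i2)
    for n, (title, seq, qual) in enumerate(r1_iter):
        try:
            t1, s1, q1 = next(i1_iter)
            t2, s2, q2 = next(i2_iter)
        except StopIteration:
            raise ValueError(
                f"index FASTQ truncated at record {n} (read {title.split()[0]!r})"
            ) from None
        rid = title.split()[0]
        for t_other, which in ((t1, i1), (t2, i2)):
            if t_other.split()[0] != rid:
                raise ValueError(
                    f"record {n}: read id mismatch between {r1} and {which} "
                    f"({rid!r} vs {t_other.split()[0]!r})"
                )
        rec2 = next(r2_iter) if r2_iter else None
        yield ReadRecord(
            read_id=rid,
            sequence=seq,
            qualities=qual,
            index1_seq=s1,
            index1_quals=q1,
            index2_seq=s2,
            index2_quals=q2,
            sequence2=rec2[1] if rec2 else None,
            qualities2=rec2[2] if rec2 else None,
        )


@dataclass(frozen=True)
class DemuxPolicy:
    max_mismatch: int = 1
    q_min: int = 20
    rc_index2: bool = False  # reverse-complement i5 reads before decoding


def _classify(
    rec: ReadRecord,
    decoder1: Decoder,
    decoder2: Decoder,
    pair_map: dict[tuple[str, str], str],
    policy: DemuxPolicy,
) -> tuple[str | None, str | None, bool]:
    """Return (sample_id, undetermined_reason, exact_both) for one read."""
    idx2 = rec.index2_seq
    q2 = rec.index2_quals
    if policy.rc_index2:
        idx2 = reverse_complement(idx2)
        q2 = q2[::-1]
    res1 = decoder1.decode_with_quality(
        rec.index1_seq, fastq.string_to_phred(rec.index1_quals), q_min=policy.q_min
    )
    res2 = decoder2.decode_with_quality(idx2, fastq.string_to_phred(q2), q_min=policy.q_min)

    # reason precedence: low_quality -> index1_fail -> index2_fail -> pair
    low_q = "low-quality" in res1.reason or "low-quality" in res2.reason
    if low_q and not (res1.assigned and res2.assigned):
        return None, "low_quality", False
    if not res1.assigned:
        return None, "index1_fail", False
    if not res2.assigned:
        return None, "index2_fail", False
    sample = pair_map.get((res1.index_seq, res2.index_seq))
    if sample is None:
        return None, "pair_not_in_sheet", False
    return sample, None, res1.status == "exact" and res2.status == "exact"


def demux_run(
    reads: Iterable[ReadRecord],
    sheet: SampleSheet,
    i7set: IndexSet,
    i5set: IndexSet,
    policy: DemuxPolicy | None = None,
    outdir: str | Path | None = None,
    compress: bool = True,
    record_assignments: bool = False,
) -> DemuxStats | tuple[DemuxStats, dict[str, str | None]]:
    """Assign reads to samples; optionally write per-sample FASTQ outputs.

    Returns DemuxStats (and, with ``record_assignments``, a read_id ->
    sample_id-or-None map for downstream evaluation).  Read counts are
    conserved: every input read lands in exactly one sample bucket or one
    undetermined reason.
    """
    policy = policy or DemuxPolicy()
    decoder1 = Decoder(i7set, max_mismatch=policy.max_mismatch)
    decoder2 = Decoder(i5set, max_mismatch=policy.max_mismatch)
    pair_map = sheet.pair_to_sample

    stats = DemuxStats(
        per_sample={
            sid: {"exact_both": 0, "corrected_any": 0, "total": 0}
            for sid in sheet.sample_ids()
        }
    )
    assignments: dict[str, str | None] = {}

    writers: dict[str, fastq.FastqWriter] = {}
    ext = ".fastq.gz" if compress else ".fastq"

    def writer_for(name: str) -> fastq.FastqWriter:
        if name not in writers:
            writers[name] = fastq.FastqWriter(Path(outdir) / f"{name}{ext}")
        return writers[name]

    try:
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
        for rec in reads:
            stats.total_reads += 1
            sample, reason, exact_both = _classify(
                rec, decoder1, decoder2, pair_map, policy
            )
            if sample is not None:
                c = stats.per_sample[sample]
                c["total"] += 1
                if exact_both:
                    c["exact_both"] += 1
                else:
                    c["corrected_any"] += 1
            else:
                stats.undetermined[reason] += 1
            if record_assignments:
                assignments[rec.read_id] = sample
            if outdir is not None:
                writer_for(sample if sample is not None else "undetermined").write(
                    rec.read_id, rec.sequence, rec.qualities
                )
    finally:
        for w in writers.values():
            w.close()

    assert stats.conserves_counts()
    if record_assignments:
        return stats, assignments
    return stats
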