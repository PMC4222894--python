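"""Synthetic dual-indexed sequencing runs with known ground truth.

The generator emulates the error regime the index design targets: per-read,
each index base is substituted independently with a per-position probability,
the substitute drawn uniformly from the 3 alternative bases.  Quality strings
reflect the simulation's knowledge: error-free bases get a high Phred score,
substituted bases a low one (optionally jittered), so quality-aware decoding
policies can be exercised.  Insert sequences are i.i.d. uniform bases — they
are irrelevant to index decoding but keep the files format-realistic.

Everything is deterministic given the profile seed, down to the output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demux import ReadRecord, SampleSheet
from . import fastq

__all__ = ["ErrorProfile", "RunPaths", "generate_run", "simulate_records", "evaluate_demux"]

BASES = "ACGT"
INDEX_LENGTH = 8


@dataclass(frozen=True)
class ErrorProfile:
    """Substitution-error model for index reads.

    per_position_rate: substitution probability at each of the 8 index
    positions (a scalar is broadcast).  q_good / q_bad: Phred scores emitted
    for error-free and substituted bases (clipped to [2, 41]); q_jitter adds
    a uniform integer jitter of +/- that many Phred units.
    """

    per_position_rate: tuple[float, ...] | float = 0.001
    q_good: int = 37
    q_bad: int = 10
    q_jitter: int = 0
    insert_length: int = 50
    seed: int = 0

    def rates(self) -> np.ndarray:
        r = np.broadcast_to(np.asarray(self.per_position_rate, dtype=float), (INDEX_LENGTH,))
        if ((r < 0) | (r > 1)).any():
            raise ValueError("substitution probabilities must be in [0, 1]")
        if not (2 <= self.q_bad <= 41 and 2 <= self.q_good <= 41):
            raise ValueError("Phred scores must be in [2, 41]")
        return r.copy()


@dataclass(frozen=True)
class RunPaths:
    r1: Path
    i1: Path
    i2: Path
    truth: Path


def _mutate_index(
    seq: str, rates: np.ndarray, profile: ErrorProfile, rng: np.random.Generator
) -> tuple[str, str, int]:
    """Apply per-position substitutions; return (read, qual string, n_errors)."""
    hits = rng.random(INDEX_LENGTH) < rates
    out = list(seq)
    quals = np.full(INDEX_LENGTH, profile.q_good, dtype=int)
    for p in np.flatnonzero(hits):
        alternatives = [b for b in BASES if b != seq[p]]
        out[p] = alternatives[rng.integers(3)]
        quals[p] = profile.q_bad
    if profile.q_jitter:
        quals = quals + rng.integers(
            -profile.q_jitter, profile.q_jitter + 1, size=INDEX_LENGTH
        )
    quals = np.clip(quals, 2, 41)
    return "".join(out), fastq.phred_to_string(quals), int(hits.sum())


def simulate_records(
    sheet: SampleSheet, n_reads: int, profile: ErrorProfile
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Generate reads in memory; returns (records, truth table).

    Reads are drawn uniformly over the sheet's samples.  The truth table has
    one row per read: read_id, true_sample_id, errors_in_index1,
    errors_in_index2.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(profile.seed)
    rates = profile.rates()
    samples = sheet.samples
    choice = rng.integers(len(samples), size=n_reads)

    records: list[ReadRecord] = []
    truth_rows = []
    for n in range(n_reads):
        sid, i7, i5 = samples[choice[n]]
        rid = f"sim_{n:07d}"
        idx1, q1, e1 = _mutate_index(i7, rates, profile, rng)
        idx2, q2, e2 = _mutate_index(i5, rates, profile, rng)
        insert = "".join(BASES[b] for b in rng.integers(4, size=profile.insert_length))
        iq = fastq.phred_to_string(np.full(profile.insert_length, profile.q_good))
        records.append(
            ReadRecord(
                read_id=rid,
                sequence=insert,
                qualities=iq,
                index1_seq=idx1,
                index1_quals=q1,
                index2_seq=idx2,
                index2_quals=q2,
            )
        )
        truth_rows.append((rid, sid, e1, e2))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "true_sample_id", "errors_in_index1", "errors_in_index2"],
    )
    return records, truth


def generate_run(
    sheet: SampleSheet,
    n_reads: int,
    profile: ErrorProfile,
    outdir: str | Path,
    compress: bool = True,
) -> tuple[RunPaths, pd.DataFrame]:
    """Write a synthetic run as R1/I1/I2 FASTQ plus a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_records(sheet, n_reads, profile)
    ext = ".fastq.gz" if compress else ".fastq"
    paths = RunPaths(
        r1=outdir / f"R1{ext}",
        i1=outdir / f"I1{ext}",
        i2=outdir / f"I2{ext}",
        truth=outdir / "truth.tsv",
    )
    with fastq.FastqWriter(paths.r1) as w_r1, fastq.FastqWriter(
        paths.i1
    ) as w_i1, fastq.FastqWriter(paths.i2) as w_i2:
        for rec in records:
            w_r1.write(rec.read_id, rec.sequence, rec.qualities)
            w_i1.write(rec.read_id, rec.index1_seq, rec.index1_quals)
            w_i2.write(rec.read_id, rec.index2_seq, rec.index2_quals)
    truth.to_csv(paths.truth, sep="\t", index=False)
    return paths, truth


def evaluate_demux(
    truth: pd.DataFrame, assignments: dict[str, str | None]
) -> dict:
    """Score demultiplexing against the simulation's ground truth.

    recovery_rate_by_error_count maps (errors_in_index1, errors_in_index2)
    to the fraction of those reads assigned to their true sample;
    misassignment_rate is the fraction of all reads assigned to a wrong
    sample (unassigned reads are not misassigned).
    """
    missing = set(truth["read_id"]) - set(assignments)
    if missing:
        raise ValueError(f"{len(missing)} truth reads missing from assignments")
    assigned_to = truth["read_id"].map(assignments)
    correct = assigned_to == truth["true_sample_id"]
    wrong = assigned_to.notna() & ~correct
    by_err = {}
    grouped = truth.assign(correct=correct).groupby(
        ["errors_in_index1", "errors_in_index2"]
    )["correct"]
    for key, frac in grouped.mean().items():
        by_err[(int(key[0]), int(key[1]))] = float(frac)
    return {
        "recovery_rate_by_error_count": by_err,
        "misassignment_rate": float(wrong.mean()),
        "overall_recovery_rate": float(correct.mean()),
        "n_reads": int(len(truth)),
    }
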