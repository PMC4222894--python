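"""Index decoding: single-error correction, double-error detection, audits.

With a minimum pairwise distance of 4 over the index set, radius-1 spheres
around the indices are disjoint: an observed 8-mer within distance 1 of some
index is within distance 1 of exactly one, so single substitutions are
corrected unambiguously and double substitutions can never land on (or
within distance 1 of) a wrong index — they are detected instead.  Triple
substitutions can reach distance 1 of a distance-4 neighbour and be
mis-corrected; `audit_errors` enumerates every such pattern exhaustively.

Decoding is by exhaustive distance to the set rather than syndrome decoding:
the filtered, offset index set is not a linear code, and 96-120 vectorised
comparisons per read are cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import BASES, IndexSet, WORD_LENGTH

__all__ = [
    "DecodeResult",
    "ErrorAudit",
    "Decoder",
    "decode",
    "decode_with_quality",
    "audit_errors",
    "distance_histogram",
]

#: Encoding for bases; N gets a symbol that mismatches every index base.
_ENC = {b: i for i, b in enumerate(BASES)}
_N_CODE = 255


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of matching one observed index read against an index set.

    status is one of:
      exact       distance 0 to a member index
      corrected   unique member at distance 1 (single substitution fixed)
      detected    no member within the radius but one within distance 2-3
                  (an error was noticed; assignment withheld)
      unassigned  distance >= 4 to every member, too many Ns, or a
                  correction rejected by the quality policy
    """

    status: str
    index_id: str | None = None
    index_seq: str | None = None
    distance: int | None = None
    corrected_positions: tuple[int, ...] = ()
    reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.status in ("exact", "corrected")


@dataclass(frozen=True)
class ErrorAudit:
    """Tally of decoder outcomes over all weight-w substitution patterns."""

    weight: int
    total_events: int
    corrected_to_truth: int
    detected: int
    miscorrected: int

    @property
    def fraction_miscorrected(self) -> float:
        return self.miscorrected / self.total_events

    def to_dict(self) -> dict:
        return {
            "weight": self.weight,
            "total_events": self.total_events,
            "corrected_to_truth": self.corrected_to_truth,
            "detected": self.detected,
            "miscorrected": self.miscorrected,
            "fraction_miscorrected": self.fraction_miscorrected,
        }


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, b in enumerate(seq):
        if b in _ENC:
            out[i] = _ENC[b]
        elif b == "N":
            out[i] = _N_CODE
        else:
            raise ValueError(f"invalid base {b!r} in index read {seq!r}")
    return out


class Decoder:
    """Reusable decoder for one IndexSet (precomputes the encoded matrix)."""

    def __init__(self, indexset: IndexSet, max_mismatch: int = 1):
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        self.indexset = indexset
        self.max_mismatch = max_mismatch
        self.ids = indexset.index_ids()
        self.matrix = np.array(
            [[_ENC[b] for b in s] for s in indexset.indices], dtype=np.uint8
        )
        self._cache: dict[str, DecodeResult] = {}

    def distances(self, observed: str) -> np.ndarray:
        obs = _encode(observed)
        return (self.matrix != obs[None, :]).sum(axis=1)

    def decode(self, observed: str) -> DecodeResult:
        if len(observed) != self.matrix.shape[1]:
            raise ValueError(
                f"index read length {len(observed)} != index length "
                f"{self.matrix.shape[1]}"
            )
        hit = self._cache.get(observed)
        if hit is not None:
            return hit
        if observed.count("N") > 1:
            res = DecodeResult(status="unassigned", reason="more than one N")
            self._cache[observed] = res
            return res
        d = self.distances(observed)
        best = int(d.min())
        result: DecodeResult
        if best == 0:
            i = int(d.argmin())
            result = DecodeResult(
                status="exact",
                index_id=self.ids[i],
                index_seq=self.indexset.indices[i],
                distance=0,
            )
        elif best <= self.max_mismatch:
            # radius-1 spheres are disjoint at min distance 4, so the match
            # is unique; assert rather than assume for general sets
            candidates = np.flatnonzero(d == best)
            if len(candidates) == 1:
                i = int(candidates[0])
                seq = self.indexset.indices[i]
                pos = tuple(p for p in range(len(seq)) if observed[p] != seq[p])
                result = DecodeResult(
                    status="corrected",
                    index_id=self.ids[i],
                    index_seq=seq,
                    distance=best,
                    corrected_positions=pos,
                )
            else:
                result = DecodeResult(
                    status="unassigned",
                    distance=best,
                    reason="ambiguous match",
                )
        elif best <= 3:
            result = DecodeResult(
                status="detected",
                distance=best,
                reason=f"nearest index at distance {best}",
            )
        else:
            result = DecodeResult(
                status="unassigned",
                distance=best,
                reason=f"nearest index at distance {best}",
            )
        self._cache[observed] = result
        return result

    def decode_with_quality(
        self, observed: str, qualities: Sequence[int], q_min: int = 20
    ) -> DecodeResult:
        """Decode, rejecting corrections that rely on low-quality bases.

        An exact match is accepted regardless of quality (no correction was
        needed).  A result requiring correction is downgraded to unassigned
        when any base of the observed index read has Phred quality < q_min:
        a likely erroneous base makes a corrected assignment untrustworthy.
        """
        if len(qualities) != len(observed):
            raise ValueError("qualities length != read length")
        result = self.decode(observed)
        if result.status == "corrected" and min(qualities) < q_min:
            return DecodeResult(
                status="unassigned",
                distance=result.distance,
                reason="low-quality correction rejected",
            )
        return result


def decode(observed: str, indexset: IndexSet, max_mismatch: int = 1) -> DecodeResult:
    """Match one observed index read against an index set (see Decoder)."""
    return Decoder(indexset, max_mismatch=max_mismatch).decode(observed)


def decode_with_quality(
    observed: str,
    qualities: Sequence[int],
    indexset: IndexSet,
    q_min: int = 20,
    max_mismatch: int = 1,
) -> DecodeResult:
    """Quality-aware decode (see Decoder.decode_with_quality)."""
    return Decoder(indexset, max_mismatch=max_mismatch).decode_with_quality(
        observed, qualities, q_min=q_min
    )


def audit_errors(indexset: IndexSet, weight: int) -> ErrorAudit:
    """Exhaustively decode every weight-w substitution of every index.

    For each index, all C(8,w) * 3^w patterns (each chosen position changed
    to each of its 3 alternative bases) are decoded with single-error
    correction against the full set and tallied.  At minimum distance 4,
    weight-1 patterns are always corrected back and weight-2 patterns are
    never mis-corrected; weight-3 patterns are mis-corrected exactly when
    they rewrite 3 of the 4 differing positions of a distance-4 neighbour.
    """
    if weight not in (1, 2, 3):
        raise ValueError("weight must be 1, 2, or 3")
    matrix = np.array(
        [[_ENC[b] for b in s] for s in indexset.indices], dtype=np.uint8
    )
    n = matrix.shape[0]
    # all weight-w corruption patterns as (positions, deltas); delta in 1..3
    patterns = [
        (pos, deltas)
        for pos in itertools.combinations(range(WORD_LENGTH), weight)
        for deltas in itertools.product((1, 2, 3), repeat=weight)
    ]
    n_pat = len(patterns)
    pos_arr = np.array([p for p, _ in patterns], dtype=np.int64)
    delta_arr = np.array([d for _, d in patterns], dtype=np.uint8)

    corrected_to_truth = miscorrected = detected = 0
    for t in range(n):
        corrupted = np.broadcast_to(matrix[t], (n_pat, WORD_LENGTH)).copy()
        rows = np.arange(n_pat)[:, None]
        corrupted[rows, pos_arr] = (corrupted[rows, pos_arr] + delta_arr) % 4
        # distances of every corrupted word to every index: (n_pat, n)
        dist = (corrupted[:, None, :] != matrix[None, :, :]).sum(axis=2)
        best = dist.min(axis=1)
        within = best <= 1
        nearest = dist.argmin(axis=1)
        # radius-1 match is unique at min distance 4
        to_truth = within & (nearest == t)
        to_wrong = within & (nearest != t)
        corrected_to_truth += int(to_truth.sum())
        miscorrected += int(to_wrong.sum())
        detected += int((~within).sum())
    total = n * n_pat
    assert corrected_to_truth + miscorrected + detected == total
    return ErrorAudit(
        weight=weight,
        total_events=total,
        corrected_to_truth=corrected_to_truth,
        detected=detected,
        miscorrected=miscorrected,
    )


def distance_histogram(indexset: IndexSet) -> np.ndarray:
    """Histogram of pairwise Hamming distances 0..8 over unordered pairs."""
    seqs = list(indexset.indices)
    if not seqs:
        raise ValueError("empty index set")
    matrix = np.array([[_ENC[b] for b in s] for s in seqs], dtype=np.uint8)
    hist = np.zeros(WORD_LENGTH + 1, dtype=np.int64)
    for i in range(len(seqs)):
        d = (matrix[i + 1 :] != matrix[i]).sum(axis=1)
        np.add.at(hist, d, 1)
    return hist
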