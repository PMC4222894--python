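"""Quaternary Hamming (8,4) code construction.

The index design starts from a length-8 code over a 4-letter alphabet with
256 code words and minimum pairwise Hamming distance 4.  Such a code supports
single-error correction and double-error detection once its words are used as
DNA sample indices.

The default construction ("bitplane") pairs two words of the extended binary
Hamming [8,4,4] code position-wise into quaternary symbols ``q_i = 2*u_i + v_i``.
Because every nonzero extended-Hamming word has binary weight >= 4, any two
distinct quaternary words produced this way differ in at least 4 positions,
and 16 x 16 = 256 = 4^4 words are obtained — exactly the size of a quaternary
code with 4 data and 4 parity characters.

A component-wise mod-4 variant ("z4") of the same parity equations is also
registered.  It too attains minimum distance 4, but it leaves a different
set of filter survivors downstream (108 rather than 120 for the reference
offset word), so the bit-plane pairing is the default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "QuaternaryWord",
    "Codebook",
    "build_binary_hamming84",
    "build_quaternary_code",
    "hamming_distance",
    "register_construction",
]

#: A length-8 word over {0,1,2,3}; plain tuples keep the codebook hashable.
QuaternaryWord = tuple[int, ...]

WORD_LENGTH = 8
DATA_POSITIONS = (0, 1, 2, 3)
PARITY_POSITIONS = (4, 5, 6, 7)


@dataclass(frozen=True)
class Codebook:
    """An ordered collection of quaternary code words.

    Attributes
    ----------
    words
        The 256 code words, each a tuple of 8 symbols in {0,1,2,3}.
    construction_id
        Registry label of the construction that produced the words.
    data_positions, parity_positions
        Disjoint position sets partitioning 0..7 (4 positions each), after
        any layout permutation has been applied.
    """

    words: tuple[QuaternaryWord, ...]
    construction_id: str
    data_positions: tuple[int, ...] = DATA_POSITIONS
    parity_positions: tuple[int, ...] = PARITY_POSITIONS

    def __len__(self) -> int:
        return len(self.words)

    def min_distance(self) -> int:
        """Minimum pairwise Hamming distance, by exhaustive comparison."""
        return min(
            hamming_distance(a, b) for a, b in itertools.combinations(self.words, 2)
        )


def build_binary_hamming84() -> list[tuple[int, ...]]:
    """Build the 16 words of the extended binary Hamming [8,4,4] code.

    Layout is (d1,d2,d3,d4,p1,p2,p3,p4) with parities
    ``p1=d1^d2^d4``, ``p2=d1^d3^d4``, ``p3=d2^d3^d4`` and overall parity
    ``p4`` making the total weight even.
    """
    words = []
    for d1, d2, d3, d4 in itertools.product((0, 1), repeat=4):
        p1 = d1 ^ d2 ^ d4
        p2 = d1 ^ d3 ^ d4
        p3 = d2 ^ d3 ^ d4
        p4 = d1 ^ d2 ^ d3 ^ d4 ^ p1 ^ p2 ^ p3
        words.append((d1, d2, d3, d4, p1, p2, p3, p4))
    return words


def _construct_bitplane() -> list[QuaternaryWord]:
    binary = build_binary_hamming84()
    return [
        tuple(2 * u + v for u, v in zip(a, b))
        for a in binary
        for b in binary
    ]


def _construct_z4() -> list[QuaternaryWord]:
    # Same parity equations read modulo 4; also min distance 4, but its
    # coset survives the filters differently from the bit-plane default.
    words = []
    for data in itertools.product(range(4), repeat=4):
        d1, d2, d3, d4 = data
        p1 = (d1 + d2 + d4) % 4
        p2 = (d1 + d3 + d4) % 4
        p3 = (d2 + d3 + d4) % 4
        p4 = (d1 + d2 + d3 + d4 + p1 + p2 + p3) % 4
        words.append((d1, d2, d3, d4, p1, p2, p3, p4))
    return words


_CONSTRUCTIONS: dict[str, Callable[[], list[QuaternaryWord]]] = {
    "bitplane": _construct_bitplane,
    "z4": _construct_z4,
}


def register_construction(name: str, builder: Callable[[], list[QuaternaryWord]]) -> None:
    """Register an additional code-construction variant under ``name``."""
    _CONSTRUCTIONS[name] = builder


def build_quaternary_code(
    construction_id: str = "bitplane",
    layout: Sequence[int] | None = None,
) -> Codebook:
    """Build the 256-word quaternary code.

    Parameters
    ----------
    construction_id
        Registered construction variant.  The default "bitplane" attains the
        minimum distance 4 required for single-error correction.
    layout
        Optional permutation of 0..7 applied to every word.  Permuting
        positions preserves all pairwise distances but changes which words
        survive the position-sensitive homopolymer filters downstream.
    """
    try:
        builder = _CONSTRUCTIONS[construction_id]
    except KeyError:
        raise ValueError(
            f"unknown construction {construction_id!r}; "
            f"registered: {sorted(_CONSTRUCTIONS)}"
        ) from None
    words = builder()
    data_pos, parity_pos = DATA_POSITIONS, PARITY_POSITIONS
    if layout is not None:
        perm = tuple(layout)
        if sorted(perm) != list(range(WORD_LENGTH)):
            raise ValueError("layout must be a permutation of 0..7")
        words = [tuple(w[p] for p in perm) for w in words]
        inv = [0] * WORD_LENGTH
        for new, old in enumerate(perm):
            inv[old] = new
        data_pos = tuple(sorted(inv[p] for p in DATA_POSITIONS))
        parity_pos = tuple(sorted(inv[p] for p in PARITY_POSITIONS))
    return Codebook(
        words=tuple(words),
        construction_id=construction_id,
        data_positions=data_pos,
        parity_positions=parity_pos,
    )


def hamming_distance(a: Sequence, b: Sequence) -> int:
    """Number of positions at which two equal-length sequences differ.

    Accepts DNA strings and symbol tuples alike; comparison is per position
    over the 4-letter alphabet, never bit-level.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))
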