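"""Combinatorial codon/polycodon arrangements and random strand assembly.

Once the first codons existed, wet/dry cycling at a hydrothermal setting
could link them into longer chains.  Two desk-scale combinatorial facts
frame the model: the four primordial GNC codons admit 4! = 24 ordered
arrangements and C(4,2) = 6 unordered pairings, and six chains admit
6! = 720 ordered arrangements.  ``enumerate_arrangements`` and
``enumerate_chain_pairs`` reproduce these counts exactly; the printed
numbers match the permutation/pair reading, so the operations are named
neutrally ("arrangements", "pairs") rather than "combinations".

``assemble_strands`` is the stochastic counterpart: strands are built by
drawing codons uniformly with replacement from a stage's sense repertoire,
with lengths uniform over the codon counts that fit a nucleotide range —
30–80 nt for pre-mRNA, 70–100 nt for the first mRNA genes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, TypeVar

import numpy as np

from .codec import encode_codon
from .tables import Stage, stage_table

__all__ = [
    "PRE_MRNA_LENGTH_NT",
    "MRNA_LENGTH_NT",
    "PolycodonChain",
    "Strand",
    "enumerate_arrangements",
    "enumerate_chain_pairs",
    "codon_count_range",
    "assemble_strands",
]

T = TypeVar("T")

#: Default nucleotide length ranges: short pre-mRNA strands and the first
#: mRNA genes.
PRE_MRNA_LENGTH_NT = (30, 80)
MRNA_LENGTH_NT = (70, 100)

_MAX_ARRANGEMENT_ITEMS = 8  # n! guard


@dataclass(frozen=True)
class PolycodonChain:
    """An ordered, non-empty chain of codons with its provenance
    (exhaustive enumeration vs. stochastic simulation)."""

    codons: tuple[str, ...]
    origin: str = "enumeration"

    def __post_init__(self) -> None:
        if not self.codons:
            raise ValueError("polycodon chain must be non-empty")


@dataclass(frozen=True)
class Strand:
    """An ordered codon sequence (pre-mRNA or mRNA) tied to a code stage."""

    codons: tuple[str, ...]
    stage: Stage

    @property
    def length_nt(self) -> int:
        return 3 * len(self.codons)

    @property
    def letters(self) -> str:
        return "".join(self.codons)

    @property
    def numeric(self) -> str:
        return "".join(encode_codon(c) for c in self.codons)


def _check_items(items: Sequence[T]) -> None:
    if len(set(items)) != len(items):
        raise ValueError(f"items must be distinct, got {list(items)!r}")
    if len(items) > _MAX_ARRANGEMENT_ITEMS:
        raise ValueError(
            f"refusing to enumerate arrangements of {len(items)} items "
            f"(limit {_MAX_ARRANGEMENT_ITEMS}); {len(items)}! is too large"
        )


def enumerate_arrangements(items: Sequence[T]) -> list[tuple[T, ...]]:
    """All n! orderings of *items*, each using every element exactly once.

    Output is deterministic: lexicographic with respect to the input
    order of the elements.  Four codons yield 24 arrangements; six chains
    yield 720.
    """
    _check_items(items)
    return list(itertools.permutations(items))


def enumerate_chain_pairs(items: Sequence[T]) -> list[tuple[T, T]]:
    """All n(n−1)/2 unordered pairs of *items* (four codons yield six
    pairings), in lexicographic input order."""
    _check_items(items)
    return list(itertools.combinations(items, 2))


def codon_count_range(length_range_nt: tuple[int, int]) -> tuple[int, int]:
    """Shrink a nucleotide range onto whole codons: ceil(lo/3) to
    floor(hi/3), so every strand honors the stated nucleotide bounds."""
    lo, hi = length_range_nt
    if lo < 3 or hi < lo:
        raise ValueError(f"invalid nucleotide length range {length_range_nt}")
    lo_c, hi_c = math.ceil(lo / 3), math.floor(hi / 3)
    if lo_c > hi_c:
        raise ValueError(
            f"no codon-multiple length lies within {length_range_nt} nt"
        )
    return lo_c, hi_c


def assemble_strands(
    stage: Stage | str,
    n_strands: int,
    length_range_nt: tuple[int, int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[Strand]:
    """Assemble *n_strands* random strands from a stage's sense codons.

    Codons are drawn uniformly with replacement; strand length (in
    codons) is uniform over the counts whose nucleotide length lies in
    the codon-rounded range.  Defaults: 30–80 nt for GNC/SNS (pre-mRNA),
    70–100 nt for UG (mRNA).  Reproducible given a seed.
    """
    stage = Stage.coerce(stage)
    if length_range_nt is None:
        length_range_nt = MRNA_LENGTH_NT if stage is Stage.UG else PRE_MRNA_LENGTH_NT
    lo_c, hi_c = codon_count_range(length_range_nt)
    alphabet = sorted(stage_table(stage).sense, key=encode_codon)
    if not alphabet:
        raise ValueError(f"stage {stage.value} has no sense codons")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    strands = []
    for _ in range(n_strands):
        n_codons = int(rng.integers(lo_c, hi_c + 1))
        idx = rng.integers(len(alphabet), size=n_codons)
        strands.append(Strand(tuple(alphabet[i] for i in idx), stage))
    return strands
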