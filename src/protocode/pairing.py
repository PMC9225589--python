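"""Watson–Crick pairing, anticodon↔codon mapping, and the tRNA/aaRS model.

The first of the two tRNA codes is purely chemical: an anticodon creates
its codon by antiparallel Watson–Crick base pairing (A–U, G–C).
Anticodons are stored 5′→3′, so the cognate codon of an anticodon is its
reverse complement and the mapping is an involution.

The second code is enzymatic: an aminoacyl-tRNA synthetase (aaRS) charges
each tRNA with the amino acid cognate to its anticodon.  There is one
synthetase per amino acid; within a stage the synthetases partition the
sense-codon anticodons.  Charging may be given a mischarge probability,
modelling the limited fidelity of the early machines; a mischarge attaches
a uniformly random non-cognate amino acid from the stage repertoire and is
flagged on the resulting tRNA.

One tRNA species exists per sense codon — wobble reading, by which modern
organisms decode 61 codons with 23–46 tRNAs, is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .codec import InvalidCodonError, encode_codon
from .tables import Stage, stage_table

__all__ = [
    "TRNA",
    "AaRS",
    "complement_base",
    "anticodon_for_codon",
    "build_trna_pool",
    "build_aars_set",
    "charge_trna",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def complement_base(b: str) -> str:
    """Watson–Crick complement of a single base (A↔U, G↔C)."""
    try:
        return _COMPLEMENT[b.upper().replace("T", "U")]
    except KeyError:
        raise InvalidCodonError(f"invalid base {b!r}") from None


def anticodon_for_codon(codon: str) -> str:
    """The anticodon pairing with *codon*, reported 5′→3′.

    Antiparallel pairing makes this the reverse complement, hence an
    involution: the anticodon of the anticodon is the codon itself.
    """
    encode_codon(codon)  # validate length and alphabet
    return "".join(complement_base(b) for b in reversed(codon.upper().replace("T", "U")))


@dataclass(frozen=True)
class TRNA:
    """An adaptor molecule carrying an anticodon and, once charged, one
    amino-acid symbol.

    ``stage_class`` is ``"pre-tRNA"`` in the GNC stage and ``"tRNA"``
    afterwards.  ``mischarged`` records whether a charging error was
    injected; a correctly charged tRNA always carries the stage table's
    assignment for its cognate codon.
    """

    anticodon: str
    stage_class: str
    charged_amino_acid: Optional[str] = None
    mischarged: bool = False

    @property
    def cognate_codon(self) -> str:
        return anticodon_for_codon(self.anticodon)

    @property
    def charged(self) -> bool:
        return self.charged_amino_acid is not None


@dataclass(frozen=True)
class AaRS:
    """An aminoacyl-tRNA synthetase serving exactly one amino acid.

    ``recognized_anticodons`` holds the anticodons of every sense codon
    assigned to that amino acid at the stage; across a stage the
    synthetases are disjoint and jointly cover all sense-codon anticodons.
    """

    stage_class: str
    amino_acid: str
    recognized_anticodons: frozenset[str]


def _stage_class(stage: Stage, enzyme: bool = False) -> str:
    if stage is Stage.GNC:
        return "pre-aaRS" if enzyme else "pre-tRNA"
    return "aaRS" if enzyme else "tRNA"


def build_trna_pool(stage: Stage | str) -> list[TRNA]:
    """One uncharged tRNA per sense codon of the stage (4, 16 or 61
    species), ordered by numeric codon."""
    stage = Stage.coerce(stage)
    cls = _stage_class(stage)
    codons = sorted(stage_table(stage).sense, key=encode_codon)
    return [TRNA(anticodon=anticodon_for_codon(c), stage_class=cls) for c in codons]


def build_aars_set(stage: Stage | str) -> list[AaRS]:
    """The stage's synthetases: one per amino acid, each recognizing the
    anticodons of all codons assigned to that acid."""
    stage = Stage.coerce(stage)
    cls = _stage_class(stage, enzyme=True)
    by_aa: dict[str, set[str]] = {}
    for codon, aa in stage_table(stage).sense.items():
        by_aa.setdefault(aa, set()).add(anticodon_for_codon(codon))
    return [
        AaRS(stage_class=cls, amino_acid=aa, recognized_anticodons=frozenset(acs))
        for aa, acs in sorted(by_aa.items())
    ]


def charge_trna(
    t: TRNA,
    stage: Stage | str,
    error_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> TRNA:
    """Charge *t* with an amino acid.

    With probability ``1 - error_rate`` the cognate amino acid (per the
    stage table) is attached; otherwise a uniformly random *other* stage
    amino acid is attached and the tRNA is flagged as mischarged.

    Parameters
    ----------
    t
        An uncharged tRNA.
    error_rate
        Mischarge probability in [0, 1).
    rng
        A seeded :class:`numpy.random.Generator` (or an int seed); only
        consulted when ``error_rate > 0``.
    """
    if t.charged:
        raise ValueError(f"tRNA {t.anticodon} is already charged")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    stage = Stage.coerce(stage)
    table = stage_table(stage)
    codon = t.cognate_codon
    cognate = table.sense.get(codon)
    if cognate is None:
        raise ValueError(f"codon {codon} is not a sense codon at stage {stage.value}")
    if error_rate == 0.0:
        return replace(t, charged_amino_acid=cognate, mischarged=False)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if rng.random() >= error_rate:
        return replace(t, charged_amino_acid=cognate, mischarged=False)
    others = sorted(table.amino_acids - {cognate})
    wrong = others[rng.integers(len(others))]
    return replace(t, charged_amino_acid=wrong, mischarged=True)
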