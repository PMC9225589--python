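"""The three staged genetic-code tables: GNC, SNS, and universal.

The model of code origin treated here holds that codon→amino-acid
assignments accumulated in three nested stages, each operated by a
progressively more capable translation machine:

* **GNC** — the primordial four-codon code of the GADV hypothesis
  (GGC→G, GCC→A, GAC→D, GUC→V), run by the pre-tRNA/pre-aaRS machine.
* **SNS** — the transitional sixteen-codon code in which the first and
  third bases are restricted to the strong (triple-hydrogen-bonded) bases
  G and C, encoding ten amino acids; run by the tRNA/aaRS machine.
* **UG** — the universal genetic code: 61 sense codons for 20 amino acids
  plus the three stops, run by the tRNA/aaRS/ribosome machine.

Assignments never change between stages; they only accumulate
(GNC ⊂ SNS ⊂ UG as mappings).  The three stop codons carry the
single-letter stop symbols J (opal, UGA), X (ochre, UAA) and Z (amber,
UAG) and exist only at the UG stage.

The tables are stored once as literal data so the package is
self-contained; tests cross-check the UG table against Biopython's
standard codon table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

from .codec import encode_codon

__all__ = [
    "Stage",
    "CodeTable",
    "STOP_LETTERS",
    "stage_table",
    "amino_acid_for",
    "new_codons",
    "redundancy",
    "stop_codons",
    "render_matrix",
    "table_rows",
    "stage_introduced",
]


class Stage(enum.Enum):
    """Code stage, totally ordered GNC < SNS < UG."""

    GNC = "GNC"
    SNS = "SNS"
    UG = "UG"

    @property
    def index(self) -> int:
        return _STAGE_ORDER.index(self)

    @property
    def previous(self) -> Optional["Stage"]:
        i = self.index
        return _STAGE_ORDER[i - 1] if i > 0 else None

    def __lt__(self, other: "Stage") -> bool:
        if not isinstance(other, Stage):
            return NotImplemented
        return self.index < other.index

    @classmethod
    def coerce(cls, value: "Stage | str") -> "Stage":
        if isinstance(value, Stage):
            return value
        return cls(str(value).upper())


_STAGE_ORDER = (Stage.GNC, Stage.SNS, Stage.UG)

#: Stop letters: J = opal (UGA), X = ochre (UAA), Z = amber (UAG).
STOP_LETTERS = MappingProxyType({"UGA": "J", "UAA": "X", "UAG": "Z"})

MACHINE_LABELS = MappingProxyType(
    {
        Stage.GNC: "pre-tRNA/pre-aaRS",
        Stage.SNS: "tRNA/aaRS",
        Stage.UG: "tRNA/aaRS/ribosome",
    }
)

# Stage-1 GNC assignments (the GADV codons).
_GNC = {
    "GGC": "G",
    "GCC": "A",
    "GAC": "D",
    "GUC": "V",
}

# Stage-2 additions: the remaining S-N-S codons (first and third base G/C).
_SNS_NEW = {
    "GGG": "G",
    "GCG": "A",
    "GUG": "V",
    "GAG": "E",
    "CAG": "Q",
    "CUC": "L",
    "CUG": "L",
    "CCC": "P",
    "CCG": "P",
    "CAC": "H",
    "CGC": "R",
    "CGG": "R",
}

# Stage-3 additions: the 45 remaining sense codons of the standard code.
_UG_NEW = {
    "GGU": "G", "GGA": "G",
    "GCU": "A", "GCA": "A",
    "GAU": "D",
    "GUU": "V", "GUA": "V",
    "GAA": "E",
    "CAA": "Q",
    "UUA": "L", "UUG": "L", "CUU": "L", "CUA": "L",
    "CCU": "P", "CCA": "P",
    "CAU": "H",
    "CGU": "R", "CGA": "R", "AGA": "R", "AGG": "R",
    "AAU": "N", "AAC": "N",
    "UGU": "C", "UGC": "C",
    "AUU": "I", "AUC": "I", "AUA": "I",
    "AAA": "K", "AAG": "K",
    "AUG": "M",
    "UUU": "F", "UUC": "F",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S", "AGU": "S", "AGC": "S",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "UGG": "W",
    "UAU": "Y", "UAC": "Y",
}

_SENSE_BY_STAGE = {
    Stage.GNC: MappingProxyType(dict(_GNC)),
    Stage.SNS: MappingProxyType({**_GNC, **_SNS_NEW}),
    Stage.UG: MappingProxyType({**_GNC, **_SNS_NEW, **_UG_NEW}),
}


@dataclass(frozen=True)
class CodeTable:
    """An immutable stage table.

    ``assignments`` maps every codon in the stage's repertoire to its
    one-letter symbol; at the UG stage this includes the three stop codons
    mapped to their stop letters.  ``sense`` excludes stops.
    """

    stage: Stage
    assignments: Mapping[str, str]
    machine_label: str
    sense: Mapping[str, str] = field(repr=False, default=None)  # type: ignore[assignment]
    amino_acids: frozenset[str] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sense = MappingProxyType(
            {c: a for c, a in self.assignments.items() if c not in STOP_LETTERS}
        )
        object.__setattr__(self, "sense", sense)
        object.__setattr__(self, "amino_acids", frozenset(sense.values()))

    def __contains__(self, codon: str) -> bool:
        return codon in self.assignments


def _build_table(stage: Stage) -> CodeTable:
    assignments = dict(_SENSE_BY_STAGE[stage])
    if stage is Stage.UG:
        assignments.update(STOP_LETTERS)
    return CodeTable(
        stage=stage,
        assignments=MappingProxyType(assignments),
        machine_label=MACHINE_LABELS[stage],
    )


_TABLES = {stage: _build_table(stage) for stage in _STAGE_ORDER}


def stage_table(stage: Stage | str) -> CodeTable:
    """Return the fixed, immutable code table for *stage*."""
    return _TABLES[Stage.coerce(stage)]


def amino_acid_for(codon: str, stage: Stage | str) -> Optional[str]:
    """The stage's symbol for *codon*, or ``None`` when the codon is not
    yet in the stage's table (an uncoded, "white circle" codon).

    Absence is a value, not an error: at the GNC stage 60 of the 64 codons
    are simply not part of the code yet.
    """
    return stage_table(stage).assignments.get(codon)


def new_codons(stage: Stage | str, include_stops: bool = False) -> frozenset[str]:
    """Codons introduced at *stage* (absent from the previous stage).

    By default only sense codons are counted — the encoded deltas 4, 12
    and 45 for GNC, SNS and UG.  With ``include_stops=True`` the UG delta
    also contains the three stop codons (48 in total), which enter the
    64-codon table at that stage without ever being encoded.
    """
    stage = Stage.coerce(stage)
    table = stage_table(stage)
    pool = table.assignments if include_stops else table.sense
    prev = stage.previous
    prev_codons = set(stage_table(prev).assignments) if prev else set()
    return frozenset(c for c in pool if c not in prev_codons)


def redundancy(stage: Stage | str) -> dict[str, int]:
    """Number of sense codons per amino acid at *stage*.

    Stops code no amino acid and are excluded; at the UG stage the counts
    sum to 61.
    """
    counts: dict[str, int] = {}
    for aa in stage_table(stage).sense.values():
        counts[aa] = counts.get(aa, 0) + 1
    return counts


def stop_codons() -> Mapping[str, str]:
    """The three stop codons mapped to their stop letters
    (UGA→J opal, UAA→X ochre, UAG→Z amber)."""
    return STOP_LETTERS


def stage_introduced(codon: str) -> Optional[Stage]:
    """The earliest stage whose table contains *codon*, or ``None`` for a
    codon that never enters the code (impossible for valid codons, since
    the UG table covers all 64)."""
    for stage in _STAGE_ORDER:
        if codon in stage_table(stage):
            return stage
    return None


def table_rows(stage: Stage | str) -> list[dict[str, str]]:
    """One export row per codon of the stage table: letters, numeric form,
    symbol, kind (sense/stop), and the stage that introduced the codon.
    Rows are ordered numerically (111, 112, … 444)."""
    table = stage_table(stage)
    rows = []
    for codon, symbol in table.assignments.items():
        rows.append(
            {
                "codon": codon,
                "numeric": encode_codon(codon),
                "symbol": symbol,
                "kind": "stop" if codon in STOP_LETTERS else "sense",
                "stage_introduced": stage_introduced(codon).value,
            }
        )
    rows.sort(key=lambda r: r["numeric"])
    return rows


def render_matrix(stage: Stage | str) -> str:
    """Render the stage table as a 16×4 numeric-codon grid.

    Rows run over (first base, third base) and columns over the second
    base, all in digit order 1..4, so redundancy blocks line up visually.
    Each of the 64 cells shows the numeric codon and its one-letter symbol
    (stop letters included), or ``·`` when the codon is not yet in the
    stage's code.
    """
    from .codec import DIGITS, decode_codon

    table = stage_table(stage)
    header = "1st\\2nd,3rd" + "".join(f"   {d}  " for d in DIGITS)
    lines = [header]
    for d1 in DIGITS:
        for d3 in DIGITS:
            cells = []
            for d2 in DIGITS:
                numeric = d1 + d2 + d3
                symbol = table.assignments.get(decode_codon(numeric), "·")
                cells.append(f"{numeric} {symbol}")
            lines.append(f"  {d1}..{d3}   " + "  ".join(cells))
    return "\n".join(lines)
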