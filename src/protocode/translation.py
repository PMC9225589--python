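"""Stage-appropriate translation of strands into peptides.

Decoding is performed by the machine that matches the code stage: the
pre-tRNA/pre-aaRS machine for GNC, the tRNA/aaRS machine for SNS, and the
full tRNA/aaRS/ribosome machine for the universal code.  Reading proceeds
5′→3′ from position 0 in a fixed frame; the model has no initiation
machinery, so AUG is just methionine.

Stop codons exist only at the universal stage, where they terminate
translation; at the GNC/SNS stages UAA/UAG/UGA are simply codons outside
the stage alphabet, handled like any other unknown codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assembly import Strand
from .codec import FrameError, decode_strand, encode_codon, is_numeric
from .tables import MACHINE_LABELS, STOP_LETTERS, Stage, stage_table

__all__ = ["Peptide", "UnknownCodonError", "MARK_SYMBOL", "translate", "machine_label"]

#: Placeholder inserted under ``unknown_policy="mark"``.  Deliberately not
#: a letter: X is already taken as the ochre stop symbol.
MARK_SYMBOL = "?"

_POLICIES = ("error", "skip", "mark")


class UnknownCodonError(ValueError):
    """A codon outside the stage's table, under the ``error`` policy."""


@dataclass(frozen=True)
class Peptide:
    """A translated amino-acid sequence.

    ``symbols`` never contains the stop letters J/X/Z: termination is
    metadata (``terminated_by_stop``), not a residue.
    """

    symbols: str
    terminated_by_stop: bool
    source_stage: Stage

    def __len__(self) -> int:
        return len(self.symbols)


def translate(
    strand: Strand | str,
    stage: Stage | str,
    unknown_policy: str = "error",
) -> Peptide:
    """Translate a strand under the stage's code.

    Accepts a :class:`~protocode.assembly.Strand`, an RNA letter string,
    or a numeric digit string (detected by alphabet).  Each codon is
    mapped through the stage table; at the universal stage a stop codon
    terminates translation.  Codons absent from a GNC/SNS table follow
    ``unknown_policy``: ``error`` (default) raises and names the codon
    and its offset, ``skip`` drops it, ``mark`` inserts ``?``.
    """
    stage = Stage.coerce(stage)
    if unknown_policy not in _POLICIES:
        raise ValueError(
            f"unknown_policy must be one of {_POLICIES}, got {unknown_policy!r}"
        )
    if isinstance(strand, Strand):
        letters = strand.letters
    else:
        letters = str(strand).upper().replace("T", "U")
        if is_numeric(letters):
            letters = decode_strand(letters)
    if len(letters) % 3:
        raise FrameError(f"strand length {len(letters)} is not a multiple of 3")
    table = stage_table(stage)
    symbols: list[str] = []
    terminated = False
    for i in range(0, len(letters), 3):
        codon = letters[i : i + 3]
        symbol = table.assignments.get(codon)
        if symbol is None:
            # validate so a malformed codon is a codec error, not "unknown"
            encode_codon(codon)
            if unknown_policy == "error":
                raise UnknownCodonError(
                    f"codon {codon} at offset {i} is not in the "
                    f"{stage.value} code"
                )
            if unknown_policy == "mark":
                symbols.append(MARK_SYMBOL)
            continue
        if codon in STOP_LETTERS:
            terminated = True
            break
        symbols.append(symbol)
    return Peptide(
        symbols="".join(symbols),
        terminated_by_stop=terminated,
        source_stage=stage,
    )


def machine_label(stage: Stage | str) -> str:
    """The translation machine operating at *stage*: pre-tRNA/pre-aaRS,
    tRNA/aaRS, or tRNA/aaRS/ribosome."""
    return MACHINE_LABELS[Stage.coerce(stage)]
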