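"""Numeric codon codec.

Nucleotide letters and digits are interchangeable representations of the
same codon under the fixed bijection U=1, C=2, A=3, G=4, which makes the
layout of the genetic-code table easy to scan numerically: the four
primordial GNC codons all start with 4, the transitional SNS codons start
with 4 or 2, and the remaining universal-code codons fill in prefixes
1 and 3.

The codec maps nucleotides only.  Amino-acid symbols — including the three
stop letters J, X and Z — belong to the code-table layer
(:mod:`protocode.tables`) and are never produced here.
"""

from __future__ import annotations

__all__ = [
    "BASES",
    "DIGITS",
    "BASE_TO_DIGIT",
    "DIGIT_TO_BASE",
    "InvalidCodonError",
    "FrameError",
    "encode_codon",
    "decode_codon",
    "encode_strand",
    "decode_strand",
    "is_numeric",
]

#: RNA bases in digit order (U=1, C=2, A=3, G=4).
BASES = "UCAG"
DIGITS = "1234"

BASE_TO_DIGIT = {"U": "1", "C": "2", "A": "3", "G": "4"}
DIGIT_TO_BASE = {d: b for b, d in BASE_TO_DIGIT.items()}


class InvalidCodonError(ValueError):
    """A codon string has the wrong length or an illegal character."""


class FrameError(ValueError):
    """A strand's length is not a multiple of three."""


def _normalize_letters(letters: str) -> str:
    # DNA tolerance: T is read as U; output is always RNA.
    return letters.upper().replace("T", "U")


def encode_codon(letters: str) -> str:
    """Encode a letter codon (e.g. ``"GGC"``) as its numeric form (``"442"``).

    Input is case-insensitive and accepts ``T`` as a synonym for ``U``.

    Raises
    ------
    InvalidCodonError
        If the input is not exactly three characters over ``{U, C, A, G}``
        (after DNA normalization); the message names the offending
        character.
    """
    norm = _normalize_letters(letters)
    if len(norm) != 3:
        raise InvalidCodonError(
            f"codon must have exactly 3 bases, got {len(norm)}: {letters!r}"
        )
    out = []
    for ch in norm:
        try:
            out.append(BASE_TO_DIGIT[ch])
        except KeyError:
            raise InvalidCodonError(
                f"invalid base {ch!r} in codon {letters!r}; expected U/C/A/G"
            ) from None
    return "".join(out)


def decode_codon(numeric: str) -> str:
    """Decode a numeric codon (e.g. ``"234"``) to letters (``"CAG"``).

    Inverse of :func:`encode_codon`.
    """
    if len(numeric) != 3:
        raise InvalidCodonError(
            f"numeric codon must have exactly 3 digits, got {len(numeric)}: "
            f"{numeric!r}"
        )
    out = []
    for ch in numeric:
        try:
            out.append(DIGIT_TO_BASE[ch])
        except KeyError:
            raise InvalidCodonError(
                f"invalid digit {ch!r} in numeric codon {numeric!r}; "
                f"expected 1/2/3/4"
            ) from None
    return "".join(out)


def encode_strand(letters: str) -> str:
    """Encode a whole RNA strand codon by codon, preserving order.

    Raises
    ------
    FrameError
        If the strand length is not a multiple of 3.
    InvalidCodonError
        If any character is not a valid base.
    """
    norm = _normalize_letters(letters)
    if len(norm) % 3:
        raise FrameError(
            f"strand length {len(norm)} is not a multiple of 3"
        )
    return "".join(
        encode_codon(norm[i : i + 3]) for i in range(0, len(norm), 3)
    )


def decode_strand(numeric: str) -> str:
    """Decode a numeric strand back to RNA letters (inverse of
    :func:`encode_strand`)."""
    if len(numeric) % 3:
        raise FrameError(
            f"numeric strand length {len(numeric)} is not a multiple of 3"
        )
    return "".join(
        decode_codon(numeric[i : i + 3]) for i in range(0, len(numeric), 3)
    )


def is_numeric(s: str) -> bool:
    """True if *s* is written in the digit alphabet (1–4) rather than
    letters.  The empty string counts as numeric (both decodings agree)."""
    return all(ch in DIGIT_TO_BASE for ch in s)
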