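"""Stage-appropriate translation of strands into peptides."""

import pytest

from protocode.assembly import assemble_strands
from protocode.codec import FrameError, InvalidCodonError
from protocode.tables import Stage, stage_table
from protocode.translation import (
    MARK_SYMBOL,
    UnknownCodonError,
    machine_label,
    translate,
)

STAGE2_NUMERIC = "444424414434234212214222224232242244"


def test_gadv_strand_translates_under_gnc():
    pep = translate("GGCGCCGACGUC", Stage.GNC)
    assert pep.symbols == "GADV"
    assert not pep.terminated_by_stop
    assert pep.source_stage is Stage.GNC


def test_stage2_numeric_listing_translates_in_printed_order():
    """The twelve transitional-code codons, read numerically, give the
    amino-acid order G,A,V,E,Q,L,L,P,P,H,R,R."""
    assert translate(STAGE2_NUMERIC, Stage.UG).symbols == "GAVEQLLPPHRR"
    # numeric and letter inputs agree
    letters = "".join(
        translate(STAGE2_NUMERIC[i : i + 3], Stage.UG).symbols
        for i in range(0, len(STAGE2_NUMERIC), 3)
    )
    assert letters == "GAVEQLLPPHRR"


def test_stop_terminates_translation_at_ug():
    pep = translate("GGCUAAGGC", Stage.UG)
    assert pep.symbols == "G"
    assert pep.terminated_by_stop
    assert "X" not in pep.symbols  # stop letters never appear as residues


def test_length_law():
    # no stop: peptide length equals codon count
    assert len(translate("GGC" * 7, Stage.UG)) == 7
    # internal stop at codon i: peptide length is i
    strand = "GGC" * 3 + "UGA" + "GGC" * 5
    pep = translate(strand, Stage.UG)
    assert len(pep) == 3 and pep.terminated_by_stop


def test_stops_are_unknown_codons_before_the_universal_stage():
    with pytest.raises(UnknownCodonError):
        translate("UAA", Stage.SNS)
    assert translate("GGCUAA", Stage.SNS, unknown_policy="skip").symbols == "G"


def test_unknown_policy_handling():
    strand = "GGCUUUGCC"  # UUU is outside the GNC code
    with pytest.raises(UnknownCodonError, match="UUU at offset 3"):
        translate(strand, Stage.GNC)
    assert translate(strand, Stage.GNC, unknown_policy="skip").symbols == "GA"
    marked = translate(strand, Stage.GNC, unknown_policy="mark").symbols
    assert marked == f"G{MARK_SYMBOL}A"
    with pytest.raises(ValueError, match="unknown_policy"):
        translate(strand, Stage.GNC, unknown_policy="drop")


def test_malformed_input_is_a_codec_error_not_unknown():
    with pytest.raises(FrameError):
        translate("GGCG", Stage.UG)
    with pytest.raises(InvalidCodonError):
        translate("GNC", Stage.UG, unknown_policy="skip")


def test_aug_is_just_methionine():
    pep = translate("AUGGGC", Stage.UG)
    assert pep.symbols == "MG"  # no initiation logic


def test_translation_is_many_to_one_for_leucine_peptides():
    """Degeneracy witness: any UG peptide containing leucine has at least
    two distinct coding strands (swap among the six leucine codons)."""
    leu_codons = [c for c, a in stage_table(Stage.UG).sense.items() if a == "L"]
    peptide = "MLG"
    strand_a = "AUG" + leu_codons[0] + "GGC"
    strand_b = "AUG" + leu_codons[1] + "GGC"
    assert strand_a != strand_b
    assert translate(strand_a, Stage.UG).symbols == peptide
    assert translate(strand_b, Stage.UG).symbols == peptide


@pytest.mark.parametrize("stage", list(Stage))
def test_assembled_strands_translate_without_unknown_codons(stage):
    """Alphabet closure: strands assembled at a stage always translate
    under that stage's code."""
    for strand in assemble_strands(stage, 25, rng=13):
        pep = translate(strand, stage)
        assert len(pep) == len(strand.codons)  # no stops drawn: sense only
        # numeric form of the same strand gives the same peptide
        assert translate(strand.numeric, stage).symbols == pep.symbols


@pytest.mark.parametrize(
    "stage,label",
    [
        (Stage.GNC, "pre-tRNA/pre-aaRS"),
        (Stage.SNS, "tRNA/aaRS"),
        (Stage.UG, "tRNA/aaRS/ribosome"),
    ],
)
def test_machine_labels(stage, label):
    assert machine_label(stage) == label
    assert stage_table(stage).machine_label == label
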