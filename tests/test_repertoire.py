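"""Repertoire classification, motif validation and θ maturation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defensinevo import (
    MotifSpec,
    PrecursorPartition,
    PseudoReason,
    Status,
    classify_coding_sequence,
    excise_nonapeptide,
    mature_theta,
    validate_motif,
)
from defensinevo.genetics import PREFERRED_CODON, translate
from defensinevo.simulate import TEMPLATE_PROTEIN

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def _template_cds() -> str:
    return "".join(PREFERRED_CODON[aa] for aa in TEMPLATE_PROTEIN)


class TestClassification:
    def test_intact_orf_is_functional(self):
        cds = _template_cds()
        assert len(cds) == 94 * 3
        cls = classify_coding_sequence(cds, 94)
        assert cls.status is Status.FUNCTIONAL
        assert cls.pseudo_reason is PseudoReason.NONE
        assert cls.stop_site is None

    def test_nonsense_at_codon_17_pseudogenizes(self):
        # the loss-of-function lesion seen in hominoid θ-defensin pseudogenes
        cds = _template_cds()
        mutant = cds[: 3 * 16] + "TAA" + cds[3 * 17 :]
        cls = classify_coding_sequence(mutant, 94)
        assert cls.status is Status.PSEUDOGENE
        assert cls.pseudo_reason is PseudoReason.PREMATURE_STOP
        assert cls.stop_site == 17

    def test_single_nt_deletion_is_frameshift(self):
        cds = _template_cds()
        mutant = cds[: 3 * 29] + cds[3 * 29 + 1 :]
        cls = classify_coding_sequence(mutant, 94)
        assert cls.status is Status.PSEUDOGENE
        assert cls.pseudo_reason is PseudoReason.FRAMESHIFT

    def test_codon_multiple_indel_is_not_frameshift(self):
        # whole-codon deletion keeps the frame: judged against the family
        # alignment, the length deviation is a multiple of 3
        cds = _template_cds()
        mutant = cds[: 3 * 29] + cds[3 * 30 :]
        cls = classify_coding_sequence(mutant, 94)
        assert cls.status is Status.FUNCTIONAL

    def test_theta_defining_stop_keeps_gene_functional(self):
        # Q77*-style nonsense in the mature peptide creates a θ precursor
        cds = _template_cds()
        mutant = cds[: 3 * 76] + "TAA" + cds[3 * 77 :]
        cls = classify_coding_sequence(mutant, 94, theta_stop_site=77)
        assert cls.status is Status.FUNCTIONAL
        assert cls.is_theta_precursor
        assert cls.stop_site == 77
        # without θ awareness the same lesion is a pseudogene call
        plain = classify_coding_sequence(mutant, 94)
        assert plain.status is Status.PSEUDOGENE

    def test_theta_site_stop_without_motif_is_pseudogene(self):
        # a stop at the θ site only rescues genes whose upstream tail still
        # carries the nonapeptide motif
        protein = TEMPLATE_PROTEIN[:65] + "A" * 29  # cysteines erased
        cds = "".join(PREFERRED_CODON[aa] for aa in protein)
        mutant = cds[: 3 * 76] + "TAA" + cds[3 * 77 :]
        cls = classify_coding_sequence(mutant, 94, theta_stop_site=77)
        assert cls.status is Status.PSEUDOGENE
        assert cls.pseudo_reason is PseudoReason.PREMATURE_STOP

    @pytest.mark.parametrize("bad", ["", "ACGJ", "ACG!T"])
    def test_invalid_input_raises(self, bad):
        with pytest.raises(ValueError):
            classify_coding_sequence(bad, 10)


class TestMotifs:
    def test_anchor_counts(self):
        assert MotifSpec.alpha_mature().n_anchors == 6
        assert MotifSpec.theta_nonapeptide().n_anchors == 3
        assert MotifSpec.theta_nonapeptide_variant().n_anchors == 3

    @pytest.mark.parametrize(
        "peptide,kind,expected",
        [
            # minimal α instance: spacers 1,3,9,6 and the adjacent Cys5-Cys6
            ("CACAAACAAAAAAAAACAAAAAACC", "alpha_mature", True),
            # spacers at their upper bounds 1,4,9,9
            ("CACAAAACAAAAAAAAACAAAAAAAAACC", "alpha_mature", True),
            # five-cysteine string without the terminal Cys pair
            ("CACAAACAAAAAAAAACAAAAAAC", "alpha_mature", False),
            # published θ nonapeptides
            ("RCICRRGVC", "theta_nonapeptide", True),
            ("RCVCTRGVC", "theta_nonapeptide", True),
            ("RCICRRGVA", "theta_nonapeptide", False),
            # colobus 13-mer variant spacing
            ("ACACAAAAAAAAC", "theta_nonapeptide_variant", True),
            ("RCICRRGVC", "theta_nonapeptide_variant", False),
            # 'X' may fill wildcard slots but never an anchor
            ("XCXCXXXXC", "theta_nonapeptide", True),
            ("RCICRRGVX", "theta_nonapeptide", False),
        ],
    )
    def test_motif_examples(self, peptide, kind, expected):
        spec = getattr(MotifSpec, kind)()
        assert bool(validate_motif(peptide, spec)) is expected

    def test_empty_peptide_fails_quietly(self):
        assert not validate_motif("", MotifSpec.alpha_mature())

    def test_anchor_positions_are_cysteines(self):
        m = validate_motif("RCICRRGVC", MotifSpec.theta_nonapeptide())
        assert m.anchor_positions == (2, 4, 9)

    def test_hnp_like_mature_matches_alpha(self):
        mature = TEMPLATE_PROTEIN[64:]
        assert validate_motif(mature, MotifSpec.alpha_mature())

    @settings(max_examples=100, derandomize=True)
    @given(
        flank_left=st.text(alphabet=AA_LETTERS, max_size=15),
        flank_right=st.text(alphabet=AA_LETTERS, max_size=15),
    )
    def test_flanking_residues_never_break_a_match(self, flank_left, flank_right):
        spec = MotifSpec.theta_nonapeptide()
        core = "RCICRRGVC"
        assert validate_motif(flank_left + core + flank_right, spec)


class TestThetaMaturation:
    @pytest.mark.parametrize(
        "tail,nona,removed",
        [
            ("RCICRRGVCRLL", "RCICRRGVC", "RLL"),
            ("RCVCTRGVCQLL", "RCVCTRGVC", "QLL"),
            ("AAAAAAAAAXYZ", "AAAAAAAAA", "XYZ"),
        ],
    )
    def test_excision_trims_three_cterminal_residues(self, tail, nona, removed):
        got_nona, got_removed = excise_nonapeptide(tail)
        assert got_nona == nona
        assert got_removed == removed

    @pytest.mark.parametrize("bad", ["RCICRRGVC", "RCICRRGVCRLLX"])
    def test_excision_rejects_wrong_length(self, bad):
        with pytest.raises(ValueError):
            excise_nonapeptide(bad)

    @pytest.mark.parametrize(
        "a,b",
        [
            ("RCICRRGVC", "RCICRRGVC"),  # homodimer
            ("RCICRRGVC", "RCVCTRGVC"),  # heterodimer
            ("ACACAAAAC", "ACACAAAAC"),  # minimal valid motif
        ],
    )
    def test_cyclization_yields_octadecapeptide(self, a, b):
        cp = mature_theta(a, b)
        assert cp.length == len(a) + len(b) == 18
        assert cp.contains(a) and cp.contains(b)
        assert len(cp.disulfides) == 3
        for i, j in cp.disulfides:
            assert cp.sequence[i - 1] == "C" and cp.sequence[j - 1] == "C"

    def test_cycle_contains_subunits_from_every_rotation(self):
        cp = mature_theta("RCICRRGVC", "RCVCTRGVC")
        for rot in cp.rotations():
            doubled = rot + rot
            assert "RCICRRGVC" in doubled and "RCVCTRGVC" in doubled

    def test_antiparallel_ladder_crosses_subunits(self):
        cp = mature_theta("RCICRRGVC", "RCICRRGVC")
        # A-Cys1–B-Cys3, A-Cys2–B-Cys2, A-Cys3–B-Cys1
        assert cp.disulfides == ((2, 18), (4, 13), (9, 11))
        parallel = mature_theta("RCICRRGVC", "RCICRRGVC", connectivity="parallel")
        assert parallel.disulfides == ((2, 11), (4, 13), (9, 18))

    def test_motif_failing_subunit_rejected(self):
        with pytest.raises(ValueError):
            mature_theta("RCICRRGVA", "RCICRRGVC")


class TestPartition:
    def test_regions_cover_the_precursor(self):
        p = PrecursorPartition()
        assert [p.region_of(c) for c in (1, 19, 20, 64, 65, 94)] == [
            "signal", "signal", "prosegment", "prosegment", "mature", "mature",
        ]

    def test_disjoint_ordered_spans_enforced(self):
        with pytest.raises(ValueError):
            PrecursorPartition(signal=(1, 20), prosegment=(20, 64), mature=(65, 94))

    def test_template_translates_cleanly(self):
        cds = _template_cds()
        assert translate(cds) == TEMPLATE_PROTEIN
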