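import math

import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoscore import (
    DEFAULT_CONFIG,
    FEATURE_NAMES,
    FeatureError,
    ProteinSequence,
    aliphatic_index,
    avg_max_asa,
    avg_solubility,
    extract_features,
    gravy,
    instability_index,
    isoelectric_point,
    sulfur_count,
)
from thermoscore.features import ResidueClassConfig, _net_charge_at_ph
from thermoscore.tables import DIPEPTIDE_INSTABILITY, MAX_ASA, SOLUBILITY, STANDARD_AA

sequences = st.text(alphabet=STANDARD_AA, min_size=2, max_size=80).map(
    lambda s: ProteinSequence("h", s)
)


class TestCompositions:
    @pytest.mark.parametrize(
        "residues, expected",
        [
            ("KKEE", {"x_K": 0.5, "x_E": 0.5, "x_pos": 0.5, "x_neg": 0.5,
                      "x_charge": 1.0, "net_charge": 0.0}),
            ("ACDEFGHIKLMNPQRSTVWY", {f"x_{aa}": 0.05 for aa in STANDARD_AA} | {"L": 20.0}),
            ("TTDD", {"x_small": 1.0, "x_tiny": 0.0}),
        ],
    )
    def test_forced_composition_values(self, residues, expected):
        fv = extract_features(ProteinSequence("s", residues))
        for name, value in expected.items():
            assert fv[name] == pytest.approx(value, abs=1e-12)

    def test_feature_vector_is_complete_and_deterministic(self):
        seq = ProteinSequence("s", "MKVLYPQWERTASDFGHCIN")
        fv1, fv2 = extract_features(seq), extract_features(seq)
        assert fv1 == fv2
        assert tuple(fv1) == FEATURE_NAMES
        assert len(fv1) == 72  # non-predicted feature count

    @given(seq=sequences)
    @settings(max_examples=50, deadline=None)
    def test_conservation_and_class_consistency(self, seq):
        fv = extract_features(seq)
        n_std = sum(fv[f"c_{aa}"] for aa in STANDARD_AA)
        assert n_std == len(seq)
        assert math.isclose(sum(fv[f"x_{aa}"] for aa in STANDARD_AA), 1.0, abs_tol=1e-9)
        cfg = DEFAULT_CONFIG
        for cls in ("small", "tiny", "aromatic", "aliphatic", "hydrophobic", "polar"):
            members = getattr(cfg, cls)
            assert fv[f"x_{cls}"] == pytest.approx(
                sum(fv[f"x_{aa}"] for aa in members), abs=1e-12)
        assert all(0.0 <= fv[f"x_{cls}"] <= 1.0 for cls in
                   ("small", "tiny", "aromatic", "aliphatic", "hydrophobic", "polar"))

    def test_ambiguity_codes_excluded_from_denominator(self):
        fv = extract_features(ProteinSequence("s", "MKXX"))
        assert fv["L"] == 4.0
        assert fv["x_M"] == 0.5 and fv["x_K"] == 0.5
        assert math.isclose(sum(fv[f"x_{aa}"] for aa in STANDARD_AA), 1.0)

    def test_feature_vector_ignores_sequence_id(self):
        a = extract_features(ProteinSequence("one", "MKVLY"))
        b = extract_features(ProteinSequence("two", "MKVLY"))
        assert a == b


class TestScalarFeatures:
    @pytest.mark.parametrize("residues, expected", [("AAAA", 1.8), ("RRRR", -4.5)])
    def test_gravy_published_values(self, residues, expected):
        assert gravy(ProteinSequence("s", residues)) == pytest.approx(expected)

    @given(seq=sequences)
    @settings(max_examples=25, deadline=None)
    def test_gravy_matches_biopython(self, seq):
        assert gravy(seq) == pytest.approx(ProteinAnalysis(seq.residues).gravy())

    @pytest.mark.parametrize(
        "residues, expected",
        [("AAAA", 100.0), ("GGGG", 0.0), ("VL", 100 * (2.9 * 0.5 + 3.9 * 0.5))],
    )
    def test_aliphatic_index(self, residues, expected):
        assert aliphatic_index(ProteinSequence("s", residues)) == pytest.approx(expected)

    def test_instability_length_two_is_five_times_diwv(self):
        ii, _ = instability_index(ProteinSequence("s", "GG"))
        assert ii == pytest.approx(5 * DIPEPTIDE_INSTABILITY["G"]["G"])

    @given(seq=sequences)
    @settings(max_examples=25, deadline=None)
    def test_instability_matches_biopython(self, seq):
        ii, _ = instability_index(seq)
        assert ii == pytest.approx(ProteinAnalysis(seq.residues).instability_index(),
                                   abs=1e-6)

    def test_instability_class_threshold(self):
        cfg = DEFAULT_CONFIG
        below = ProteinSequence("s", "GG")  # II = 66.7 -> unstable
        assert instability_index(below, cfg)[1] == "unstable"
        stable_cfg = cfg.override(instability_threshold=70.0)
        assert instability_index(below, stable_cfg)[1] == "stable"

    def test_instability_not_permutation_invariant(self):
        a, _ = instability_index(ProteinSequence("s", "GPWC"))
        b, _ = instability_index(ProteinSequence("s", "PGWC"))
        assert a != b

    def test_instability_needs_two_residues(self):
        with pytest.raises(FeatureError):
            instability_index(ProteinSequence("s", "G"))

    @pytest.mark.parametrize("residues", ["GW", "MK", "AY"])
    def test_two_residue_table_means(self, residues):
        seq = ProteinSequence("s", residues)
        a, b = residues
        assert avg_max_asa(seq) == pytest.approx((MAX_ASA[a] + MAX_ASA[b]) / 2)
        assert avg_solubility(seq) == pytest.approx((SOLUBILITY[a] + SOLUBILITY[b]) / 2)

    def test_single_residue_means_equal_table_value(self):
        assert avg_max_asa(ProteinSequence("s", "W")) == MAX_ASA["W"]
        assert avg_solubility(ProteinSequence("s", "W")) == SOLUBILITY["W"]

    @given(seq=sequences)
    @settings(max_examples=25, deadline=None)
    def test_order_free_means_are_permutation_invariant(self, seq):
        rev = ProteinSequence(seq.id, seq.residues[::-1])
        assert gravy(seq) == pytest.approx(gravy(rev))
        assert avg_max_asa(seq) == pytest.approx(avg_max_asa(rev))
        assert avg_solubility(seq) == pytest.approx(avg_solubility(rev))

    def test_sulfur_count_and_additivity(self):
        assert sulfur_count(ProteinSequence("s", "CCMM")) == 4
        assert sulfur_count(ProteinSequence("s", "AAAA")) == 0
        a, b = "CMKA", "WCMY"
        assert (sulfur_count(ProteinSequence("s", a + b))
                == sulfur_count(ProteinSequence("s", a))
                + sulfur_count(ProteinSequence("s", b)))


class TestIsoelectricPoint:
    @given(seq=sequences)
    @settings(max_examples=20, deadline=None)
    def test_net_charge_near_zero_at_pi(self, seq):
        pi, _ = isoelectric_point(seq)
        assert abs(_net_charge_at_ph(seq.residues, pi, DEFAULT_CONFIG)) < 0.01

    def test_basic_sequence_pi_exceeds_acidic(self):
        poly_k, _ = isoelectric_point(ProteinSequence("s", "KKKKKKKK"))
        poly_d, _ = isoelectric_point(ProteinSequence("s", "DDDDDDDD"))
        assert poly_k > poly_d

    def test_bisection_matches_dense_grid_scan(self):
        seq = ProteinSequence("s", "ACDEFGHIKLMNPQRSTVWY")
        pi, _ = isoelectric_point(seq)
        import numpy as np
        grid = np.arange(0.0, 14.0, 0.001)
        charges = [_net_charge_at_ph(seq.residues, ph, DEFAULT_CONFIG) for ph in grid]
        root = grid[int(np.argmin(np.abs(charges)))]
        assert pi == pytest.approx(root, abs=0.01)

    def test_mean_residue_pi(self):
        _, pia = isoelectric_point(ProteinSequence("s", "KD"))
        cfg = DEFAULT_CONFIG
        assert pia == pytest.approx((cfg.residue_pi["K"] + cfg.residue_pi["D"]) / 2)


class TestConfig:
    def test_histidine_as_positive_is_one_override_away(self):
        cfg = DEFAULT_CONFIG.override(positive=frozenset("KRH"))
        fv = extract_features(ProteinSequence("s", "KH"), cfg)
        assert fv["x_pos"] == 1.0
        default = extract_features(ProteinSequence("s", "KH"))
        assert default["x_pos"] == 0.5

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            ResidueClassConfig(positive=frozenset("KX"))

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="cover all 20"):
            ResidueClassConfig(max_asa={"A": 100.0})
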