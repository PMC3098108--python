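import numpy as np
import pytest

from thermoscore import (
    GeneratorSpec,
    LabeledPair,
    ProteinSequence,
    ScoringModel,
    cross_validate,
    determine_signs,
    evaluate,
    finalize_model,
    generate_dataset,
    hill_climb_fit,
)
from thermoscore.scoring import SCORING_FEATURES, ModelError
from thermoscore.training import FitResult, TrainingError, delta_matrix


def pair(stable_res, other_res, i=0):
    return LabeledPair(stable=ProteinSequence(f"hp{i}", stable_res),
                       other=ProteinSequence(f"mp{i}", other_res))


class TestDetermineSigns:
    def test_median_direction_fixes_sign(self):
        # stable side systematically K-richer and Q-poorer than other side
        pairs = [pair("KKKKQAAA", "KKQQAAAA", 0),
                 pair("KKKQQAAA", "KQQQAAAA", 1),
                 pair("KKKKKQAA", "KKKQQAAA", 2)]
        sa = determine_signs(pairs, ("x_K", "x_Q"))
        assert sa.signs == {"x_K": 1, "x_Q": -1}
        assert sa.medians["x_K"] > 0 > sa.medians["x_Q"]

    def test_zero_median_feature_excluded_with_warning(self):
        pairs = [pair("KKAA", "AAKK", 0), pair("AKAK", "KAKA", 1)]
        with pytest.warns(UserWarning, match="x_K"):
            sa = determine_signs(pairs, ("x_K",))
        assert "x_K" in sa.excluded and "x_K" not in sa.signs

    def test_requires_pairs(self):
        with pytest.raises(TrainingError):
            determine_signs([], ("x_K",))

    def test_synthetic_bias_reproduces_published_sign_set(self, biased_pairs):
        sa = determine_signs(biased_pairs, SCORING_FEATURES)
        expected = {"x_K": 1, "x_E": 1, "x_pos": 1, "x_charge": 1, "ASA": 1,
                    "x_small": -1, "x_tiny": -1, "x_A": -1, "x_Q": -1, "x_T": -1}
        assert sa.signs == expected


class TestHillClimb:
    def test_zero_iterations_returns_initial_weights(self, biased_pairs):
        sa = determine_signs(biased_pairs, SCORING_FEATURES)
        fit = hill_climb_fit(biased_pairs, sa, iterations=0, seed=5)
        assert fit.iterations == 0 and fit.accepted_steps == 0
        assert len(fit.weights) == 10

    def test_negative_iterations_rejected(self, biased_pairs):
        sa = determine_signs(biased_pairs, SCORING_FEATURES)
        with pytest.raises(TrainingError):
            hill_climb_fit(biased_pairs, sa, iterations=-1, seed=0)

    def test_reproducible_given_seed(self, biased_pairs):
        sa = determine_signs(biased_pairs, SCORING_FEATURES)
        a = hill_climb_fit(biased_pairs, sa, iterations=2000, seed=42)
        b = hill_climb_fit(biased_pairs, sa, iterations=2000, seed=42)
        assert a == b

    def test_weights_stay_in_bounds_and_signs_match(self, biased_pairs):
        sa = determine_signs(biased_pairs, SCORING_FEATURES)
        fit = hill_climb_fit(biased_pairs, sa, iterations=3000, seed=1)
        for name, w in zip(fit.features, fit.weights):
            assert abs(w) <= 1.0
            assert np.sign(w) == sa.signs[name] or w == 0.0

    def test_fit_improves_over_initial_weights(self, biased_pairs):
        sa = determine_signs(biased_pairs, SCORING_FEATURES)
        init = hill_climb_fit(biased_pairs, sa, iterations=0, seed=9)
        fit = hill_climb_fit(biased_pairs, sa, iterations=5000, seed=9)
        assert fit.accuracy >= init.accuracy

    def test_separable_pairs_reach_perfect_training_accuracy(self, biased_pairs):
        # keep only pairs a fixed witness weight vector orders correctly,
        # so a perfect solution exists in the search space by construction
        witness = ScoringModel()
        D = delta_matrix(biased_pairs, witness.features)
        keep = D @ np.array(witness.weights) > 0
        sep = [p for p, k in zip(biased_pairs, keep) if k]
        assert len(sep) >= 50
        sa = determine_signs(sep, witness.features)
        fit = hill_climb_fit(sep, sa, iterations=100_000, seed=3)
        assert fit.accuracy == 1.0


class TestCrossValidate:
    def test_folds_partition_pairs(self, biased_pairs):
        cv = cross_validate(biased_pairs, k=5, iterations=500, restarts=2, seed=0)
        assert len(cv.fold_results) == 5
        assert len(cv.test_accuracies) == 5

    def test_k_larger_than_pairs_rejected(self, biased_pairs):
        with pytest.raises(TrainingError):
            cross_validate(biased_pairs[:3], k=5)

    def test_fold_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        perm = rng.permutation(23)
        folds = [perm[i::5] for i in range(5)]
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1
        assert sorted(np.concatenate(folds).tolist()) == list(range(23))

    def test_parameter_recovery_single_shifted_feature(self):
        # only lysine systematically shifted: dropping the x_K term hurts
        # training accuracy more than dropping any other term
        spec = GeneratorSpec(n_pairs=80, bias={"K": 0.03, "S": -0.03}, seed=21)
        pairs = list(generate_dataset(spec).pairs)
        feats = ("x_K", "x_E", "x_A", "x_Q", "ASA")
        sa = determine_signs(pairs, feats)
        fit = hill_climb_fit(pairs, sa, iterations=20_000, seed=2)
        drops = {}
        for j, name in enumerate(fit.features):
            w = list(fit.weights)
            w[j] = 0.0
            drops[name] = evaluate(pairs, ScoringModel(features=fit.features,
                                                       weights=tuple(w)))
        assert min(drops, key=drops.get) == "x_K"


class TestFinalizeModel:
    def _fit(self, weights):
        return FitResult(features=("x_K", "x_Q"), weights=weights, accuracy=0.9,
                         accepted_steps=1, iterations=10, seed=0)

    def test_identical_folds_pass_through(self):
        model = finalize_model([self._fit((0.5, -0.2))] * 3)
        assert model.weights == pytest.approx((0.5, -0.2))

    def test_elementwise_mean(self):
        model = finalize_model([self._fit((0.6, -0.2)), self._fit((0.8, -0.4))])
        assert model.weights == pytest.approx((0.7, -0.3))

    def test_sign_conflict_names_feature(self):
        with pytest.raises(ModelError, match="x_Q"):
            finalize_model([self._fit((0.6, -0.2)), self._fit((0.8, 0.2))])

    def test_empty_input_rejected(self):
        with pytest.raises(TrainingError):
            finalize_model([])
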