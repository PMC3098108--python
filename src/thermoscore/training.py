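"""Fitting scoring-model weights from labeled ortholog pairs.

The training pipeline mirrors how the scoring function was developed:

1. *Sign determination.*  For each candidate feature the relative difference
   Dx(stable, other) is computed over all training pairs.  The cumulative
   distribution of these deltas is sigmoid-shaped and its inflexion point
   sits at half height, i.e. at the empirical median; a median on the
   positive side of zero fixes the weight sign to +1, a negative median to
   -1.  A feature whose median delta is exactly zero has no defensible sign
   and is excluded with a warning.

2. *Hill climbing.*  Weight magnitudes start uniform in [0, 1].  Each
   iteration redraws the magnitude of one uniformly chosen feature and keeps
   the proposal iff the number of correctly oriented pairs (positive score
   for (stable, other)) strictly increases.

3. *Cross-validation.*  A seeded k-fold split; per fold, signs are
   determined and several restarts of the hill climb are run on the training
   portion, restart weights averaged, and held-out pairwise accuracy
   measured.  The final model averages fold weights element-wise (all folds
   must agree on every sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import DEFAULT_CONFIG, ResidueClassConfig, extract_features
from .scoring import SCORING_FEATURES, ModelError, ScoringModel, relative_delta
from .seqio import LabeledPair


class TrainingError(ValueError):
    """Invalid training configuration or inconsistent fold results."""


@dataclass(frozen=True)
class SignAssignment:
    """Per-feature weight sign (+1/-1) with the median delta behind it."""

    signs: dict[str, int]
    medians: dict[str, float]
    excluded: tuple[str, ...] = ()

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.signs)


@dataclass(frozen=True)
class FitResult:
    features: tuple[str, ...]
    weights: tuple[float, ...]  # signed
    accuracy: float  # fraction of training pairs correctly oriented
    accepted_steps: int
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise TrainingError("accuracy outside [0, 1]")
        for w in self.weights:
            if abs(w) > 1.0:
                raise TrainingError("|weight| > 1")


@dataclass(frozen=True)
class CrossValidationResult:
    fold_results: tuple[FitResult, ...]
    test_accuracies: tuple[float, ...]
    train_accuracy_mean: float
    train_accuracy_sd: float
    test_accuracy_mean: float
    test_accuracy_sd: float


def delta_matrix(
    pairs: list[LabeledPair],
    features: tuple[str, ...] | list[str] = SCORING_FEATURES,
    cfg: ResidueClassConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """(n_pairs, n_features) matrix of Dx(stable, other) relative differences."""
    rows = []
    for p in pairs:
        f_s = extract_features(p.stable, cfg)
        f_o = extract_features(p.other, cfg)
        rows.append([relative_delta(f_s, f_o, name) for name in features])
    return np.asarray(rows, dtype=float)


def determine_signs(
    pairs: list[LabeledPair],
    features: tuple[str, ...] | list[str] = SCORING_FEATURES,
    cfg: ResidueClassConfig = DEFAULT_CONFIG,
    deltas: np.ndarray | None = None,
) -> SignAssignment:
    """Fix weight signs from the median relative difference per feature.

    ``deltas`` may be supplied to reuse a precomputed matrix from
    :func:`delta_matrix`.
    """
    if not pairs:
        raise TrainingError("sign determination requires at least one pair")
    D = delta_matrix(pairs, features, cfg) if deltas is None else deltas
    signs: dict[str, int] = {}
    medians: dict[str, float] = {}
    excluded: list[str] = []
    for j, name in enumerate(features):
        med = float(np.median(D[:, j]))
        medians[name] = med
        if med > 0.0:
            signs[name] = 1
        elif med < 0.0:
            signs[name] = -1
        else:
            warnings.warn(
                f"feature {name!r}: median relative difference is exactly 0; "
                "excluded from the model", stacklevel=2)
            excluded.append(name)
    return SignAssignment(signs=signs, medians=medians, excluded=tuple(excluded))


def _objective(D: np.ndarray, w: np.ndarray) -> int:
    """Number of pairs with strictly positive score."""
    return int(np.count_nonzero(D @ w > 0.0))


def hill_climb_fit(
    pairs: list[LabeledPair],
    signs: SignAssignment,
    iterations: int = 100_000,
    seed: int = 0,
    cfg: ResidueClassConfig = DEFAULT_CONFIG,
    deltas: np.ndarray | None = None,
) -> FitResult:
    """Fit weight magnitudes by random-restart-free stochastic hill climbing.

    Magnitudes are initialized uniformly in [0, 1].  Each iteration picks one
    feature uniformly at random, redraws its magnitude uniformly in [0, 1],
    and accepts iff the count of correctly oriented pairs strictly
    increases.  Deterministic given ``seed``.
    """
    if iterations < 0:
        raise TrainingError("iterations must be >= 0")
    if not pairs:
        raise TrainingError("fitting requires at least one pair")
    features = signs.features
    if not features:
        raise TrainingError("no signed features to fit")
    D = delta_matrix(pairs, features, cfg) if deltas is None else deltas
    sign_vec = np.array([signs.signs[f] for f in features], dtype=float)
    rng = np.random.default_rng(seed)
    mags = rng.uniform(0.0, 1.0, size=len(features))
    scores = D @ (sign_vec * mags)
    best = int(np.count_nonzero(scores > 0.0))
    accepted = 0
    for _ in range(iterations):
        j = int(rng.integers(len(features)))
        new_mag = float(rng.uniform())
        delta_scores = D[:, j] * (sign_vec[j] * (new_mag - mags[j]))
        cand_scores = scores + delta_scores
        cand = int(np.count_nonzero(cand_scores > 0.0))
        if cand > best:
            mags[j] = new_mag
            scores = cand_scores
            best = cand
            accepted += 1
    return FitResult(
        features=features,
        weights=tuple(float(s * m) for s, m in zip(sign_vec, mags)),
        accuracy=best / len(pairs),
        accepted_steps=accepted,
        iterations=iterations,
        seed=seed,
    )


def evaluate(
    pairs: list[LabeledPair],
    model: ScoringModel,
    cfg: ResidueClassConfig = DEFAULT_CONFIG,
    deltas: np.ndarray | None = None,
) -> float:
    """Fraction of pairs with score(stable, other) > 0."""
    if not pairs:
        raise TrainingError("evaluation requires at least one pair")
    D = delta_matrix(pairs, model.features, cfg) if deltas is None else deltas
    w = np.asarray(model.weights, dtype=float)
    return _objective(D, w) / len(pairs)


def cross_validate(
    pairs: list[LabeledPair],
    k: int = 5,
    features: tuple[str, ...] | list[str] = SCORING_FEATURES,
    iterations: int = 100_000,
    restarts: int = 5,
    seed: int = 0,
    cfg: ResidueClassConfig = DEFAULT_CONFIG,
) -> CrossValidationResult:
    """Seeded k-fold cross-validation of the sign + hill-climb pipeline.

    Per fold: signs and weights come from the training portion only; the
    ``restarts`` independent hill climbs are averaged into one weight vector
    per fold; accuracy is measured on the held-out portion.  Folds differ in
    size by at most one and partition the pairs exactly.
    """
    if k < 2:
        raise TrainingError("k must be >= 2")
    if len(pairs) < k:
        raise TrainingError(f"need at least k={k} pairs, got {len(pairs)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    folds = [sorted(perm[i::k].tolist()) for i in range(k)]

    D_all = delta_matrix(pairs, features, cfg)
    fold_results: list[FitResult] = []
    test_accs: list[float] = []
    for fold_idx, test_ids in enumerate(folds):
        train_ids = sorted(set(range(len(pairs))) - set(test_ids))
        train_pairs = [pairs[i] for i in train_ids]
        D_train = D_all[train_ids]
        signs = determine_signs(train_pairs, features, cfg, deltas=D_train)
        kept = [features.index(f) if isinstance(features, list) else list(features).index(f)
                for f in signs.features]
        D_fit = D_train[:, kept]
        restart_weights = []
        best_acc = 0.0
        total_accepted = 0
        for r in range(restarts):
            sub_seed = int(rng.integers(2**31 - 1))
            fit = hill_climb_fit(train_pairs, signs, iterations, sub_seed, cfg, deltas=D_fit)
            restart_weights.append(fit.weights)
            best_acc = max(best_acc, fit.accuracy)
            total_accepted += fit.accepted_steps
        mean_w = tuple(float(np.mean(col)) for col in zip(*restart_weights))
        fold_model = ScoringModel(features=signs.features, weights=mean_w)
        train_acc = evaluate(train_pairs, fold_model, cfg, deltas=D_fit)
        D_test = D_all[np.asarray(test_ids)][:, kept]
        test_acc = evaluate([pairs[i] for i in test_ids], fold_model, cfg, deltas=D_test)
        fold_results.append(FitResult(
            features=signs.features, weights=mean_w, accuracy=train_acc,
            accepted_steps=total_accepted, iterations=iterations * restarts,
            seed=seed,
        ))
        test_accs.append(test_acc)

    train_accs = [fr.accuracy for fr in fold_results]
    return CrossValidationResult(
        fold_results=tuple(fold_results),
        test_accuracies=tuple(test_accs),
        train_accuracy_mean=float(np.mean(train_accs)),
        train_accuracy_sd=float(np.std(train_accs, ddof=1)),
        test_accuracy_mean=float(np.mean(test_accs)),
        test_accuracy_sd=float(np.std(test_accs, ddof=1)),
    )


def finalize_model(fold_results: list[FitResult] | tuple[FitResult, ...]) -> ScoringModel:
    """Element-wise mean of fold weight vectors into one scoring model.

    All folds must carry the same features in the same order and agree on
    every weight sign; a sign conflict is an error naming the feature.
    """
    if not fold_results:
        raise TrainingError("no fold results to average")
    features = fold_results[0].features
    for fr in fold_results[1:]:
        if fr.features != features:
            raise TrainingError("fold results carry different feature sets")
    W = np.array([fr.weights for fr in fold_results], dtype=float)
    for j, name in enumerate(features):
        col = W[:, j]
        if np.any(col > 0) and np.any(col < 0):
            raise ModelError(f"sign disagreement across folds for feature {name!r}")
    mean_w = tuple(float(x) for x in W.mean(axis=0))
    return ScoringModel(features=features, weights=mean_w)
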