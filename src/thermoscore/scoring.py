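"""Relative feature differences, the linear scoring function, and ranking.

The score of an ordered sequence pair is

    S(seq1, seq2) = sum_i  w_i * Dx_i(seq1, seq2)

where Dx_i is the symmetric mean-normalized relative difference of feature
i between the two sequences and w_i is a signed weight.  A positive score
predicts seq1 to be the more thermostable sequence.  The shipped default
model carries the ten features and fitted weights of the published scoring
function; positive weights sit on features enriched in hyperthermophilic
proteins (Lys, Glu, positive and total charge, mean maximum ASA) and
negative weights on features depleted there (small, tiny, Ala, Gln, Thr
fractions).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from .features import DEFAULT_CONFIG, ResidueClassConfig, extract_features
from .seqio import ProteinSequence

#: The ten scoring features, in canonical order.
SCORING_FEATURES: tuple[str, ...] = (
    "x_K", "x_E", "x_pos", "x_charge", "ASA",
    "x_small", "x_tiny", "x_A", "x_Q", "x_T",
)

#: Final fitted weights of the default model, aligned with SCORING_FEATURES.
DEFAULT_WEIGHTS: tuple[float, ...] = (
    0.75, 0.20, 0.80, 0.20, 0.90, -0.20, -0.20, -0.30, -0.10, -0.20,
)


class ModelError(ValueError):
    """Inconsistent scoring-model definition."""


@dataclass(frozen=True)
class ScoringModel:
    """An ordered list of feature names with signed weights, |w| <= 1."""

    features: tuple[str, ...] = SCORING_FEATURES
    weights: tuple[float, ...] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        if len(self.features) != len(self.weights):
            raise ModelError("features and weights differ in length")
        if len(set(self.features)) != len(self.features):
            raise ModelError("duplicate feature names in model")
        for name, w in zip(self.features, self.weights):
            if abs(w) > 1.0:
                raise ModelError(f"|weight| > 1 for feature {name!r}: {w}")

    def to_dict(self) -> dict:
        return {"features": list(self.features), "weights": list(self.weights)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringModel":
        return cls(features=tuple(d["features"]), weights=tuple(float(w) for w in d["weights"]))

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ScoringModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


DEFAULT_MODEL = ScoringModel()


@dataclass(frozen=True)
class PairScore:
    """Score of an ordered pair with its per-feature deltas."""

    score: float
    deltas: dict[str, float]
    prediction: str  # "seq1", "seq2", or "tie"


def relative_delta(f1: dict[str, float], f2: dict[str, float], name: str) -> float:
    """Symmetric mean-normalized relative difference of one feature.

    Dx = (x1 - x2) / ((x1 + x2) / 2), with the degenerate x1 = x2 = 0 case
    defined as 0.  Antisymmetric, scale-free, bounded in [-2, 2] for
    non-negative features.
    """
    try:
        x1, x2 = f1[name], f2[name]
    except KeyError:
        raise KeyError(f"feature {name!r} missing from feature vector") from None
    if x1 == x2:
        return 0.0
    mean = (x1 + x2) / 2.0
    if mean == 0.0:
        return 0.0
    return (x1 - x2) / mean


def score_feature_vectors(
    f1: dict[str, float], f2: dict[str, float], model: ScoringModel = DEFAULT_MODEL
) -> PairScore:
    """Score a pair from precomputed feature vectors."""
    deltas = {name: relative_delta(f1, f2, name) for name in model.features}
    score = sum(w * deltas[name] for name, w in zip(model.features, model.weights))
    if score > 0.0:
        pred = "seq1"
    elif score < 0.0:
        pred = "seq2"
    else:
        pred = "tie"
    return PairScore(score=score, deltas=deltas, prediction=pred)


def score_pair(
    seq1: ProteinSequence,
    seq2: ProteinSequence,
    model: ScoringModel = DEFAULT_MODEL,
    cfg: ResidueClassConfig = DEFAULT_CONFIG,
) -> PairScore:
    """Score an ordered pair of sequences; positive favors ``seq1``."""
    return score_feature_vectors(extract_features(seq1, cfg), extract_features(seq2, cfg), model)


def classify_pair(
    seq1: ProteinSequence,
    seq2: ProteinSequence,
    model: ScoringModel = DEFAULT_MODEL,
    cfg: ResidueClassConfig = DEFAULT_CONFIG,
) -> str:
    """Label which sequence is predicted more thermostable.

    Returns "seq1_more_stable", "seq2_more_stable", or "tie".
    """
    ps = score_pair(seq1, seq2, model, cfg)
    if ps.prediction == "tie":
        return "tie"
    return "seq1_more_stable" if ps.prediction == "seq1" else "seq2_more_stable"


@dataclass(frozen=True)
class RankedSequence:
    rank: int
    seq: ProteinSequence
    wins: int
    total_score: float


@dataclass(frozen=True)
class RankingResult:
    """All-pairs ranking: Copeland wins with total-score tiebreak."""

    ranking: tuple[RankedSequence, ...]
    #: ordered-pair scores, keyed by (id_i, id_j) over all i != j
    pair_scores: dict[tuple[str, str], float]

    @property
    def n_comparisons(self) -> int:
        """Number of unordered pairwise comparisons, n(n-1)/2."""
        return len(self.pair_scores) // 2


def rank_sequences(
    seqs: list[ProteinSequence],
    model: ScoringModel = DEFAULT_MODEL,
    cfg: ResidueClassConfig = DEFAULT_CONFIG,
) -> RankingResult:
    """Rank sequences by predicted relative thermostability.

    All ordered pairwise scores are computed; each sequence's wins is its
    number of strictly positive scores against the others (Copeland count).
    Output is sorted by wins descending, then total score sum descending,
    then input order.  Pairwise predictions need not be transitive; the
    Copeland aggregation always yields a total order.
    """
    if len(seqs) < 2:
        raise ValueError("ranking requires at least 2 sequences")
    fvs = [extract_features(s, cfg) for s in seqs]
    n = len(seqs)
    wins = [0] * n
    totals = [0.0] * n
    pair_scores: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            s = score_feature_vectors(fvs[i], fvs[j], model).score
            pair_scores[(seqs[i].id, seqs[j].id)] = s
            pair_scores[(seqs[j].id, seqs[i].id)] = -s
            totals[i] += s
            totals[j] -= s
            if s > 0.0:
                wins[i] += 1
            elif s < 0.0:
                wins[j] += 1
    order = sorted(range(n), key=lambda k: (-wins[k], -totals[k], k))
    ranking = tuple(
        RankedSequence(rank=r + 1, seq=seqs[k], wins=wins[k], total_score=totals[k])
        for r, k in enumerate(order)
    )
    return RankingResult(ranking=ranking, pair_scores=pair_scores)
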