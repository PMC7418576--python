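"""Cross-validation protocols and ranking metrics.

Two schemes over the known associations of a bipartite network:

* **LOOCV** — each known association is masked in turn; all four similarity
  matrices, the bandwidths, and the fused matrices are rebuilt from the
  masked training matrix, and the held-out pair's score is ranked against the
  scores of every pair unknown in the original dataset.
* **Repeated k-fold CV** — the known associations are shuffled (seeded) into
  k near-equal contiguous folds; each fold is masked jointly and similarities
  are recomputed per fold; the per-repeat AUC is summarised over repeats.

The AUC is the rank-based (Mann-Whitney) statistic over all (positive,
fold-matched negative) comparisons with ties counted 1/2 — each fold's
held-out positives are compared against that fold's unknown-pair scores.
Because every fold recomputes similarities from scratch, the held-out cells
cannot leak into their own fold's scores.

AUPR and the fixed-specificity stringency tables are computed from the
pooled positives and the across-fold mean score of each unknown pair, so the
negative class keeps the size it has in the network itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .dataset import AssociationDataset
from .exceptions import EvaluationError, ParameterError
from .fusion import FusionWeights
from .ncp import ScoreMatrix

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "FoldRecord",
    "CVResult",
    "roc_auc",
    "pr_auc",
    "confusion_metrics",
    "stringency_table",
    "loocv",
    "kfold_cv",
    "ablation_grid",
    "grid_search",
    "pooled_auc",
    "permutation_null",
]


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of known (positive) and unknown (negative) pairs by call."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class MetricSet:
    """Threshold metrics; any ratio with a zero denominator is reported as 0."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    mcc: float


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy, precision, F1 and MCC from counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fp + tn + fn == 0:
        raise ParameterError("confusion counts are all zero")
    mcc_den = float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    return MetricSet(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        precision=_ratio(tp, tp + fp),
        f1=_ratio(2 * tp, 2 * tp + fn + fp),
        mcc=_ratio(tp * tn - fp * fn, np.sqrt(mcc_den)) if mcc_den else 0.0,
    )


# ---------------------------------------------------------------------------
# rank metrics


def _pair_statistic(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney U numerator: #(pos > neg) + 0.5 * #(pos == neg)."""
    n_pos = pos.size
    ranks = rankdata(np.concatenate([pos, neg]))
    return float(ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0)


def roc_auc(positive_scores, negative_scores) -> float:
    """Rank-based AUC: fraction of (pos, neg) pairs with pos > neg, ties 1/2.

    Equals the trapezoidal area under the ROC curve swept over all
    thresholds.
    """
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("roc_auc requires non-empty positive and negative scores")
    return _pair_statistic(pos, neg) / (pos.size * neg.size)


def pr_auc(positive_scores, negative_scores) -> float:
    """Area under the precision-recall curve.

    Step-wise integration over descending score thresholds with ties
    grouped: sum over recall steps of (delta recall) * precision.
    """
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    if pos.size == 0:
        raise EvaluationError("pr_auc requires at least one positive score")
    if neg.size == 0:
        return 1.0
    y = np.concatenate([np.ones(pos.size, dtype=int), np.zeros(neg.size, dtype=int)])
    return float(average_precision_score(y, np.concatenate([pos, neg])))


# ---------------------------------------------------------------------------
# cross-validation containers


@dataclass(frozen=True)
class FoldRecord:
    """One fold: held-out pairs, their scores, and the fold's negative scores."""

    held_out: tuple[tuple[int, int], ...]
    positive_scores: np.ndarray = field(repr=False)
    negative_scores: np.ndarray = field(repr=False)


@dataclass
class CVResult:
    """Outcome of a cross-validation run.

    ``auc`` is the fold-matched rank statistic; ``aupr`` is computed on the
    pooled scores.  For k-fold runs, ``repeat_aucs`` holds one AUC per
    repeat with ``auc_mean``/``auc_std`` their summary, and ``auc`` equals
    ``auc_mean``.
    """

    scheme: str
    fold_records: list[FoldRecord]
    auc: float
    aupr: float
    repeat_aucs: list[float] | None = None
    auc_mean: float | None = None
    auc_std: float | None = None
    stringency: dict[float, MetricSet] | None = None

    def pooled_positive_scores(self) -> np.ndarray:
        return np.concatenate([f.positive_scores for f in self.fold_records])

    def pooled_negative_scores(self, reduce: str = "concat") -> np.ndarray:
        """Pooled negative scores across folds.

        ``reduce="concat"`` concatenates every fold's negative vector (each
        unknown pair appears once per fold); ``reduce="mean"`` averages each
        unknown pair's score across folds, restoring the class balance of
        the underlying network — this is the variant used for AUPR and the
        stringency tables.
        """
        if reduce == "concat":
            return np.concatenate([f.negative_scores for f in self.fold_records])
        if reduce == "mean":
            return np.mean([f.negative_scores for f in self.fold_records], axis=0)
        raise ParameterError(f"reduce must be 'concat' or 'mean', got {reduce!r}")


def _fold_matched_auc(folds: Iterable[FoldRecord]) -> float:
    num = 0.0
    den = 0
    for f in folds:
        if f.positive_scores.size and f.negative_scores.size:
            num += _pair_statistic(f.positive_scores, f.negative_scores)
            den += f.positive_scores.size * f.negative_scores.size
    if den == 0:
        raise EvaluationError("no (positive, negative) comparisons available")
    return num / den


# ---------------------------------------------------------------------------
# fold scoring


def _fold_scores(
    ds: AssociationDataset,
    held_out: Sequence[tuple[int, int]],
    neg_rows: np.ndarray,
    neg_cols: np.ndarray,
    weights: FusionWeights,
    lambda_prime: float,
    microbe_similarity: str,
    disease_similarity: str,
    norm: str,
) -> FoldRecord:
    """Mask the held-out pairs, refit the pipeline, and collect fold scores.

    The fold's scores depend only on the masked training matrix: the value
    the original dataset held in the masked cells is never read.
    """
    from .estimator import NetworkConsistencyProjection

    masked = ds.mask(held_out)
    if masked.n_associations == 0:
        raise EvaluationError("masked training matrix has no associations left")
    est = NetworkConsistencyProjection(
        alpha=weights.alpha,
        beta=weights.beta,
        lambda_prime=lambda_prime,
        microbe_similarity=microbe_similarity,
        disease_similarity=disease_similarity,
        norm=norm,
    ).fit(masked)
    scores = est.scores_
    pos = np.array([scores[i, j] for i, j in held_out], dtype=float)
    return FoldRecord(tuple(held_out), pos, scores[neg_rows, neg_cols].copy())


def _negative_index(ds: AssociationDataset) -> tuple[np.ndarray, np.ndarray]:
    # negatives = all pairs unknown in the ORIGINAL dataset
    rows, cols = np.nonzero(ds.MD == 0)
    return rows, cols


def loocv(
    ds: AssociationDataset,
    weights: FusionWeights | None = None,
    lambda_prime: float = 1.0,
    *,
    microbe_similarity: str = "fused",
    disease_similarity: str = "fused",
    norm: str = "l2",
) -> CVResult:
    """Leave-one-out cross-validation over the known associations.

    Each known pair is masked in turn, all similarities are rebuilt from the
    masked matrix, and the held-out score is ranked against the scores of
    every originally-unknown pair in that fold.
    """
    if ds.n_associations < 2:
        raise EvaluationError("LOOCV requires at least 2 known associations")
    weights = weights or FusionWeights()
    neg_rows, neg_cols = _negative_index(ds)
    records = [
        _fold_scores(
            ds, [pair], neg_rows, neg_cols, weights, lambda_prime,
            microbe_similarity, disease_similarity, norm,
        )
        for pair in ds.known_pairs()
    ]
    result = CVResult(
        scheme="loocv",
        fold_records=records,
        auc=_fold_matched_auc(records),
        aupr=0.0,
    )
    result.aupr = pr_auc(
        result.pooled_positive_scores(), result.pooled_negative_scores("mean")
    )
    result.stringency = stringency_table(result)
    return result


def kfold_cv(
    ds: AssociationDataset,
    weights: FusionWeights | None = None,
    lambda_prime: float = 1.0,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    *,
    microbe_similarity: str = "fused",
    disease_similarity: str = "fused",
    norm: str = "l2",
) -> CVResult:
    """Repeated k-fold cross-validation over the known associations.

    Per repeat the positives are shuffled (seeded) into k near-equal
    contiguous folds; each fold is masked jointly with similarities
    recomputed from the masked matrix.  The per-repeat AUC is fold-matched;
    ``auc_mean``/``auc_std`` summarise the repeats.
    """
    n_pos = ds.n_associations
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if k > n_pos:
        raise ParameterError(f"k={k} exceeds the association count {n_pos}")
    if repeats < 1:
        raise ParameterError(f"repeats must be >= 1, got {repeats}")
    weights = weights or FusionWeights()
    pairs = ds.known_pairs()
    neg_rows, neg_cols = _negative_index(ds)
    rng = np.random.default_rng(seed)

    all_records: list[FoldRecord] = []
    repeat_aucs: list[float] = []
    for _ in range(repeats):
        perm = rng.permutation(n_pos)
        repeat_records = []
        for fold_idx in np.array_split(perm, k):
            held = [pairs[i] for i in fold_idx]
            repeat_records.append(
                _fold_scores(
                    ds, held, neg_rows, neg_cols, weights, lambda_prime,
                    microbe_similarity, disease_similarity, norm,
                )
            )
        repeat_aucs.append(_fold_matched_auc(repeat_records))
        all_records.extend(repeat_records)

    auc_mean = float(np.mean(repeat_aucs))
    result = CVResult(
        scheme="kfold",
        fold_records=all_records,
        auc=auc_mean,
        aupr=0.0,
        repeat_aucs=repeat_aucs,
        auc_mean=auc_mean,
        auc_std=float(np.std(repeat_aucs)),
    )
    result.aupr = pr_auc(
        result.pooled_positive_scores(), result.pooled_negative_scores("mean")
    )
    result.stringency = stringency_table(result)
    return result


# ---------------------------------------------------------------------------
# stringency tables


def stringency_table(
    cv: CVResult, specificity_levels: Sequence[float] = (0.95, 0.99)
) -> dict[float, MetricSet]:
    """Threshold metrics at fixed operating specificities.

    For each requested level the threshold is the smallest pooled score
    whose resulting specificity (scores >= threshold called positive) is at
    least the level; no interpolation between achievable specificities is
    performed, and the achieved specificity is reported in the MetricSet.

    Negatives are pooled by their across-fold mean score, so each unknown
    pair is counted once and the confusion counts reflect the network's own
    class balance.
    """
    pos = np.sort(cv.pooled_positive_scores())
    neg = np.sort(cv.pooled_negative_scores("mean"))
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("stringency_table requires pooled positive and negative scores")
    out: dict[float, MetricSet] = {}
    thresholds = np.unique(np.concatenate([pos, neg]))
    # specificity at threshold t = fraction of negatives strictly below t
    spec_at = np.searchsorted(neg, thresholds, side="left") / neg.size
    for level in specificity_levels:
        if not 0.0 < level < 1.0:
            raise ParameterError(f"specificity level must lie in (0, 1), got {level}")
        ok = np.nonzero(spec_at >= level)[0]
        if ok.size:
            t = thresholds[ok[0]]
            tn = int(np.searchsorted(neg, t, side="left"))
            fn = int(np.searchsorted(pos, t, side="left"))
        else:  # no realizable threshold: call nothing positive
            tn, fn = neg.size, pos.size
        counts = ConfusionCounts(tp=pos.size - fn, fp=neg.size - tn, tn=tn, fn=fn)
        out[float(level)] = confusion_metrics(counts)
    return out


# ---------------------------------------------------------------------------
# drivers


_TABLE3_COMBOS: tuple[tuple[str, str], ...] = (
    ("gip", "gip"),
    ("gip", "cosine"),
    ("cosine", "cosine"),
    ("cosine", "gip"),
    ("fused", "fused"),
)


def ablation_grid(
    ds: AssociationDataset,
    lambda_prime: float = 1.0,
    combos: Sequence[tuple[str, str]] = _TABLE3_COMBOS,
    weights: FusionWeights | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """LOOCV and k-fold AUC for each (microbe, disease) similarity choice.

    Single-similarity combos bypass fusion; ("fused", "fused") is the
    default pipeline.
    """
    valid = {"gip", "cosine", "fused"}
    rows = []
    for m_sim, d_sim in combos:
        if m_sim not in valid or d_sim not in valid:
            raise ParameterError(f"unknown similarity combo ({m_sim!r}, {d_sim!r})")
        loo = loocv(ds, weights, lambda_prime,
                    microbe_similarity=m_sim, disease_similarity=d_sim)
        kf = kfold_cv(ds, weights, lambda_prime, k=k, repeats=repeats, seed=seed,
                      microbe_similarity=m_sim, disease_similarity=d_sim)
        rows.append({
            "microbe_similarity": m_sim,
            "disease_similarity": d_sim,
            "loocv_auc": loo.auc,
            "kfold_auc_mean": kf.auc_mean,
            "kfold_auc_std": kf.auc_std,
        })
    return pd.DataFrame(rows)


def grid_search(
    ds: AssociationDataset,
    grid: Sequence[float] | None = None,
    lambda_prime: float = 1.0,
) -> pd.DataFrame:
    """LOOCV AUC over a grid of fusion weights (alpha rows, beta columns).

    The full grid is returned rather than silently picking a maximum.
    Defaults to weights 0.1 .. 0.9 in steps of 0.1.
    """
    if grid is None:
        grid = np.round(np.arange(0.1, 0.91, 0.1), 10)
    grid = [float(g) for g in grid]
    table = np.empty((len(grid), len(grid)))
    for i, alpha in enumerate(grid):
        for j, beta in enumerate(grid):
            table[i, j] = loocv(ds, FusionWeights(alpha, beta), lambda_prime).auc
    return pd.DataFrame(
        table,
        index=pd.Index(grid, name="alpha"),
        columns=pd.Index(grid, name="beta"),
    )


# ---------------------------------------------------------------------------
# permutation null


def pooled_auc(cv: CVResult) -> float:
    """Rank AUC of the pooled positives against the pooled negatives."""
    return roc_auc(cv.pooled_positive_scores(), cv.pooled_negative_scores())


def permutation_null(
    positive_scores,
    negative_scores,
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null AUC distribution: positive labels re-drawn at random from the pool.

    The pooled scores are ranked once; each permutation relabels a random
    subset of the pool (same size as the true positive set) as positives and
    recomputes the rank AUC, which is O(n_pos) per permutation.
    """
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("permutation null requires both score lists")
    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_tot = pos.size, pos.size + neg.size
    n_neg = n_tot - n_pos
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    offset = n_pos * (n_pos + 1) / 2.0
    for b in range(n_permutations):
        idx = rng.choice(n_tot, size=n_pos, replace=False)
        null[b] = (ranks[idx].sum() - offset) / (n_pos * n_neg)
    return null
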