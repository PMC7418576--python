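import numpy as np
import pytest

from ncplink import (
    AssociationDataset,
    ConfusionCounts,
    FusionWeights,
    NetworkConsistencyProjection,
    ablation_grid,
    confusion_metrics,
    grid_search,
    kfold_cv,
    loocv,
    pr_auc,
    roc_auc,
    stringency_table,
)
from ncplink.evaluation import CVResult, FoldRecord, _fold_scores
from ncplink.exceptions import EvaluationError, ParameterError

from .conftest import random_dataset
from .oracles import roc_auc_brute

# ---------------------------------------------------------------------------
# rank metrics


@pytest.mark.parametrize(
    "pos, neg, expected",
    [
        ([3.0, 2.0], [1.0, 0.5], 1.0),
        ([0.5], [0.5], 0.5),
        ([0.9, 0.4], [0.6, 0.2], 0.75),
    ],
)
def test_roc_auc_hand_cases(pos, neg, expected):
    assert roc_auc(pos, neg) == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(20))
def test_roc_auc_equals_brute_force_pair_count(seed):
    rng = np.random.default_rng(seed)
    # discrete grid guarantees ties occur
    pos = rng.integers(0, 8, size=rng.integers(1, 15)) / 4.0
    neg = rng.integers(0, 8, size=rng.integers(1, 25)) / 4.0
    assert roc_auc(pos, neg) == pytest.approx(roc_auc_brute(list(pos), list(neg)), abs=0)


def test_roc_auc_complement_identity():
    rng = np.random.default_rng(1)
    pos = rng.random(12)
    neg = rng.random(9)  # continuous, so tie-free
    assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0)


def test_roc_auc_requires_both_lists():
    with pytest.raises(EvaluationError):
        roc_auc([], [1.0])
    with pytest.raises(EvaluationError):
        roc_auc([1.0], [])


@pytest.mark.parametrize(
    "pos, neg, expected",
    [
        ([0.9, 0.8], [0.5, 0.1], 1.0),
        ([0.9], [0.8, 0.7], 1.0),
        ([0.5], [0.9], 0.5),
    ],
)
def test_pr_auc_hand_enumerations(pos, neg, expected):
    assert pr_auc(pos, neg) == pytest.approx(expected)


def test_pr_auc_requires_a_positive():
    with pytest.raises(EvaluationError):
        pr_auc([], [0.5])


# ---------------------------------------------------------------------------
# confusion metrics


def test_confusion_metrics_perfect_classifier():
    ms = confusion_metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
    assert (ms.sensitivity, ms.specificity, ms.accuracy, ms.precision, ms.f1, ms.mcc) \
        == (1, 1, 1, 1, 1, 1)


def test_confusion_metrics_hand_case():
    ms = confusion_metrics(ConfusionCounts(tp=2, fp=1, tn=3, fn=1))
    assert ms.sensitivity == pytest.approx(2 / 3)
    assert ms.specificity == pytest.approx(3 / 4)
    assert ms.accuracy == pytest.approx(5 / 7)
    assert ms.precision == pytest.approx(2 / 3)
    assert ms.f1 == pytest.approx(2 / 3)
    assert ms.mcc == pytest.approx(5 / 12)


def test_confusion_metrics_zero_denominator_conventions():
    ms = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=1, fn=1))
    assert ms.precision == 0.0
    assert ms.mcc == 0.0
    with pytest.raises(ParameterError):
        confusion_metrics(ConfusionCounts(0, 0, 0, 0))
    with pytest.raises(ParameterError):
        ConfusionCounts(-1, 0, 0, 0)


# ---------------------------------------------------------------------------
# stringency tables


def _cv_from_scores(pos, neg):
    rec = FoldRecord((), np.asarray(pos, dtype=float), np.asarray(neg, dtype=float))
    return CVResult(scheme="loocv", fold_records=[rec], auc=0.5, aupr=0.5)


def _stringency_scan_oracle(pos, neg, level):
    """Exhaustive threshold scan: smallest pooled score with spec >= level."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    for t in sorted(set(pos) | set(neg)):
        spec = np.mean(neg < t)
        if spec >= level:
            return ConfusionCounts(
                tp=int((pos >= t).sum()), fp=int((neg >= t).sum()),
                tn=int((neg < t).sum()), fn=int((pos < t).sum()),
            )
    return ConfusionCounts(tp=0, fp=0, tn=neg.size, fn=pos.size)


def test_stringency_matches_exhaustive_scan():
    pos = [3.0, 2.0, 1.0]
    neg = [2.5, 1.5] + [0.5 - 0.01 * i for i in range(20)]
    cv = _cv_from_scores(pos, neg)
    table = stringency_table(cv, [0.5, 0.9, 0.95])
    for level, ms in table.items():
        oracle = confusion_metrics(_stringency_scan_oracle(pos, neg, level))
        assert ms == oracle


def test_stringency_perfect_separation_keeps_full_sensitivity():
    cv = _cv_from_scores([5.0, 4.0, 3.0], np.linspace(0, 1, 50))
    table = stringency_table(cv, [0.95, 0.99])
    assert all(ms.sensitivity == 1.0 for ms in table.values())
    assert all(ms.specificity >= level for level, ms in table.items())


def test_stringency_on_complete_ties():
    cv = _cv_from_scores([1.0, 1.0], [1.0] * 10)
    (ms,) = stringency_table(cv, [0.5]).values()
    # no realizable threshold reaches spec 0.5 -> nothing called positive
    assert ms == confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=2))


def test_stringency_level_validation():
    cv = _cv_from_scores([1.0], [0.5])
    with pytest.raises(ParameterError):
        stringency_table(cv, [1.5])


# ---------------------------------------------------------------------------
# LOOCV


def test_loocv_smoke_on_identity(identity_ds):
    cv = loocv(identity_ds)
    assert cv.scheme == "loocv"
    assert len(cv.fold_records) == 2
    for rec in cv.fold_records:
        assert rec.positive_scores.size == 1
        assert rec.negative_scores.size == 2  # the two originally-unknown cells
    assert 0.0 <= cv.auc <= 1.0
    assert 0.0 <= cv.aupr <= 1.0


def test_loocv_recovers_duplicated_profile_association(toy_ds):
    # m1 and m2 share disease d1; masking (m1, d1) leaves m2's copy as evidence
    cv = loocv(toy_ds)
    rec = next(r for r in cv.fold_records if r.held_out == ((0, 0),))
    assert rec.positive_scores[0] > 0


def test_loocv_requires_two_associations():
    ds = AssociationDataset(("m1",), ("d1", "d2"), np.array([[1, 0]]))
    with pytest.raises(EvaluationError):
        loocv(ds)


def test_loocv_fold_count_matches_association_count(small_planted_ds):
    cv = loocv(small_planted_ds)
    assert len(cv.fold_records) == small_planted_ds.n_associations
    assert cv.auc > 0.5


@pytest.mark.parametrize("seed", range(20))
def test_fold_scores_depend_only_on_masked_matrix(seed):
    """Fuzzing the original value of the held-out cell never changes fold scores."""
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, nm=8, nd=5, density=0.3)
    pairs = ds.known_pairs()
    i, j = pairs[rng.integers(len(pairs))]
    neg_rows, neg_cols = np.nonzero(ds.MD == 0)
    weights = FusionWeights()
    rec = _fold_scores(ds, [(i, j)], neg_rows, neg_cols, weights, 1.0,
                       "fused", "fused", "l2")

    # independent reconstruction: training matrix built from scratch with the
    # held-out cell replaced by an arbitrary value, then forced to 0
    md = np.array(ds.MD, dtype=float)
    md[i, j] = rng.normal()  # any number; masking must erase it
    md[i, j] = 0
    refit = NetworkConsistencyProjection().fit(
        AssociationDataset(ds.microbe_names, ds.disease_names, md.astype(int))
    )
    assert refit.scores_[i, j] == rec.positive_scores[0]
    np.testing.assert_array_equal(refit.scores_[neg_rows, neg_cols], rec.negative_scores)


# ---------------------------------------------------------------------------
# k-fold CV


def test_kfold_fixed_seed_is_bit_reproducible(small_planted_ds):
    a = kfold_cv(small_planted_ds, k=5, repeats=2, seed=11)
    b = kfold_cv(small_planted_ds, k=5, repeats=2, seed=11)
    assert a.repeat_aucs == b.repeat_aucs
    for ra, rb in zip(a.fold_records, b.fold_records):
        assert ra.held_out == rb.held_out
        np.testing.assert_array_equal(ra.positive_scores, rb.positive_scores)
    assert a.auc == a.auc_mean
    assert a.auc_std > 0  # non-degenerate data, distinct splits


def test_kfold_different_seed_changes_partition(small_planted_ds):
    a = kfold_cv(small_planted_ds, k=5, repeats=1, seed=1)
    b = kfold_cv(small_planted_ds, k=5, repeats=1, seed=2)
    assert any(ra.held_out != rb.held_out
               for ra, rb in zip(a.fold_records, b.fold_records))


def test_kfold_with_k_equal_n_matches_loocv_folds():
    rng = np.random.default_rng(4)
    ds = random_dataset(rng, nm=8, nd=4, density=0.3)
    n = ds.n_associations
    loo = loocv(ds)
    kf = kfold_cv(ds, k=n, repeats=1, seed=0)
    loo_map = {r.held_out: float(r.positive_scores[0]) for r in loo.fold_records}
    kf_map = {r.held_out: float(r.positive_scores[0]) for r in kf.fold_records}
    assert loo_map == kf_map
    assert kf.repeat_aucs[0] == pytest.approx(loo.auc)


def test_kfold_per_repeat_positive_count_is_conserved(small_planted_ds):
    cv = kfold_cv(small_planted_ds, k=5, repeats=2, seed=3)
    n_pos_per_repeat = small_planted_ds.n_associations
    held = [p for r in cv.fold_records for p in r.held_out]
    assert len(held) == 2 * n_pos_per_repeat
    assert sorted(set(held)) == sorted(small_planted_ds.known_pairs())


@pytest.mark.parametrize("kwargs", [{"k": 1}, {"k": 10_000}, {"repeats": 0}])
def test_kfold_parameter_validation(identity_ds, kwargs):
    with pytest.raises(ParameterError):
        kfold_cv(identity_ds, **{"repeats": 1, **kwargs})


# ---------------------------------------------------------------------------
# drivers


def test_ablation_grid_runs_all_combos(small_planted_ds):
    table = ablation_grid(small_planted_ds, k=5, repeats=2, seed=0)
    assert len(table) == 5
    assert np.isfinite(table["loocv_auc"]).all()
    assert np.isfinite(table["kfold_auc_mean"]).all()
    fused_row = table[(table.microbe_similarity == "fused")
                      & (table.disease_similarity == "fused")].iloc[0]
    assert fused_row["loocv_auc"] == pytest.approx(loocv(small_planted_ds).auc)
    with pytest.raises(ParameterError):
        ablation_grid(small_planted_ds, combos=[("gip", "unknown")])


def test_grid_search_returns_full_auc_grid():
    rng = np.random.default_rng(9)
    ds = random_dataset(rng, nm=10, nd=5, density=0.3)
    grid = grid_search(ds, grid=[0.3, 0.6])
    assert grid.shape == (2, 2)
    assert grid.loc[0.3, 0.6] == pytest.approx(
        loocv(ds, FusionWeights(alpha=0.3, beta=0.6)).auc
    )
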