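"""Classifier training, grid search, metrics, PR bootstrap, repeated splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from senoscreen import (
    EnsembleConfig,
    MlpConfig,
    SvmConfig,
    compute_metrics,
    grid_search,
    lifespan_extension_rate,
    pr_curve_bootstrap,
    repeated_random_split_eval,
    train_mlp,
    train_mlp_ensemble,
    train_svm,
)
from senoscreen.models import MlpEnsemble


def blobs(n_per=50, sep=6.0, seed=0, dim=4):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_per, dim)), rng.normal(sep, 1, (n_per, dim))])
    y = np.repeat([0, 1], n_per)
    return X, y


FAST_MLP = dict(hidden_width=16, max_epochs=500, patience=50, learning_rate=1e-3)


# -- SVM ---------------------------------------------------------------------

def test_svm_separable_training_accuracy_one():
    X, y = blobs()
    model = train_svm(X, y)
    assert np.mean(model.predict(X) == y) == 1.0


def test_svm_label_is_sign_of_score():
    X, y = blobs(seed=3)
    model = train_svm(X, y)
    scores = model.decision_scores(X)
    np.testing.assert_array_equal(model.predict(X), (scores > 0).astype(int))


def test_svm_single_class_rejected():
    X = np.zeros((5, 2))
    with pytest.raises(ValueError):
        train_svm(X, np.ones(5, dtype=int))


def test_balanced_weighting_helps_minority_recall():
    # 90:10 imbalance with overlapping classes; paired over seeds
    wins = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1.5, (180, 3)), rng.normal(2.0, 1.5, (20, 3))])
        y = np.repeat([0, 1], [180, 20])
        balanced = train_svm(X, y, SvmConfig(class_weight="balanced"))
        plain = train_svm(X, y, SvmConfig(class_weight=None))
        rec = lambda m: recall_score(y, m.predict(X))
        wins += rec(balanced) >= rec(plain)
    assert wins == 5


# -- MLP ---------------------------------------------------------------------

def test_mlp_probability_contract_and_reproducibility():
    X, y = blobs(seed=1)
    cfg = MlpConfig(seed=11, **FAST_MLP)
    p1 = train_mlp(X, y, cfg).predict_proba(X)
    p2 = train_mlp(X, y, cfg).predict_proba(X)
    assert np.all((p1 >= 0) & (p1 <= 1))
    np.testing.assert_array_equal(p1, p2)


def test_mlp_learns_separable_data():
    for seed in range(3):
        X, y = blobs(seed=seed)
        Xh, yh = blobs(seed=seed + 100)
        model = train_mlp(X, y, MlpConfig(seed=seed, **FAST_MLP))
        assert roc_auc_score(yh, model.predict_proba(Xh)) > 0.95


def test_mlp_rejects_nonfinite_features():
    X, y = blobs()
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        train_mlp(X, y)


def test_mlp_config_validation():
    with pytest.raises(ValueError):
        MlpConfig(max_epochs=50, patience=100)


# -- ensemble ----------------------------------------------------------------

class StubMlp:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.full(len(X), self.p)


def test_ensemble_probability_is_arithmetic_mean():
    ens = MlpEnsemble([StubMlp(0.2), StubMlp(0.4), StubMlp(0.6)], EnsembleConfig(n_sub=3))
    assert ens.predict_proba(np.zeros((4, 2)))[0] == pytest.approx(0.4)


def test_singleton_ensemble_equals_single_model():
    X, y = blobs(seed=2)
    cfg = MlpConfig(seed=5, **FAST_MLP)
    single = train_mlp(X, y, cfg).predict_proba(X)
    ens = train_mlp_ensemble(X, y, cfg, EnsembleConfig(n_sub=1)).predict_proba(X)
    np.testing.assert_array_equal(single, ens)


def test_ensemble_averaging_reduces_across_seed_variance():
    X, y = blobs(n_per=30, sep=2.0, seed=4)
    Xq = X[:10]
    sub_probs, ens_probs = [], []
    for base in range(4):
        cfg = MlpConfig(seed=100 * base, **FAST_MLP)
        ens = train_mlp_ensemble(X, y, cfg, EnsembleConfig(n_sub=4))
        sub_probs.append([m.predict_proba(Xq) for m in ens.members])
        ens_probs.append(ens.predict_proba(Xq))
    sub = np.asarray(sub_probs)        # (base, member, query)
    ens_var = np.var(np.asarray(ens_probs), axis=0).mean()
    sub_var = np.var(sub, axis=0).mean()
    assert ens_var <= sub_var + 1e-12


# -- grid search -------------------------------------------------------------

def test_grid_of_one_point_returned():
    X, y = blobs(n_per=20)
    best, table = grid_search("svm", {"C": [2.0]}, X, y, folds=2)
    assert best == {"C": 2.0}
    assert len(table) == 1


def test_grid_search_prefers_required_capacity():
    # tight interleaved clusters: C=0.01 underfits badly, C=20 separates
    rng = np.random.default_rng(0)
    centers = rng.normal(0, 3, (8, 2))
    X = np.vstack([c + rng.normal(0, 0.15, (12, 2)) for c in centers])
    y = np.tile(np.repeat([0, 1], [6, 6]), 8)
    best, table = grid_search("svm", {"C": [0.01, 20.0]}, X, y, folds=3, seed=1)
    direct = {row["params"]["C"]: row["mean_f1"] for _, row in table.iterrows()}
    assert direct[20.0] > direct[0.01]
    assert best == {"C": 20.0}


def test_grid_search_reproducible():
    X, y = blobs(n_per=15, sep=2.0)
    g = {"C": [0.5, 5.0]}
    assert grid_search("svm", g, X, y, folds=2, seed=3)[0] == \
        grid_search("svm", g, X, y, folds=2, seed=3)[0]


def test_grid_search_infeasible_folds():
    X, y = blobs(n_per=3)
    with pytest.raises(ValueError, match="fold"):
        grid_search("svm", {"C": [1.0]}, X, y, folds=5)


# -- metrics -----------------------------------------------------------------

def test_metrics_worked_confusion_example():
    # TP=3, FP=1, FN=1, TN=5
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    s = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1])
    rep = compute_metrics(y, s, threshold=0.5)
    assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 1, 5)
    assert rep.accuracy == pytest.approx(0.8)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.75)
    assert rep.f1 == pytest.approx(0.75)
    assert rep.mcc == pytest.approx(14 / 24)


def test_metrics_perfect_predictions():
    y = np.array([0, 1, 0, 1])
    rep = compute_metrics(y, y.astype(float), threshold=0.5)
    assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0
    assert rep.mcc == 1.0 and rep.auc == 1.0


def test_metrics_inverted_predictions_mcc_minus_one():
    y = np.array([0, 1, 0, 1])
    rep = compute_metrics(y, 1.0 - y, threshold=0.5)
    assert rep.mcc == -1.0


def test_metrics_degenerate_policy():
    y = np.array([1, 1, 0])
    s = np.zeros(3)
    rep = compute_metrics(y, s, threshold=0.5)
    assert rep.precision == 0.0 and "precision" in rep.degenerate
    assert rep.recall == 0.0 and "recall" not in rep.degenerate


def test_metrics_single_class_auc_flagged():
    rep = compute_metrics(np.ones(4, dtype=int), np.linspace(0, 1, 4), 0.5)
    assert rep.auc is None and "auc" in rep.degenerate


def test_metrics_length_mismatch():
    with pytest.raises(ValueError):
        compute_metrics([0, 1], [0.5], 0.5)


@given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=2, max_size=60))
@settings(derandomize=True, max_examples=200)
def test_metrics_agree_with_reference_implementation(pairs):
    y = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    rep = compute_metrics(y, s, threshold=0.5)
    pred = (s > 0.5).astype(int)
    assert rep.accuracy == pytest.approx(accuracy_score(y, pred))
    assert rep.precision == pytest.approx(precision_score(y, pred, zero_division=0))
    assert rep.recall == pytest.approx(recall_score(y, pred, zero_division=0))
    assert rep.f1 == pytest.approx(f1_score(y, pred, zero_division=0))
    if len(np.unique(pred)) == 2 and len(np.unique(y)) == 2:
        assert rep.mcc == pytest.approx(matthews_corrcoef(y, pred))
    if len(np.unique(y)) == 2:
        assert rep.auc == pytest.approx(roc_auc_score(y, s))
    assert rep.f1 <= 2 * rep.precision + 1e-12
    assert rep.f1 <= 2 * rep.recall + 1e-12


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    s = rng.normal(size=50)
    a1 = compute_metrics(y, s, 0.0).auc
    a2 = compute_metrics(y, np.exp(3 * s) - 5, np.exp(0) - 5).auc
    assert a1 == pytest.approx(a2)


# -- PR bootstrap ------------------------------------------------------------

def test_pr_perfect_ranking_auprc_one():
    y = np.repeat([0, 1], [20, 10])
    s = np.concatenate([np.linspace(0, 0.4, 20), np.linspace(0.6, 1, 10)])
    res = pr_curve_bootstrap(y, s, n_boot=20, seed=0)
    assert res.auprc == pytest.approx(1.0)


def test_pr_random_scores_auprc_near_prevalence():
    rng = np.random.default_rng(42)
    n, prev = 5000, 0.2
    y = (rng.random(n) < prev).astype(int)
    s = rng.random(n)
    res = pr_curve_bootstrap(y, s, n_boot=10, seed=1)
    assert abs(res.auprc - prev) < 0.03


def test_pr_ci_contains_point_estimate():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 80)
    y[:2] = [0, 1]
    s = rng.random(80)
    res = pr_curve_bootstrap(y, s, n_boot=100, seed=5)
    assert res.ci[0] <= res.auprc <= res.ci[1]


def test_pr_point_estimate_equals_nonbootstrap_computation():
    from sklearn.metrics import auc, precision_recall_curve

    rng = np.random.default_rng(8)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    s = rng.random(60)
    res = pr_curve_bootstrap(y, s, n_boot=5, seed=0)
    prec, rec, _ = precision_recall_curve(y, s)
    assert res.auprc == pytest.approx(auc(rec, prec))


def test_pr_nboot_validation():
    with pytest.raises(ValueError):
        pr_curve_bootstrap([0, 1], [0.1, 0.9], n_boot=1)


# -- repeated random splits --------------------------------------------------

def _svm_pipeline(embedder):
    from senoscreen import compute_metrics as cm
    from senoscreen import oversample_positives, train_svm as ts

    def pipeline(train_ds, test_ds, seed):
        aug = oversample_positives(train_ds, embedder, k=2, seed=seed)
        model = ts(aug.features, aug.labels)
        Xt = embedder.embed(test_ds.molecules, seed=seed).values
        return cm(test_ds.labels, model.decision_scores(Xt), threshold=0.0)

    return pipeline


def test_repeated_eval_mean_and_reproducibility(small_library, mock_embedder):
    from senoscreen import SplitSpec
    from senoscreen.cli import _dataset_from_table

    ds = _dataset_from_table(small_library[["id", "smiles", "label"]])
    pipe = _svm_pipeline(mock_embedder)
    mean1, reports = repeated_random_split_eval(pipe, ds, n_iter=3,
                                                spec=SplitSpec(seed=7))
    mean2, _ = repeated_random_split_eval(pipe, ds, n_iter=3, spec=SplitSpec(seed=7))
    assert mean1 == mean2
    assert mean1["recall"] == pytest.approx(np.mean([r.recall for r in reports]))


def test_repeated_eval_reports_failing_iteration(small_library, mock_embedder):
    from senoscreen import SplitSpec
    from senoscreen.cli import _dataset_from_table

    ds = _dataset_from_table(small_library[["id", "smiles", "label"]])

    def broken(train_ds, test_ds, seed):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="iteration 0"):
        repeated_random_split_eval(broken, ds, n_iter=2, spec=SplitSpec(seed=1))


# -- lifespan extension rate -------------------------------------------------

@pytest.mark.parametrize(
    "treated,control,expected",
    [
        (26.39, 22.15, 19.1),
        (19.52, 22.15, -11.9),
        (22.77, 22.15, 2.8),
        (22.53, 22.15, 1.7),
        (23.37, 22.15, 5.5),
        (25.78, 23.15, 11.4),  # 11.36% rounds half-up to 11.4
        (10.0, 10.0, 0.0),
    ],
)
def test_lifespan_extension_rate(treated, control, expected):
    assert lifespan_extension_rate(treated, control) == expected


def test_lifespan_extension_rate_rejects_nonpositive_control():
    with pytest.raises(ValueError):
        lifespan_extension_rate(10.0, 0.0)
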