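"""The dual predictor (RBF-kernel SVM + small MLP ensemble) and the evaluation
protocol: stratified grid search, repeated random-split evaluation, confusion
metrics, and bootstrap precision–recall curves.

The two classifiers play complementary roles in the consensus screen: the SVM
contributes a signed margin score (positive = predicted senolytic) and the
MLP ensemble an averaged probability (> 0.5 = predicted senolytic). Defaults
are the tuned settings for the senolytic task: SVM ``C=20, rbf,
class_weight=balanced``; MLP with one hidden layer, Adam at lr 1e-4, up to
3000 epochs with patience 100 on the training loss, aggregated over 10
seed-differing sub-models by arithmetic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "SvmConfig",
    "MlpConfig",
    "EnsembleConfig",
    "MetricsReport",
    "PRCurveResult",
    "train_svm",
    "train_mlp",
    "train_mlp_ensemble",
    "grid_search",
    "compute_metrics",
    "pr_curve_bootstrap",
    "repeated_random_split_eval",
    "lifespan_extension_rate",
]


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SvmConfig:
    """Maximum-margin classifier settings (RBF kernel, class-balanced)."""

    C: float = 20.0
    kernel: str = "rbf"
    class_weight: Optional[str] = "balanced"

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class MlpConfig:
    """Single-hidden-layer network settings.

    The backend is scikit-learn's MLPClassifier (Adam, cross-entropy).
    ``alpha`` is the L2 penalty standing in for dropout regularization,
    which this backend does not implement. Early stopping monitors the
    training loss: training halts when it fails to improve by ``tol`` for
    ``patience`` consecutive epochs, or at ``max_epochs``.
    """

    hidden_width: int = 256
    learning_rate: float = 1e-4
    alpha: float = 1e-4
    max_epochs: int = 3000
    patience: int = 100
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be positive")


@dataclass(frozen=True)
class EnsembleConfig:
    """Sub-model count and aggregation rule (arithmetic mean of probabilities)."""

    n_sub: int = 10

    def __post_init__(self):
        if self.n_sub < 1:
            raise ValueError("n_sub must be >= 1")


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


class SvmModel:
    """Wrapper exposing the signed decision score; label = score > 0."""

    def __init__(self, estimator: SVC, config: SvmConfig):
        self.estimator = estimator
        self.config = config

    def decision_scores(self, X) -> np.ndarray:
        return np.asarray(self.estimator.decision_function(X), dtype=float)

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) > 0.0).astype(int)


def train_svm(X, y, cfg: SvmConfig = SvmConfig()) -> SvmModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    est = SVC(C=cfg.C, kernel=cfg.kernel, class_weight=cfg.class_weight)
    est.fit(X, y)
    return SvmModel(est, cfg)


class MlpModel:
    """Wrapper exposing the positive-class probability; label = p > 0.5."""

    def __init__(self, estimator: MLPClassifier, config: MlpConfig):
        self.estimator = estimator
        self.config = config

    def predict_proba(self, X) -> np.ndarray:
        pos_col = list(self.estimator.classes_).index(1)
        return np.asarray(self.estimator.predict_proba(X)[:, pos_col], dtype=float)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)


def train_mlp(X, y, cfg: MlpConfig = MlpConfig()) -> MlpModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("MLP features must be finite")
    est = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_width,),
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        alpha=cfg.alpha,
        max_iter=cfg.max_epochs,
        n_iter_no_change=cfg.patience,
        tol=cfg.tol,
        early_stopping=False,  # patience applies to the training loss
        random_state=cfg.seed,
    )
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    if not np.isfinite(est.loss_):
        raise RuntimeError("MLP training diverged (non-finite loss)")
    return MlpModel(est, cfg)


class MlpEnsemble:
    """Mean-aggregated ensemble of seed-differing MLP sub-models."""

    def __init__(self, members: List[MlpModel], config: EnsembleConfig):
        self.members = members
        self.config = config

    def predict_proba(self, X) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)


def train_mlp_ensemble(
    X,
    y,
    cfg: MlpConfig = MlpConfig(),
    ens: EnsembleConfig = EnsembleConfig(),
) -> MlpEnsemble:
    """Train ``ens.n_sub`` sub-models differing only by seed (cfg.seed + i)."""
    members = [
        train_mlp(X, y, MlpConfig(**{**asdict(cfg), "seed": cfg.seed + i}))
        for i in range(ens.n_sub)
    ]
    return MlpEnsemble(members, ens)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

_FAMILY_THRESHOLD = {"svm": 0.0, "mlp": 0.5}


def _fit_score(family: str, params: dict, X_tr, y_tr, X_te):
    if family == "svm":
        model = train_svm(X_tr, y_tr, SvmConfig(**params))
        return model.decision_scores(X_te)
    if family == "mlp":
        model = train_mlp(X_tr, y_tr, MlpConfig(**params))
        return model.predict_proba(X_te)
    raise ValueError(f"unknown model family: {family!r}")


def grid_search(
    family: str,
    grid: dict,
    X,
    y,
    folds: int = 5,
    selection: str = "f1",
    seed: int = 0,
) -> Tuple[dict, pd.DataFrame]:
    """Exhaustive stratified k-fold grid search.

    Returns the winning parameter dict (best mean ``selection`` metric, ties
    broken by mean AUC, then by grid order) and the full results table.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if int(np.bincount(y).min()) < folds:
        raise ValueError(
            f"smallest class has {int(np.bincount(y).min())} members, fewer than "
            f"{folds} folds — reduce the fold count"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    threshold = _FAMILY_THRESHOLD[family]
    rows = []
    for gi, params in enumerate(ParameterGrid(grid)):
        fold_sel, fold_auc = [], []
        for tr, te in skf.split(X, y):
            scores = _fit_score(family, params, X[tr], y[tr], X[te])
            rep = compute_metrics(y[te], scores, threshold=threshold)
            fold_sel.append(getattr(rep, selection))
            fold_auc.append(rep.auc if rep.auc is not None else 0.0)
        rows.append(
            {"grid_index": gi, "params": dict(params),
             f"mean_{selection}": float(np.mean(fold_sel)),
             "mean_auc": float(np.mean(fold_auc))}
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        [f"mean_{selection}", "mean_auc", "grid_index"],
        ascending=[False, False, True],
        kind="stable",
    )
    best = order.iloc[0]["params"]
    return dict(best), table


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived scores at a fixed decision threshold.

    Ratios with zero denominators are reported as 0.0 and their names listed
    in ``degenerate`` so averaged cross-validation reports stay computable.
    ``auc`` is None (and flagged) when y_true is single-class.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: Optional[float]
    degenerate: frozenset = frozenset()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["degenerate"] = sorted(self.degenerate)
        return d


def compute_metrics(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Confusion metrics for ``predicted label = score > threshold``.

    accuracy = (TP+TN)/(TP+FN+FP+TN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); F1 = harmonic mean of precision and recall;
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have the same length")
    if not np.isin(y_true, (0, 1)).all():
        raise ValueError("y_true must be binary")
    y_pred = (scores > threshold).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    degenerate = set()

    def ratio(num, den, name):
        if den == 0:
            degenerate.add(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, tp + fn + fp + tn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0:
        degenerate.add("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den

    if len(np.unique(y_true)) < 2:
        degenerate.add("auc")
        auc_val = None
    else:
        auc_val = float(roc_auc_score(y_true, scores))

    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        mcc=mcc, auc=auc_val, degenerate=frozenset(degenerate),
    )


# ---------------------------------------------------------------------------
# precision–recall curves with bootstrap confidence band
# ---------------------------------------------------------------------------

@dataclass
class PRCurveResult:
    recall: np.ndarray
    precision: np.ndarray
    auprc: float
    ci: Tuple[float, float]
    boot_auprcs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"recall": self.recall, "precision": self.precision})


def _auprc(y_true, scores) -> Tuple[np.ndarray, np.ndarray, float]:
    precision, recall, _ = precision_recall_curve(y_true, scores)
    return recall, precision, float(sk_auc(recall, precision))


def pr_curve_bootstrap(
    y_true,
    scores,
    n_boot: int = 100,
    ci: float = 0.95,
    seed: int = 0,
) -> PRCurveResult:
    """Precision–recall curve on the full data, with a percentile bootstrap CI
    on auPRC from ``n_boot`` resamples with replacement (resamples lacking a
    class are redrawn)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    recall, precision, point = _auprc(y_true, scores)
    rng = np.random.default_rng(seed)
    n = len(y_true)
    boots = []
    while len(boots) < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y_true[idx])) < 2:
            continue
        boots.append(_auprc(y_true[idx], scores[idx])[2])
    boots = np.array(boots)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    lo, hi = min(lo, point), max(hi, point)
    return PRCurveResult(
        recall=recall, precision=precision, auprc=point,
        ci=(float(lo), float(hi)), boot_auprcs=boots,
    )


# ---------------------------------------------------------------------------
# repeated random-split evaluation
# ---------------------------------------------------------------------------

def repeated_random_split_eval(
    pipeline: Callable,
    ds,
    n_iter: int = 20,
    spec=None,
) -> Tuple[Dict[str, float], List[MetricsReport]]:
    """Average a pipeline's test metrics over ``n_iter`` repeated random splits.

    ``pipeline(train_ds, test_ds, seed) -> MetricsReport`` is called once per
    iteration with a seed from a reproducible stream derived from
    ``spec.seed``. Returns (mean metric dict, per-iteration reports). A
    pipeline failure aborts with the iteration index in the message.
    """
    from .curation import SplitSpec, stratified_split

    spec = spec or SplitSpec()
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(spec.seed).spawn(n_iter)
    ]
    reports: List[MetricsReport] = []
    for i, it_seed in enumerate(seeds):
        it_spec = SplitSpec(
            test_fraction=spec.test_fraction, seed=it_seed, stratified=spec.stratified
        )
        train_ds, test_ds = stratified_split(ds, it_spec)
        try:
            reports.append(pipeline(train_ds, test_ds, it_seed))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at iteration {i}: {exc}") from exc
    fields = ("accuracy", "precision", "recall", "f1", "mcc")
    mean: Dict[str, float] = {
        f: float(np.mean([getattr(r, f) for r in reports])) for f in fields
    }
    aucs = [r.auc for r in reports if r.auc is not None]
    mean["auc"] = float(np.mean(aucs)) if aucs else float("nan")
    return mean, reports


# ---------------------------------------------------------------------------
# reporting utility: lifespan extension rate
# ---------------------------------------------------------------------------

def lifespan_extension_rate(treated_mean_days: float, control_mean_days: float) -> float:
    """Percent lifespan extension, 100·(treated − control)/control, rounded
    half-up to one decimal (as printed in organism survival summaries)."""
    if control_mean_days <= 0:
        raise ValueError("control mean lifespan must be positive")
    pct = 100.0 * (treated_mean_days - control_mean_days) / control_mean_days
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
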