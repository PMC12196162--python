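"""Applicability-domain gating, dual-model consensus screening, ranking and
structural-novelty reporting.

The applicability domain (AD) is distance-to-model: over the training feature
matrix, let D and σ be the mean and standard deviation of all pairwise
Euclidean distances (unordered pairs, self-distances excluded; σ uses the
population convention). A query is inside the AD when the distance to its
nearest training row is strictly below ``ADT = D + Z·σ`` (Z defaults to 0.5).

A library compound is a consensus hit only when *both* models call it
positive — SVM margin strictly above 0 and ensemble probability strictly
above 0.5 — and hits are ranked by the raw sum of the two scores. Structural
novelty is the maximum ECFP Tanimoto to the training actives (``match_degree``,
with the nearest active's id); out-of-AD records are flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .chem import Fingerprint, tanimoto
from .errors import FeatureMismatchError

__all__ = [
    "ADModel",
    "fit_ad",
    "in_ad",
    "novelty",
    "consensus_screen",
    "novelty_histogram",
    "RECORD_COLUMNS",
]


@dataclass
class ADModel:
    """Distance-to-model applicability domain: ADT = D + Z·σ."""

    D: float
    sigma: float
    Z: float
    reference_matrix: np.ndarray

    @property
    def adt(self) -> float:
        return self.D + self.Z * self.sigma

    def nearest_distance(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if queries.shape[1] != self.reference_matrix.shape[1]:
            raise FeatureMismatchError(
                f"query dim {queries.shape[1]} != reference dim "
                f"{self.reference_matrix.shape[1]}"
            )
        return cdist(queries, self.reference_matrix).min(axis=1)


def fit_ad(train_features: np.ndarray, Z: float = 0.5) -> ADModel:
    """Fit the AD from all unordered pairwise Euclidean distances of the
    training rows (self-distances excluded; population σ)."""
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit the AD")
    d = pdist(X)
    return ADModel(D=float(d.mean()), sigma=float(d.std()), Z=float(Z),
                   reference_matrix=X.copy())


def in_ad(query_rows: np.ndarray, ad: ADModel) -> np.ndarray:
    """True where the nearest-neighbour distance is strictly below ADT."""
    return ad.nearest_distance(query_rows) < ad.adt


def novelty(
    query: Fingerprint, actives: Sequence[Tuple[str, Fingerprint]]
) -> Tuple[float, str]:
    """(max Tanimoto to the active set, id of the nearest active).

    Ties on similarity break to the lexicographically smallest id.
    """
    if not actives:
        raise ValueError("active set must be non-empty")
    best_sim, best_id = -1.0, ""
    for aid, afp in sorted(actives, key=lambda t: t[0]):
        s = tanimoto(query, afp)
        if s > best_sim:
            best_sim, best_id = s, aid
    return best_sim, best_id


RECORD_COLUMNS = [
    "id", "match_degree", "match_id", "svm_score", "svm_label",
    "mlp_prob", "mlp_label", "consensus", "rank_score", "in_ad",
]


def consensus_screen(
    ids: Sequence[str],
    features: np.ndarray,
    fingerprints: Sequence[Fingerprint],
    svm_model,
    mlp_ensemble,
    ad: ADModel,
    actives: Sequence[Tuple[str, Fingerprint]],
    normalized_rank: bool = False,
) -> pd.DataFrame:
    """Score a featurized library with both models and annotate every compound.

    Returns one row per compound with the decision scores, per-model labels,
    the consensus call (both strictly positive), the rank score (raw
    ``svm_score + mlp_prob`` by default; min–max normalized within the library
    when ``normalized_rank``), the in-AD flag and the novelty annotation.
    Rows are ordered consensus hits first, descending rank score, ties broken
    by id.
    """
    features = np.asarray(features, dtype=float)
    if len(ids) != features.shape[0] or len(fingerprints) != features.shape[0]:
        raise ValueError("ids, features and fingerprints must align")
    svm_scores = svm_model.decision_scores(features)
    mlp_probs = mlp_ensemble.predict_proba(features)
    svm_labels = (svm_scores > 0.0).astype(int)
    mlp_labels = (mlp_probs > 0.5).astype(int)
    consensus = svm_labels & mlp_labels
    if normalized_rank:
        def mm(x):
            span = x.max() - x.min()
            return np.zeros_like(x) if span == 0 else (x - x.min()) / span
        rank_score = mm(svm_scores) + mm(mlp_probs)
    else:
        rank_score = svm_scores + mlp_probs
    inside = in_ad(features, ad)
    degrees, match_ids = zip(*(novelty(fp, actives) for fp in fingerprints))
    df = pd.DataFrame(
        {
            "id": [str(i) for i in ids],
            "match_degree": degrees,
            "match_id": match_ids,
            "svm_score": svm_scores,
            "svm_label": svm_labels,
            "mlp_prob": mlp_probs,
            "mlp_label": mlp_labels,
            "consensus": consensus,
            "rank_score": rank_score,
            "in_ad": inside,
        },
        columns=RECORD_COLUMNS,
    )
    df = df.sort_values(
        ["consensus", "rank_score", "id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return df


def novelty_histogram(
    records: pd.DataFrame, thresholds: Iterable[float] = (0.3, 0.5), bins: int = 10
) -> Tuple[Dict[float, int], pd.DataFrame]:
    """Counts of consensus hits with ``match_degree`` strictly below each
    threshold, plus a [0, 1] histogram table of hit match degrees for plotting.
    """
    thresholds = list(thresholds)
    normalized = sorted(set(thresholds))
    if normalized != thresholds:
        import warnings

        warnings.warn("thresholds normalized to sorted unique order", stacklevel=2)
    hits = records.loc[records["consensus"] == 1, "match_degree"].to_numpy()
    counts = {float(t): int((hits < t).sum()) for t in normalized}
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(hits, bins=edges)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
    )
    return counts, table
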