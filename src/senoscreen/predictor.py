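"""The model/results surface tying the pipeline together.

:class:`SenolyticPredictor` is constructed from a curated labeled dataset and
an embedder; ``fit()`` runs the full training protocol — stratified split,
positive oversampling, dual-model training, held-out evaluation with
bootstrap PR curves, applicability-domain fitting — and returns a
:class:`ScreeningResults` carrying the fitted models, their test metrics and
everything needed to screen external libraries.

Two oversampling modes are supported. ``leakage_safe`` (default) splits
compounds first and augments only the training partition, so no replicate of
a test compound can reach training. ``paper_faithful`` augments the full
dataset before splitting at the row level: replicates of a test-set active
then typically appear in training, which inflates recall — the mode exists to
reproduce and study that behaviour and is flagged in every output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .chem import (
    EmbedderContract,
    Fingerprint,
    Molecule,
    descriptor_list_hash,
    fingerprint,
)
from .curation import (
    AugmentedTrainingSet,
    CuratedDataset,
    SplitSpec,
    assemble_dataset,
    filter_negatives,
    oversample_positives,
    stratified_split,
)
from .models import (
    EnsembleConfig,
    MetricsReport,
    MlpConfig,
    MlpEnsemble,
    PRCurveResult,
    SvmConfig,
    SvmModel,
    compute_metrics,
    pr_curve_bootstrap,
    train_mlp_ensemble,
    train_svm,
)
from .screening import ADModel, consensus_screen, fit_ad, novelty_histogram

__all__ = ["SenolyticPredictor", "ScreeningResults"]


def _child_seeds(seed: int, n: int) -> List[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


class SenolyticPredictor:
    """Dual-model senolytic activity predictor.

    Parameters
    ----------
    dataset
        Curated labeled compounds (after negative-similarity filtering).
    embedder
        Any :class:`~senoscreen.chem.EmbedderContract`; its embeddings are the
        feature space for both classifiers and for the applicability domain.
    oversample_k
        Number of stochastic embedding replicates per positive (default 5).
    oversample_mode
        ``"leakage_safe"`` or ``"paper_faithful"`` (see module docstring).
    ad_z
        Z multiplier of the applicability-domain threshold ADT = D + Z·σ.
    seed
        Master seed; every internal source of randomness derives from it.
    """

    def __init__(
        self,
        dataset: CuratedDataset,
        embedder: EmbedderContract,
        svm_config: SvmConfig = SvmConfig(),
        mlp_config: MlpConfig = MlpConfig(),
        ensemble_config: EnsembleConfig = EnsembleConfig(),
        oversample_k: int = 5,
        oversample_mode: str = "leakage_safe",
        ad_z: float = 0.5,
        seed: int = 0,
    ):
        if oversample_mode not in ("leakage_safe", "paper_faithful"):
            raise ValueError(f"unknown oversampling mode: {oversample_mode!r}")
        self.dataset = dataset
        self.embedder = embedder
        self.svm_config = svm_config
        self.mlp_config = mlp_config
        self.ensemble_config = ensemble_config
        self.oversample_k = oversample_k
        self.oversample_mode = oversample_mode
        self.ad_z = ad_z
        self.seed = seed

    @classmethod
    def from_tables(
        cls,
        pos_table: pd.DataFrame,
        neg_table: pd.DataFrame,
        embedder: EmbedderContract,
        similarity_threshold: float = 0.9,
        **kwargs,
    ) -> "SenolyticPredictor":
        """Assemble, similarity-filter and wrap raw positive/negative tables."""
        ds = filter_negatives(
            assemble_dataset(pos_table, neg_table), threshold=similarity_threshold
        )
        return cls(ds, embedder, **kwargs)

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, embedder: EmbedderContract, **kwargs
    ) -> "SenolyticPredictor":
        """Build from a single (id, smiles, label[, provenance]) table."""
        pos = table[table["label"] == 1]
        neg = table[table["label"] == 0]
        return cls.from_tables(pos, neg, embedder, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self, test_fraction: float = 0.2, n_boot: int = 100) -> "ScreeningResults":
        seeds = _child_seeds(self.seed, 6)
        if self.oversample_mode == "leakage_safe":
            train_ds, test_ds = stratified_split(
                self.dataset,
                SplitSpec(test_fraction=test_fraction, seed=seeds[0]),
            )
            aug = oversample_positives(
                train_ds,
                self.embedder,
                k=self.oversample_k,
                mode="leakage_safe",
                seed=seeds[1],
            )
            X_train, y_train = aug.features, aug.labels
            test_mat = self.embedder.embed(test_ds.molecules, seed=seeds[2])
            X_test = test_mat.values
            y_test = test_ds.labels
        else:  # paper_faithful: augment everything, then split at row level
            aug = oversample_positives(
                self.dataset,
                self.embedder,
                k=self.oversample_k,
                mode="paper_faithful",
                seed=seeds[1],
            )
            idx = np.arange(aug.n_rows)
            tr, te = train_test_split(
                idx,
                test_size=test_fraction,
                random_state=seeds[0],
                stratify=aug.labels,
            )
            X_train, y_train = aug.features[tr], aug.labels[tr]
            X_test, y_test = aug.features[te], aug.labels[te]
            train_ids = {aug.origin[i][0] for i in tr}
            test_ds = None
            train_ds = self.dataset

        svm = train_svm(X_train, y_train, self.svm_config)
        mlp_cfg = MlpConfig(**{**asdict(self.mlp_config), "seed": seeds[3]})
        mlp = train_mlp_ensemble(X_train, y_train, mlp_cfg, self.ensemble_config)

        svm_scores = svm.decision_scores(X_test)
        mlp_probs = mlp.predict_proba(X_test)
        svm_metrics = compute_metrics(y_test, svm_scores, threshold=0.0)
        mlp_metrics = compute_metrics(y_test, mlp_probs, threshold=0.5)
        svm_pr = pr_curve_bootstrap(y_test, svm_scores, n_boot=n_boot, seed=seeds[4])
        mlp_pr = pr_curve_bootstrap(y_test, mlp_probs, n_boot=n_boot, seed=seeds[4])

        # AD reference: one deterministic base row per training compound
        # (replicate rows would bias the pairwise-distance mean downward).
        ad_mols = train_ds.molecules
        ad_matrix = self.embedder.embed(ad_mols, seed=seeds[5]).values
        ad = fit_ad(ad_matrix, Z=self.ad_z)

        actives = [
            (c.molecule.id, fingerprint(c.molecule)) for c in train_ds.positives
        ]

        return ScreeningResults(
            predictor=self,
            svm_model=svm,
            mlp_ensemble=mlp,
            ad=ad,
            active_fingerprints=actives,
            svm_metrics=svm_metrics,
            mlp_metrics=mlp_metrics,
            svm_pr=svm_pr,
            mlp_pr=mlp_pr,
            train_dataset=train_ds,
            test_dataset=test_ds,
            augmented=aug,
        )


@dataclass
class ScreeningResults:
    """Fitted dual predictor with held-out diagnostics and screening methods."""

    predictor: SenolyticPredictor
    svm_model: SvmModel
    mlp_ensemble: MlpEnsemble
    ad: ADModel
    active_fingerprints: List[Tuple[str, Fingerprint]]
    svm_metrics: MetricsReport
    mlp_metrics: MetricsReport
    svm_pr: PRCurveResult
    mlp_pr: PRCurveResult
    train_dataset: CuratedDataset
    test_dataset: Optional[CuratedDataset]
    augmented: AugmentedTrainingSet

    # -- screening ----------------------------------------------------------

    def screen(
        self,
        library: pd.DataFrame,
        embed_seed: Optional[int] = None,
        normalized_rank: bool = False,
    ) -> pd.DataFrame:
        """Score a library table (id, smiles) and return prediction records.

        The library is embedded once (seeded for reproducibility when
        ``embed_seed`` is given), scored by both models, gated by the
        applicability domain and annotated with structural novelty against
        the training actives.
        """
        mols = [Molecule.from_smiles(r.id, r.smiles) for r in library.itertuples(index=False)]
        feats = self.predictor.embedder.embed(mols, seed=embed_seed).values
        fps = [fingerprint(m) for m in mols]
        return consensus_screen(
            [m.id for m in mols],
            feats,
            fps,
            self.svm_model,
            self.mlp_ensemble,
            self.ad,
            self.active_fingerprints,
            normalized_rank=normalized_rank,
        )

    def novelty_histogram(self, records: pd.DataFrame, thresholds=(0.3, 0.5)):
        return novelty_histogram(records, thresholds=thresholds)

    # -- reporting ----------------------------------------------------------

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep, pr in (
            ("svm", self.svm_metrics, self.svm_pr),
            ("mlp_ensemble", self.mlp_metrics, self.mlp_pr),
        ):
            d = rep.to_dict()
            d["model"] = name
            d["auprc"] = pr.auprc
            d["auprc_ci_lo"], d["auprc_ci_hi"] = pr.ci
            rows.append(d)
        cols = [
            "model", "tp", "tn", "fp", "fn", "accuracy", "precision",
            "recall", "f1", "mcc", "auc", "auprc", "auprc_ci_lo", "auprc_ci_hi",
        ]
        return pd.DataFrame(rows)[cols]

    def summary(self) -> str:
        """Plain-text summary table in the style of statistical model results."""
        from statsmodels.iolib.table import SimpleTable

        p = self.predictor
        head = SimpleTable(
            [
                ["n compounds", str(len(p.dataset))],
                ["n positives", str(len(p.dataset.positives))],
                ["n negatives", str(len(p.dataset.negatives))],
                ["embedder", getattr(p.embedder, "name", "?")],
                ["oversampling", f"k={p.oversample_k} ({p.oversample_mode})"],
                ["augmented rows", str(self.augmented.n_rows)],
                ["AD threshold", f"{self.ad.adt:.4f} (D={self.ad.D:.4f}, "
                                 f"sigma={self.ad.sigma:.4f}, Z={self.ad.Z})"],
            ],
            headers=["", ""],
            title="Senolytic predictor (SVM + MLP ensemble consensus)",
        )
        mf = self.metrics_frame()
        body = SimpleTable(
            [
                [row["model"]]
                + [f"{row[c]:.3f}" if row[c] == row[c] else "nan"
                   for c in ("accuracy", "precision", "recall", "f1", "mcc",
                             "auc", "auprc")]
                for _, row in mf.iterrows()
            ],
            headers=["model", "acc", "prec", "rec", "F1", "MCC", "AUC", "auPRC"],
            title="Held-out test metrics",
        )
        return str(head) + "\n" + str(body)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Persist the model bundle: estimators + JSON metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.svm_model, directory / "svm.joblib")
        joblib.dump(self.mlp_ensemble, directory / "mlp_ensemble.joblib")
        joblib.dump(self.ad, directory / "ad.joblib")
        joblib.dump(self.active_fingerprints, directory / "actives.joblib")
        p = self.predictor
        meta = {
            "svm_config": asdict(p.svm_config),
            "mlp_config": asdict(p.mlp_config),
            "ensemble_config": asdict(p.ensemble_config),
            "oversample_k": p.oversample_k,
            "oversample_mode": p.oversample_mode,
            "ad_z": p.ad_z,
            "seed": p.seed,
            "embedder": getattr(p.embedder, "name", "?"),
            "feature_dim": int(self.ad.reference_matrix.shape[1]),
            "descriptor_list_hash": descriptor_list_hash(),
            "n_train_compounds": len(self.train_dataset),
            "metrics": self.metrics_frame().to_dict(orient="records"),
        }
        with open(directory / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @staticmethod
    def load_bundle(directory) -> dict:
        """Load a persisted bundle as a dict of its parts."""
        directory = Path(directory)
        with open(directory / "metadata.json") as fh:
            meta = json.load(fh)
        return {
            "svm_model": joblib.load(directory / "svm.joblib"),
            "mlp_ensemble": joblib.load(directory / "mlp_ensemble.joblib"),
            "ad": joblib.load(directory / "ad.joblib"),
            "active_fingerprints": joblib.load(directory / "actives.joblib"),
            "metadata": meta,
        }
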