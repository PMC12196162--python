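"""Training-corpus assembly, negative-set similarity filtering, splitting, and
stochastic-embedding oversampling of the positive class.

The curation rules mirror standard practice for phenotype-derived bioactivity
sets: the positive class is small and trusted, the negative pool is large and
noisy, so (i) a compound appearing in both tables resolves positive-wins, and
(ii) any negative whose ECFP Tanimoto similarity to *any* positive exceeds the
threshold (default 0.9, strict) is removed — it is more likely an unannotated
active than a hard negative.

Oversampling exploits a stochastic embedder: each positive is embedded ``k``
times in separate unseeded batches, so the replicates are distinct feature
rows of the *same real compound* rather than synthetic interpolations.
``mode="leakage_safe"`` (default) augments only the training partition after
splitting; ``mode="paper_faithful"`` augments before splitting, which leaks
replicate rows of test actives into training and drives recall up — it exists
to reproduce that published behaviour and is labelled accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .chem import EmbedderContract, Fingerprint, Molecule, fingerprint, tanimoto
from .errors import CurationError

__all__ = [
    "LabeledCompound",
    "CuratedDataset",
    "SplitSpec",
    "AugmentedTrainingSet",
    "assemble_dataset",
    "filter_negatives",
    "stratified_split",
    "oversample_positives",
]


@dataclass(frozen=True)
class LabeledCompound:
    molecule: Molecule
    label: int  # 1 = senolytic, 0 = non-senolytic
    provenance: str = "unspecified"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not self.provenance:
            raise ValueError("provenance must be non-empty")


@dataclass
class CuratedDataset:
    """A deduplicated labeled corpus plus an ordered log of curation actions."""

    compounds: List[LabeledCompound]
    curation_log: List[Tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = {}
        for c in self.compounds:
            if c.molecule.canonical_smiles in seen:
                raise CurationError(
                    "duplicate canonical structure in dataset: "
                    f"{seen[c.molecule.canonical_smiles]} vs {c.molecule.id}"
                )
            seen[c.molecule.canonical_smiles] = c.molecule.id

    @property
    def positives(self) -> List[LabeledCompound]:
        return [c for c in self.compounds if c.label == 1]

    @property
    def negatives(self) -> List[LabeledCompound]:
        return [c for c in self.compounds if c.label == 0]

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.compounds], dtype=int)

    @property
    def molecules(self) -> List[Molecule]:
        return [c.molecule for c in self.compounds]

    def __len__(self) -> int:
        return len(self.compounds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.molecule.id for c in self.compounds],
                "smiles": [c.molecule.canonical_smiles for c in self.compounds],
                "label": self.labels,
                "provenance": [c.provenance for c in self.compounds],
            }
        )

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curation_log, columns=["rule", "id", "reason"])


def _rows_to_compounds(table: pd.DataFrame, label: int) -> List[LabeledCompound]:
    out = []
    for row in table.itertuples(index=False):
        prov = getattr(row, "provenance", None) or "unspecified"
        mol = Molecule.from_smiles(str(row.id), row.smiles)
        out.append(LabeledCompound(molecule=mol, label=label, provenance=str(prov)))
    return out


def assemble_dataset(pos_table: pd.DataFrame, neg_table: pd.DataFrame) -> CuratedDataset:
    """Canonicalize, deduplicate and merge positive and negative tables.

    Resolution rules (each one logged):

    * one id with two conflicting structures → hard :class:`CurationError`;
    * the same canonical structure under several ids within one label → first
      occurrence kept;
    * the same canonical structure in both tables → kept once as positive
      (positive-wins: the negative pool may harbour undetected actives).
    """
    log: List[Tuple[str, str, str]] = []
    for name, table in (("positive", pos_table), ("negative", neg_table)):
        by_id = {}
        for row in table.itertuples(index=False):
            cid = str(row.id)
            if cid in by_id and by_id[cid] != row.smiles:
                raise CurationError(
                    f"{name} table: id {cid!r} carries conflicting SMILES "
                    f"{by_id[cid]!r} vs {row.smiles!r}"
                )
            by_id[cid] = row.smiles

    compounds: List[LabeledCompound] = []
    by_structure = {}
    for comp in _rows_to_compounds(pos_table, 1) + _rows_to_compounds(neg_table, 0):
        key = comp.molecule.canonical_smiles
        if key not in by_structure:
            by_structure[key] = comp
            compounds.append(comp)
            continue
        kept = by_structure[key]
        if kept.label == comp.label:
            log.append(
                ("dedup_same_label", comp.molecule.id,
                 f"duplicate structure of {kept.molecule.id}")
            )
        else:
            # positive first in iteration order, so kept is always the positive
            log.append(
                ("overlap_positive_wins", comp.molecule.id,
                 f"structure also labeled positive as {kept.molecule.id}")
            )
    return CuratedDataset(compounds=compounds, curation_log=log)


def filter_negatives(
    ds: CuratedDataset,
    threshold: float = 0.9,
    fingerprints: Optional[dict] = None,
) -> CuratedDataset:
    """Drop negatives with max ECFP Tanimoto to any positive strictly above ``threshold``.

    The boundary is strict: a negative at similarity exactly ``threshold`` is
    kept. Positives are never touched. ``fingerprints`` may supply precomputed
    ``{compound id: Fingerprint}`` to avoid recomputation.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    fps = fingerprints or {}

    def fp_of(comp: LabeledCompound) -> Fingerprint:
        if comp.molecule.id not in fps:
            fps[comp.molecule.id] = fingerprint(comp.molecule)
        return fps[comp.molecule.id]

    pos_fps = [fp_of(c) for c in ds.positives]
    kept: List[LabeledCompound] = list(ds.positives)
    log = list(ds.curation_log)
    for comp in ds.negatives:
        if pos_fps:
            sims = [tanimoto(fp_of(comp), pfp) for pfp in pos_fps]
            if max(sims) > threshold:
                log.append(
                    ("similarity_filter", comp.molecule.id,
                     f"max Tanimoto to positives {max(sims):.3f} > {threshold}")
                )
                continue
        kept.append(comp)
    # preserve original compound order
    order = {c.molecule.id: i for i, c in enumerate(ds.compounds)}
    kept.sort(key=lambda c: order[c.molecule.id])
    return CuratedDataset(compounds=kept, curation_log=log)


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")


def stratified_split(
    ds: CuratedDataset, spec: SplitSpec
) -> Tuple[CuratedDataset, CuratedDataset]:
    """Disjoint, exhaustive train/test partition preserving class proportions."""
    labels = ds.labels
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to split")
    min_class = min(n_pos, n_neg)
    if spec.stratified and min_class < 2:
        raise ValueError(
            f"smallest class has {min_class} member(s); need at least 2 for a "
            "stratified split — use fewer folds or more data"
        )
    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=spec.test_fraction,
        random_state=spec.seed,
        stratify=labels if spec.stratified else None,
        shuffle=True,
    )
    train = CuratedDataset(
        compounds=[ds.compounds[i] for i in sorted(train_idx)],
        curation_log=list(ds.curation_log),
    )
    test = CuratedDataset(compounds=[ds.compounds[i] for i in sorted(test_idx)])
    return train, test


@dataclass
class AugmentedTrainingSet:
    """Feature matrix after positive oversampling, with per-row provenance.

    ``origin`` holds one ``(compound_id, replicate_index)`` pair per row;
    replicate index is 1..k for positives and 1 for negatives.
    """

    features: np.ndarray
    labels: np.ndarray
    origin: List[Tuple[str, int]]
    k: int
    mode: str

    def __post_init__(self):
        if not (len(self.features) == len(self.labels) == len(self.origin)):
            raise ValueError("features, labels and origin must align")

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    def origin_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.origin, columns=["id", "replicate"]).assign(
            label=self.labels
        )


def oversample_positives(
    train: CuratedDataset,
    embedder: EmbedderContract,
    k: int = 5,
    mode: str = "leakage_safe",
    seed: Optional[int] = None,
) -> AugmentedTrainingSet:
    """Embed each positive ``k`` times in separate batches; negatives once.

    With a stochastic embedder each replicate batch receives fresh noise, so
    the k rows per positive differ while describing the same compound. When
    ``seed`` is given, per-batch child seeds are spawned from it: batches
    still differ from one another but the whole augmentation is reproducible.
    With a deterministic embedder and k > 1 the replicates are identical
    copies, which is allowed but warned about.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("leakage_safe", "paper_faithful"):
        raise ValueError(f"unknown oversampling mode: {mode!r}")
    if getattr(embedder, "deterministic", False) and k > 1:
        warnings.warn(
            "deterministic embedder with k > 1: replicate rows are identical copies",
            stacklevel=2,
        )
    positives = train.positives
    negatives = train.negatives
    if seed is not None:
        child_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(k + 1)
        ]
    else:
        child_seeds = [None] * (k + 1)

    blocks = []
    labels: List[int] = []
    origin: List[Tuple[str, int]] = []
    pos_mols = [c.molecule for c in positives]
    for rep in range(1, k + 1):
        if pos_mols:
            mat = embedder.embed(pos_mols, seed=child_seeds[rep - 1])
            blocks.append(mat.values)
            labels.extend([1] * len(pos_mols))
            origin.extend((m.id, rep) for m in pos_mols)
    neg_mols = [c.molecule for c in negatives]
    if neg_mols:
        mat = embedder.embed(neg_mols, seed=child_seeds[k])
        blocks.append(mat.values)
        labels.extend([0] * len(neg_mols))
        origin.extend((m.id, 1) for m in neg_mols)

    features = (
        np.vstack(blocks) if blocks else np.empty((0, embedder.dim))
    )
    return AugmentedTrainingSet(
        features=features,
        labels=np.array(labels, dtype=int),
        origin=origin,
        k=k,
        mode=mode,
    )
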