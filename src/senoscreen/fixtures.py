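"""Synthetic compound libraries, a stochastic mock embedder, and source maps
with planted signal.

The generator does not aim for chemical realism — only for the statistical
structure the pipeline assumes: actives share a small set of planted
heteroaromatic scaffolds, negatives come from disjoint decoy scaffolds (except
for a controllable ``scaffold_overlap`` fraction of negatives built on active
scaffolds), and labels can be flipped at a ``label_noise`` rate. Every
generated SMILES parses and canonicalizes; canonical structures are unique
within a library.

The mock embedder emulates a pretrained chemical language model whose output
varies from batch to batch: the base vector of a compound is a fixed seeded
Gaussian random projection of its ECFP count vector (so embedding geometry
tracks structural similarity), and every unseeded batch adds independent
N(0, τ²I) noise per row. With a fixed seed the batch is reproducible; with
τ = 0 the embedder is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import EmbeddingMatrix, Molecule, register_embedder
from .enrichment import SourceMapping

__all__ = [
    "FixtureSpec",
    "MockEmbedderSpec",
    "MockEmbedder",
    "generate_library",
    "generate_source_map",
    "scaffold_grammar",
]


def scaffold_grammar() -> dict:
    """The frozen scaffold templates and substituent grammar."""
    with resources.files("senoscreen.data").joinpath("scaffolds.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a synthetic library.

    Defaults are the benchmark conditions used throughout the test-suite:
    a 1:20 imbalanced library of 50 actives and 1000 inactives, 5% of
    negatives carrying an active scaffold and 2% label noise.
    """

    n_pos: int = 50
    n_neg: int = 1000
    n_scaffolds: int = 3
    label_noise: float = 0.02
    scaffold_overlap: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("compound counts must be positive")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must be in [0, 1)")
        if not (0.0 <= self.scaffold_overlap <= 1.0):
            raise ValueError("scaffold_overlap must be in [0, 1]")
        grammar = scaffold_grammar()
        if self.n_scaffolds < 1 or self.n_scaffolds > len(grammar["active_templates"]):
            raise ValueError(
                f"n_scaffolds must be in [1, {len(grammar['active_templates'])}]"
            )


def _decorate(template: str, r1: str, r2: str) -> str:
    return template.replace("{R1}", r1).replace("{R2}", r2)


def _sample_unique(
    templates: Sequence[str],
    subs: Sequence[str],
    count: int,
    rng: np.random.Generator,
    taken: Set[str],
) -> List[Tuple[str, str]]:
    """Draw ``count`` molecules with unseen canonical SMILES from the grammar.

    Returns (canonical_smiles, template) pairs. Raises when the grammar is
    exhausted, which marks the spec as infeasible.
    """
    combos = [
        (t, a, b) for t in templates for a, b in product(subs, subs)
    ]
    rng.shuffle(combos)
    out: List[Tuple[str, str]] = []
    for t, a, b in combos:
        if len(out) == count:
            break
        smiles = _decorate(t, a, b)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar guarantees parseability; guard anyway
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in taken:
            continue
        taken.add(canonical)
        out.append((canonical, t))
    if len(out) < count:
        raise ValueError(
            f"infeasible fixture: grammar exhausted at {len(out)} of {count} "
            "requested unique molecules"
        )
    return out


def generate_library(spec: FixtureSpec) -> pd.DataFrame:
    """Generate a labeled compound table under ``spec``.

    Columns: id, smiles (canonical), label, scaffold (template string),
    scaffold_class ('active'/'decoy') and true_label (pre-noise). With
    ``label_noise=0`` and ``scaffold_overlap=0``, ``label`` equals membership
    of the active scaffold class exactly.
    """
    grammar = scaffold_grammar()
    rng = np.random.default_rng(spec.seed)
    active_templates = grammar["active_templates"][: spec.n_scaffolds]
    decoy_templates = grammar["decoy_templates"]
    subs = grammar["substituents"]

    taken: Set[str] = set()
    pos = _sample_unique(active_templates, subs, spec.n_pos, rng, taken)
    n_overlap = int(round(spec.scaffold_overlap * spec.n_neg))
    neg_overlap = _sample_unique(active_templates, subs, n_overlap, rng, taken)
    neg_decoy = _sample_unique(
        decoy_templates, subs, spec.n_neg - n_overlap, rng, taken
    )

    rows = []
    for i, (smiles, template) in enumerate(pos):
        rows.append(
            {"id": f"POS{i:05d}", "smiles": smiles, "true_label": 1,
             "scaffold": template, "scaffold_class": "active"}
        )
    for i, (smiles, template) in enumerate(neg_overlap + neg_decoy):
        cls = "active" if i < len(neg_overlap) else "decoy"
        rows.append(
            {"id": f"NEG{i:05d}", "smiles": smiles, "true_label": 0,
             "scaffold": template, "scaffold_class": cls}
        )
    df = pd.DataFrame(rows)
    flips = rng.random(len(df)) < spec.label_noise
    df["label"] = np.where(flips, 1 - df["true_label"], df["true_label"])
    return df[
        ["id", "smiles", "label", "true_label", "scaffold", "scaffold_class"]
    ]


# ---------------------------------------------------------------------------
# mock embedder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MockEmbedderSpec:
    dim: int = 768
    tau: float = 0.05  # per-batch noise standard deviation
    base_seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


class MockEmbedder:
    """Stochastic mock satisfying :class:`senoscreen.chem.EmbedderContract`.

    ``base(molecule)`` is a pure function of (canonical SMILES, base_seed):
    the ECFP-2048 count vector, L2-normalized, projected through a fixed
    N(0, 1/√dim) Gaussian matrix drawn once from ``base_seed``. Each call adds
    row-wise N(0, τ²I) noise drawn from ``seed`` (or fresh OS entropy when
    unseeded), emulating batch-to-batch embedding variability.
    """

    _NBITS = 2048
    _RADIUS = 2

    def __init__(self, spec: MockEmbedderSpec = MockEmbedderSpec()):
        self.spec = spec
        self.name = f"mock-{spec.dim}d-tau{spec.tau:g}"
        self.dim = spec.dim
        self.deterministic = spec.tau == 0.0
        proj_rng = np.random.default_rng(spec.base_seed)
        self._projection = proj_rng.normal(
            0.0, 1.0 / np.sqrt(spec.dim), size=(self._NBITS, spec.dim)
        )
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self._RADIUS, fpSize=self._NBITS
        )
        self._base_cache: Dict[str, np.ndarray] = {}

    def base(self, mol: Molecule) -> np.ndarray:
        key = mol.canonical_smiles
        if key not in self._base_cache:
            counts = np.zeros(self._NBITS)
            fp = self._gen.GetCountFingerprint(mol.rdkit_mol())
            for bit, c in fp.GetNonzeroElements().items():
                counts[bit] = c
            norm = np.linalg.norm(counts)
            if norm > 0:
                counts = counts / norm
            self._base_cache[key] = counts @ self._projection
        return self._base_cache[key]

    def embed(
        self, batch: Sequence[Molecule], seed: Optional[int] = None
    ) -> EmbeddingMatrix:
        base = (
            np.vstack([self.base(m) for m in batch])
            if batch
            else np.empty((0, self.dim))
        )
        tag = f"seed={seed}" if seed is not None else "unseeded"
        if self.spec.tau == 0.0 or not len(batch):
            return EmbeddingMatrix(values=base, batch_tag=tag)
        rng = np.random.default_rng(seed)  # seed=None -> fresh entropy
        noise = rng.normal(0.0, self.spec.tau, size=base.shape)
        return EmbeddingMatrix(values=base + noise, batch_tag=tag)


def default_mock_embedder(
    dim: int = 768, tau: float = 0.05, base_seed: int = 0
) -> MockEmbedder:
    emb = MockEmbedder(MockEmbedderSpec(dim=dim, tau=tau, base_seed=base_seed))
    register_embedder(emb)
    return emb


# ---------------------------------------------------------------------------
# source maps with planted enrichment
# ---------------------------------------------------------------------------

def generate_source_map(
    compound_ids: Iterable[str],
    n_sources: int = 20,
    planted: Optional[Tuple[str, Iterable[str]]] = None,
    seed: int = 0,
    sources_per_compound: Tuple[int, int] = (1, 2),
) -> SourceMapping:
    """Random compound→source assignment with an optional planted source.

    Every compound is assigned 1–2 random sources; ``planted=(name, members)``
    additionally creates a source containing exactly the given member ids
    (which must all be in ``compound_ids``).
    """
    ids = [str(c) for c in compound_ids]
    id_set = set(ids)
    rng = np.random.default_rng(seed)
    entries: Dict[str, Set[str]] = {cid: set() for cid in ids}
    names = [f"source_{i:03d}" for i in range(n_sources)]
    lo, hi = sources_per_compound
    for cid in ids:
        for name in rng.choice(names, size=rng.integers(lo, hi + 1), replace=False):
            entries[cid].add(str(name))
    if planted is not None:
        pname, members = planted
        members = [str(m) for m in members]
        missing = set(members) - id_set
        if missing:
            raise ValueError(f"planted members not in compound list: {sorted(missing)}")
        for m in members:
            entries[m].add(pname)
    return SourceMapping(entries=entries)
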