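"""Reading and writing the plain-text formats the pipeline consumes.

Compound tables are CSV/TSV with columns ``id``, ``smiles`` and optionally
``label`` and ``provenance``; SDF input maps the molecule title to ``id``.
Feature matrices are written with a JSON sidecar recording provenance
(scheme, bits/radius or embedding dim, descriptor-list hash, embedder, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "read_compound_table",
    "write_compound_table",
    "read_sdf",
    "write_feature_matrix",
    "read_feature_matrix",
]

REQUIRED_COLUMNS = ("id", "smiles")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_compound_table(path) -> pd.DataFrame:
    """Read a compound table (CSV or TSV by extension); lower-cases headers."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["id"] = df["id"].astype(str)
    return df


def write_compound_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_sdf(path) -> pd.DataFrame:
    """Read an (uncompressed) SDF; the molecule title becomes ``id``."""
    rows = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rows.append({"id": name or f"sdf_{i}", "smiles": Chem.MolToSmiles(mol)})
    return pd.DataFrame(rows, columns=["id", "smiles"])


def write_feature_matrix(
    values: np.ndarray,
    ids,
    path,
    header: Optional[dict] = None,
) -> None:
    """Write a feature matrix as TSV (id + columns) with a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(values))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(header or {}, fh, indent=1)


def read_feature_matrix(path):
    """Read a TSV feature matrix; returns (ids, values, header dict)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    ids = df["id"].astype(str).tolist()
    values = df.drop(columns=["id"]).to_numpy(dtype=float)
    sidecar = path.with_suffix(path.suffix + ".json")
    header = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            header = json.load(fh)
    return ids, values, header
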