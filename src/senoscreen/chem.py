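"""Molecular identity, fingerprints, descriptors, similarity, and the embedder contract.

Everything downstream (curation, training, screening) works with three feature
views of a molecule:

* hashed circular fingerprints (ECFP / Morgan, default 2048 bits, radius 2) or
  path-based FP2 bits via the optional Open Babel backend;
* a fixed, frozen vector of 200 RDKit descriptors;
* dense embeddings produced by any object satisfying :class:`EmbedderContract`
  (a pretrained chemical language model in production, a stochastic mock in
  tests — see :mod:`senoscreen.fixtures`).

All feature functions are pure functions of the canonical SMILES, so two
spellings of the same structure always featurize identically.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdmolops

from .errors import CapabilityError, FeatureMismatchError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "Fingerprint",
    "DescriptorVector",
    "EmbeddingMatrix",
    "EmbedderContract",
    "canonicalize",
    "fingerprint",
    "descriptors",
    "descriptor_names",
    "tanimoto",
    "jaccard_distance",
    "embed",
    "register_embedder",
    "get_embedder",
]


# ---------------------------------------------------------------------------
# canonical SMILES and the Molecule record
# ---------------------------------------------------------------------------

def canonicalize(smiles: str, keep_largest_fragment: bool = False) -> str:
    """Return the canonical (isomeric) RDKit SMILES for ``smiles``.

    Parameters
    ----------
    smiles
        Input SMILES; must be non-empty and parseable.
    keep_largest_fragment
        If True, multi-fragment inputs (salts, mixtures) are reduced to their
        largest fragment by heavy-atom count. By default the input is kept
        intact and a warning is emitted for multi-fragment structures.

    Raises
    ------
    SmilesParseError
        If the string is empty or RDKit cannot parse it.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    frags = rdmolops.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        if keep_largest_fragment:
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        else:
            warnings.warn(
                f"multi-fragment SMILES kept intact: {smiles!r}", stacklevel=2
            )
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """A compound with a stable id and its canonical structure."""

    id: str
    input_smiles: str
    canonical_smiles: str

    @classmethod
    def from_smiles(
        cls, id: str, smiles: str, keep_largest_fragment: bool = False
    ) -> "Molecule":
        return cls(
            id=str(id),
            input_smiles=smiles,
            canonical_smiles=canonicalize(smiles, keep_largest_fragment),
        )

    def rdkit_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.canonical_smiles)
        if mol is None:  # cannot normally happen for a constructed Molecule
            raise SmilesParseError(self.canonical_smiles)
        return mol


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

ECFP_DEFAULT_NBITS = 2048
ECFP_DEFAULT_RADIUS = 2
FP2_DEFAULT_NBITS = 1024


@dataclass(frozen=True)
class Fingerprint:
    """A hashed binary fingerprint stored as its set of on-bit indices."""

    scheme: str  # "ecfp" or "fp2"
    nbits: int
    on_bits: frozenset
    radius: int = 0  # meaningful for ecfp only

    def __post_init__(self):
        if self.on_bits and (max(self.on_bits) >= self.nbits or min(self.on_bits) < 0):
            raise ValueError("fingerprint bit index outside [0, nbits)")

    @property
    def n_on(self) -> int:
        return len(self.on_bits)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.nbits, dtype=np.uint8)
        if self.on_bits:
            arr[sorted(self.on_bits)] = 1
        return arr


def _ecfp_bits(mol: Chem.Mol, nbits: int, radius: int) -> frozenset:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


def _fp2_bits(smiles: str, nbits: int) -> frozenset:
    """Path-based FP2 bits via the Open Babel command-line backend.

    ``obabel -ofpt`` prints the 1024-bit fingerprint as 32-bit hexadecimal
    words; word ``j`` (in printed order) holds bits ``[32*j, 32*j + 32)`` with
    bit ``i`` set when ``word & (1 << i)``. The mapping convention is fixed and
    documented here; only within-convention consistency matters downstream.
    """
    if shutil.which("obabel") is None:
        raise CapabilityError(
            "FP2 fingerprints need the Open Babel backend ('obabel' not on PATH)"
        )
    if nbits != FP2_DEFAULT_NBITS:
        raise ValueError("the FP2 backend produces 1024-bit fingerprints")
    out = subprocess.run(
        ["obabel", f"-:{smiles}", "-ofpt", "-xfFP2"],
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    words = [w for line in out.splitlines() if not line.startswith(">") for w in line.split()]
    bits = set()
    for j, word in enumerate(words):
        val = int(word, 16)
        for i in range(32):
            if val & (1 << i):
                bits.add(32 * j + i)
    return frozenset(b for b in bits if b < nbits)


def fingerprint(
    mol: Molecule,
    scheme: str = "ecfp",
    nbits: Optional[int] = None,
    radius: int = ECFP_DEFAULT_RADIUS,
) -> Fingerprint:
    """Compute a binary fingerprint of ``mol``.

    ``scheme`` is ``"ecfp"`` (default 2048 bits, radius 2) or ``"fp2"``
    (1024 bits; requires Open Babel).
    """
    if scheme == "ecfp":
        nbits = ECFP_DEFAULT_NBITS if nbits is None else nbits
        if radius < 0:
            raise ValueError("radius must be non-negative")
        bits = _ecfp_bits(mol.rdkit_mol(), nbits, radius)
        return Fingerprint(scheme="ecfp", nbits=nbits, on_bits=bits, radius=radius)
    if scheme == "fp2":
        nbits = FP2_DEFAULT_NBITS if nbits is None else nbits
        bits = _fp2_bits(mol.canonical_smiles, nbits)
        return Fingerprint(scheme="fp2", nbits=nbits, on_bits=bits)
    raise ValueError(f"unsupported fingerprint scheme: {scheme!r}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a∩b| / |a∪b| of two fingerprints.

    Both-empty fingerprints are defined as similarity 0.0 (with a warning):
    a conservative choice for novelty screening, where an undefined 0/0
    should never report a query as identical to a training active.
    """
    if a.scheme != b.scheme or a.nbits != b.nbits:
        raise FeatureMismatchError(
            f"cannot compare {a.scheme}/{a.nbits} with {b.scheme}/{b.nbits}"
        )
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0.0", stacklevel=2)
        return 0.0
    return len(a.on_bits & b.on_bits) / union


def jaccard_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard (Tanimoto) distance, 1 − Tanimoto similarity."""
    return 1.0 - tanimoto(a, b)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def _load_descriptor_names() -> tuple:
    with resources.files("senoscreen.data").joinpath("descriptors_200.json").open() as fh:
        payload = json.load(fh)
    return tuple(payload["names"])


DESCRIPTOR_NAMES: tuple = _load_descriptor_names()
_DESC_FUNCS = dict(Descriptors._descList)


def descriptor_names() -> tuple:
    """The frozen, alphabetically ordered list of the 200 descriptor names."""
    return DESCRIPTOR_NAMES


def descriptor_list_hash() -> str:
    return hashlib.sha256("|".join(DESCRIPTOR_NAMES).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class DescriptorVector:
    """200 RDKit descriptor values in the frozen documented order.

    ``flagged`` marks entries that failed to compute or were non-finite;
    their values follow the NaN policy used at construction.
    """

    values: np.ndarray
    names: tuple = DESCRIPTOR_NAMES
    flagged: frozenset = frozenset()

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("descriptor vector length mismatch")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def descriptors(mol: Molecule, nan_policy: str = "flag") -> DescriptorVector:
    """Compute the frozen 200-descriptor vector for ``mol``.

    nan_policy:
        * ``"flag"`` (default) — failed/non-finite entries kept as NaN and
          recorded in ``flagged``;
        * ``"impute_zero"`` — replaced by 0.0 and recorded in ``flagged``;
        * ``"fail"`` — raise on the first failure.
    """
    if nan_policy not in ("flag", "impute_zero", "fail"):
        raise ValueError(f"unknown nan_policy: {nan_policy!r}")
    rdmol = mol.rdkit_mol()
    values = np.empty(len(DESCRIPTOR_NAMES), dtype=float)
    flagged = set()
    for i, name in enumerate(DESCRIPTOR_NAMES):
        try:
            v = float(_DESC_FUNCS[name](rdmol))
        except Exception as exc:  # descriptor-specific failure on a valid molecule
            if nan_policy == "fail":
                raise SenoscreenDescriptorError(mol.id, name) from exc
            v = np.nan
        if not np.isfinite(v):
            if nan_policy == "fail":
                raise SenoscreenDescriptorError(mol.id, name)
            flagged.add(name)
            v = 0.0 if nan_policy == "impute_zero" else np.nan
        values[i] = v
    return DescriptorVector(values=values, flagged=frozenset(flagged))


class SenoscreenDescriptorError(Exception):
    def __init__(self, mol_id: str, descriptor: str):
        super().__init__(f"descriptor {descriptor!r} failed for molecule {mol_id!r}")
        self.mol_id = mol_id
        self.descriptor = descriptor


# ---------------------------------------------------------------------------
# embedder contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingMatrix:
    """A dense n×dim embedding block, row order matching the input batch."""

    values: np.ndarray
    batch_tag: str = ""

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("embedding values must be 2-D")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@runtime_checkable
class EmbedderContract(Protocol):
    """The interface every embedding backend must satisfy.

    ``embed(batch, seed)`` returns an :class:`EmbeddingMatrix` of shape
    (len(batch), dim). With a fixed seed, repeated calls on the same batch
    must be bit-identical. With ``seed=None`` the embedder *may* return
    batch-varying output — that variability is the raw material for the
    positive-oversampling strategy.
    """

    name: str
    dim: int
    deterministic: bool

    def embed(
        self, batch: Sequence[Molecule], seed: Optional[int] = None
    ) -> EmbeddingMatrix: ...


_EMBEDDER_REGISTRY: dict = {}


def register_embedder(embedder: EmbedderContract) -> None:
    _EMBEDDER_REGISTRY[embedder.name] = embedder


def get_embedder(name: str) -> EmbedderContract:
    try:
        return _EMBEDDER_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown embedder {name!r}; registered: {sorted(_EMBEDDER_REGISTRY)}"
        ) from None


def embed(
    batch: Iterable[Molecule],
    embedder: EmbedderContract,
    seed: Optional[int] = None,
) -> EmbeddingMatrix:
    """Embed ``batch`` through ``embedder``; see :class:`EmbedderContract`."""
    batch = list(batch)
    out = embedder.embed(batch, seed=seed)
    if out.values.shape != (len(batch), embedder.dim):
        raise FeatureMismatchError(
            f"embedder {embedder.name!r} returned shape {out.values.shape}, "
            f"declared dim {embedder.dim}"
        )
    return out
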