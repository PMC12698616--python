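"""Molecular parsing, fingerprints, similarity, and physicochemical properties.

This module wraps RDKit behind small, deterministic primitives used by the
rest of the package:

* :func:`canonicalize` parses a SMILES string into a :class:`CompoundRecord`
  holding the canonical form (largest organic fragment, charges preserved).
* :func:`morgan_fp` / :func:`maccs_fp` / :func:`path_fp` compute binary
  fingerprints as :class:`Fingerprint` objects.
* :func:`tanimoto` and :func:`cosine` are the two similarity primitives.
* :func:`physchem` computes the six properties used for property-matched
  decoy selection (MW, logP, rotatable bonds, HBA, HBD, net formal charge).

Conventions: molecular weight is the average (natural-abundance) weight
including implicit hydrogens; logP is the Crippen atom-contribution
estimate; HBA/HBD are Lipinski N/O counts. Salts are reduced to the largest
organic fragment without neutralizing formal charges, because decoy
matching requires the real net charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "Fingerprint",
    "PropertyVector",
    "canonicalize",
    "morgan_fp",
    "maccs_fp",
    "path_fp",
    "tanimoto",
    "tanimoto_matrix",
    "physchem",
    "cosine",
]


@dataclass(frozen=True)
class CompoundRecord:
    """A parsed molecule. ``parse_ok`` is False for unparsable input."""

    compound_id: str
    smiles: str
    parse_ok: bool
    mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def require_mol(self) -> Chem.Mol:
        if not self.parse_ok or self.mol is None:
            raise ValueError(
                f"compound {self.compound_id!r} has no parsed structure"
            )
        return self.mol


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint with its generating parameters."""

    bits: np.ndarray  # uint8 vector of 0/1
    n_bits: int
    radius: int
    kind: str  # {"morgan", "maccs", "path"}

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1 or arr.shape[0] != self.n_bits:
            raise ValueError("bits length does not match n_bits")
        object.__setattr__(self, "bits", arr)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def same_params(self, other: "Fingerprint") -> bool:
        return (
            self.kind == other.kind
            and self.n_bits == other.n_bits
            and self.radius == other.radius
        )


@dataclass(frozen=True)
class PropertyVector:
    """The six physicochemical properties used for decoy matching."""

    mw: float
    logp: float
    rot_bonds: int
    hba: int
    hbd: int
    net_charge: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mw, self.logp, self.rot_bonds, self.hba, self.hbd, self.net_charge],
            dtype=float,
        )


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def canonicalize(smiles: str, compound_id: str = "") -> CompoundRecord:
    """Parse a SMILES string and return its canonical form.

    Multi-fragment inputs (salts) are reduced to the largest organic
    fragment; formal charges are kept. Unparsable input yields a record
    with ``parse_ok=False`` rather than raising, so the caller can choose
    between drop-with-warning and abort.
    """
    if not isinstance(smiles, str) or not smiles:
        raise ValueError("smiles must be a non-empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return CompoundRecord(compound_id=compound_id, smiles=smiles, parse_ok=False)
    if len(Chem.GetMolFrags(mol)) > 1:
        mol = _FRAGMENT_CHOOSER.choose(mol)
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    return CompoundRecord(
        compound_id=compound_id, smiles=canonical, parse_ok=True, mol=mol
    )


def morgan_fp(record: CompoundRecord, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Folded Morgan (circular) fingerprint.

    256 bits are used for the summed pair encoding; 2048 bits (the default
    here) for Tanimoto thresholds and filters, where folding collisions
    matter more.
    """
    if n_bits <= 0 or radius < 0:
        raise ValueError("n_bits must be positive and radius non-negative")
    mol = record.require_mol()
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=arr, n_bits=n_bits, radius=radius, kind="morgan")


def maccs_fp(record: CompoundRecord) -> Fingerprint:
    mol = record.require_mol()
    bv = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(167, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=arr, n_bits=167, radius=0, kind="maccs")


def path_fp(record: CompoundRecord, n_bits: int = 2048) -> Fingerprint:
    """RDKit topological path fingerprint."""
    mol = record.require_mol()
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=arr, n_bits=n_bits, radius=0, kind="path")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| over set bits.

    Raises on mismatched fingerprint parameters and on two empty
    fingerprints (the ratio is undefined).
    """
    if not a.same_params(b):
        raise ValueError(
            f"fingerprint parameter mismatch: ({a.kind},{a.n_bits},{a.radius}) vs "
            f"({b.kind},{b.n_bits},{b.radius})"
        )
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    return inter / union


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between rows of two 0/1 matrices.

    Vectorized helper for pipeline-scale filtering; semantics match
    :func:`tanimoto` except that all-zero vs all-zero yields 0.
    """
    A = np.asarray(A, dtype=np.float32)
    B = np.asarray(B, dtype=np.float32)
    inter = A @ B.T
    pa = A.sum(axis=1)[:, None]
    pb = B.sum(axis=1)[None, :]
    union = pa + pb - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = np.where(union > 0, inter / union, 0.0)
    return tc


def physchem(record: CompoundRecord) -> PropertyVector:
    """Compute the six decoy-matching properties for a parsed molecule."""
    mol = record.require_mol()
    return PropertyVector(
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        rot_bonds=int(Lipinski.NumRotatableBonds(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        net_charge=int(Chem.GetFormalCharge(mol)),
    )


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity between two embedding vectors.

    Used by the embedding baselines; raises on dimension mismatch or a
    zero-norm vector.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("embedding vectors must share one fixed dimension")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))
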