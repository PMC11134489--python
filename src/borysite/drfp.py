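"""Differential reaction fingerprints (DRFP), built from scratch.

The fingerprint of a reaction is the symmetric set difference between
the circular-substructure SMILES shingles of the reactant side and the
product side, hashed onto a fixed-length bit vector. Identical features
on both sides cancel, so the bits that remain describe exactly what the
reaction *changes* - for a site reaction ``substrate>>site_product``
that is the chemical environment of the borylated position.

Shingles are the canonical SMILES of every atom-centred circular
environment up to ``radius`` bonds plus every smallest ring. Hashing
uses CRC-32 (:func:`zlib.crc32`), a platform-independent 32-bit string
hash, so fingerprints are bit-identical across processes and machines.
Agents are ignored by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_core import Molecule, ParseError, canonicalize

#: Name of the shingle hash, recorded in run configs for reproducibility.
HASH_NAME = "crc32"

DEFAULT_N_BITS = 256
DEFAULT_RADIUS = 3


def stable_hash(shingle: str) -> int:
    """Deterministic 32-bit hash of a shingle string (CRC-32)."""
    return zlib.crc32(shingle.encode("utf-8")) & 0xFFFFFFFF


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary feature vector for one reaction."""

    bits: np.ndarray
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if len(self.bits) != self.n_bits:
            raise ValueError(f"expected {self.n_bits} bits, got {len(self.bits)}")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def extract_shingles(mol: Molecule, radius: int = DEFAULT_RADIUS) -> set[str]:
    """Circular-environment and ring shingles of a molecule.

    For every atom and every r in 0..radius, the canonical SMILES of the
    radius-r environment centred on that atom; plus the canonical SMILES
    of every smallest ring. Returned as a set, so symmetry-equivalent
    environments collapse and the result is independent of atom order.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    m = mol.mol
    shingles: set[str] = set()
    for atom in m.GetAtoms():
        idx = atom.GetIdx()
        shingles.add(Chem.MolFragmentToSmiles(m, atomsToUse=[idx], bondsToUse=[]))
        for r in range(1, radius + 1):
            env = Chem.FindAtomEnvironmentOfRadiusN(m, r, idx)
            if not env:
                break
            atoms = set()
            for bond_idx in env:
                bond = m.GetBondWithIdx(bond_idx)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            shingles.add(
                Chem.MolFragmentToSmiles(m, atomsToUse=sorted(atoms), bondsToUse=list(env))
            )
    for ring in Chem.GetSymmSSSR(m):
        ring_atoms = sorted(ring)
        ring_bonds = [
            b.GetIdx()
            for b in m.GetBonds()
            if b.GetBeginAtomIdx() in ring and b.GetEndAtomIdx() in ring
        ]
        shingles.add(
            Chem.MolFragmentToSmiles(m, atomsToUse=ring_atoms, bondsToUse=ring_bonds)
        )
    return shingles


@lru_cache(maxsize=65536)
def _cached_shingles(canonical_smiles: str, radius: int) -> frozenset[str]:
    return frozenset(extract_shingles(Molecule(canonical_smiles), radius))


def _side_shingles(field: str, radius: int) -> set[str]:
    shingles: set[str] = set()
    for token in field.split("."):
        if token:
            shingles |= _cached_shingles(canonicalize(token), radius)
    return shingles


def reaction_shingles(rxn_smiles: str, radius: int = DEFAULT_RADIUS) -> set[str]:
    """Symmetric difference of reactant-side and product-side shingles."""
    parts = rxn_smiles.split(">")
    if len(parts) != 3:
        raise ParseError(f"reaction SMILES needs two '>' separators: {rxn_smiles!r}")
    reactants = _side_shingles(parts[0], radius)
    products = _side_shingles(parts[2], radius)
    return reactants ^ products


def drfp(
    rxn_smiles: str,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
) -> BitFingerprint:
    """Differential reaction fingerprint of one reaction SMILES."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    bits = np.zeros(n_bits, dtype=np.uint8)
    for shingle in reaction_shingles(rxn_smiles, radius):
        bits[stable_hash(shingle) % n_bits] = 1
    return BitFingerprint(bits=bits, n_bits=n_bits, radius=radius)


class DrfpFeaturizer(TransformerMixin, BaseEstimator):
    """Transform reaction SMILES into a dense 0/1 DRFP matrix.

    Stateless (``fit`` only validates parameters), so it slots into
    scikit-learn pipelines ahead of any estimator.

    Parameters
    ----------
    n_bits : int, default 256
        Fingerprint length.
    radius : int, default 3
        Maximum circular-environment radius in bonds.
    """

    def __init__(self, n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS):
        self.n_bits = n_bits
        self.radius = radius

    def fit(self, X, y=None):
        if self.n_bits < 1:
            raise ValueError("n_bits must be >= 1")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        """X: iterable of reaction SMILES -> (n_samples, n_bits) array."""
        rows = [drfp(rxn, self.n_bits, self.radius).bits for rxn in X]
        if not rows:
            return np.zeros((0, self.n_bits), dtype=np.uint8)
        return np.vstack(rows)
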