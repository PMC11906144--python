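"""Molecular descriptor families computed from isomeric SMILES with RDKit.

Four families are exposed: the full physicochemical descriptor list, Morgan
circular fingerprints (2048 bits, radius 2, chirality-aware hashing so that
enantiomers can receive distinct bit patterns), RDKit path-based fingerprints,
and the 166 MACCS substructure keys. All featurization is deterministic; parsed
molecules are cached keyed by their input SMILES.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .featureblock import FeatureBlock

logger = logging.getLogger(__name__)


@lru_cache(maxsize=4096)
def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical isomeric SMILES (stereochemistry retained)."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles), isomericSmiles=True)


def _check_molecules(molecules: Sequence) -> list[str]:
    if not molecules:
        raise ValueError("empty molecule list")
    return [m.molecule_id for m in molecules]


def physchem_descriptors(molecules: Sequence) -> FeatureBlock:
    """The toolkit's full physicochemical descriptor list (~200 columns).

    Columns that come out non-finite for any molecule are dropped with a
    logged warning (handled by FeatureBlock validation).
    """
    ids = _check_molecules(molecules)
    names = [name for name, _ in Descriptors._descList]
    rows = np.empty((len(molecules), len(names)))
    for i, m in enumerate(molecules):
        mol = _mol_from_smiles(m.smiles)
        desc = Descriptors.CalcMolDescriptors(mol)
        rows[i] = [desc[name] for name in names]
    return FeatureBlock(ids, list(names), rows, block_name="physchem")


def morgan_fingerprint(
    molecules: Sequence, n_bits: int = 2048, radius: int = 2
) -> FeatureBlock:
    """Morgan circular fingerprints as a binary matrix with ``n_bits`` columns.

    Hashing includes chirality, so enantiomer pairs described by isomeric
    SMILES may (and for menthol do) produce different rows.
    """
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    ids = _check_molecules(molecules)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=True
    )
    rows = np.zeros((len(molecules), n_bits))
    for i, m in enumerate(molecules):
        fp = gen.GetFingerprint(_mol_from_smiles(m.smiles))
        rows[i, list(fp.GetOnBits())] = 1.0
    columns = [f"morgan_{j}" for j in range(n_bits)]
    return FeatureBlock(ids, columns, rows, block_name="morgan")


def rdkit_fingerprint(molecules: Sequence, n_bits: int = 2048) -> FeatureBlock:
    """RDKit topological (path-based) fingerprints at toolkit defaults."""
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    ids = _check_molecules(molecules)
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    rows = np.zeros((len(molecules), n_bits))
    for i, m in enumerate(molecules):
        fp = gen.GetFingerprint(_mol_from_smiles(m.smiles))
        rows[i, list(fp.GetOnBits())] = 1.0
    columns = [f"rdkit_{j}" for j in range(n_bits)]
    return FeatureBlock(ids, columns, rows, block_name="rdkitfp")


def maccs_keys(molecules: Sequence) -> FeatureBlock:
    """MACCS substructure keys: exactly 166 named binary columns.

    RDKit's native MACCS vector carries a dummy bit 0; it is dropped so the
    block exposes the catalogue's 166 keys as maccs_1 .. maccs_166.
    """
    ids = _check_molecules(molecules)
    rows = np.zeros((len(molecules), 166))
    for i, m in enumerate(molecules):
        fp = MACCSkeys.GenMACCSKeys(_mol_from_smiles(m.smiles))
        on = [b - 1 for b in fp.GetOnBits() if b >= 1]
        rows[i, on] = 1.0
    columns = [f"maccs_{j}" for j in range(1, 167)]
    return FeatureBlock(ids, columns, rows, block_name="maccs")


MOL_VARIANTS = {
    "physchem": physchem_descriptors,
    "morgan": morgan_fingerprint,
    "rdkitfp": rdkit_fingerprint,
    "maccs": maccs_keys,
}


def featurize_molecules(molecules: Sequence, variant: str) -> FeatureBlock:
    """Dispatch to one of the four molecular descriptor families."""
    if variant not in MOL_VARIANTS:
        raise ValueError(
            f"unknown molecular variant {variant!r}; choose from {sorted(MOL_VARIANTS)}"
        )
    return MOL_VARIANTS[variant](molecules)
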