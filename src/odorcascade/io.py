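"""Domain records and table/FASTA readers for molecule–receptor binding studies.

The binding data model follows the screening convention in which every
(molecule, receptor) pair carries a non-negative log(EC50): 0 encodes "no
binding observed" and any strictly positive value encodes a measured binding
strength. Binary binding labels are therefore *derived* — ``positive`` iff
log(EC50) > 0 — and the full molecule × receptor grid must be present before
per-molecule activation profiles can be assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem

from .protfeats import AlignmentMatrix, validate_sequence

logger = logging.getLogger(__name__)

POSITIVE = 1
NEGATIVE = 0

SPECIES_TAGS = ("mouse", "human", "unknown")


@dataclass
class MoleculeRecord:
    """One odorant molecule: id, isomeric SMILES, and free-text odor notes."""

    molecule_id: str
    smiles: str
    odor_labels: set[str] = field(default_factory=set)


@dataclass
class ReceptorRecord:
    """One olfactory receptor: id, amino-acid sequence, species metadata."""

    receptor_id: str
    sequence: str
    species_tag: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.receptor_id}: empty sequence")
        if self.species_tag not in SPECIES_TAGS:
            raise ValueError(
                f"{self.receptor_id}: species_tag must be one of {SPECIES_TAGS}"
            )
        validate_sequence(self.sequence)


@dataclass
class BindingSample:
    """One (molecule, receptor, log_ec50) triple with its derived binary label."""

    molecule_id: str
    receptor_id: str
    log_ec50: float

    def __post_init__(self) -> None:
        if self.log_ec50 < 0:
            raise ValueError(
                f"({self.molecule_id}, {self.receptor_id}): log_ec50 must be "
                f"non-negative (0 encodes no binding); got {self.log_ec50}"
            )

    @property
    def label(self) -> int:
        """``POSITIVE`` (1) iff log_ec50 > 0, else ``NEGATIVE`` (0)."""
        return binarize(self.log_ec50)


@dataclass
class ActivationProfile:
    """log(EC50) of one molecule across the receptor panel, in panel order."""

    molecule_id: str
    values: np.ndarray
    panel: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.panel),):
            raise ValueError(
                f"{self.molecule_id}: profile length {self.values.shape} does not "
                f"match panel size {len(self.panel)}"
            )
        if (self.values < 0).any():
            raise ValueError(f"{self.molecule_id}: profile entries must be >= 0")


def binarize(log_ec50: float) -> int:
    """Binary binding label: positive iff log(EC50) is strictly greater than 0."""
    if log_ec50 < 0:
        raise ValueError(f"log_ec50 must be non-negative, got {log_ec50}")
    return POSITIVE if log_ec50 > 0 else NEGATIVE


def _normalize_labels(raw: str) -> set[str]:
    if not isinstance(raw, str):
        return set()
    return {tok.strip().casefold() for tok in raw.split(";") if tok.strip()}


def read_molecule_table(path) -> list[MoleculeRecord]:
    """Read a molecule CSV with columns molecule_id, smiles, odor_labels.

    Odor labels are ';'-separated, trimmed and case-folded; empty tokens are
    dropped. Every SMILES must parse; rows that fail are collected and
    reported together, naming the offending molecule_ids.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"molecule_id", "smiles", "odor_labels"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"molecule table is missing columns: {sorted(missing)}")
    records: list[MoleculeRecord] = []
    bad: list[str] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        mid = row["molecule_id"].strip()
        if mid in seen:
            raise ValueError(f"duplicate molecule_id {mid!r}")
        seen.add(mid)
        if Chem.MolFromSmiles(row["smiles"]) is None:
            bad.append(mid)
            continue
        records.append(
            MoleculeRecord(
                molecule_id=mid,
                smiles=row["smiles"].strip(),
                odor_labels=_normalize_labels(row["odor_labels"]),
            )
        )
    if bad:
        raise ValueError(f"unparsable SMILES for molecule_id(s): {bad}")
    return records


def write_molecule_table(molecules: Sequence[MoleculeRecord], path) -> None:
    pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in molecules],
            "smiles": [m.smiles for m in molecules],
            "odor_labels": [";".join(sorted(m.odor_labels)) for m in molecules],
        }
    ).to_csv(path, index=False)


def read_receptor_fasta(path, species_tags: Optional[dict[str, str]] = None
                        ) -> list[ReceptorRecord]:
    """Read receptor sequences from FASTA.

    The species tag is taken from a ``species=...`` token in the FASTA
    description when present, from ``species_tags`` otherwise, defaulting to
    ``unknown`` (it is metadata only and never enters a descriptor).
    """
    records: list[ReceptorRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate receptor_id {rec.id!r} in FASTA")
        seen.add(rec.id)
        tag = "unknown"
        for tok in rec.description.split():
            if tok.startswith("species="):
                tag = tok.split("=", 1)[1]
        if species_tags and rec.id in species_tags:
            tag = species_tags[rec.id]
        records.append(ReceptorRecord(rec.id, str(rec.seq), tag))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_receptor_fasta(receptors: Sequence[ReceptorRecord], path) -> None:
    with open(path, "w") as fh:
        for r in receptors:
            fh.write(f">{r.receptor_id} species={r.species_tag}\n{r.sequence}\n")


def read_alignment_fasta(path) -> AlignmentMatrix:
    """Read a pre-computed multiple alignment (gap character '-') from FASTA."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no sequences found in {path}")
    return AlignmentMatrix(receptor_ids=ids, aligned_sequences=seqs)


def read_binding_table(
    path,
    molecules: Sequence[MoleculeRecord],
    receptors: Sequence[ReceptorRecord],
) -> tuple[list[BindingSample], float]:
    """Read a binding CSV (molecule_id, receptor_id, log_ec50).

    Every id must reference a known molecule/receptor and every log_ec50 must
    be non-negative (0 is the no-binding code). Returns the samples plus the
    coverage: the fraction of the full molecule × receptor grid present.
    """
    df = pd.read_csv(path, dtype={"molecule_id": str, "receptor_id": str})
    required = {"molecule_id", "receptor_id", "log_ec50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"binding table is missing columns: {sorted(missing)}")
    known_m = {m.molecule_id for m in molecules}
    known_r = {r.receptor_id for r in receptors}
    samples: list[BindingSample] = []
    for _, row in df.iterrows():
        mid, rid = row["molecule_id"], row["receptor_id"]
        if mid not in known_m:
            raise ValueError(f"binding table references unknown molecule_id {mid!r}")
        if rid not in known_r:
            raise ValueError(f"binding table references unknown receptor_id {rid!r}")
        value = float(row["log_ec50"])
        if value < 0:
            raise ValueError(
                f"({mid}, {rid}): negative log_ec50 {value} (0 is reserved for "
                "non-binding; negative values are not representable)"
            )
        samples.append(BindingSample(mid, rid, value))
    coverage = len(samples) / (len(known_m) * len(known_r))
    return samples, coverage


def write_binding_table(samples: Sequence[BindingSample], path) -> None:
    pd.DataFrame(
        {
            "molecule_id": [s.molecule_id for s in samples],
            "receptor_id": [s.receptor_id for s in samples],
            "log_ec50": [s.log_ec50 for s in samples],
        }
    ).to_csv(path, index=False)


def build_profiles(
    samples: Sequence[BindingSample], panel: Sequence[str]
) -> list[ActivationProfile]:
    """Assemble per-molecule activation profiles over a fixed receptor panel.

    The (molecule × panel) grid must be complete: a missing pair is an error
    (zero-filling it would conflate "unmeasured" with "non-binding"), and so
    is a duplicate measurement.
    """
    panel = list(panel)
    by_mol: dict[str, dict[str, float]] = {}
    for s in samples:
        cell = by_mol.setdefault(s.molecule_id, {})
        if s.receptor_id in cell:
            raise ValueError(
                f"duplicate sample for ({s.molecule_id}, {s.receptor_id})"
            )
        cell[s.receptor_id] = s.log_ec50
    missing = [
        (mid, rid)
        for mid, cell in by_mol.items()
        for rid in panel
        if rid not in cell
    ]
    if missing:
        raise ValueError(f"incomplete binding grid; missing pairs: {missing[:10]}")
    return [
        ActivationProfile(mid, np.array([by_mol[mid][rid] for rid in panel]), panel)
        for mid in by_mol
    ]
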