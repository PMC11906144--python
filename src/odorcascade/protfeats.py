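"""Receptor-sequence descriptors: k-mer amino-acid composition and alignment one-hot.

Six composition variants are supported — overlapping k-mer counts for
k = 1, 2, 3 ("1AAF", "2AAF", "3AAF") and their window-normalized proportions
("1AAFperc", "2AAFperc", "3AAFperc") — plus a seventh variant that flattens a
multiple sequence alignment into a per-position one-hot over the 20 canonical
amino acids and the gap symbol. The composition variants ignore residue
position entirely; the alignment variant encodes nothing *but* residue
identity per aligned position, so the two families bracket how much ordering
information the downstream model sees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .featureblock import FeatureBlock

#: the 20 canonical amino acids, alphabetical one-letter codes
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"

KAAF_VARIANTS = ("1AAF", "2AAF", "3AAF", "1AAFperc", "2AAFperc", "3AAFperc")
RECEPTOR_VARIANTS = KAAF_VARIANTS + ("alignment",)


@dataclass(frozen=True)
class KmerVocabulary:
    """All length-``k`` strings over the canonical amino-acid alphabet, sorted."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")

    @property
    def kmers(self) -> tuple[str, ...]:
        return _kmers(self.k)

    def __len__(self) -> int:
        return len(AMINO_ACIDS) ** self.k

    def index(self, kmer: str) -> int:
        # lexicographic order == mixed-radix number in the alphabet
        idx = 0
        for ch in kmer:
            idx = idx * len(AMINO_ACIDS) + AMINO_ACIDS.index(ch)
        return idx


@lru_cache(maxsize=None)
def _kmers(k: int) -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(AMINO_ACIDS, repeat=k))


@lru_cache(maxsize=None)
def _aa_index() -> dict[str, int]:
    return {a: i for i, a in enumerate(AMINO_ACIDS)}


def validate_sequence(sequence: str) -> None:
    """Raise if the sequence contains a non-canonical residue.

    Ambiguity codes (X, B, Z, ...) are rejected rather than remapped: silently
    folding them into a canonical residue would corrupt composition counts.
    """
    table = _aa_index()
    for pos, ch in enumerate(sequence):
        if ch not in table:
            raise ValueError(
                f"non-canonical amino acid {ch!r} at position {pos} "
                f"(alphabet is {AMINO_ACIDS})"
            )


def kmer_counts(sequence: str, k: int) -> np.ndarray:
    """Count overlapping k-mers of ``sequence`` over the full 20**k vocabulary.

    The output vector is indexed by the lexicographic vocabulary of
    :class:`KmerVocabulary` and sums to ``len(sequence) - k + 1``.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    validate_sequence(sequence)
    table = _aa_index()
    a = len(AMINO_ACIDS)
    counts = np.zeros(a**k, dtype=float)
    # rolling mixed-radix index over the window
    codes = [table[ch] for ch in sequence]
    idx = 0
    for j in range(k):
        idx = idx * a + codes[j]
    counts[idx] += 1
    base = a ** (k - 1)
    for j in range(k, len(codes)):
        idx = (idx % base) * a + codes[j]
        counts[idx] += 1
    return counts


def kmer_proportions(sequence: str, k: int) -> np.ndarray:
    """k-mer counts divided by the window count ``len(sequence) - k + 1``.

    Entries sum to 1 (to within floating-point), which makes receptors of
    different lengths directly comparable.
    """
    counts = kmer_counts(sequence, k)
    return counts / (len(sequence) - k + 1)


@dataclass
class AlignmentMatrix:
    """A multiple sequence alignment of the receptor panel.

    All sequences must share the same aligned length; the gap character is
    ``-``. The alignment is consumed, never computed, here.
    """

    receptor_ids: list[str]
    aligned_sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.receptor_ids) != len(self.aligned_sequences):
            raise ValueError("receptor_ids and aligned_sequences differ in length")
        if not self.aligned_sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.aligned_sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"aligned sequences have unequal lengths: {sorted(lengths)}"
            )
        table = _aa_index()
        for rid, seq in zip(self.receptor_ids, self.aligned_sequences):
            if all(ch == GAP for ch in seq):
                raise ValueError(f"{rid}: alignment row is all gaps")
            for pos, ch in enumerate(seq):
                if ch != GAP and ch not in table:
                    raise ValueError(
                        f"{rid}: unknown symbol {ch!r} at alignment position {pos}"
                    )

    @property
    def n_positions(self) -> int:
        return len(self.aligned_sequences[0])


def alignment_onehot(alignment: AlignmentMatrix) -> FeatureBlock:
    """Flatten an alignment into per-position 21-state one-hot rows.

    Each aligned position contributes a block of 21 indicator columns (20
    amino acids plus the gap); exactly one indicator per block is 1. Row
    length is ``n_positions * 21``.
    """
    symbols = AMINO_ACIDS + GAP
    sym_idx = {s: i for i, s in enumerate(symbols)}
    npos = alignment.n_positions
    rows = np.zeros((len(alignment.receptor_ids), npos * len(symbols)))
    for i, seq in enumerate(alignment.aligned_sequences):
        for pos, ch in enumerate(seq):
            rows[i, pos * len(symbols) + sym_idx[ch]] = 1.0
    columns = [
        f"pos{pos}_{sym}" for pos in range(npos) for sym in symbols
    ]
    return FeatureBlock(
        row_ids=list(alignment.receptor_ids),
        column_names=columns,
        values=rows,
        block_name="alignment",
    )


def featurize_receptors(
    receptors: Sequence,
    variant: str,
    alignment: Optional[AlignmentMatrix] = None,
) -> FeatureBlock:
    """Compute one receptor descriptor variant for a panel of receptors.

    Parameters
    ----------
    receptors : sequence of ReceptorRecord
        Objects exposing ``receptor_id`` and ``sequence``.
    variant : str
        One of ``1AAF``, ``2AAF``, ``3AAF`` (overlapping k-mer counts),
        ``1AAFperc``, ``2AAFperc``, ``3AAFperc`` (proportions), or
        ``alignment`` (flattened one-hot of a supplied alignment).
    alignment : AlignmentMatrix, optional
        Required for the ``alignment`` variant; must cover every receptor.
    """
    if variant not in RECEPTOR_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {RECEPTOR_VARIANTS}")
    if not receptors:
        raise ValueError("empty receptor list")
    if variant == "alignment":
        if alignment is None:
            raise ValueError("variant 'alignment' requires an AlignmentMatrix")
        block = alignment_onehot(alignment)
        wanted = [r.receptor_id for r in receptors]
        missing = [rid for rid in wanted if rid not in block.row_ids]
        if missing:
            raise ValueError(f"alignment does not cover receptors: {missing[:5]}")
        order = [block.row_ids.index(rid) for rid in wanted]
        return FeatureBlock(
            row_ids=wanted,
            column_names=block.column_names,
            values=block.values[order],
            block_name="alignment",
        )

    k = int(variant[0])
    perc = variant.endswith("perc")
    fn = kmer_proportions if perc else kmer_counts
    rows = np.vstack([fn(r.sequence, k) for r in receptors])
    return FeatureBlock(
        row_ids=[r.receptor_id for r in receptors],
        column_names=list(_kmers(k)),
        values=rows,
        block_name=variant,
    )
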