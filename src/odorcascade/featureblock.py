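"""Named descriptor matrices shared by the molecular and protein featurizers."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FeatureBlock:
    """A (rows × columns) real matrix with row identifiers and a feature vocabulary.

    Parameters
    ----------
    row_ids : list of str
        Entity identifiers (molecule or receptor ids), one per matrix row.
    column_names : list of str
        Feature vocabulary, one per matrix column; must be unique.
    values : ndarray of shape (len(row_ids), len(column_names))
        The descriptor values. Columns containing non-finite entries are
        dropped at construction with a logged warning, so a validated block
        never carries NaN/inf into a model.
    block_name : str
        Short name identifying the descriptor family (e.g. ``"morgan"``).
    """

    row_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    block_name: str = "block"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.row_ids):
            raise ValueError(
                f"{self.block_name}: {len(self.row_ids)} row_ids but {n} matrix rows"
            )
        if p != len(self.column_names):
            raise ValueError(
                f"{self.block_name}: {len(self.column_names)} column_names but {p} matrix columns"
            )
        if len(set(self.column_names)) != p:
            raise ValueError(f"{self.block_name}: column_names are not unique")
        bad = ~np.isfinite(self.values).all(axis=0)
        if bad.any():
            dropped = [c for c, b in zip(self.column_names, bad) if b]
            logger.warning(
                "%s: dropping %d column(s) with non-finite values: %s",
                self.block_name, len(dropped), ", ".join(dropped[:10]),
            )
            self.values = self.values[:, ~bad]
            self.column_names = [c for c, b in zip(self.column_names, bad) if not b]

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def row(self, row_id: str) -> np.ndarray:
        """Return the feature vector of one entity."""
        try:
            i = self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"{self.block_name}: unknown row id {row_id!r}") from None
        return self.values[i]

    def select_columns(self, names: list[str]) -> "FeatureBlock":
        """Reindex the block to a fixed column list (order preserved)."""
        idx = {c: j for j, c in enumerate(self.column_names)}
        missing = [c for c in names if c not in idx]
        if missing:
            raise KeyError(f"{self.block_name}: unknown columns {missing[:5]}")
        cols = [idx[c] for c in names]
        return FeatureBlock(
            row_ids=list(self.row_ids),
            column_names=list(names),
            values=self.values[:, cols],
            block_name=self.block_name,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)

    def to_csv(self, path) -> None:
        """Serialize as CSV with the row ids in the first column."""
        df = self.to_frame()
        df.index.name = "row_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, block_name: str = "block") -> "FeatureBlock":
        df = pd.read_csv(path, index_col=0)
        return cls(
            row_ids=[str(i) for i in df.index],
            column_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            block_name=block_name,
        )


def drop_constant_columns(block: FeatureBlock) -> FeatureBlock:
    """Remove columns with zero variance across rows (degenerate for scaling)."""
    if block.n_rows == 0:
        return block
    keep = block.values.std(axis=0) > 0.0
    if keep.all():
        return block
    dropped = int((~keep).sum())
    logger.info("%s: dropping %d constant column(s)", block.block_name, dropped)
    return FeatureBlock(
        row_ids=list(block.row_ids),
        column_names=[c for c, k in zip(block.column_names, keep) if k],
        values=block.values[:, keep],
        block_name=block.block_name,
    )
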