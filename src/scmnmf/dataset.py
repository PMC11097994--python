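"""Container for aligned multi-block single-cell data.

A *block* is one cell-by-feature matrix for a single modality (RNA counts,
ADT counts, ATAC gene counts, ...). All blocks share the cell axis: row i of
every block is the same cell. The container is desk-scale and keeps blocks
as dense float64 arrays; sparse inputs are densified on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["MultiOmicsDataset"]


def _as_dense(x) -> np.ndarray:
    if sp.issparse(x):
        x = x.toarray()
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"each block must be a 2-D cell x feature matrix, got ndim={arr.ndim}")
    return arr


@dataclass
class MultiOmicsDataset:
    """M non-negative cell x feature blocks sharing a cell axis.

    Parameters
    ----------
    blocks
        List of M matrices, each ``n_cells x J_k``, non-negative and finite.
    block_names
        Identifiers for the blocks (default ``block_0 .. block_{M-1}``).
    cell_ids
        Barcodes, one per cell (default ``cell_0000 ..``).
    feature_names
        Optional per-block feature name lists, matching block widths.
    true_labels
        Optional per-cell category used only for evaluation.
    """

    blocks: list
    block_names: list | None = None
    cell_ids: list | None = None
    feature_names: list | None = None
    true_labels: np.ndarray | None = None
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.blocks = [_as_dense(b) for b in self.blocks]
        if len(self.blocks) < 1:
            raise ValueError("need at least one omics block")
        n = self.blocks[0].shape[0]
        if self.block_names is None:
            self.block_names = [f"block_{k}" for k in range(len(self.blocks))]
        self.block_names = [str(s) for s in self.block_names]
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i:04d}" for i in range(n)]
        self.cell_ids = list(map(str, self.cell_ids))
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels)
        if not self._skip_validation:
            self.validate()

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_features(self) -> list:
        return [b.shape[1] for b in self.blocks]

    def validate(self) -> None:
        """Check the shared-cell-axis and non-negativity invariants."""
        n = self.n_cells
        if len(self.block_names) != self.n_blocks:
            raise ValueError("block_names length does not match number of blocks")
        if len(self.cell_ids) != n:
            raise ValueError(f"cell_ids has {len(self.cell_ids)} entries for {n} cells")
        for name, b in zip(self.block_names, self.blocks):
            if b.shape[0] != n:
                raise ValueError(
                    f"block {name!r} has {b.shape[0]} cells, expected {n}: "
                    "all blocks must share the cell axis"
                )
            if not np.all(np.isfinite(b)):
                raise ValueError(f"block {name!r} contains non-finite entries")
            if b.min(initial=0.0) < 0:
                raise ValueError(f"block {name!r} contains negative entries")
        if self.feature_names is not None:
            for name, b, fn in zip(self.block_names, self.blocks, self.feature_names):
                if len(fn) != b.shape[1]:
                    raise ValueError(
                        f"block {name!r}: {len(fn)} feature names for {b.shape[1]} features"
                    )
        if self.true_labels is not None and len(self.true_labels) != n:
            raise ValueError("true_labels length does not match number of cells")

    def subset_cells(self, index: np.ndarray) -> "MultiOmicsDataset":
        """Return a dataset restricted to the given cell positions (order kept)."""
        index = np.asarray(index)
        return MultiOmicsDataset(
            blocks=[b[index] for b in self.blocks],
            block_names=list(self.block_names),
            cell_ids=[self.cell_ids[i] for i in index],
            feature_names=None if self.feature_names is None else [list(f) for f in self.feature_names],
            true_labels=None if self.true_labels is None else self.true_labels[index],
        )
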