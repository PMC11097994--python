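"""Count-matrix preprocessing shared by every analysis entry point.

Raw per-block counts are filtered (rare features, empty cells), library-size
scaled per cell, optionally log1p-transformed, and reduced to the most
variable features per block. Every step keeps the output non-negative and
preserves the cell order identically across blocks, so the solver's shared
cell axis is never broken. Cell filtering is intersection-based: a cell is
dropped from *all* blocks if it fails the threshold in *any* block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MultiOmicsDataset

__all__ = ["PreprocessConfig", "preprocess_dataset", "concatenate_for_graph"]


@dataclass
class PreprocessConfig:
    """Preprocessing switches and thresholds.

    Defaults follow common single-cell practice: drop features seen in
    fewer than 3 cells, keep cells with at least 1 detected feature per
    block, scale each cell to a library size of 1e4, log1p, and keep the
    2000 most variable features per block. Every step can be disabled.
    """

    min_cells_per_feature: int = 3
    min_features_per_cell: int = 1
    target_sum: float | None = 1e4
    log_transform: bool = True
    n_top_features: int | str = 2000
    block_scale: bool = True

    def __post_init__(self):
        if self.min_cells_per_feature < 0 or self.min_features_per_cell < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.target_sum is not None and self.target_sum <= 0:
            raise ValueError("target_sum must be positive")
        if self.n_top_features != "all" and int(self.n_top_features) < 0:
            raise ValueError("n_top_features must be >= 0 or 'all'")

    @classmethod
    def identity(cls) -> "PreprocessConfig":
        """A configuration that disables every step (output == input)."""
        return cls(
            min_cells_per_feature=0,
            min_features_per_cell=0,
            target_sum=None,
            log_transform=False,
            n_top_features="all",
        )


def preprocess_dataset(
    data: MultiOmicsDataset, cfg: PreprocessConfig | None = None
) -> MultiOmicsDataset:
    """Apply the configured preprocessing to every block.

    Order of operations: feature filter -> joint cell filter -> per-cell
    library scaling -> log1p -> top-variance feature selection. Raises a
    descriptive error if any filter empties a block or removes all cells.
    """
    cfg = cfg or PreprocessConfig()
    data.validate()
    blocks = [b.copy() for b in data.blocks]
    feature_names = (
        [list(f) for f in data.feature_names]
        if data.feature_names is not None
        else [[f"{name}_f{j}" for j in range(b.shape[1])] for name, b in zip(data.block_names, blocks)]
    )

    # 1) feature filter: drop features detected in too few cells
    if cfg.min_cells_per_feature > 0:
        for k, b in enumerate(blocks):
            keep = (b > 0).sum(axis=0) >= cfg.min_cells_per_feature
            if not keep.any():
                raise ValueError(
                    f"min_cells_per_feature={cfg.min_cells_per_feature} removed every "
                    f"feature of block {data.block_names[k]!r}"
                )
            blocks[k] = b[:, keep]
            feature_names[k] = [f for f, m in zip(feature_names[k], keep) if m]

    # 2) joint cell filter: cell must pass in every block
    if cfg.min_features_per_cell > 0:
        keep_cells = np.ones(data.n_cells, dtype=bool)
        for b in blocks:
            keep_cells &= (b > 0).sum(axis=1) >= cfg.min_features_per_cell
        if not keep_cells.any():
            raise ValueError(
                f"min_features_per_cell={cfg.min_features_per_cell} removed every cell"
            )
        if not keep_cells.all():
            idx = np.flatnonzero(keep_cells)
            blocks = [b[idx] for b in blocks]
            cell_ids = [data.cell_ids[i] for i in idx]
            true_labels = None if data.true_labels is None else data.true_labels[idx]
        else:
            cell_ids, true_labels = list(data.cell_ids), data.true_labels
    else:
        cell_ids, true_labels = list(data.cell_ids), data.true_labels

    # 3) per-cell library scaling (cells with zero total stay zero)
    if cfg.target_sum is not None:
        for k, b in enumerate(blocks):
            sums = b.sum(axis=1, keepdims=True)
            scale = np.divide(
                cfg.target_sum, sums, out=np.zeros_like(sums), where=sums > 0
            )
            blocks[k] = b * scale

    # 4) log transform
    if cfg.log_transform:
        blocks = [np.log1p(b) for b in blocks]

    # 5) per-block top-variance features
    if cfg.n_top_features != "all":
        n_top = int(cfg.n_top_features)
        if n_top > 0:
            for k, b in enumerate(blocks):
                if b.shape[1] > n_top:
                    var = b.var(axis=0)
                    # stable selection: sort by (-variance, index)
                    order = np.lexsort((np.arange(b.shape[1]), -var))[:n_top]
                    order = np.sort(order)
                    blocks[k] = b[:, order]
                    feature_names[k] = [feature_names[k][j] for j in order]

    return MultiOmicsDataset(
        blocks=blocks,
        block_names=list(data.block_names),
        cell_ids=cell_ids,
        feature_names=feature_names,
        true_labels=true_labels,
    )


def concatenate_for_graph(data: MultiOmicsDataset, block_scale: bool = True) -> np.ndarray:
    """Concatenate blocks along features for affinity-graph construction.

    With ``block_scale`` each block is divided by its Frobenius norm first,
    so no single modality dominates the cell-cell distances.
    """
    parts = []
    for b in data.blocks:
        if block_scale:
            norm = np.linalg.norm(b)
            parts.append(b / norm if norm > 0 else b)
        else:
            parts.append(b)
    return np.hstack(parts)
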