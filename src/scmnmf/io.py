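"""Readers and writers for the on-disk dataset layout and run artifacts.

Blocks live either as Matrix-Market triplets with 10x-style sidecars
(matrix.mtx features-in-rows by default, features.tsv, barcodes.tsv) or as
dense CSV/TSV with a header row and a leading id column. Labels travel as
``cell_id,label`` CSV. A YAML run configuration ties blocks, preprocessing,
hyperparameters and output paths together; paths inside it are resolved
relative to the config file.

Matrix-Market indices are 1-based on disk per the standard; everything in
memory is 0-based — scipy handles the conversion at the boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

from .dataset import MultiOmicsDataset
from .model import Hyperparameters
from .preprocess import PreprocessConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_block",
    "write_block",
    "read_labels",
    "write_labels",
    "write_dataset",
    "RunConfig",
    "load_run_config",
    "load_dataset",
    "save_results",
]


# ----------------------------------------------------------------------
# block-level readers/writers
# ----------------------------------------------------------------------
def _read_sidecar(path) -> list:
    """First whitespace-separated column of a features/barcodes file."""
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                names.append(line.split("\t")[0].split(",")[0])
    return names


def read_block(
    matrix_path,
    features_path=None,
    barcodes_path=None,
    orientation: str = "features_in_rows",
):
    """Read one block; returns (cells x features matrix, features, barcodes).

    ``matrix_path`` may be a Matrix-Market ``.mtx`` with sidecar text files,
    or a dense CSV/TSV with a header row and the cell/feature ids in the
    first column. ``orientation`` states what the on-disk rows are; the
    returned matrix always has cells in rows. Counts are preserved exactly.
    """
    if orientation not in ("features_in_rows", "cells_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = mmread(str(matrix_path))
        mat = sp.csr_matrix(mat).toarray()
        row_names = _read_sidecar(features_path) if features_path else None
        col_names = _read_sidecar(barcodes_path) if barcodes_path else None
        if orientation == "cells_in_rows":
            row_names, col_names = col_names, row_names
        feat_names, bc_names = row_names, col_names
        n_rows, n_cols = mat.shape
        if feat_names is not None and len(feat_names) != (
            n_rows if orientation == "features_in_rows" else n_cols
        ):
            axis = n_rows if orientation == "features_in_rows" else n_cols
            raise ValueError(
                f"features sidecar has {len(feat_names)} entries but the matrix "
                f"has {axis} features"
            )
        if bc_names is not None and len(bc_names) != (
            n_cols if orientation == "features_in_rows" else n_rows
        ):
            axis = n_cols if orientation == "features_in_rows" else n_rows
            raise ValueError(
                f"barcodes sidecar has {len(bc_names)} entries but the matrix "
                f"has {axis} cells"
            )
        if orientation == "features_in_rows":
            mat = mat.T
    else:
        sep = "\t" if matrix_path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        if orientation == "features_in_rows":
            df = df.T
        mat = df.to_numpy(dtype=float)
        bc_names = list(map(str, df.index))
        feat_names = list(map(str, df.columns))
    if mat.min(initial=0.0) < 0:
        raise ValueError(f"{matrix_path} contains negative entries")
    if feat_names is None:
        feat_names = [f"f{j}" for j in range(mat.shape[1])]
    if bc_names is None:
        bc_names = [f"cell_{i:04d}" for i in range(mat.shape[0])]
    return np.asarray(mat, dtype=float), feat_names, bc_names


def write_block(outdir, matrix, feature_names, barcodes) -> dict:
    """Write one block as matrix.mtx (features in rows) + sidecars.

    Returns the paths written. Round-trips exactly with :func:`read_block`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix)
    if mat.shape != (len(barcodes), len(feature_names)):
        raise ValueError("matrix shape does not match sidecar lengths")
    paths = {
        "matrix": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
    }
    coo = sp.coo_matrix(mat.T)  # features in rows on disk
    is_int = np.allclose(coo.data, np.round(coo.data)) if coo.nnz else True
    if is_int:
        mmwrite(str(paths["matrix"]), coo.astype(np.int64))
    else:
        mmwrite(str(paths["matrix"]), coo, precision=17)
    paths["features"].write_text("".join(f"{f}\n" for f in feature_names))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in barcodes))
    return {k: str(v) for k, v in paths.items()}


def read_labels(path) -> pd.Series:
    """Read a ``cell_id,label`` CSV into a Series indexed by cell id."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    if "cell_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path} must have columns 'cell_id,label'")
    return df.set_index("cell_id")["label"]


def write_labels(path, cell_ids, labels) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "label": list(labels)}).to_csv(
        path, index=False
    )


def write_dataset(data: MultiOmicsDataset, outdir, config_stub: bool = True) -> dict:
    """Write every block (mtx layout), optional labels, and a run config.

    The emitted ``config.yaml`` points at the written files and carries
    default preprocessing/hyperparameter sections so a clustering run can
    start immediately.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block_entries = []
    for k, name in enumerate(data.block_names):
        feats = (
            data.feature_names[k]
            if data.feature_names is not None
            else [f"{name}_f{j}" for j in range(data.blocks[k].shape[1])]
        )
        paths = write_block(outdir / name, data.blocks[k], feats, data.cell_ids)
        block_entries.append(
            {
                "name": name,
                "matrix": f"{name}/matrix.mtx",
                "features": f"{name}/features.tsv",
                "barcodes": f"{name}/barcodes.tsv",
                "orientation": "features_in_rows",
            }
        )
    manifest = {"blocks": block_entries}
    if data.true_labels is not None:
        write_labels(outdir / "labels.csv", data.cell_ids, data.true_labels)
        manifest["labels"] = "labels.csv"
    if config_stub:
        k_types = (
            int(len(np.unique(data.true_labels))) if data.true_labels is not None else 2
        )
        manifest.update(
            {
                "preprocess": {},
                "hyperparameters": {"k1": k_types},
                "output_dir": "results",
                "seed": 0,
            }
        )
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------
@dataclass
class RunConfig:
    """Parsed YAML run configuration with resolved paths."""

    blocks: list                         # dicts: name/matrix/features/barcodes/orientation
    labels: Path | None
    preprocess: PreprocessConfig
    hyperparameters: Hyperparameters
    output_dir: Path
    seed: int
    root: Path = field(default_factory=Path)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    root = path.parent
    if "blocks" not in raw or not raw["blocks"]:
        raise ValueError("config must list at least one block under 'blocks'")
    blocks = []
    for entry in raw["blocks"]:
        block = dict(entry)
        for key in ("matrix", "features", "barcodes"):
            if key in block and block[key] is not None:
                p = root / block[key]
                if not p.exists():
                    raise FileNotFoundError(f"block file not found: {p}")
                block[key] = p
        block.setdefault("orientation", "features_in_rows")
        block.setdefault("name", Path(str(block["matrix"])).parent.name)
        blocks.append(block)
    labels = None
    if raw.get("labels"):
        labels = root / raw["labels"]
        if not labels.exists():
            raise FileNotFoundError(f"labels file not found: {labels}")
    pre = PreprocessConfig(**(raw.get("preprocess") or {}))
    hp = Hyperparameters(**(raw.get("hyperparameters") or {}))
    return RunConfig(
        blocks=blocks,
        labels=labels,
        preprocess=pre,
        hyperparameters=hp,
        output_dir=root / raw.get("output_dir", "results"),
        seed=int(raw.get("seed", 0)),
        root=root,
    )


def load_dataset(config: RunConfig) -> MultiOmicsDataset:
    """Read all configured blocks and align them by barcode intersection.

    The first block's barcode order is preserved; barcodes missing from any
    block are dropped and the counts logged.
    """
    mats, names, featss, bcs = [], [], [], []
    for block in config.blocks:
        mat, feats, barcodes = read_block(
            block["matrix"],
            block.get("features"),
            block.get("barcodes"),
            block.get("orientation", "features_in_rows"),
        )
        mats.append(mat)
        names.append(block["name"])
        featss.append(feats)
        bcs.append(barcodes)

    common = [b for b in bcs[0] if all(b in set(other) for other in bcs[1:])]
    if not common:
        raise ValueError("barcode intersection across blocks is empty")
    for name, barcodes in zip(names, bcs):
        missing = len(barcodes) - len(common)
        if missing:
            logger.info(
                "block %s: dropping %d of %d barcodes not shared by all blocks",
                name, missing, len(barcodes),
            )
    aligned = []
    for mat, barcodes in zip(mats, bcs):
        pos = {b: i for i, b in enumerate(barcodes)}
        aligned.append(mat[[pos[b] for b in common]])

    true_labels = None
    if config.labels is not None:
        series = read_labels(config.labels)
        missing = [b for b in common if b not in series.index]
        if missing:
            raise ValueError(
                f"labels file is missing {len(missing)} barcodes (e.g. {missing[0]!r})"
            )
        true_labels = series.loc[common].to_numpy()

    return MultiOmicsDataset(
        blocks=aligned,
        block_names=names,
        cell_ids=common,
        feature_names=featss,
        true_labels=true_labels,
    )


# ----------------------------------------------------------------------
# result serialization
# ----------------------------------------------------------------------
def save_results(results, outdir) -> dict:
    """Write labels, embedding, objective trace, factors and metadata.

    All output is deterministic for a fixed fit (no timestamps), so two
    identical runs produce bit-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = results.dataset
    write_labels(outdir / "labels.csv", ds.cell_ids, results.labels)

    B = results.model.B
    emb = pd.DataFrame(
        B, index=pd.Index(ds.cell_ids, name="cell_id"),
        columns=[f"factor_{j}" for j in range(B.shape[1])],
    )
    emb.to_csv(outdir / "embedding.csv", float_format="%.17g")

    trace = pd.DataFrame(
        {"iteration": np.arange(len(results.objective_trace)),
         "objective": results.objective_trace}
    )
    trace.to_csv(outdir / "trace.csv", index=False, float_format="%.17g")

    factors = outdir / "factors"
    factors.mkdir(exist_ok=True)
    mmwrite(str(factors / "W.mtx"), sp.coo_matrix(results.model.W), precision=17)
    mmwrite(str(factors / "B.mtx"), sp.coo_matrix(results.model.B), precision=17)
    mmwrite(str(factors / "F.mtx"), sp.coo_matrix(results.model.F), precision=17)
    for name, H in zip(ds.block_names, results.model.H):
        mmwrite(str(factors / f"H_{name}.mtx"), sp.coo_matrix(H), precision=17)

    meta = {
        "hyperparameters": results.hp.to_dict(),
        "latent_dim": results.p,
        "seed": results.seed,
        "n_iter": results.n_iter,
        "converged": bool(results.converged),
        "assignment_method": results.assignment_method,
        "final_objective": results.objective,
        "n_cells": ds.n_cells,
        "blocks": {n: j for n, j in zip(ds.block_names, ds.n_features)},
        "cluster_sizes": results.cluster_sizes(),
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return meta
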