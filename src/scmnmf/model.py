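"""Joint NMF model for multi-omics dimensionality reduction and clustering.

The model factorizes M aligned non-negative blocks X_k (n cells x J_k
features) through a shared non-negative cell embedding W (n x p),

    X_k ~ W H_k,        W ~ B F,

where the secondary factorization splits W into per-cell cluster evidence
B (n x k1) and a cluster-to-factor map F (k1 x p). The fitted objective is

    O = sum_k ||X_k - W H_k||_F^2 + sum_k lambda_k ||H_k||_1
        + mu * sum_i ||w_i.||_1 + ||W - B F||_F^2 + alpha * Tr(B^T L B),

with L the Laplacian of a kNN heat-kernel graph over cells. The l1 terms
make H_k select features and keep W sparse; the Laplacian term makes rows
of B vary smoothly over the cell graph, preserving local geometry.

Optimization is by alternating multiplicative updates. Each rule is the
exact minimizer of the standard quadratic auxiliary function for its
sub-problem (Lee-Seung for W, H_k and F; the graph-regularized split
alpha*A*B / alpha*D*B for B), so every update keeps its factor non-negative
and never increases the objective — the per-iteration objective trace is
monotone non-increasing up to floating-point noise.

Usage follows the model/results convention::

    model = ScMNMF(data, n_clusters=3)
    res = model.fit(seed=0)
    res.labels, res.objective_trace, res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import MultiOmicsDataset
from .graph import AffinityGraph, build_affinity, graph_penalty
from .preprocess import PreprocessConfig, preprocess_dataset, concatenate_for_graph

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparameters",
    "FactorModel",
    "ScMNMF",
    "ScMNMFResults",
    "evaluate_objective",
    "objective_terms",
    "initialize_factors",
    "update_w",
    "update_h",
    "update_b",
    "update_f",
    "assign_clusters",
]


# ======================================================================
# configuration
# ======================================================================
@dataclass
class Hyperparameters:
    """Model and solver settings.

    Parameters
    ----------
    k1
        Number of cell clusters (columns of B). Must be >= 2.
    p
        Latent dimension (columns of W). Capped at fit time to
        min(n_cells, min_k J_k) - 1 and floored at k1.
    lambda_h
        l1 weight on each H_k. A scalar is broadcast to all blocks; a
        sequence gives per-block weights.
    mu
        l1 weight on the rows of W (scalar, broadcast to all cells).
    alpha
        Weight of the graph-Laplacian smoothness penalty on B.
    coupling
        Weight on the ||W - BF||^2 term linking the two factorizations.
        Fixed at 1 in the model; exposed so the solver degenerates to
        classical two-factor NMF when coupling = lambda = mu = alpha = 0
        (used for diagnostics and cross-checks).
    n_neighbors, sigma
        Affinity-graph settings (see :func:`scmnmf.graph.build_affinity`).
    max_iter, tol, eps, seed
        Solver settings. Convergence when the relative objective change
        |O_t - O_{t-1}| / max(O_{t-1}, eps) drops below ``tol``.
    """

    k1: int = 2
    p: int = 50
    lambda_h: float | list = 0.01
    mu: float = 0.01
    alpha: float = 1.0
    coupling: float = 1.0
    n_neighbors: int = 15
    sigma: float | str = "auto"
    max_iter: int = 500
    tol: float = 1e-6
    eps: float = 1e-10
    seed: int = 0

    def __post_init__(self):
        if self.k1 < 2:
            raise ValueError("k1 (number of clusters) must be >= 2")
        if self.p < self.k1:
            raise ValueError(f"latent dimension p={self.p} must be >= k1={self.k1}")
        weights = np.atleast_1d(np.asarray(self.lambda_h, dtype=float))
        if (weights < 0).any() or self.mu < 0 or self.alpha < 0 or self.coupling < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.tol <= 0 or self.eps <= 0:
            raise ValueError("tol and eps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def lambda_per_block(self, n_blocks: int) -> np.ndarray:
        lam = np.atleast_1d(np.asarray(self.lambda_h, dtype=float))
        if lam.size == 1:
            return np.full(n_blocks, float(lam[0]))
        if lam.size != n_blocks:
            raise ValueError(
                f"lambda_h has {lam.size} entries for {n_blocks} blocks"
            )
        return lam.astype(float)

    def resolve_p(self, n_cells: int, n_features: list) -> int:
        """Cap the latent dimension at min(n, J_k) - 1, floor at k1."""
        cap = min(n_cells, min(n_features)) - 1
        if cap < self.k1:
            raise ValueError(
                f"data too small: latent-dimension cap {cap} is below k1={self.k1}"
            )
        return max(self.k1, min(self.p, cap))

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["lambda_h"], np.ndarray):
            d["lambda_h"] = d["lambda_h"].tolist()
        return d


@dataclass
class FactorModel:
    """The four learned non-negative factors."""

    W: np.ndarray          # n x p shared cell embedding
    H: list                # per block: p x J_k feature loadings
    B: np.ndarray          # n x k1 cluster evidence
    F: np.ndarray          # k1 x p cluster-to-factor map

    def copy(self) -> "FactorModel":
        return FactorModel(
            W=self.W.copy(), H=[h.copy() for h in self.H], B=self.B.copy(), F=self.F.copy()
        )

    def check(self) -> None:
        for name, arrs in (("W", [self.W]), ("H", self.H), ("B", [self.B]), ("F", [self.F])):
            for a in arrs:
                if not np.all(np.isfinite(a)):
                    raise FloatingPointError(f"factor {name} contains non-finite entries")
                if a.min(initial=0.0) < 0:
                    raise ValueError(f"factor {name} contains negative entries")


# ======================================================================
# objective
# ======================================================================
def objective_terms(
    model: FactorModel,
    blocks: list,
    graph: AffinityGraph | None,
    hp: Hyperparameters,
) -> dict:
    """Additive decomposition of the objective into its named terms.

    Returns a dict with the reconstruction part ``R`` (block residuals plus
    both l1 penalties) and the clustering part ``Q`` (coupling residual plus
    the graph penalty), alongside the individual pieces.
    """
    model.check()
    lam = hp.lambda_per_block(len(blocks))
    if len(model.H) != len(blocks):
        raise ValueError("number of H factors does not match number of blocks")
    recon = 0.0
    l1_h = 0.0
    for X, H, lk in zip(blocks, model.H, lam):
        if X.shape != (model.W.shape[0], H.shape[1]) or H.shape[0] != model.W.shape[1]:
            raise ValueError("factor/block shapes are inconsistent")
        recon += float(np.sum((X - model.W @ H) ** 2))
        l1_h += float(lk * np.abs(H).sum())
    l1_w = float(hp.mu * np.abs(model.W).sum())
    couple = float(hp.coupling * np.sum((model.W - model.B @ model.F) ** 2))
    smooth = (
        float(hp.alpha * graph_penalty(model.B, graph))
        if (graph is not None and hp.alpha > 0)
        else 0.0
    )
    return {
        "reconstruction": recon,
        "l1_H": l1_h,
        "l1_W": l1_w,
        "coupling": couple,
        "graph": smooth,
        "R": recon + l1_h + l1_w,
        "Q": couple + smooth,
    }


def evaluate_objective(
    model: FactorModel,
    blocks: list,
    graph: AffinityGraph | None,
    hp: Hyperparameters,
) -> float:
    """Value of the joint objective O = R + Q (non-negative)."""
    t = objective_terms(model, blocks, graph, hp)
    return t["R"] + t["Q"]


# ======================================================================
# multiplicative updates
#
# Each rule multiplies the factor entrywise by (numerator + eps) /
# (denominator + eps), where numerator/denominator are the negative and
# positive parts of half the gradient. Adding the same eps to both sides
# keeps the update on the segment between the current iterate and the
# auxiliary-function minimizer (so monotonicity survives) and makes exact
# 0/0 stalls a no-op instead of a hard zero.
# ======================================================================
def _mult(factor: np.ndarray, num: np.ndarray, den: np.ndarray, eps: float) -> np.ndarray:
    return factor * ((num + eps) / (den + eps))


def update_w(model: FactorModel, blocks: list, hp: Hyperparameters) -> FactorModel:
    """One multiplicative step on W with all other factors fixed.

    W <- W * [sum_k X_k H_k^T + c*BF] / [W (sum_k H_k H_k^T + c*I) + mu/2]
    """
    W = model.W
    num = hp.coupling * (model.B @ model.F)
    gram = hp.coupling * np.eye(W.shape[1])
    for X, H in zip(blocks, model.H):
        num += X @ H.T
        gram += H @ H.T
    den = W @ gram + 0.5 * hp.mu
    out = model.copy()
    out.W = _mult(W, num, den, hp.eps)
    return out


def update_h(model: FactorModel, blocks: list, hp: Hyperparameters, k: int) -> FactorModel:
    """One multiplicative step on block k's loadings H_k.

    H_k <- H_k * [W^T X_k] / [W^T W H_k + lambda_k/2]
    """
    if not 0 <= k < len(model.H):
        raise IndexError(f"block index {k} out of range for {len(model.H)} blocks")
    lam = hp.lambda_per_block(len(blocks))[k]
    W, H = model.W, model.H[k]
    num = W.T @ blocks[k]
    den = (W.T @ W) @ H + 0.5 * lam
    out = model.copy()
    out.H[k] = _mult(H, num, den, hp.eps)
    return out


def update_b(model: FactorModel, graph: AffinityGraph | None, hp: Hyperparameters) -> FactorModel:
    """One graph-regularized multiplicative step on the cluster evidence B.

    B <- B * [W F^T + alpha*A B] / [B F F^T + alpha*D B]
    """
    B, F = model.B, model.F
    num = model.W @ F.T
    den = B @ (F @ F.T)
    if graph is not None and hp.alpha > 0:
        num = num + hp.alpha * (graph.A @ B)
        den = den + hp.alpha * (graph.degrees[:, None] * B)
    out = model.copy()
    out.B = _mult(B, num, den, hp.eps)
    return out


def update_f(model: FactorModel, hp: Hyperparameters) -> FactorModel:
    """One multiplicative step on the cluster-to-factor map F.

    F <- F * [B^T W] / [B^T B F]
    """
    B, F = model.B, model.F
    num = B.T @ model.W
    den = (B.T @ B) @ F
    out = model.copy()
    out.F = _mult(F, num, den, hp.eps)
    return out


def initialize_factors(
    blocks: list, hp: Hyperparameters, p: int, seed: int
) -> FactorModel:
    """Seeded strictly positive initialization, scaled to the data.

    All factors are drawn uniform on (0, 1]; H_k and F are then rescaled so
    the initial reconstructions W H_k and B F match the mean magnitude of
    X_k and W respectively.
    """
    rng = np.random.default_rng(seed)
    n = blocks[0].shape[0]

    def positive(shape):
        return 1.0 - rng.random(shape)  # uniform on (0, 1]

    W = positive((n, p))
    B = positive((n, hp.k1))
    F = positive((hp.k1, p))
    H = []
    for X in blocks:
        Hk = positive((p, X.shape[1]))
        approx = float((W @ Hk).mean())
        target = float(X.mean())
        if approx > 0 and target > 0:
            Hk *= target / approx
        H.append(Hk)
    bf_mean = float((B @ F).mean())
    if bf_mean > 0:
        F *= float(W.mean()) / bf_mean
    return FactorModel(W=W, H=H, B=B, F=F)


def assign_clusters(B: np.ndarray, n_clusters: int | None = None, seed: int = 0):
    """Hard labels from the cluster-evidence matrix B.

    Rows of B are l1-normalized and each cell takes the argmax column
    (ties -> lowest column index; an all-zero row gets label 1). If that
    leaves any of the ``n_clusters`` clusters empty, the assignment is
    redone by seeded k-means on the rows of B so every cluster can be
    populated. Returns (labels in {1..k1}, method), method in
    {"argmax", "kmeans"}.
    """
    B = np.asarray(B, dtype=np.float64)
    if B.min(initial=0.0) < 0:
        raise ValueError("B must be non-negative")
    if n_clusters is None:
        n_clusters = B.shape[1]
    sums = B.sum(axis=1, keepdims=True)
    normed = np.divide(B, sums, out=np.zeros_like(B), where=sums > 0)
    labels = normed.argmax(axis=1) + 1
    if len(np.unique(labels)) < n_clusters:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(B) + 1
        return labels.astype(int), "kmeans"
    return labels.astype(int), "argmax"


# ======================================================================
# model / results objects
# ======================================================================
class ScMNMF:
    """Joint NMF clustering model for a :class:`MultiOmicsDataset`.

    Parameters
    ----------
    data
        Aligned multi-block dataset (raw counts are fine; preprocessing is
        applied at fit time).
    n_clusters
        Number of cell clusters k1. Required unless given via
        ``hyperparameters``.
    hyperparameters
        A full :class:`Hyperparameters`; keyword arguments override its
        fields (or the defaults).
    preprocess
        A :class:`PreprocessConfig`, ``None`` to skip preprocessing, or the
        default configuration when omitted.
    """

    def __init__(
        self,
        data: MultiOmicsDataset,
        n_clusters: int | None = None,
        hyperparameters: Hyperparameters | None = None,
        preprocess: PreprocessConfig | None | str = "default",
        **hp_overrides,
    ):
        if not isinstance(data, MultiOmicsDataset):
            data = MultiOmicsDataset(blocks=list(data))
        data.validate()
        self.data = data
        base = hyperparameters.to_dict() if hyperparameters is not None else {}
        if n_clusters is not None:
            base["k1"] = int(n_clusters)
        base.update(hp_overrides)
        self.hp = Hyperparameters(**base)
        if preprocess == "default":
            preprocess = PreprocessConfig()
        self.preprocess = preprocess

    @classmethod
    def from_dataframes(cls, frames: dict, true_labels=None, **kwargs) -> "ScMNMF":
        """Build from a dict of cell-indexed pandas DataFrames (one per block)."""
        names = list(frames)
        first = frames[names[0]]
        cells = list(map(str, first.index))
        blocks, feats = [], []
        for name in names:
            df = frames[name]
            if list(map(str, df.index)) != cells:
                raise ValueError(f"block {name!r} index does not match the first block")
            blocks.append(df.to_numpy(dtype=float))
            feats.append(list(map(str, df.columns)))
        data = MultiOmicsDataset(
            blocks=blocks, block_names=names, cell_ids=cells,
            feature_names=feats, true_labels=true_labels,
        )
        return cls(data, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None, verbose: bool = False) -> "ScMNMFResults":
        """Run preprocessing, graph construction and alternating updates.

        Returns a :class:`ScMNMFResults` with hard labels, the learned
        factors, and the per-iteration objective trace. Deterministic for a
        fixed (data, hyperparameters, seed).
        """
        hp = self.hp
        seed = hp.seed if seed is None else int(seed)
        pre = (
            preprocess_dataset(self.data, self.preprocess)
            if self.preprocess is not None
            else self.data
        )
        blocks = pre.blocks
        n = pre.n_cells
        p = hp.resolve_p(n, pre.n_features)

        graph = None
        if hp.alpha > 0:
            points = concatenate_for_graph(pre)
            n_neighbors = min(hp.n_neighbors, n - 1)
            graph = build_affinity(points, n_neighbors=n_neighbors, sigma=hp.sigma)

        model = initialize_factors(blocks, hp, p, seed)
        trace = [evaluate_objective(model, blocks, graph, hp)]
        converged = False
        it = 0
        for it in range(1, hp.max_iter + 1):
            model = update_w(model, blocks, hp)
            for k in range(len(blocks)):
                model = update_h(model, blocks, hp, k)
            model = update_b(model, graph, hp)
            model = update_f(model, hp)
            obj = evaluate_objective(model, blocks, graph, hp)
            if not np.isfinite(obj):
                for fname, arrs in (("W", [model.W]), ("H", model.H),
                                    ("B", [model.B]), ("F", [model.F])):
                    if any(not np.all(np.isfinite(a)) for a in arrs):
                        raise FloatingPointError(
                            f"objective became non-finite at iteration {it}; "
                            f"factor {fname} contains non-finite entries"
                        )
                raise FloatingPointError(f"objective became non-finite at iteration {it}")
            prev = trace[-1]
            trace.append(obj)
            if verbose:
                logger.info("iter %d: objective %.6g", it, obj)
            if abs(obj - prev) / max(prev, hp.eps) < hp.tol:
                converged = True
                break

        labels, method = assign_clusters(model.B, hp.k1, seed)
        return ScMNMFResults(
            model=model,
            labels=labels,
            objective_trace=np.asarray(trace),
            converged=converged,
            n_iter=it,
            assignment_method=method,
            graph=graph,
            dataset=pre,
            hp=hp,
            seed=seed,
            p=p,
        )


@dataclass
class ScMNMFResults:
    """Fitted factors, hard labels and convergence diagnostics."""

    model: FactorModel
    labels: np.ndarray                # per-cell cluster ids in {1..k1}
    objective_trace: np.ndarray       # objective value per iteration (incl. init)
    converged: bool
    n_iter: int
    assignment_method: str            # "argmax" or "kmeans"
    graph: AffinityGraph | None
    dataset: MultiOmicsDataset        # the (preprocessed) data that was fitted
    hp: Hyperparameters
    seed: int
    p: int

    @property
    def embedding(self) -> np.ndarray:
        """Per-cell cluster-evidence embedding (rows of B)."""
        return self.model.B

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def cluster_sizes(self) -> dict:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def score(self, truth=None):
        """Agreement of the labels with reference labels (default: the
        dataset's true_labels). Returns a :class:`~scmnmf.metrics.MetricsReport`."""
        from .metrics import report

        if truth is None:
            truth = self.dataset.true_labels
        if truth is None:
            raise ValueError("no reference labels available to score against")
        return report(self.labels, truth)

    def summary(self) -> str:
        """Plain-text fit summary."""
        hp = self.hp
        sizes = ", ".join(f"{k}:{v}" for k, v in sorted(self.cluster_sizes().items()))
        lines = [
            "scMNMF joint factorization results",
            "=" * 42,
            f"cells:              {self.dataset.n_cells}",
            f"blocks:             {self.dataset.n_blocks} "
            f"({', '.join(f'{n}={j}' for n, j in zip(self.dataset.block_names, self.dataset.n_features))})",
            f"latent dim p:       {self.p}",
            f"clusters k1:        {hp.k1}",
            f"lambda (l1 on H):   {hp.lambda_h}",
            f"mu (l1 on W):       {hp.mu}",
            f"alpha (graph):      {hp.alpha}",
            f"iterations:         {self.n_iter} ({'converged' if self.converged else 'max_iter reached'})",
            f"final objective:    {self.objective:.6g}",
            f"assignment:         {self.assignment_method}",
            f"cluster sizes:      {sizes}",
            f"seed:               {self.seed}",
        ]
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Objective value against iteration (log-scaled y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.objective_trace)), self.objective_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("objective O")
        ax.set_yscale("log")
        return ax

    def save(self, outdir) -> None:
        """Write labels, embedding, trace, factors and run metadata."""
        from . import io as _io

        _io.save_results(self, outdir)
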