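"""External clustering-agreement measures: ACC, ARI, NMI and AMI.

All four compare a predicted hard clustering with reference labels through
their contingency table. ACC maximizes plain agreement over one-to-one
mappings between cluster ids and class ids (Hungarian assignment); ARI is
the chance-adjusted pair-counting index (Hubert-Arabie); NMI normalizes
mutual information by the mean entropy, 2*MI / (h(P)+h(Q)); AMI subtracts
the expected MI under the permutation (hypergeometric) model and normalizes
by max(h(P), h(Q)). Natural logs throughout — all reported quantities are
ratios in which the base cancels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "MetricsReport",
    "contingency",
    "accuracy",
    "ari",
    "nmi",
    "ami",
    "expected_mutual_information",
    "report",
]


@dataclass
class ContingencyTable:
    """Cluster-by-class joint count table with marginals."""

    counts: np.ndarray  # clusters x classes, non-negative ints
    row_marginals: np.ndarray
    col_marginals: np.ndarray
    n: int

    def __post_init__(self):
        if int(self.counts.sum()) != self.n:
            raise ValueError("contingency counts do not sum to the number of items")


def _check_pair(pred, truth, min_len: int = 1):
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape[0] != truth.shape[0]:
        raise ValueError(
            f"label vectors differ in length: {pred.shape[0]} vs {truth.shape[0]}"
        )
    if pred.shape[0] < min_len:
        raise ValueError(f"need at least {min_len} labelled items")
    return pred, truth


def contingency(pred, truth) -> ContingencyTable:
    """Build the contingency table of two labelings."""
    pred, truth = _check_pair(pred, truth)
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    counts = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(counts, (pi, ti), 1)
    return ContingencyTable(
        counts=counts,
        row_marginals=counts.sum(axis=1),
        col_marginals=counts.sum(axis=0),
        n=int(pred.shape[0]),
    )


def _entropy(marginals: np.ndarray, n: int) -> float:
    p = marginals[marginals > 0] / n
    return float(-np.sum(p * np.log(p)))


def _mutual_information(tab: ContingencyTable) -> float:
    C = tab.counts
    n = tab.n
    nz = C > 0
    pij = C[nz] / n
    outer = np.outer(tab.row_marginals, tab.col_marginals)[nz] / (n * n)
    return float(np.sum(pij * np.log(pij / outer)))


def _same_partition(pred, truth) -> bool:
    """True if the two labelings induce identical groupings (up to relabel)."""
    tab = contingency(pred, truth)
    return bool(
        np.all((tab.counts > 0).sum(axis=0) <= 1)
        and np.all((tab.counts > 0).sum(axis=1) <= 1)
    )


# ----------------------------------------------------------------------
def accuracy(pred, truth) -> float:
    """Clustering accuracy: best agreement over one-to-one label mappings.

    The contingency table is zero-padded to square and the optimal
    assignment of predicted clusters to true classes is found by the
    Hungarian algorithm; the score is the matched fraction, in [0, 1].
    """
    pred, truth = _check_pair(pred, truth, min_len=1)
    tab = contingency(pred, truth)
    r, c = tab.counts.shape
    size = max(r, c)
    square = np.zeros((size, size), dtype=np.int64)
    square[:r, :c] = tab.counts
    rows, cols = linear_sum_assignment(square, maximize=True)
    return float(square[rows, cols].sum() / tab.n)


def ari(pred, truth) -> float:
    """Adjusted Rand index (Hubert-Arabie contingency-table form).

    1 for identical partitions; expectation 0 under independent random
    labelings. Degenerate case (both partitions trivial, zero adjusted
    range) returns 1.0 by convention.
    """
    pred, truth = _check_pair(pred, truth, min_len=2)
    tab = contingency(pred, truth)

    def comb2(x):
        x = np.asarray(x, dtype=np.float64)
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(tab.counts).sum()
    sum_a = comb2(tab.row_marginals).sum()
    sum_b = comb2(tab.col_marginals).sum()
    total = comb2(tab.n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def nmi(pred, truth) -> float:
    """Normalized mutual information, 2*MI / (h(P) + h(Q)), in [0, 1]."""
    pred, truth = _check_pair(pred, truth, min_len=1)
    tab = contingency(pred, truth)
    hp = _entropy(tab.row_marginals, tab.n)
    hq = _entropy(tab.col_marginals, tab.n)
    if hp + hq == 0.0:
        return 1.0 if _same_partition(pred, truth) else 0.0
    mi = _mutual_information(tab)
    return float(2.0 * mi / (hp + hq))


def expected_mutual_information(tab: ContingencyTable) -> float:
    """E[MI] between two labelings with fixed marginals under the
    permutation (hypergeometric) model.

    Exact summation over all feasible cell counts n_ij; O(R*C*n) terms.
    """
    a = tab.row_marginals.astype(np.int64)
    b = tab.col_marginals.astype(np.int64)
    n = tab.n
    lgn = gammaln(n + 1)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term = nij / n * np.log(n * nij / (ai * bj))
            # hypergeometric pmf via log-factorials
            logp = (
                gammaln(ai + 1)
                + gammaln(bj + 1)
                + gammaln(n - ai + 1)
                + gammaln(n - bj + 1)
                - lgn
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float(np.sum(term * np.exp(logp)))
    return emi


def ami(pred, truth) -> float:
    """Adjusted mutual information, (MI - E[MI]) / (max(h(P), h(Q)) - E[MI]).

    1 for identical partitions; expectation 0 under independent random
    labelings; degenerate zero denominator handled as in :func:`nmi`.
    """
    pred, truth = _check_pair(pred, truth, min_len=2)
    tab = contingency(pred, truth)
    hp = _entropy(tab.row_marginals, tab.n)
    hq = _entropy(tab.col_marginals, tab.n)
    if max(hp, hq) == 0.0:
        return 1.0 if _same_partition(pred, truth) else 0.0
    mi = _mutual_information(tab)
    emi = expected_mutual_information(tab)
    denom = max(hp, hq) - emi
    if denom == 0.0:
        return 1.0 if _same_partition(pred, truth) else 0.0
    return float((mi - emi) / denom)


@dataclass
class MetricsReport:
    """The four agreement scores for one (prediction, truth) pair."""

    acc: float
    ari: float
    nmi: float
    ami: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def report(pred, truth) -> MetricsReport:
    """Bundle all four metrics for one labelling pair."""
    pred, truth = _check_pair(pred, truth, min_len=2)
    return MetricsReport(
        acc=accuracy(pred, truth),
        ari=ari(pred, truth),
        nmi=nmi(pred, truth),
        ami=ami(pred, truth),
        n=int(len(pred)),
    )
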