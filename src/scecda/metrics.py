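"""Clustering and biology-conservation metrics plus their aggregates.

Label-agreement metrics (ARI, NMI, ACC via Hungarian matching, purity) score
the predicted partition against ground truth; embedding metrics (cASW =
cell-type average silhouette width, scaled cLISI = cell-type local inverse
Simpson's index) score how well cell types separate in the fused feature
space. Aggregates: cluster_avg = (ARI+NMI+ACC+PUR)/4, bio_avg =
(cLISI+cASW)/2, performance = mean of all six.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

from .types import LabelVector


def _labels(x) -> np.ndarray:
    if isinstance(x, LabelVector):
        return x.labels
    return np.asarray(x, dtype=np.int64)


def _check_lengths(pred, truth):
    pred, truth = _labels(pred), _labels(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def _contingency(pred, truth) -> np.ndarray:
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    C = np.zeros((len(pu), len(tu)), dtype=np.int64)
    np.add.at(C, (pi, ti), 1)
    return C


def ari(pred, truth) -> float:
    """Adjusted Rand index in [-1, 1]; 1 = identical partitions."""
    pred, truth = _check_lengths(pred, truth)
    return float(adjusted_rand_score(truth, pred))


def nmi(pred, truth, average_method: str = "geometric") -> float:
    """Mutual information normalized by the geometric mean of the entropies
    (``average_method="arithmetic"`` switches to the arithmetic-mean form)."""
    pred, truth = _check_lengths(pred, truth)
    return float(
        normalized_mutual_info_score(truth, pred, average_method=average_method)
    )


def acc(pred, truth) -> float:
    """Clustering accuracy under the optimal one-to-one cluster/class matching."""
    pred, truth = _check_lengths(pred, truth)
    C = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(-C)
    return float(C[rows, cols].sum() / len(pred))


def purity(pred, truth) -> float:
    """Mean proportion of each predicted cluster's majority true class."""
    pred, truth = _check_lengths(pred, truth)
    C = _contingency(pred, truth)
    return float(C.max(axis=1).sum() / len(pred))


def casw(H, truth, rescale: bool = False) -> float:
    """Cell-type average silhouette width on the fused features (Euclidean).

    Reported on the raw [-1, 1] silhouette scale; ``rescale=True`` maps it
    to [0, 1] via (s+1)/2 for aggregation alongside [0, 1] metrics.
    """
    truth = _labels(truth)
    H = np.asarray(H, dtype=np.float64)
    if len(np.unique(truth)) < 2:
        raise ValueError("cASW requires at least two cell types")
    s = float(silhouette_score(H, truth, metric="euclidean"))
    return (s + 1.0) / 2.0 if rescale else s


def _lisi_per_cell(H, labels, perplexity: float, tol: float = 1e-5) -> np.ndarray:
    """Inverse Simpson's index of label composition in a perplexity-weighted
    Gaussian neighborhood of each cell (the LISI procedure)."""
    n = H.shape[0]
    k = min(n - 1, int(np.ceil(3 * perplexity)))
    nn = NearestNeighbors(n_neighbors=k).fit(H)
    dist, idx = nn.kneighbors(H)
    # drop the self column when present
    if np.allclose(dist[:, 0], 0) and np.all(idx[:, 0] == np.arange(n)):
        dist, idx = dist[:, 1:], idx[:, 1:]
    logU = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        beta, beta_min, beta_max = 1.0, -np.inf, np.inf
        for _ in range(64):
            w = np.exp(-d2 * beta)
            s = w.sum()
            if s <= 0:
                p = np.ones_like(w) / len(w)
                break
            p = w / s
            ent = -np.sum(p * np.log(np.clip(p, 1e-300, None)))
            diff = ent - logU
            if abs(diff) < tol:
                break
            if diff > 0:  # entropy too high -> sharpen
                beta_min = beta
                beta = beta * 2 if beta_max == np.inf else (beta + beta_max) / 2
            else:
                beta_max = beta
                beta = beta / 2 if beta_min == -np.inf else (beta + beta_min) / 2
        probs = np.zeros(int(labels.max()) + 1)
        np.add.at(probs, labels[idx[i]], p)
        out[i] = 1.0 / np.sum(probs**2)
    return out


def clisi(H, truth, perplexity: float = 30.0) -> float:
    """Scaled cell-type LISI: 1 = every neighborhood is label-pure, 0 = mixed.

    The median per-cell inverse Simpson's index (raw LISI, in
    [1, n_types]) is rescaled as (n_types − LISI) / (n_types − 1).
    """
    truth = _labels(truth)
    H = np.asarray(H, dtype=np.float64)
    n_types = len(np.unique(truth))
    if n_types < 2:
        raise ValueError("cLISI undefined for a single cell type")
    if H.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"need more than {int(3 * perplexity)} cells for perplexity {perplexity}"
        )
    raw = float(np.median(_lisi_per_cell(H, truth, perplexity)))
    return (n_types - raw) / (n_types - 1)


@dataclass
class MetricsReport:
    ari: float
    nmi: float
    acc: float
    pur: float
    casw: float
    clisi_scaled: float

    @property
    def cluster_avg(self) -> float:
        return (self.ari + self.nmi + self.acc + self.pur) / 4

    @property
    def bio_avg(self) -> float:
        return (self.clisi_scaled + self.casw) / 2

    @property
    def performance(self) -> float:
        return (
            self.ari + self.nmi + self.acc + self.pur + self.casw + self.clisi_scaled
        ) / 6

    def to_dict(self) -> dict:
        return {
            "ari": self.ari,
            "nmi": self.nmi,
            "acc": self.acc,
            "pur": self.pur,
            "casw": self.casw,
            "clisi_scaled": self.clisi_scaled,
            "cluster_avg": self.cluster_avg,
            "bio_avg": self.bio_avg,
            "performance": self.performance,
        }


def evaluate(H, pred, truth, perplexity: float = 30.0) -> MetricsReport:
    """All six metrics of a clustering against ground truth."""
    return MetricsReport(
        ari=ari(pred, truth),
        nmi=nmi(pred, truth),
        acc=acc(pred, truth),
        pur=purity(pred, truth),
        casw=casw(H, truth),
        clisi_scaled=clisi(H, truth, perplexity=perplexity),
    )
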