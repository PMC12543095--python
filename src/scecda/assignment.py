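"""Latent-space quality filtering, center initialization and soft assignment.

Sparse modalities (especially chromatin accessibility) leave noisy cells in
the latent space that distort K-means centers. Before initializing centers we
therefore project the latent features to a 40-dimensional PCA space, compute
each cell's nearest-neighbor distance, and drop cells beyond the Tukey fence
Q3 + 1.5·IQR of those distances. K-means then runs on the retained cells only.

Soft assignment maps latent features through a Student-t style kernel around
the centers: q_ij ∝ (1 + ‖z_i − ξ_j‖)⁻¹ with the unsquared Euclidean norm by
default; ``squared_distance=True`` switches to the classic deep-embedded-
clustering kernel (1 + ‖·‖²)⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import autograd as ag
from .networks import LatentMatrix


@dataclass
class QualityReport:
    """Outcome of the PCA + IQR-fence cell quality filter."""

    embedding: np.ndarray
    nearest_dist: np.ndarray
    q1: float
    q3: float
    iqr: float
    threshold: float
    keep_mask: np.ndarray

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        ids = cell_ids if cell_ids is not None else np.arange(len(self.nearest_dist))
        return pd.DataFrame(
            {"cell_id": ids, "mdis": self.nearest_dist, "kept": self.keep_mask}
        )


@dataclass
class Centers:
    """Cluster centers ξ for one modality's latent space."""

    values: np.ndarray
    omics_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 centers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite centers")


def _latent_array(Z) -> np.ndarray:
    if isinstance(Z, LatentMatrix):
        return Z.values
    return ag.value(Z) if isinstance(Z, ag.Tensor) else np.asarray(Z, float)


def quality_filter(Z, n_components: int = 40) -> QualityReport:
    """Flag outlier cells by nearest-neighbor distance in PCA space.

    The fence is threshold = Q3 + 1.5·IQR over the per-cell nearest-neighbor
    distances (self-distances excluded); cells above it are dropped. With
    fewer than 3 cells filtering is disabled.
    """
    z = _latent_array(Z)
    n, d = z.shape
    if n < 3:
        warnings.warn("fewer than 3 cells; quality filtering disabled")
        mdis = np.zeros(n)
        return QualityReport(z.copy(), mdis, 0.0, 0.0, 0.0, 0.0, np.ones(n, bool))
    k = min(n_components, n - 1, d)
    h = PCA(n_components=k, svd_solver="full").fit_transform(z)
    D = squareform(pdist(h))
    np.fill_diagonal(D, np.inf)
    mdis = D.min(axis=1)
    q1, q3 = np.percentile(mdis, [25, 75])  # type-7 linear interpolation
    iqr = q3 - q1
    threshold = q3 + 1.5 * iqr
    # tolerance absorbs PCA round-off on exact-boundary distances
    keep = mdis <= threshold * (1 + 1e-9) + 1e-12
    if keep.sum() < 2:
        warnings.warn("fence would keep <2 cells; keeping all")
        keep = np.ones(n, bool)
    return QualityReport(h, mdis, float(q1), float(q3), float(iqr), float(threshold), keep)


def init_centers(Z, report: QualityReport, y: int, seed: int = 0, n_init: int = 10) -> Centers:
    """K-means centers on the quality-retained latent cells."""
    z = _latent_array(Z)
    kept = z[report.keep_mask]
    if y > kept.shape[0]:
        raise ValueError(f"y={y} exceeds {kept.shape[0]} retained cells")
    km = KMeans(n_clusters=y, n_init=n_init, random_state=seed).fit(kept)
    idx = 0
    if isinstance(Z, LatentMatrix):
        idx = Z.omics_index
    return Centers(km.cluster_centers_, omics_index=idx)


def _pairwise_dist(z, centers, squared: bool):
    """‖z_i − ξ_j‖ (or squared), differentiable in both arguments."""
    z2 = ag.tsum(z * z, axis=1, keepdims=True)
    c2t = ag.transpose(ag.tsum(centers * centers, axis=1, keepdims=True))
    sq = ag.clip(z2 + c2t - 2.0 * ag.matmul(z, ag.transpose(centers)), 0.0, np.inf)
    if squared:
        return sq
    return ag.sqrt(sq + 1e-12)


def soft_assign(Z, centers, squared_distance: bool = False):
    """Student-t style soft assignment of cells to centers.

    Returns a row-stochastic n × y matrix (ndarray for ndarray inputs, graph
    tensor when any input is a tensor, so the same code serves training).
    """
    z = Z.values if isinstance(Z, LatentMatrix) else Z
    c = centers.values if isinstance(centers, Centers) else centers
    dist = _pairwise_dist(z, c, squared_distance)
    kernel = 1.0 / (1.0 + dist)
    return kernel / ag.tsum(kernel, axis=1, keepdims=True)
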