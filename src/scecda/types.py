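"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

MODALITIES = ("RNA", "ATAC", "ADT")


@dataclass
class OmicsMatrix:
    """One modality's cells × features matrix.

    All modalities in a run must carry identical ``cell_ids`` in identical
    order: the method assumes paired measurements of the same physical cells.
    """

    values: np.ndarray | sp.spmatrix
    modality: str
    feature_names: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    layer_name: str = ""

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        n, m = self.values.shape
        if not self.feature_names:
            self.feature_names = [f"{self.modality}_f{j}" for j in range(m)]
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if len(self.feature_names) != m:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {m} features"
            )
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)


@dataclass
class LabelVector:
    """Integer cluster/cell-type labels, values in [0, n_types)."""

    labels: np.ndarray
    n_types: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.n_types < 1:
            raise ValueError("n_types must be positive")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_types
        ):
            raise ValueError("labels out of range [0, n_types)")

    def __len__(self) -> int:
        return self.labels.size

    @classmethod
    def from_values(cls, values) -> "LabelVector":
        """Encode arbitrary hashable labels as contiguous integers."""
        values = np.asarray(values)
        uniq, codes = np.unique(values, return_inverse=True)
        return cls(labels=codes, n_types=len(uniq))


def check_paired(layers: list[OmicsMatrix]) -> None:
    """Raise if the omics layers do not describe the same cells in order."""
    if not layers:
        raise ValueError("no omics layers given")
    ref = layers[0].cell_ids
    for layer in layers[1:]:
        if layer.cell_ids != ref:
            raise ValueError("unpaired cells: cell ids differ between omics layers")
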