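"""Paired multi-omics simulator with known cluster structure.

Cells are drawn around ``n_types`` cluster means in a 10-dimensional latent
space (means placed on scaled orthonormal directions so every pair of
clusters is ``separation`` apart; per-cell latent noise has unit scale, so
``separation`` is directly interpretable as a signal-to-noise ratio). Each
modality observes a mixture of the true latent and pure unclustered noise of
matched marginal scale — the ``informativeness`` knob: at 1 the modality
carries the full cluster signal, at 0 it carries none (emulating, e.g., an
accessibility layer that contributes nothing to cell identity). The mixed
latent is pushed through a fixed random linear map and a softplus to obtain
non-negative rates, then sampled from the modality's observation model:

* ``gaussian``    — rate + Gaussian noise (noise_sd)
* ``lognormal``   — exp(Normal(log1p(rate), noise_sd)), intensity-like
* ``nb_counts``   — negative binomial counts (dispersion 1, mean ≈ nb_mean),
                    RNA-like
* ``bernoulli_sparse`` — binarized detection with probability 1 − e^(−rate),
                    ATAC-like

``dropout_rate`` sets the layer's target *total* zero fraction: Bernoulli
dropout is calibrated on top of the distribution's intrinsic sampling zeros
(a count layer that is already sparser than the target is left as drawn).
All randomness flows from a single seed, so fixtures are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import LabelVector, OmicsMatrix

LATENT_DIM = 10

DISTRIBUTIONS = ("gaussian", "nb_counts", "bernoulli_sparse", "lognormal")


@dataclass
class ModalityConfig:
    modality: str = "RNA"
    feature_dim: int = 100
    noise_sd: float = 0.3
    dropout_rate: float = 0.0
    informativeness: float = 1.0
    distribution: str = "nb_counts"
    nb_mean: float = 20.0  # target mean count for nb_counts
    nb_dispersion: float = 1.0

    def __post_init__(self):
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not 0.0 <= self.informativeness <= 1.0:
            raise ValueError("informativeness must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class SynthConfig:
    n_cells: int = 600
    n_types: int = 3
    modalities: list[ModalityConfig] = field(
        default_factory=lambda: [
            ModalityConfig("RNA", 100, distribution="nb_counts", dropout_rate=0.3),
            ModalityConfig("ATAC", 200, distribution="bernoulli_sparse", dropout_rate=0.5),
        ]
    )
    separation: float = 5.0
    seed: int = 0
    latent_dim: int = LATENT_DIM

    def __post_init__(self):
        if self.n_types > self.latent_dim:
            raise ValueError("n_types cannot exceed the latent dimension")
        if self.n_cells < self.n_types * 10:
            raise ValueError("need at least 10 cells per cluster")
        if not self.modalities:
            raise ValueError("need at least one modality")


def _cluster_means(n_types, latent_dim, separation, rng) -> np.ndarray:
    """Means on orthonormal random directions, pairwise ``separation`` apart."""
    basis, _ = np.linalg.qr(rng.normal(size=(latent_dim, n_types)))
    return (separation / np.sqrt(2.0)) * basis.T


def _softplus(x):
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _sample_modality(
    latent: np.ndarray, mc: ModalityConfig, rng: np.random.Generator
) -> np.ndarray:
    W = rng.normal(size=(latent.shape[1], mc.feature_dim)) / np.sqrt(latent.shape[1])
    rate = _softplus(latent @ W)
    if mc.distribution == "gaussian":
        x = rate + rng.normal(0.0, mc.noise_sd, rate.shape)
    elif mc.distribution == "lognormal":
        x = np.exp(rng.normal(np.log1p(rate), mc.noise_sd))
    elif mc.distribution == "nb_counts":
        mu = rate * (mc.nb_mean / max(rate.mean(), 1e-9))
        if mc.noise_sd > 0:
            mu = mu * np.exp(rng.normal(0.0, mc.noise_sd, mu.shape))
        r = mc.nb_dispersion
        x = rng.negative_binomial(r, r / (r + mu)).astype(np.float64)
    else:  # bernoulli_sparse
        x = (rng.random(rate.shape) < (1.0 - np.exp(-rate))).astype(np.float64)
    if mc.dropout_rate > 0:
        # dropout_rate targets the layer's *total* zero fraction: top up the
        # intrinsic sampling zeros with calibrated Bernoulli dropout
        intrinsic = float((x == 0).mean())
        if intrinsic < mc.dropout_rate:
            p_extra = (mc.dropout_rate - intrinsic) / (1.0 - intrinsic)
            x = x * (rng.random(x.shape) >= p_extra)
    return x


def _latent_for(
    visible_labels: np.ndarray,
    means: np.ndarray,
    informativeness: float,
    n_cells: int,
    latent_dim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    signal = means[visible_labels] + rng.normal(size=(n_cells, latent_dim))
    if informativeness >= 1.0:
        return signal
    # pure (unclustered) noise, scaled to the signal's marginal spread so the
    # downstream observation model sees comparable magnitudes
    scale = np.sqrt(1.0 + np.mean(means**2) * means.shape[0])
    noise = rng.normal(scale=scale, size=(n_cells, latent_dim))
    return informativeness * signal + (1.0 - informativeness) * noise


def generate(cfg: SynthConfig) -> tuple[list[OmicsMatrix], LabelVector]:
    """Draw paired omics layers sharing one latent cluster structure."""
    rng = np.random.default_rng(cfg.seed)
    labels = rng.integers(0, cfg.n_types, cfg.n_cells)
    means = _cluster_means(cfg.n_types, cfg.latent_dim, cfg.separation, rng)
    cells = [f"cell{i}" for i in range(cfg.n_cells)]
    layers = []
    for u, mc in enumerate(cfg.modalities):
        latent = _latent_for(
            labels, means, mc.informativeness, cfg.n_cells, cfg.latent_dim, rng
        )
        x = _sample_modality(latent, mc, rng)
        layers.append(
            OmicsMatrix(
                x,
                mc.modality,
                [f"{mc.modality}{u}_f{j}" for j in range(mc.feature_dim)],
                list(cells),
                layer_name=f"synthetic_{mc.modality}{u}",
            )
        )
    return layers, LabelVector(labels, cfg.n_types)


def partial_information_scenario(
    cfg: SynthConfig,
) -> tuple[list[OmicsMatrix], LabelVector]:
    """Four clusters, each modality resolving only a coarse two-group split.

    Modality 0 sees {0,1} vs {2,3}; modality 1 sees {0,2} vs {1,3}; any
    further modality sees the full four-cluster structure. Only jointly are
    all four clusters identifiable, which stresses genuine cross-omics
    integration.
    """
    if cfg.n_types != 4:
        raise ValueError("partial_information_scenario requires n_types=4")
    if len(cfg.modalities) < 2:
        raise ValueError("need at least two modalities")
    rng = np.random.default_rng(cfg.seed)
    labels = rng.integers(0, 4, cfg.n_cells)
    cells = [f"cell{i}" for i in range(cfg.n_cells)]
    layers = []
    for u, mc in enumerate(cfg.modalities):
        if u == 0:
            visible = labels // 2
            means = _cluster_means(2, cfg.latent_dim, cfg.separation, rng)
        elif u == 1:
            visible = labels % 2
            means = _cluster_means(2, cfg.latent_dim, cfg.separation, rng)
        else:
            visible = labels
            means = _cluster_means(4, cfg.latent_dim, cfg.separation, rng)
        latent = _latent_for(
            visible, means, mc.informativeness, cfg.n_cells, cfg.latent_dim, rng
        )
        x = _sample_modality(latent, mc, rng)
        layers.append(
            OmicsMatrix(
                x,
                mc.modality,
                [f"{mc.modality}{u}_f{j}" for j in range(mc.feature_dim)],
                list(cells),
                layer_name=f"synthetic_partial_{mc.modality}{u}",
            )
        )
    return layers, LabelVector(labels, 4)
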