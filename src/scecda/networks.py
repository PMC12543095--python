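"""Per-omics autoencoders and their pretraining objective.

Each modality gets its own fully-connected autoencoder so it can learn that
modality's feature distribution independently. The published architecture is
``[input, 500, 500, 2000, hidden]`` with a mirrored decoder; the widths are
configurable because low-dimensional inputs (e.g. ADT panels or compact
synthetic fixtures) do not warrant a 2000-unit layer. Hidden layers use ReLU,
output layers are linear, and pretraining minimizes the mean squared
reconstruction error summed over modalities.

An auxiliary "augmented" encoder shares the main encoder's weights and adds
dropout plus a small isotropic Gaussian perturbation to the latent output,
emulating variation in sequencing depth; it is the augmentation used to build
contrastive positive pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .types import OmicsMatrix

DEFAULT_WIDTHS = (500, 500, 2000)


@dataclass
class AugmentConfig:
    """Latent-space augmentation: dropout rate and perturbation scale."""

    dropout_p: float = 0.1
    eps_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.eps_sigma < 0:
            raise ValueError("eps_sigma must be non-negative")


@dataclass
class LatentMatrix:
    """Encoder output for one modality (optionally augmented)."""

    values: np.ndarray
    augmented: bool = False
    omics_index: int = 0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _as_array(X) -> np.ndarray:
    if isinstance(X, OmicsMatrix):
        return X.dense()
    if isinstance(X, LatentMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


class Autoencoder:
    """Fully-connected autoencoder for one omics layer.

    Parameters are plain autograd tensors; ``encode``/``decode`` accept either
    ndarrays (inference, no graph when called via ``*_np``) or build the
    computation graph used during training.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_dim: int = 64,
        widths: tuple[int, ...] = DEFAULT_WIDTHS,
        seed: int = 0,
    ):
        if hidden_dim >= input_dim:
            raise ValueError("hidden_dim must be smaller than input_dim")
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.encoder_layers = [input_dim, *widths, hidden_dim]
        self.decoder_layers = list(reversed(self.encoder_layers))
        rng = np.random.default_rng(seed)
        self.enc_W, self.enc_b = self._init_stack(self.encoder_layers, rng)
        self.dec_W, self.dec_b = self._init_stack(self.decoder_layers, rng)

    @staticmethod
    def _init_stack(dims, rng):
        Ws, bs = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
            Ws.append(ag.parameter(rng.uniform(-limit, limit, (d_in, d_out))))
            bs.append(ag.parameter(np.zeros(d_out)))
        return Ws, bs

    @property
    def parameters(self) -> list[ag.Tensor]:
        return [*self.enc_W, *self.enc_b, *self.dec_W, *self.dec_b]

    @staticmethod
    def _forward(x, Ws, bs):
        h = x
        last = len(Ws) - 1
        for i, (W, b) in enumerate(zip(Ws, bs)):
            h = ag.matmul(h, W) + b
            if i < last:  # linear output layer
                h = ag.relu(h)
        return h

    def encode(self, X):
        """Latent features Z = E(X); returns a graph tensor."""
        return self._forward(_as_array(X), self.enc_W, self.enc_b)

    def decode(self, Z):
        return self._forward(Z, self.dec_W, self.dec_b)

    def encode_np(self, X) -> np.ndarray:
        return self._forward(
            _as_array(X), [W.data for W in self.enc_W], [b.data for b in self.enc_b]
        )

    def decode_np(self, Z) -> np.ndarray:
        return self._forward(
            np.asarray(Z), [W.data for W in self.dec_W], [b.data for b in self.dec_b]
        )

    def reconstruction_loss(self, X):
        """Mean squared error between X and its reconstruction."""
        x = _as_array(X)
        xhat = self.decode(self.encode(x))
        diff = xhat - x
        return ag.tmean(diff * diff)

    def encode_augmented_t(self, X, cfg: AugmentConfig, rng) -> ag.Tensor:
        """Graph-building augmented encoding (shared weights + dropout + ε)."""
        Z = self.encode(X)
        n, d = Z.shape
        if cfg.dropout_p > 0:
            mask = (rng.random((n, d)) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)
            Z = Z * mask
        if cfg.eps_sigma > 0:
            Z = Z + rng.normal(0.0, cfg.eps_sigma, (n, d))
        return Z


def encode(ae: Autoencoder, X, omics_index: int = 0) -> LatentMatrix:
    """Encode a layer to its latent representation (inference path)."""
    x = _as_array(X)
    if x.shape[1] != ae.input_dim:
        raise ValueError(
            f"input has {x.shape[1]} features, autoencoder expects {ae.input_dim}"
        )
    return LatentMatrix(ae.encode_np(x), augmented=False, omics_index=omics_index)


def encode_augmented(
    ae: Autoencoder, X, cfg: AugmentConfig, omics_index: int = 0
) -> LatentMatrix:
    """Augmented encoding Z~ = Dropout(E(X)) + ε, sharing the main weights."""
    rng = np.random.default_rng(cfg.seed)
    Z = ae.encode_np(_as_array(X))
    n, d = Z.shape
    if cfg.dropout_p > 0:
        mask = (rng.random((n, d)) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)
        Z = Z * mask
    if cfg.eps_sigma > 0:
        Z = Z + rng.normal(0.0, cfg.eps_sigma, (n, d))
    return LatentMatrix(Z, augmented=True, omics_index=omics_index)


def reconstruction_loss(ae: Autoencoder, X) -> float:
    """MSE between X and D(E(X)) as a plain float."""
    x = _as_array(X)
    xhat = ae.decode_np(ae.encode_np(x))
    return float(np.mean((x - xhat) ** 2))


def pretrain(
    aes: list[Autoencoder],
    data: list,
    epochs: int = 50,
    lr: float = 1e-4,
    batch_size: int = 256,
    seed: int = 0,
) -> list[float]:
    """Stage-1 pretraining: minimize the summed reconstruction MSE.

    Returns the per-epoch loss trace (sum over modalities of the epoch-mean
    MSE). Parameters are updated in place with Adam.
    """
    if len(aes) != len(data):
        raise ValueError("one autoencoder per omics layer required")
    mats = [_as_array(X) for X in data]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("unpaired cells: layers have different row counts")
    params = [p for ae in aes for p in ae.parameters]
    opt = ag.Adam(params, lr=lr)
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss = None
            for ae, mat in zip(aes, mats):
                term = ae.reconstruction_loss(mat[idx])
                loss = term if loss is None else loss + term
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite pretraining loss at epoch {len(trace)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        trace.append(epoch_loss / n_batches)
    return trace
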