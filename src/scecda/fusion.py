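"""Differential-attention fusion of concatenated per-omics latent features.

Attention operates over cells within a batch: queries/keys are two paired
projections (G1,K1) and (G2,K2) of the concatenated latent matrix Z, and the
attention map is the *difference* softmax(G1K1ᵀ/√f) − λ·softmax(G2K2ᵀ/√f)
applied to a value projection Z′. Subtracting a second, λ-scaled attention
map cancels attention mass assigned to irrelevant cells, which sharpens the
signal-to-noise ratio of the fused features. λ is a learnable scalar
reparameterized through four f-vectors:

    λ = exp(λg1·λk1) − exp(λg2·λk2) + 0.8 − 0.6·exp(−0.3·λ0)

so with zero-initialized vectors λ starts at 0.8 − 0.6·e^(−0.3·λ0) (≈0.666
for the default λ0 = 5). The output passes through LayerNorm, a residual
connection and a linear transform: O′ = Norm(Z + O), H = Norm(O′W4 + O′).

The value/output projections keep the width of Z (Σd_u) so the residual
connections are well-typed for any number of modalities; H always has exactly
the shape of the concatenated input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag

_DOT_CLAMP = 20.0


class DiffAttnParams:
    """Learnable parameters of the differential-attention fusion block."""

    def __init__(
        self,
        input_dim: int,
        two_f: int = 256,
        lambda0: float = 5.0,
        seed: int = 0,
    ):
        if two_f % 2 != 0 or two_f < 2:
            raise ValueError("two_f must be an even integer ≥ 2")
        if not 0.0 < lambda0 < 10.0:
            raise ValueError("lambda0 must lie in (0, 10)")
        self.input_dim = input_dim
        self.f = two_f // 2
        self.lambda0 = float(lambda0)
        rng = np.random.default_rng(seed)

        def glorot(d_in, d_out):
            limit = np.sqrt(6.0 / (d_in + d_out))
            return ag.parameter(rng.uniform(-limit, limit, (d_in, d_out)))

        self.W1 = glorot(input_dim, two_f)  # -> [G1; G2]
        self.W2 = glorot(input_dim, two_f)  # -> [K1; K2]
        self.W3 = glorot(input_dim, input_dim)  # value projection Z'
        self.W4 = glorot(input_dim, input_dim)  # output transform
        self.lg1 = ag.parameter(np.zeros(self.f))
        self.lg2 = ag.parameter(np.zeros(self.f))
        self.lk1 = ag.parameter(np.zeros(self.f))
        self.lk2 = ag.parameter(np.zeros(self.f))

    @property
    def parameters(self):
        return [self.W1, self.W2, self.W3, self.W4,
                self.lg1, self.lg2, self.lk1, self.lk2]

    def numpy(self) -> "DiffAttnParams":
        """A detached view whose forward pass stays in plain NumPy."""
        clone = object.__new__(DiffAttnParams)
        clone.input_dim = self.input_dim
        clone.f = self.f
        clone.lambda0 = self.lambda0
        for name in ("W1", "W2", "W3", "W4", "lg1", "lg2", "lk1", "lk2"):
            setattr(clone, name, getattr(self, name).data)
        return clone


@dataclass
class FusionState:
    """Intermediate and final products of one fusion forward pass."""

    Z_concat: object
    G1: object
    G2: object
    K1: object
    K2: object
    Zp: object
    O: object
    Op: object
    H: object
    lam: object


def lambda_value(p: DiffAttnParams):
    """Learnable attention-difference scale λ (dot products clamped ±20)."""
    d1 = ag.clip(ag.tsum(p.lg1 * p.lk1), -_DOT_CLAMP, _DOT_CLAMP)
    d2 = ag.clip(ag.tsum(p.lg2 * p.lk2), -_DOT_CLAMP, _DOT_CLAMP)
    init = 0.8 - 0.6 * np.exp(-0.3 * p.lambda0)
    return ag.exp(d1) - ag.exp(d2) + init


def diff_attention(Z_concat, p: DiffAttnParams, attention: str = "differential") -> FusionState:
    """Fuse concatenated latent features into H (same shape as the input).

    ``attention="self"`` is the ablation variant using only the first softmax
    map (standard single-head self-attention).
    """
    z = Z_concat
    if ag.value(z).shape[1] != p.input_dim:
        raise ValueError(
            f"Z has {ag.value(z).shape[1]} columns, fusion expects {p.input_dim}"
        )
    f = p.f
    GK = ag.matmul(z, p.W1)
    G1, G2 = ag.cols(GK, 0, f), ag.cols(GK, f, 2 * f)
    KK = ag.matmul(z, p.W2)
    K1, K2 = ag.cols(KK, 0, f), ag.cols(KK, f, 2 * f)
    Zp = ag.matmul(z, p.W3)

    scale = 1.0 / np.sqrt(f)
    attn1 = ag.softmax(ag.matmul(G1, ag.transpose(K1)) * scale, axis=1)
    lam = lambda_value(p)
    if attention == "differential":
        attn2 = ag.softmax(ag.matmul(G2, ag.transpose(K2)) * scale, axis=1)
        combined = attn1 - lam * attn2
    elif attention == "self":
        combined = attn1
    else:
        raise ValueError(f"unknown attention mode {attention!r}")
    O = ag.matmul(combined, Zp)
    Op = ag.layer_norm(z + O)
    H = ag.layer_norm(ag.matmul(Op, p.W4) + Op)
    if not np.all(np.isfinite(ag.value(H))):
        raise FloatingPointError("non-finite activations in fusion forward pass")
    return FusionState(z, G1, G2, K1, K2, Zp, O, Op, H, lam)
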