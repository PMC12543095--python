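"""Cross-omics contrastive alignment loss with entropy regularization.

The contrastive features are the soft-assignment rows q_i· (one per view):
for each cell there are v "clean" views (one per modality) and, when
augmentation is enabled, v augmented views from the perturbed shared encoder.

Positive pairs for cell i:
  * every unordered clean pair across modalities (u < l), and
  * every ordered augmented–clean pair across modalities (u ≠ l);
  * with a single modality, the augmented–clean pair of that modality.
Negative pairs for cell i are all pairings with a *different* cell k in the
batch: clean–clean, augmented–clean and clean–augmented over all modality
combinations.

The default loss is the InfoNCE composition over these sets with cosine
similarity at temperature τ; ``variant="ratio"`` instead uses the literal
ratio −log(d⁺/(d⁺+d⁻)) where d⁻ sums similarities before exponentiation.
The entropy regularizer Σ_u Σ_j ρ_j log ρ_j over the batch-mean cluster usage
ρ of each clean view discourages cluster collapse (it is maximal, zero, for
one-hot usage and most negative for balanced usage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from . import autograd as ag

_EPS = 1e-12


@dataclass
class PairBatch:
    """Soft-assignment views for one mini-batch plus the temperature."""

    q_clean: list
    q_aug: list
    batch_indices: np.ndarray | None = None
    tau: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not self.q_clean:
            raise ValueError("need at least one clean view")
        b = ag.value(self.q_clean[0]).shape[0]
        if b == 0:
            raise ValueError("empty batch")
        for q in [*self.q_clean, *self.q_aug]:
            if ag.value(q).shape[0] != b:
                raise ValueError("views disagree on batch size")

    @property
    def b(self) -> int:
        return ag.value(self.q_clean[0]).shape[0]

    @property
    def v(self) -> int:
        return len(self.q_clean)


@dataclass
class ContrastiveLosses:
    L_contrastive: object
    L_entropy: object
    L_stage2: object
    rho: np.ndarray = field(default=None)


def build_pairs(q_clean, q_aug, batch_indices=None, tau: float = 1.0) -> PairBatch:
    """Restrict views to a batch and package them for the loss."""
    if batch_indices is not None:
        batch_indices = np.asarray(batch_indices)
        q_clean = [ag.value(q)[batch_indices] for q in q_clean]
        q_aug = [ag.value(q)[batch_indices] for q in q_aug]
    return PairBatch(list(q_clean), list(q_aug), batch_indices, tau)


def positive_pairs(v: int, with_aug: bool) -> list[tuple[int, int]]:
    """Index pairs into the combined view list (clean u -> u, augmented u -> v+u)."""
    pairs = [(u, l) for u in range(v) for l in range(u + 1, v)]
    if with_aug:
        if v == 1:
            pairs.append((1, 0))  # augmented-clean pair of the single modality
        else:
            pairs.extend((v + u, l) for u, l in product(range(v), range(v)) if u != l)
    return pairs


def negative_view_pairs(v: int, with_aug: bool) -> list[tuple[int, int]]:
    pairs = [(u, l) for u, l in product(range(v), range(v))]  # clean-clean
    if with_aug:
        pairs += [(v + u, l) for u, l in product(range(v), range(v))]  # aug-clean
        pairs += [(u, v + l) for u, l in product(range(v), range(v))]  # clean-aug
    return pairs


def _normalize_rows(q):
    norm = ag.sqrt(ag.tsum(q * q, axis=1, keepdims=True)) + _EPS
    return q / norm


def contrastive_loss(pb: PairBatch, variant: str = "nt_xent") -> ContrastiveLosses:
    """Alignment loss (Eq. 5 composition): L_stage2 = L_contrastive + L_entropy."""
    v, b = pb.v, pb.b
    with_aug = len(pb.q_aug) > 0
    views = [*pb.q_clean, *pb.q_aug]
    normed = [_normalize_rows(q) for q in views]
    pos = positive_pairs(v, with_aug)
    if not pos:
        raise ValueError(
            "no positive pairs: need ≥2 modalities or augmented views"
        )

    def sim(a_idx, b_idx):
        return ag.matmul(normed[a_idx], ag.transpose(normed[b_idx])) * (1.0 / pb.tau)

    offdiag = 1.0 - np.eye(b)
    if b > 1:
        neg_exp = None  # per-cell Σ over negative pairs of exp(similarity)
        neg_sim = None  # per-cell Σ of raw similarities (ratio variant)
        for a_idx, b_idx in negative_view_pairs(v, with_aug):
            S = sim(a_idx, b_idx)
            e = ag.tsum(ag.exp(S) * offdiag, axis=1)
            s = ag.tsum(S * offdiag, axis=1)
            neg_exp = e if neg_exp is None else neg_exp + e
            neg_sim = s if neg_sim is None else neg_sim + s
    else:
        neg_exp = neg_sim = 0.0  # boundary: no other cells in the batch

    eye = np.eye(b)
    total = None
    for a_idx, b_idx in pos:
        s_pos = ag.tsum(sim(a_idx, b_idx) * eye, axis=1)  # diagonal entries
        if variant == "nt_xent":
            term = ag.log(ag.exp(s_pos) + neg_exp) - s_pos
        elif variant == "ratio":
            d_plus = ag.clip(s_pos, _EPS, np.inf)
            term = -ag.log(d_plus / ag.clip(d_plus + neg_sim, _EPS, np.inf))
        else:
            raise ValueError(f"unknown variant {variant!r}")
        t = ag.tsum(term)
        total = t if total is None else total + t
    L_con = total * (1.0 / (len(pos) * b))

    L_ent = None
    rho_rows = []
    for q in pb.q_clean:
        rho = ag.tmean(q, axis=0)
        rho_rows.append(ag.value(rho))
        term = ag.tsum(rho * ag.log(ag.clip(rho, _EPS, np.inf)))
        L_ent = term if L_ent is None else L_ent + term
    return ContrastiveLosses(
        L_contrastive=L_con,
        L_entropy=L_ent,
        L_stage2=L_con + L_ent,
        rho=np.vstack(rho_rows),
    )
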