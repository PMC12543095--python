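"""Clustering head, target distribution, joint objective and training loop.

The clustering head scores fused features with a linear map and softmax,
A = softmax(H·W5). A sharpened target distribution

    P_ij = (A_ij² / f_j) / Σ_j' (A_ij'² / f_j'),   f_j = Σ_i A_ij

(the self-training construction of deep embedded clustering, with the
frequency term discouraging megaclusters) is aligned with each modality's
soft assignment through L_stage3 = (1/v) Σ_u KL(P ‖ q^u). The total objective

    L = α·L_stage1 + β·L_stage2 + γ·L_stage3

joins reconstruction, contrastive alignment and clustering; defaults
α = 1, β = 1, γ = 0.5. Training is two-stage: autoencoder pretraining, then
end-to-end optimization of encoders, decoders, cluster centers, fusion
parameters and the clustering head with Adam. P stays inside the computation
graph (it is the only path by which gradients reach the fusion block and W5);
the full-dataset P recomputed each epoch is used for label extraction and for
the convergence check, which stops training once fewer than ``convergence_tol``
of the labels change between epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .assignment import Centers, init_centers, quality_filter, soft_assign
from .contrastive import build_pairs, contrastive_loss
from .fusion import DiffAttnParams, diff_attention
from .networks import AugmentConfig, Autoencoder, pretrain
from .types import LabelVector, OmicsMatrix, check_paired

_EPS = 1e-12


@dataclass
class LossWeights:
    """Weights (α, β, γ) of the reconstruction/contrastive/clustering terms."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.5

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class TrainConfig:
    """Hyperparameters of the two-stage training schedule."""

    batch_size: int = 256
    pretrain_epochs: int = 50
    train_epochs: int = 200
    pretrain_lr: float = 1e-4
    lr: float = 1e-4
    seed: int = 0
    convergence_tol: float = 0.001  # fraction of labels changing per epoch
    hidden_dims: int | list[int] = 64
    encoder_widths: tuple[int, ...] = (500, 500, 2000)
    dropout_p: float = 0.1
    eps_sigma: float = 0.1
    tau: float = 1.0
    two_f: int = 256
    lambda0: float = 5.0
    squared_distance: bool = False
    contrastive_variant: str = "nt_xent"
    kmeans_n_init: int = 10
    target_interval: int = 1  # epochs between full-data refreshes of P/labels
    attach_target: bool = False  # differentiate through P instead of staling it
    head_warmup_steps: int = 300  # W5 distillation steps before joint training
    head_warmup_lr: float = 1e-2
    # ablation switches
    use_contrastive: bool = True
    use_augmentation: bool = True
    attention: str = "differential"

    def __post_init__(self):
        if self.use_contrastive and self.batch_size < 2:
            raise ValueError("batch_size must be ≥ 2 when contrastive loss is on")


def cluster_probs(H, W5):
    """Soft cluster probabilities A = softmax(H W5), row-stochastic."""
    return ag.softmax(ag.matmul(H, W5), axis=1)


def target_distribution(A):
    """Sharpened, frequency-corrected target P from soft probabilities A."""
    f = ag.clip(ag.tsum(A, axis=0, keepdims=True), _EPS, np.inf)
    t = (A * A) / f
    return t / ag.tsum(t, axis=1, keepdims=True)


def kl_stage3(P, q_views):
    """(1/v) Σ_u KL(P ‖ q^u), summed over cells and clusters."""
    if not q_views:
        raise ValueError("no assignment views given")
    logP = ag.log(ag.clip(P, _EPS, np.inf))
    total = None
    for q in q_views:
        term = ag.tsum(P * (logP - ag.log(ag.clip(q, _EPS, np.inf))))
        total = term if total is None else total + term
    return total * (1.0 / len(q_views))


def total_loss(L1, L2, L3, w: LossWeights):
    """L = α·L1 + β·L2 + γ·L3."""
    return w.alpha * L1 + w.beta * L2 + w.gamma * L3


def predict_labels(P) -> LabelVector:
    """Hard labels c_i = argmax_j P_ij (ties break to the lowest index)."""
    p = ag.value(P)
    return LabelVector(np.argmax(p, axis=1), n_types=p.shape[1])


@dataclass
class FittedModel:
    """Everything produced by :func:`fit` on one dataset."""

    autoencoders: list[Autoencoder]
    centers: list
    fusion: DiffAttnParams
    W5: ag.Tensor
    config: TrainConfig
    weights: LossWeights
    y: int
    H: np.ndarray = None
    A: np.ndarray = None
    P: np.ndarray = None
    labels: LabelVector = None
    quality_reports: list = field(default_factory=list)
    pretrain_trace: list = field(default_factory=list)
    train_trace: list = field(default_factory=list)  # dicts of per-epoch losses
    label_change_trace: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)

    def transform(self, data: list[OmicsMatrix]):
        """Full forward pass on (preprocessed) layers: returns (H, A, P, labels)."""
        mats = [X.dense() if isinstance(X, OmicsMatrix) else np.asarray(X) for X in data]
        Zs = [ae.encode_np(m) for ae, m in zip(self.autoencoders, mats)]
        Zc = np.concatenate(Zs, axis=1)
        fs = diff_attention(Zc, self.fusion.numpy(), attention=self.config.attention)
        A = cluster_probs(fs.H, self.W5.data)
        P = target_distribution(A)
        return fs.H, A, P, predict_labels(P)

    def soft_assignments(self, data) -> list[np.ndarray]:
        mats = [X.dense() if isinstance(X, OmicsMatrix) else np.asarray(X) for X in data]
        return [
            soft_assign(ae.encode_np(m), c.data, self.config.squared_distance)
            for ae, m, c in zip(self.autoencoders, mats, self.centers)
        ]

    def save(self, path):
        """Checkpoint all parameters to a single .npz archive."""
        arrays = {}
        for u, ae in enumerate(self.autoencoders):
            for i, (W, b) in enumerate(zip(ae.enc_W, ae.enc_b)):
                arrays[f"ae{u}_encW{i}"] = W.data
                arrays[f"ae{u}_encb{i}"] = b.data
            for i, (W, b) in enumerate(zip(ae.dec_W, ae.dec_b)):
                arrays[f"ae{u}_decW{i}"] = W.data
                arrays[f"ae{u}_decb{i}"] = b.data
            arrays[f"centers{u}"] = self.centers[u].data
        for name in ("W1", "W2", "W3", "W4", "lg1", "lg2", "lk1", "lk2"):
            arrays[f"fusion_{name}"] = getattr(self.fusion, name).data
        arrays["W5"] = self.W5.data
        np.savez(path, **arrays)

    def load_params(self, path):
        """Restore parameters saved by :meth:`save` (architecture must match)."""
        with np.load(path) as npz:
            for u, ae in enumerate(self.autoencoders):
                for i, (W, b) in enumerate(zip(ae.enc_W, ae.enc_b)):
                    W.data[...] = npz[f"ae{u}_encW{i}"]
                    b.data[...] = npz[f"ae{u}_encb{i}"]
                for i, (W, b) in enumerate(zip(ae.dec_W, ae.dec_b)):
                    W.data[...] = npz[f"ae{u}_decW{i}"]
                    b.data[...] = npz[f"ae{u}_decb{i}"]
                self.centers[u].data[...] = npz[f"centers{u}"]
            for name in ("W1", "W2", "W3", "W4", "lg1", "lg2", "lk1", "lk2"):
                getattr(self.fusion, name).data[...] = npz[f"fusion_{name}"]
            self.W5.data[...] = npz["W5"]


def _align_center_indices(Zs, centers, squared: bool) -> None:
    """Permute each modality's centers so cluster indices agree across omics.

    K-means indexes clusters arbitrarily per modality, but the KL and
    contrastive terms compare soft-assignment columns across modalities, so
    column j must mean the same cluster everywhere. Clusters are matched to
    modality 0 by maximum overlap of hard assignments (Hungarian matching on
    the cross-modality contingency table); the cells are paired, so overlap
    is well-defined.
    """
    from scipy.optimize import linear_sum_assignment

    y = centers[0].data.shape[0]
    ref = np.argmax(soft_assign(Zs[0], centers[0].data, squared), axis=1)
    for u in range(1, len(centers)):
        hard = np.argmax(soft_assign(Zs[u], centers[u].data, squared), axis=1)
        C = np.zeros((y, y))
        np.add.at(C, (hard, ref), 1)
        rows, colmatch = linear_sum_assignment(-C)
        perm = np.empty(y, dtype=int)
        perm[colmatch] = rows
        centers[u].data = centers[u].data[perm].copy()


def _warm_up_head(Zs, centers, fus: DiffAttnParams, W5, y: int,
                  cfg: TrainConfig) -> None:
    """Initialize W5 from a K-means partition of the fused features.

    Before joint training the head is random, so the differentiable target P
    would drag the (well-initialized) soft assignments toward noise. Following
    the usual deep-embedded-clustering convention of initializing the cluster
    layer by K-means on the embedding, we cluster the full-dataset fused
    features H, match the resulting cluster indices to the modality-consensus
    soft assignment (Hungarian overlap, so the KL term compares like with
    like), and fit W5 to the one-hot partition by cross-entropy. The KL term
    then refines this initialization end to end.
    """
    from scipy.optimize import linear_sum_assignment
    from sklearn.cluster import KMeans

    qbar = np.mean(
        [soft_assign(Z, c.data, cfg.squared_distance) for Z, c in zip(Zs, centers)],
        axis=0,
    )
    H = diff_attention(
        np.concatenate(Zs, axis=1), fus.numpy(), attention=cfg.attention
    ).H
    km = KMeans(n_clusters=y, n_init=cfg.kmeans_n_init,
                random_state=cfg.seed).fit_predict(H)
    ref = np.argmax(qbar, axis=1)
    C = np.zeros((y, y))
    np.add.at(C, (km, ref), 1)
    rows, colmatch = linear_sum_assignment(-C)
    relabel = np.empty(y, dtype=int)
    relabel[rows] = colmatch
    # soft target: the K-means partition at the sharpness of the consensus
    # assignment, so the distilled head matches the scale the KL term expects
    onehot = np.eye(y)[relabel[km]]
    sharp = float(np.mean(qbar.max(axis=1)))
    target = sharp * onehot + (1.0 - sharp) / y
    opt = ag.Adam([W5], lr=cfg.head_warmup_lr)
    for _ in range(cfg.head_warmup_steps):
        A = cluster_probs(ag.Tensor(H), W5)
        loss = -ag.tmean(ag.tsum(target * ag.log(ag.clip(A, _EPS, np.inf)), axis=1))
        opt.zero_grad()
        loss.backward()
        opt.step()


def fit(
    data: list[OmicsMatrix],
    y: int,
    cfg: TrainConfig | None = None,
    weights: LossWeights | None = None,
) -> FittedModel:
    """Two-stage training on paired (already preprocessed) omics layers."""
    cfg = cfg or TrainConfig()
    weights = weights or LossWeights()
    if y < 2:
        raise ValueError("y must be ≥ 2")
    check_paired(data)
    mats = [X.dense() for X in data]
    n = mats[0].shape[0]
    v = len(mats)
    hidden = cfg.hidden_dims if isinstance(cfg.hidden_dims, (list, tuple)) else [cfg.hidden_dims] * v
    rng = np.random.default_rng(cfg.seed)

    # ---- stage 1: autoencoder pretraining --------------------------------
    aes = [
        Autoencoder(m.shape[1], hidden[u], widths=tuple(cfg.encoder_widths),
                    seed=cfg.seed + 101 * u)
        for u, m in enumerate(mats)
    ]
    pre_trace = pretrain(
        aes, mats, epochs=cfg.pretrain_epochs, lr=cfg.pretrain_lr,
        batch_size=cfg.batch_size, seed=cfg.seed,
    )

    # ---- quality filtering + center initialization per modality ----------
    reports, centers, Zs_full = [], [], []
    for u, (ae, m) in enumerate(zip(aes, mats)):
        Z = ae.encode_np(m)
        Zs_full.append(Z)
        rep = quality_filter(Z)
        reports.append(rep)
        c = init_centers(Z, rep, y, seed=cfg.seed + u, n_init=cfg.kmeans_n_init)
        centers.append(ag.parameter(c.values))
    _align_center_indices(Zs_full, centers, cfg.squared_distance)

    # ---- stage 2+3: joint end-to-end training ----------------------------
    fus = DiffAttnParams(sum(hidden), two_f=cfg.two_f, lambda0=cfg.lambda0,
                         seed=cfg.seed + 7)
    limit = np.sqrt(6.0 / (sum(hidden) + y))
    W5 = ag.parameter(rng.uniform(-limit, limit, (sum(hidden), y)))
    if cfg.head_warmup_steps > 0:
        _warm_up_head(Zs_full, centers, fus, W5, y, cfg)
    params = [p for ae in aes for p in ae.parameters]
    params += centers + fus.parameters + [W5]
    opt = ag.Adam(params, lr=cfg.lr)
    aug = AugmentConfig(cfg.dropout_p, cfg.eps_sigma, cfg.seed)

    model = FittedModel(aes, centers, fus, W5, cfg, weights, y,
                        quality_reports=reports, pretrain_trace=pre_trace,
                        cell_ids=list(data[0].cell_ids))
    _, _, P_stale, lab0 = model.transform(data)
    prev_labels = lab0.labels
    for epoch in range(cfg.train_epochs):
        order = rng.permutation(n)
        sums = {"L1": 0.0, "L2": 0.0, "L3": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            b = len(idx)
            Zs, L1 = [], None
            for ae, m in zip(aes, mats):
                xb = m[idx]
                Z = ae.encode(xb)
                diff = ae.decode(Z) - xb
                term = ag.tmean(diff * diff)
                L1 = term if L1 is None else L1 + term
                Zs.append(Z)
            q_clean = [
                soft_assign(Z, c, cfg.squared_distance)
                for Z, c in zip(Zs, centers)
            ]
            if cfg.use_contrastive and b >= 2:
                q_aug = []
                if cfg.use_augmentation:
                    for ae, m, c in zip(aes, mats, centers):
                        Zt = ae.encode_augmented_t(m[idx], aug, rng)
                        q_aug.append(soft_assign(Zt, c, cfg.squared_distance))
                if v >= 2 or q_aug:
                    pb = build_pairs(q_clean, q_aug, tau=cfg.tau)
                    L2 = contrastive_loss(pb, cfg.contrastive_variant).L_stage2
                else:
                    L2 = ag.Tensor(0.0)
            else:
                L2 = ag.Tensor(0.0)
            if cfg.attach_target:
                # fully end-to-end variant: differentiate through P so the
                # KL term also trains the fusion block and clustering head
                Zc = ag.concat(Zs, axis=1)
                fs = diff_attention(Zc, fus, attention=cfg.attention)
                A = cluster_probs(fs.H, W5)
                P = target_distribution(A)
            else:
                # self-training: P is the stale full-dataset target,
                # refreshed every target_interval epochs
                P = P_stale[idx]
            L3 = kl_stage3(P, q_clean) * (1.0 / b)  # per-cell scale
            loss = total_loss(L1, L2, L3, weights)
            if not np.isfinite(ag.value(loss)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: "
                    f"L1={ag.value(L1)}, L2={ag.value(L2)}, L3={ag.value(L3)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            for key, val in (("L1", L1), ("L2", L2), ("L3", L3), ("total", loss)):
                sums[key] += float(ag.value(val))
            n_batches += 1
        model.train_trace.append({k: s / n_batches for k, s in sums.items()})

        if (epoch + 1) % cfg.target_interval == 0 or epoch == cfg.train_epochs - 1:
            _, _, P_stale, lab = model.transform(data)
            labels = lab.labels
            change = float(np.mean(labels != prev_labels))
            model.label_change_trace.append(change)
            prev_labels = labels
            if change < cfg.convergence_tol:
                break

    model.H, model.A, model.P, model.labels = model.transform(data)
    return model
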