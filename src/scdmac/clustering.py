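"""Weighted soft K-means and KL self-training in the embedding space, plus
the staged end-to-end fit.

Soft cluster weights use a Gaussian kernel on embedding-to-center distances
with an optional Markov-like inflation exponent; centers are weighted means.
Soft assignments q use a Student-t kernel (as in deep embedded clustering);
the sharpened target p up-weights confident assignments and the KL(p‖q) term
self-trains the encoder. The total objective is

    L = α·L_zinb + β·L_mask + φ·L_kmeans + θ·L_cluster
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .autograd import Tensor
from .corruption import corrupt
from .masked_ae import MaskedAEConfig, MaskedAutoencoder
from .nn import Adam
from .preprocessing import (AugmentationConfig, CountMatrix, augment,
                            build_knn_graph, normalize_library_size,
                            select_hvg)
from .zinb import DenoiserConfig, denoise, train_denoiser

logger = logging.getLogger(__name__)

Q_EPS = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ClusterState:
    centers: np.ndarray            # (C, latent_dim)
    weights: np.ndarray            # w_ik, (n, C), rows sum to 1
    q: np.ndarray                  # soft assignments, rows sum to 1
    p: np.ndarray                  # target distribution, rows sum to 1
    inflation: float = 1.0
    t_dof: float = 1.0


@dataclass
class LossWeights:
    """Mixing weights (α, β, φ, θ) of the total objective."""

    alpha: float = 0.0   # ZINB likelihood; 0 = denoiser frozen after pretraining
    beta: float = 1.0    # masked-autoencoder loss
    phi: float = 0.1     # weighted K-means loss
    theta_: float = 1.0  # KL self-training loss

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.phi, self.theta_)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


# ---------------------------------------------------------------------------
# soft K-means pieces
# ---------------------------------------------------------------------------

def _sq_dists(Z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = Z[:, None, :] - centers[None, :, :]
    return np.einsum("ikd,ikd->ik", diff, diff)


def soft_weights(Z: np.ndarray, centers: np.ndarray,
                 inflation: float = 1.0) -> np.ndarray:
    """Gaussian-kernel soft weights w̄ sharpened by the inflation exponent.

    w̄_ik ∝ exp(−‖z_i − c_k‖²); w_ik ∝ w̄_ik^α. Rows sum to 1.
    """
    d2 = _sq_dists(Z, centers)
    d2 = d2 - d2.min(axis=1, keepdims=True)  # stabilize the softmax
    w = np.exp(-d2)
    w /= w.sum(axis=1, keepdims=True)
    if inflation != 1.0:
        w = w ** inflation
        w /= w.sum(axis=1, keepdims=True)
    return w


def update_centers(Z: np.ndarray, weights: np.ndarray,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """c_k = Σ_i w_ik z_i / Σ_i w_ik.

    A cluster whose total weight underflows is re-seeded from the cell
    farthest from its current assignment's center.
    """
    totals = weights.sum(axis=0)
    centers = np.empty((weights.shape[1], Z.shape[1]))
    for k in range(weights.shape[1]):
        if totals[k] < 1e-12:
            d2 = _sq_dists(Z, centers[:k] if k else Z.mean(0, keepdims=True))
            far = int(np.argmax(d2.min(axis=1)))
            logger.warning("cluster %d collapsed; re-seeding from cell %d", k, far)
            centers[k] = Z[far]
        else:
            centers[k] = weights[:, k] @ Z / totals[k]
    return centers


def kmeans_loss(Z: np.ndarray, centers: np.ndarray,
                weights: np.ndarray) -> float:
    """Σ_i Σ_k w_ik ‖z_i − c_k‖²."""
    return float((weights * _sq_dists(Z, centers)).sum())


def soft_assign(Z: np.ndarray, centers: np.ndarray,
                t_dof: float = 1.0) -> np.ndarray:
    """Student-t soft assignment of cells to centers.

    q_ik ∝ (1 + ‖z_i − c_k‖²/t)^{−(t+1)/2}, rows normalized to 1.
    """
    if t_dof <= 0:
        raise ValueError("t_dof must be positive")
    num = (1.0 + _sq_dists(Z, centers) / t_dof) ** (-(t_dof + 1.0) / 2.0)
    return num / num.sum(axis=1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened self-training target p_ik ∝ q_ik² / Σ_i q_ik."""
    f = q.sum(axis=0)
    p = q ** 2 / f
    return p / p.sum(axis=1, keepdims=True)


def cluster_kl_loss(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p‖q) = Σ_i Σ_k p_ik log(p_ik / q_ik); zero q is clipped."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        logger.warning("q contains non-positive entries; clipping at %g", Q_EPS)
        q = np.clip(q, Q_EPS, None)
    p = np.asarray(p, dtype=float)
    terms = np.where(p > 0, p * np.log(np.clip(p, Q_EPS, None) / q), 0.0)
    return float(terms.sum())


def total_loss(Lzinb: float, Lmask: float, Lkmeans: float, Lcluster: float,
               w: LossWeights) -> float:
    """α·L_zinb + β·L_mask + φ·L_kmeans + θ·L_cluster."""
    return (w.alpha * Lzinb + w.beta * Lmask
            + w.phi * Lkmeans + w.theta_ * Lcluster)


# -- tape versions used during joint training --------------------------------

def _kmeans_loss_t(Z: Tensor, centers: np.ndarray, weights: np.ndarray) -> Tensor:
    C = centers.shape[0]
    total = Tensor(0.0)
    for k in range(C):
        diff = Z - Tensor(centers[k][None, :])
        total = total + (Tensor(weights[:, k][:, None]) * diff * diff).sum()
    return total


def _soft_assign_t(Z: Tensor, centers: np.ndarray, t_dof: float) -> Tensor:
    C = centers.shape[0]
    cols = []
    for k in range(C):
        diff = Z - Tensor(centers[k][None, :])
        d2 = (diff * diff).sum(axis=1, keepdims=True)
        cols.append((1.0 + d2 * (1.0 / t_dof)) ** (-(t_dof + 1.0) / 2.0))
    from .autograd import concat
    num = concat(cols, axis=1)
    return num / num.sum(axis=1, keepdims=True)


def _kl_t(p: np.ndarray, q: Tensor) -> Tensor:
    qc = q.clip(Q_EPS, 1.0)
    logp = np.log(np.clip(p, Q_EPS, None))
    kl = (Tensor(p) * (Tensor(logp) - qc.log())).sum()
    # exact KL is ≥ 0; at p ≈ q floating-point cancellation can leave an
    # O(1e-16) negative, which would pollute the logged history
    if -1e-9 < float(kl.data) < 0.0:
        kl.data = np.zeros_like(kl.data)
    return kl


# ---------------------------------------------------------------------------
# end-to-end fit
# ---------------------------------------------------------------------------

@dataclass
class ScDMACConfig:
    """Everything the staged pipeline needs, fully seeded.

    Ablation switches: `use_denoiser=False` drops the ZINB pre-denoising
    stage; `masked_ae.use_mask_predictor=False` removes mask prediction and
    its loss; `masked_ae.weights.lambda_=0.5` removes reconstruction
    weighting.
    """

    n_top_genes: int = 2000
    denoiser: DenoiserConfig = field(default_factory=DenoiserConfig)
    masked_ae: MaskedAEConfig = field(default_factory=MaskedAEConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    use_denoiser: bool = True
    use_augmentation: bool = True
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    knn_k: int = 15
    inflation: float = 1.0
    t_dof: float = 1.0
    joint_epochs: int = 120
    joint_learning_rate: float = 1e-3
    refresh_interval: int = 20
    label_change_tol: float = 1e-3
    kmeans_restarts: int = 20
    seed: int = 0

    def derive(self, seed: int) -> "ScDMACConfig":
        """Copy of this config with all stage seeds fanned out from `seed`."""
        import copy
        cfg = copy.deepcopy(self)
        cfg.seed = seed
        cfg.denoiser.seed = seed * 7 + 1
        cfg.masked_ae.seed = seed * 7 + 2
        cfg.augmentation.seed = seed * 7 + 3
        return cfg


@dataclass
class FitResult:
    labels: np.ndarray
    embedding: np.ndarray
    history: list[dict[str, float]]
    state: ClusterState
    model: MaskedAutoencoder
    cell_ids: list[str]


def fit(X: CountMatrix, n_clusters: int,
        config: ScDMACConfig | None = None) -> FitResult:
    """Run the full staged pipeline and return labels, embedding, history.

    Stages: (1) pretrain the ZINB denoiser on raw counts and denoise;
    (2) log1p the denoised matrix, corrupt it, pretrain the masked
    autoencoder; (3) initialize centers by hard K-means on Z, then alternate
    soft-weight/center updates with gradient steps on the total objective,
    refreshing the self-training target on a fixed interval. Final labels
    are argmax_k q_ik.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    cfg = config or ScDMACConfig()

    # -- stage 0: preprocessing -------------------------------------------
    norm = normalize_library_size(X)
    if len(norm.kept_cells) < X.n_cells:
        X = CountMatrix(X.values[norm.kept_cells],
                        [X.cell_ids[i] for i in norm.kept_cells],
                        list(X.gene_ids))
    hvg = select_hvg(X, cfg.n_top_genes)
    Xf = X.subset_genes(hvg)

    # -- stage 1: ZINB denoising ------------------------------------------
    denoiser = None
    if cfg.use_denoiser:
        denoiser = train_denoiser(Xf, cfg.denoiser)
        Xz = denoise(denoiser, Xf)
        zinb_hist = denoiser.history
    else:
        Xz = normalize_library_size(Xf).values
        zinb_hist = []
    X_log = np.log1p(Xz)

    # -- stage 2: masked-AE pretraining -----------------------------------
    graph = build_knn_graph(X_log, k=min(cfg.knn_k, X_log.shape[0] - 1))
    aug_rng = np.random.default_rng(cfg.augmentation.seed)
    mae_cfg = cfg.masked_ae
    model = MaskedAutoencoder(X_log.shape[1], mae_cfg)
    rng = np.random.default_rng(mae_cfg.seed + 1)
    opt = Adam(model.params, lr=mae_cfg.learning_rate)
    for _ in range(mae_cfg.epochs):
        view = (augment(X_log, graph, cfg.augmentation, aug_rng)
                if cfg.use_augmentation else X_log)
        batch = corrupt(view, mae_cfg.mask_ratio, rng)
        loss, lm, lrec = model.loss_t(X_log, batch.corrupted, batch.true_mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.history.append({"loss": float(loss.data), "L_m": lm, "L_rec": lrec})

    # -- stage 3: joint clustering ----------------------------------------
    Z = model.encode(X_log)
    km = KMeans(n_clusters=n_clusters, init="k-means++",
                n_init=cfg.kmeans_restarts, random_state=cfg.seed % (2 ** 31))
    km.fit(Z)
    centers = km.cluster_centers_.copy()
    n = Z.shape[0]
    q = soft_assign(Z, centers, cfg.t_dof)
    p = target_distribution(q)
    labels = q.argmax(axis=1)
    history: list[dict[str, float]] = []
    opt = Adam(model.params, lr=cfg.joint_learning_rate)
    lw = cfg.loss_weights
    # α > 0 re-enables the ZINB likelihood during joint training: the
    # denoiser keeps taking gradient steps and the reconstruction target is
    # re-denoised at every target refresh. With the default α = 0 the
    # denoiser is an explicit, frozen pre-denoising stage.
    joint_zinb = lw.alpha > 0 and denoiser is not None
    if joint_zinb:
        from .zinb import ZINBDenoiser, _zinb_nll_tape
        den_opt = Adam(denoiser.params, lr=cfg.denoiser.learning_rate)
        x_enc, sf, raw = ZINBDenoiser._prepare(Xf)
    zinb_val = zinb_hist[-1] if zinb_hist else 0.0
    for epoch in range(cfg.joint_epochs):
        if epoch > 0 and epoch % cfg.refresh_interval == 0:
            if joint_zinb:
                X_log = np.log1p(denoise(denoiser, Xf))
            q = soft_assign(model.encode(X_log), centers, cfg.t_dof)
            p = target_distribution(q)
            new_labels = q.argmax(axis=1)
            changed = float(np.mean(new_labels != labels))
            labels = new_labels
            if changed < cfg.label_change_tol:
                break

        view = (augment(X_log, graph, cfg.augmentation, aug_rng)
                if cfg.use_augmentation else X_log)
        batch = corrupt(view, mae_cfg.mask_ratio, rng)
        l_mask_t, lm, lrec = model.loss_t(X_log, batch.corrupted, batch.true_mask)

        z_t = model.encode_t(X_log)
        w = soft_weights(z_t.data, centers, cfg.inflation)
        l_km_t = _kmeans_loss_t(z_t, centers, w) * (1.0 / n)
        q_t = _soft_assign_t(z_t, centers, cfg.t_dof)
        l_kl_t = _kl_t(p, q_t) * (1.0 / n)

        loss_t = (lw.beta * l_mask_t + lw.phi * l_km_t + lw.theta_ * l_kl_t)
        opt.zero_grad()
        loss_t.backward()
        opt.step()

        if joint_zinb:
            mu, th, pi = denoiser._forward(x_enc, sf)
            l_zinb_t = _zinb_nll_tape(raw, mu, th, pi) * lw.alpha
            den_opt.zero_grad()
            l_zinb_t.backward()
            den_opt.step()
            zinb_val = float(l_zinb_t.data) / lw.alpha

        Z = model.encode(X_log)
        w = soft_weights(Z, centers, cfg.inflation)
        centers = update_centers(Z, w)
        history.append({
            "epoch": float(epoch), "L_mask": float(l_mask_t.data),
            "L_m": lm, "L_rec": lrec,
            "L_kmeans": float(l_km_t.data) * n,
            "L_cluster": float(l_kl_t.data) * n,
            "total": float(loss_t.data),
            "L_zinb": zinb_val,
        })
    Z = model.encode(X_log)
    q = soft_assign(Z, centers, cfg.t_dof)
    labels = q.argmax(axis=1)
    state = ClusterState(centers=centers,
                         weights=soft_weights(Z, centers, cfg.inflation),
                         q=q, p=target_distribution(q),
                         inflation=cfg.inflation, t_dof=cfg.t_dof)
    return FitResult(labels=labels, embedding=Z, history=history, state=state,
                     model=model, cell_ids=list(X.cell_ids))
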