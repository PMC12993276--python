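"""Masked autoencoder: encoder → embedding Z, mask predictor M′, decoder.

The encoder maps the corrupted matrix X_M to a low-dimensional embedding
through σ(W_f Z_{f−1} + b_f) layers with a linear final layer. A linear mask
predictor estimates which entries were replaced; the decoder reconstructs
expression from the concatenation of Z and M′. Training combines a
cross-entropy mask-prediction loss L_m with a mask-weighted reconstruction
MSE L_rec:

    L_mask = γ_m·L_m + (1 − γ_m)·L_rec
    L_rec  = (1/N) Σ_ij W_ij (X_ij − X̃_ij)²,  W_ij = λM_ij + (1−λ)(1−M_ij)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .corruption import corrupt
from .nn import MLP, Adam, Dense, relu

PRED_EPS = 1e-7


@dataclass
class MaskLossWeights:
    """λ weights masked entries in the reconstruction; γ_m mixes the mask
    prediction loss with the reconstruction loss."""

    lambda_: float = 0.7
    gamma_m: float = 0.65

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_ <= 1.0 and 0.0 <= self.gamma_m <= 1.0):
            raise ValueError("lambda_ and gamma_m must lie in [0, 1]")


@dataclass
class MaskedAEConfig:
    hidden_sizes: tuple[int, ...] = (256, 64)
    latent_dim: int = 32
    learning_rate: float = 1e-3
    epochs: int = 400
    mask_ratio: float = 0.3
    weights: MaskLossWeights = None  # type: ignore[assignment]
    use_mask_predictor: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = MaskLossWeights()


# ---------------------------------------------------------------------------
# losses (NumPy-level; the tape versions below share the same formulas)
# ---------------------------------------------------------------------------

def mask_loss(M: np.ndarray, M_pred: np.ndarray,
              positive_only: bool = False) -> float:
    """Mask-prediction cross entropy (mean).

    By default the full binary cross entropy
    −mean[M log M′ + (1−M) log(1−M′)]; `positive_only=True` gives the
    positive-term-only variant −mean[M log M′] (degenerate: minimized by
    M′ ≡ 1; kept for debugging).
    """
    if M.shape != M_pred.shape:
        raise ValueError("shapes must match")
    p = np.clip(M_pred, PRED_EPS, 1.0 - PRED_EPS)
    if positive_only:
        return float(-(M * np.log(p)).mean())
    return float(-(M * np.log(p) + (1.0 - M) * np.log(1.0 - p)).mean())


def weighted_mse(X: np.ndarray, X_rec: np.ndarray, M: np.ndarray,
                 lambda_: float) -> float:
    """Mask-weighted reconstruction MSE, W = λM + (1−λ)(1−M), mean over all
    matrix entries."""
    if not (X.shape == X_rec.shape == M.shape):
        raise ValueError("shapes must match")
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda_ must lie in [0, 1]")
    W = lambda_ * M + (1.0 - lambda_) * (1.0 - M)
    return float((W * (X - X_rec) ** 2).mean())


def total_mask_loss(Lm: float, Lrec: float, gamma_m: float) -> float:
    """γ_m·L_m + (1−γ_m)·L_rec."""
    if not 0.0 <= gamma_m <= 1.0:
        raise ValueError("gamma_m must lie in [0, 1]")
    return gamma_m * Lm + (1.0 - gamma_m) * Lrec


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MaskedAutoencoder:
    """Feed-forward masked autoencoder with optional mask predictor.

    With the predictor disabled, the decoder consumes Z alone and the mask
    loss term is dropped (the ablation without mask prediction).
    """

    def __init__(self, n_genes: int, cfg: MaskedAEConfig):
        self.cfg = cfg
        self.n_genes = n_genes
        rng = np.random.default_rng(cfg.seed)
        self.encoder = MLP([n_genes, *cfg.hidden_sizes, cfg.latent_dim], rng,
                           hidden_activation=relu)
        self.mask_predictor = Dense(cfg.latent_dim, n_genes, rng)
        dec_in = cfg.latent_dim + (n_genes if cfg.use_mask_predictor else 0)
        self.decoder = MLP([dec_in, *reversed(cfg.hidden_sizes), n_genes], rng,
                           hidden_activation=relu)
        self.history: list[dict[str, float]] = []

    @property
    def params(self) -> list[Tensor]:
        ps = self.encoder.params + self.decoder.params
        if self.cfg.use_mask_predictor:
            ps += self.mask_predictor.params
        return ps

    def save(self, path) -> None:
        """Serialize config and weights to a single .npz checkpoint."""
        import dataclasses
        import json
        arrays = {f"param_{i}": p.data
                  for i, p in enumerate(self.encoder.params
                                        + self.decoder.params
                                        + self.mask_predictor.params)}
        meta = dict(dataclasses.asdict(self.cfg), n_genes=self.n_genes)
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "MaskedAutoencoder":
        import json
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            n_genes = meta.pop("n_genes")
            meta["hidden_sizes"] = tuple(meta["hidden_sizes"])
            meta["weights"] = MaskLossWeights(**meta["weights"])
            model = cls(n_genes, MaskedAEConfig(**meta))
            all_params = (model.encoder.params + model.decoder.params
                          + model.mask_predictor.params)
            for i, p in enumerate(all_params):
                p.data = data[f"param_{i}"]
        return model

    # -- forward ----------------------------------------------------------
    def encode_t(self, x: np.ndarray | Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        return self.encoder(x)

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Embedding Z of (possibly corrupted) expression, cells × latent."""
        return self.encode_t(x).data

    def predict_mask_t(self, z: Tensor) -> Tensor:
        return self.mask_predictor(z).sigmoid().clip(PRED_EPS, 1.0 - PRED_EPS)

    def predict_mask(self, z: np.ndarray) -> np.ndarray:
        return self.predict_mask_t(Tensor(z)).data

    def decode_t(self, z: Tensor, m_pred: Tensor | None) -> Tensor:
        if self.cfg.use_mask_predictor:
            if m_pred is None:
                raise ValueError("mask prediction required by this decoder")
            return self.decoder(concat([z, m_pred], axis=1))
        return self.decoder(z)

    def decode(self, z: np.ndarray, m_pred: np.ndarray | None = None) -> np.ndarray:
        mp = None if m_pred is None else Tensor(m_pred)
        return self.decode_t(Tensor(z), mp).data

    # -- training loss on the tape ----------------------------------------
    def loss_t(self, x_target: np.ndarray, x_corrupted: np.ndarray,
               true_mask: np.ndarray) -> tuple[Tensor, float, float]:
        """Differentiable L_mask on one corruption draw.

        Returns (loss tensor, L_m value, L_rec value).
        """
        w = self.cfg.weights
        z = self.encode_t(x_corrupted)
        if self.cfg.use_mask_predictor:
            m_pred = self.predict_mask_t(z)
            lm = -(Tensor(true_mask) * m_pred.log()
                   + Tensor(1.0 - true_mask) * (1.0 - m_pred).log()).mean()
            rec = self.decode_t(z, m_pred)
        else:
            lm = Tensor(0.0)
            rec = self.decode_t(z, None)
        W = w.lambda_ * true_mask + (1.0 - w.lambda_) * (1.0 - true_mask)
        lrec = (Tensor(W) * (Tensor(x_target) - rec) ** 2).mean()
        if self.cfg.use_mask_predictor:
            loss = w.gamma_m * lm + (1.0 - w.gamma_m) * lrec
        else:
            loss = lrec
        return loss, float(lm.data), float(lrec.data)


def pretrain_masked_ae(X_log: np.ndarray, cfg: MaskedAEConfig | None = None
                       ) -> MaskedAutoencoder:
    """Pretrain on the log1p denoised matrix; a fresh within-gene shuffle and
    Bernoulli mask are drawn every epoch."""
    cfg = cfg or MaskedAEConfig()
    model = MaskedAutoencoder(X_log.shape[1], cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=cfg.learning_rate)
    for _ in range(cfg.epochs):
        batch = corrupt(X_log, cfg.mask_ratio, rng)
        loss, lm, lrec = model.loss_t(X_log, batch.corrupted, batch.true_mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.history.append({"loss": float(loss.data), "L_m": lm, "L_rec": lrec})
    return model
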