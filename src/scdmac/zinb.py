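"""Zero-inflated negative binomial likelihood and the denoising autoencoder.

The ZINB distribution mixes a point mass at zero (dropout probability π)
with a negative binomial of mean μ and dispersion θ:

    ZINB(x | π, μ, θ) = π·δ(x) + (1 − π)·NB(x | μ, θ)
    NB(x | μ, θ)      = Γ(x+θ)/(x! Γ(θ)) · (θ/(θ+μ))^θ · (μ/(μ+θ))^x

A feed-forward autoencoder parameterizes (Θ, M, Π) per matrix entry through
three output heads on a shared decoder trunk; training minimizes the mean
negative log-likelihood of the raw counts. The denoised matrix is the fitted
conditional mean M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import autograd as ag
from .autograd import Tensor
from .nn import MLP, Adam, Dense, elu
from .preprocessing import CountMatrix, normalize_library_size

# numerical floors: keep parameters strictly inside the valid domain so the
# log-likelihood stays finite
THETA_MIN, THETA_MAX = 1e-6, 1e6
MU_MIN, MU_MAX = 1e-6, 1e6
PI_EPS = 1e-6


# ---------------------------------------------------------------------------
# likelihood (plain NumPy — used for evaluation and as training target math)
# ---------------------------------------------------------------------------

def nb_log_pmf(x, mu, theta):
    """Log pmf of the negative binomial in (mean, dispersion) form.

    Vectorized; computed through log-gamma for stability.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(theta))):
        raise ValueError("mu and theta must be finite")
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    return (gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
            + theta * np.log(theta / (theta + mu))
            + x * np.log(mu / (mu + theta)))


def zinb_log_pmf(x, pi, mu, theta):
    """Log pmf of the zero-inflated negative binomial.

    At x = 0 the two mixture components are combined in log space
    (log-sum-exp); for x > 0 only the NB component contributes.
    """
    x = np.asarray(x, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    nb = nb_log_pmf(x, mu, theta)
    shape = np.broadcast_shapes(x.shape, pi.shape, nb.shape)
    x = np.broadcast_to(x, shape)
    nb = np.broadcast_to(nb, shape)
    pi_b = np.broadcast_to(pi, shape)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_b)
        log_1mpi = np.log1p(-pi_b)
    zero_case = np.logaddexp(log_pi, log_1mpi + nb)
    return np.where(x == 0, zero_case, log_1mpi + nb)


@dataclass
class ZINBParams:
    """Per-entry ZINB parameters (all cells × genes)."""

    mean: np.ndarray
    dispersion: np.ndarray
    dropout: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.mean.shape, self.dispersion.shape, self.dropout.shape}
        if len(shapes) != 1:
            raise ValueError("mean, dispersion and dropout shapes must match")
        if np.any(self.mean < 0):
            raise ValueError("mean must be non-negative")
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersion must be strictly positive")
        if np.any((self.dropout < 0) | (self.dropout > 1)):
            raise ValueError("dropout must lie in [0, 1]")


def zinb_loss(X, params: ZINBParams, exclude_mask: np.ndarray | None = None) -> float:
    """Mean negative ZINB log-likelihood over (non-excluded) entries.

    `exclude_mask` marks entries (1 = excluded) to leave out of the
    likelihood, e.g. deliberately corrupted positions.
    """
    x = X.values if isinstance(X, CountMatrix) else np.asarray(X, dtype=float)
    if x.shape != params.mean.shape:
        raise ValueError("data and parameter shapes do not match")
    mu = np.clip(params.mean, MU_MIN, MU_MAX)
    theta = np.clip(params.dispersion, THETA_MIN, THETA_MAX)
    pi = np.clip(params.dropout, PI_EPS, 1.0 - PI_EPS)
    ll = zinb_log_pmf(x, pi, mu, theta)
    if exclude_mask is not None:
        include = 1.0 - np.asarray(exclude_mask, dtype=float)
        return float(-(ll * include).sum() / include.sum())
    return float(-ll.mean())


# ---------------------------------------------------------------------------
# likelihood on the autodiff tape
# ---------------------------------------------------------------------------

def _zinb_nll_tape(x: np.ndarray, mu: Tensor, theta: Tensor, pi: Tensor,
                   include: np.ndarray | None = None) -> Tensor:
    """Mean negative ZINB log-likelihood as a differentiable scalar."""
    mu = mu.clip(MU_MIN, MU_MAX)
    theta = theta.clip(THETA_MIN, THETA_MAX)
    pi = pi.clip(PI_EPS, 1.0 - PI_EPS)
    nb = ((Tensor(x) + theta).lgamma() - theta.lgamma()
          - Tensor(gammaln(x + 1.0))
          + theta * ((theta / (theta + mu)).log())
          + Tensor(x) * ((mu / (mu + theta)).log()))
    one_m_pi = 1.0 - pi
    zero_case = (pi + one_m_pi * nb.exp()).log()
    ll = ag.where(x == 0, zero_case, one_m_pi.log() + nb)
    if include is None:
        return -ll.mean()
    inc = np.asarray(include, dtype=float)
    return -(ll * Tensor(inc)).sum() / float(inc.sum())


# ---------------------------------------------------------------------------
# denoising autoencoder
# ---------------------------------------------------------------------------

@dataclass
class DenoiserConfig:
    hidden_sizes: tuple[int, ...] = (256, 64)
    latent_dim: int = 32
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 256
    seed: int = 0
    patience: int = 20          # early stop after this many non-improving epochs
    min_rel_improvement: float = 1e-4
    validation_fraction: float = 0.1  # held-out cells for early stopping
    mean_with_dropout: bool = False  # denoise() returns (1−Π)⊙M instead of M

    def __post_init__(self) -> None:
        if (self.latent_dim <= 0 or self.learning_rate <= 0
                or self.epochs <= 0 or self.batch_size <= 0
                or any(h <= 0 for h in self.hidden_sizes)):
            raise ValueError("all DenoiserConfig sizes must be positive")


class ZINBDenoiser:
    """Encoder–decoder with three ZINB parameter heads.

    The encoder consumes log1p depth-normalized expression; the likelihood is
    evaluated on the raw counts, with the mean head scaled per cell by the
    size factor: M = diag(s_i)·exp(W_μ D), Θ = exp(W_θ D), Π = sigmoid(W_π D).
    """

    def __init__(self, n_genes: int, cfg: DenoiserConfig):
        self.cfg = cfg
        self.n_genes = n_genes
        rng = np.random.default_rng(cfg.seed)
        enc_sizes = [n_genes, *cfg.hidden_sizes, cfg.latent_dim]
        dec_sizes = [cfg.latent_dim, *reversed(cfg.hidden_sizes)]
        self.encoder = MLP(enc_sizes, rng, hidden_activation=elu,
                           out_activation=elu)
        self.decoder_trunk = MLP(dec_sizes, rng, hidden_activation=elu,
                                 out_activation=elu)
        self.head_theta = Dense(dec_sizes[-1], n_genes, rng)
        self.head_mu = Dense(dec_sizes[-1], n_genes, rng)
        self.head_pi = Dense(dec_sizes[-1], n_genes, rng)
        self.trained = False
        self.history: list[float] = []

    @property
    def params(self) -> list[Tensor]:
        return (self.encoder.params + self.decoder_trunk.params
                + self.head_theta.params + self.head_mu.params
                + self.head_pi.params)

    # -- forward ----------------------------------------------------------
    def _forward(self, x_enc: np.ndarray, size_factors: np.ndarray
                 ) -> tuple[Tensor, Tensor, Tensor]:
        z = self.encoder(Tensor(x_enc))
        d = self.decoder_trunk(z)
        theta = self.head_theta(d).clip(-30.0, 30.0).exp()
        mu = self.head_mu(d).clip(-30.0, 30.0).exp() * Tensor(size_factors[:, None])
        pi = self.head_pi(d).sigmoid()
        return mu, theta, pi

    def predict_params(self, X: CountMatrix) -> ZINBParams:
        x_enc, sf, _ = self._prepare(X)
        mu, theta, pi = self._forward(x_enc, sf)
        return ZINBParams(mean=mu.data, dispersion=theta.data, dropout=pi.data)

    def save(self, path) -> None:
        """Serialize config and weights to a single .npz checkpoint."""
        import dataclasses
        import json
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params)}
        meta = dict(dataclasses.asdict(self.cfg), n_genes=self.n_genes,
                    trained=self.trained)
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ZINBDenoiser":
        import json
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            n_genes = meta.pop("n_genes")
            trained = meta.pop("trained")
            meta["hidden_sizes"] = tuple(meta["hidden_sizes"])
            model = cls(n_genes, DenoiserConfig(**meta))
            for i, p in enumerate(model.params):
                p.data = data[f"param_{i}"]
        model.trained = trained
        return model

    @staticmethod
    def _prepare(X: CountMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        norm = normalize_library_size(X)
        if norm.values.shape[0] != X.n_cells:
            raise ValueError("count matrix contains all-zero cells; "
                             "run preprocessing first")
        return np.log1p(norm.values), norm.size_factors, X.values


def parameter_heads(D: np.ndarray, W_theta: np.ndarray, W_mu: np.ndarray,
                    W_pi: np.ndarray, size_factors: np.ndarray) -> ZINBParams:
    """Functional form of the three output heads, exposed for testing:
    Θ = exp(D·W_θ), M = diag(s)·exp(D·W_μ), Π = sigmoid(D·W_π)."""
    theta = np.exp(D @ W_theta)
    mu = size_factors[:, None] * np.exp(D @ W_mu)
    pi = 1.0 / (1.0 + np.exp(-(D @ W_pi)))
    return ZINBParams(mean=mu, dispersion=theta, dropout=pi)


def train_denoiser(X: CountMatrix, cfg: DenoiserConfig | None = None,
                   exclude_mask: np.ndarray | None = None) -> ZINBDenoiser:
    """Fit the denoising autoencoder by minibatch Adam on the ZINB NLL.

    Entries flagged in `exclude_mask` (1 = excluded) do not contribute to the
    likelihood. Training stops early when the epoch loss has not improved
    (relatively) for `cfg.patience` epochs.
    """
    cfg = cfg or DenoiserConfig()
    model = ZINBDenoiser(X.n_genes, cfg)
    x_enc, sf, raw = ZINBDenoiser._prepare(X)
    n = raw.shape[0]
    include = None if exclude_mask is None else 1.0 - np.asarray(exclude_mask, float)
    rng = np.random.default_rng(cfg.seed + 1)
    perm = rng.permutation(n)
    n_val = int(round(cfg.validation_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training cells")
    opt = Adam(model.params, lr=cfg.learning_rate)
    best, stale = np.inf, 0
    best_params = [p.data.copy() for p in model.params]

    def monitored_loss() -> float:
        idx = val_idx if n_val else train_idx
        mu, theta, pi = model._forward(x_enc[idx], sf[idx])
        inc = None if include is None else include[idx]
        return float(_zinb_nll_tape(raw[idx], mu, theta, pi, include=inc).data)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(train_idx), cfg.batch_size):
            idx = train_idx[order[start:start + cfg.batch_size]]
            mu, theta, pi = model._forward(x_enc[idx], sf[idx])
            inc = None if include is None else include[idx]
            loss = _zinb_nll_tape(raw[idx], mu, theta, pi, include=inc)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"ZINB training loss became non-finite at epoch {epoch}; "
                    "check input scale and learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        model.history.append(epoch_loss / len(train_idx))
        # early stopping monitors held-out cells so the mean head stops
        # before it starts chasing sampling noise in individual counts
        mon = monitored_loss()
        if mon < best * (1.0 - cfg.min_rel_improvement):
            best, stale = mon, 0
            best_params = [p.data.copy() for p in model.params]
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    for p, bp in zip(model.params, best_params):
        p.data = bp
    model.trained = True
    return model


def denoise(model: ZINBDenoiser, X: CountMatrix,
            size_scaled: bool = False) -> np.ndarray:
    """Denoised matrix X_z: the fitted ZINB mean (optionally (1−Π)⊙mean).

    By default the per-cell size factors are divided out, returning the
    depth-normalized conditional mean exp(W_μ D) — sequencing-depth
    variation is a technical nuisance downstream representation learning
    should not see. `size_scaled=True` returns the library-scale mean
    diag(s_i)·exp(W_μ D) that parameterizes the likelihood, for comparison
    against raw counts.
    """
    if not model.trained:
        raise RuntimeError("denoiser has not been trained")
    params = model.predict_params(X)
    mean = params.mean
    if not size_scaled:
        sf = normalize_library_size(X).size_factors
        mean = mean / sf[:, None]
    if model.cfg.mean_with_dropout:
        return (1.0 - params.dropout) * mean
    return mean
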