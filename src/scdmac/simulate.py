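"""Seeded generator of clustered zero-inflated negative binomial counts.

The generator emulates the data properties the clustering model targets:
cluster-specific mean profiles (a fraction of genes differentially
expressed per cluster), gene-wise negative binomial dispersion, cell-specific
library-size variation (log-normal), and mean-dependent dropout — lowly
expressed entries are zeroed with higher probability through a logistic
curve on log mean, the mechanism the ZINB denoiser assumes. Ground-truth
labels, per-entry means and dropout probabilities are returned alongside
the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocessing import CountMatrix


@dataclass
class SimulationConfig:
    n_cells: int = 600
    n_genes: int = 200
    n_clusters: int = 3
    de_gene_fraction: float = 0.2     # genes differentially expressed per cluster
    log_fc: float = 1.0               # mean |log-fold-change| of DE genes
    base_mean_range: tuple[float, float] = (0.5, 10.0)
    dispersion: float = 2.0           # NB dispersion θ (shared across genes)
    dropout_midpoint: float = 0.0     # logistic midpoint on log-mean scale
    dropout_steepness: float = 1.0    # 0 disables mean-dependent dropout
    libsize_sigma: float = 0.25       # log-normal spread of library factors
    cluster_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_clusters) <= 0:
            raise ValueError("n_cells, n_genes, n_clusters must be positive")
        if not 0.0 <= self.de_gene_fraction <= 1.0:
            raise ValueError("de_gene_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.base_mean_range[0] <= 0 or self.base_mean_range[1] < self.base_mean_range[0]:
            raise ValueError("base_mean_range must be a positive interval")
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions, dtype=float)
            if len(p) != self.n_clusters or not np.isclose(p.sum(), 1.0):
                raise ValueError("cluster_proportions must be a simplex vector "
                                 "of length n_clusters")


def simulate(cfg: SimulationConfig
             ) -> tuple[CountMatrix, np.ndarray, np.ndarray, np.ndarray]:
    """Draw one clustered ZINB count matrix.

    Returns (counts, labels, true_means, true_dropout) where `true_means`
    includes the per-cell library factor (the quantity a size-factor-aware
    mean head estimates) and `true_dropout` the per-entry zeroing
    probability.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g, C = cfg.n_cells, cfg.n_genes, cfg.n_clusters

    lo, hi = cfg.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=g))

    # cluster mean profiles: each cluster up-/down-regulates its own DE set
    n_de = int(round(cfg.de_gene_fraction * g))
    cluster_means = np.tile(base, (C, 1))
    for k in range(C):
        de = rng.choice(g, size=n_de, replace=False)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        cluster_means[k, de] *= np.exp(sign * cfg.log_fc)

    props = (np.full(C, 1.0 / C) if cfg.cluster_proportions is None
             else np.asarray(cfg.cluster_proportions, dtype=float))
    labels = rng.choice(C, size=n, p=props)

    lib = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=n))
    mu = cluster_means[labels] * lib[:, None]

    theta = cfg.dispersion
    # NB draw in gamma-Poisson form
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(float)

    if cfg.dropout_steepness > 0:
        logmu = np.log(np.clip(mu, 1e-12, None))
        pi = 1.0 / (1.0 + np.exp(cfg.dropout_steepness * (logmu - cfg.dropout_midpoint)))
    else:
        pi = np.zeros_like(mu)
    counts[rng.random(mu.shape) < pi] = 0.0

    X = CountMatrix(values=counts,
                    cell_ids=[f"cell_{i}" for i in range(n)],
                    gene_ids=[f"gene_{j}" for j in range(g)])
    return X, labels, mu, pi


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _fit_and_score(X: CountMatrix, labels: np.ndarray, n_clusters: int,
                   fit_config) -> tuple[float, float]:
    from .clustering import fit
    from .metrics import adjusted_rand_index, normalized_mutual_information
    res = fit(X, n_clusters, fit_config)
    return (adjusted_rand_index(labels, res.labels),
            normalized_mutual_information(labels, res.labels))


def _variant_configs(base_config) -> dict[str, "object"]:
    """Full model plus the three ablations: -Z drops the denoiser, -W forces
    λ = 0.5 (no reconstruction weighting), -P removes the mask predictor."""
    import copy
    variants = {}
    full = copy.deepcopy(base_config)
    variants["scDMAC"] = full
    no_z = copy.deepcopy(base_config)
    no_z.use_denoiser = False
    variants["scDMAC-Z"] = no_z
    no_w = copy.deepcopy(base_config)
    no_w.masked_ae.weights.lambda_ = 0.5
    variants["scDMAC-W"] = no_w
    no_p = copy.deepcopy(base_config)
    no_p.masked_ae.use_mask_predictor = False
    variants["scDMAC-P"] = no_p
    return variants


def ablation_suite(cfg: SimulationConfig, fit_config=None,
                   seeds: tuple[int, ...] = (0, 1, 2, 3, 4)) -> pd.DataFrame:
    """Run the full model and its three ablations on shared simulations.

    Returns a table with one (method, metric) row per variant — ARI and NMI —
    and one column per seed plus their mean.
    """
    from .clustering import ScDMACConfig
    fit_config = fit_config or ScDMACConfig()
    rows: dict[tuple[str, str], dict[str, float]] = {}
    for seed in seeds:
        sim_cfg = replace(cfg, seed=seed)
        X, labels, _, _ = simulate(sim_cfg)
        for name, variant in _variant_configs(fit_config).items():
            ari, nmi = _fit_and_score(X, labels, cfg.n_clusters,
                                      variant.derive(seed))
            rows.setdefault((name, "ARI"), {})[f"seed_{seed}"] = ari
            rows.setdefault((name, "NMI"), {})[f"seed_{seed}"] = nmi
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["method", "metric"])
    df["mean"] = df.mean(axis=1)
    return df


def sweep(parameter: str, values, cfg: SimulationConfig, fit_config=None,
          seeds: tuple[int, ...] = (0, 1, 2, 3, 4)) -> pd.DataFrame:
    """Hyperparameter sweep over `mask_ratio`, `lambda_` or `gamma_m`.

    Returns a long-format table with one row per (value, seed) and ARI/NMI
    columns.
    """
    import copy
    from .clustering import ScDMACConfig
    if parameter not in {"mask_ratio", "lambda_", "gamma_m"}:
        raise ValueError(f"unknown sweep parameter: {parameter!r}")
    fit_config = fit_config or ScDMACConfig()
    records = []
    for seed in seeds:
        sim_cfg = replace(cfg, seed=seed)
        X, labels, _, _ = simulate(sim_cfg)
        for value in values:
            variant = copy.deepcopy(fit_config)
            if parameter == "mask_ratio":
                variant.masked_ae.mask_ratio = float(value)
            elif parameter == "lambda_":
                variant.masked_ae.weights.lambda_ = float(value)
            else:
                variant.masked_ae.weights.gamma_m = float(value)
            ari, nmi = _fit_and_score(X, labels, cfg.n_clusters,
                                      variant.derive(seed))
            records.append({"parameter": parameter, "value": float(value),
                            "seed": seed, "ari": ari, "nmi": nmi})
    return pd.DataFrame.from_records(records)
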