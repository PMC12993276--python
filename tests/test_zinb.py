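"""ZINB likelihood correctness and denoiser training behavior."""

import math

import numpy as np
import pytest
from scipy import stats

from scdmac import (CountMatrix, DenoiserConfig, SimulationConfig, ZINBParams,
                    denoise, nb_log_pmf, simulate, train_denoiser,
                    zinb_log_pmf, zinb_loss)
from scdmac.autograd import Tensor
from scdmac.zinb import _zinb_nll_tape, parameter_heads


def scalar_zinb_oracle(x, pi, mu, theta):
    """Independent scalar evaluation of the mixture pmf via math.lgamma."""
    log_nb = (math.lgamma(x + theta) - math.lgamma(x + 1) - math.lgamma(theta)
              + theta * math.log(theta / (theta + mu))
              + x * math.log(mu / (mu + theta)))
    nb = math.exp(log_nb)
    return math.log(pi * (1.0 if x == 0 else 0.0) + (1.0 - pi) * nb)


class TestNBLogPmf:
    def test_zero_count_closed_form(self):
        # at x=0 the pmf collapses to θ·log(θ/(θ+μ))
        assert np.isclose(nb_log_pmf(0, 2.0, 1.0), math.log(1 / 3), atol=1e-9)

    def test_poisson_limit(self):
        xs = np.arange(11)
        nb = nb_log_pmf(xs, 3.0, 1e8)
        pois = stats.poisson.logpmf(xs, 3.0)
        assert np.allclose(nb, pois, atol=1e-5)

    @pytest.mark.parametrize("x,mu,theta", [(4, 2.5, 0.7), (0, 0.3, 5.0),
                                            (17, 8.1, 2.2), (2, 1.0, 1.0)])
    def test_matches_independent_scalar_oracle(self, x, mu, theta):
        assert np.isclose(nb_log_pmf(x, mu, theta),
                          scalar_zinb_oracle(x, 0.0, mu, theta), atol=1e-8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            nb_log_pmf(1, -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1, np.inf, 1.0)


class TestZINBLogPmf:
    def test_certain_zero(self):
        assert zinb_log_pmf(0, 1.0, 2.0, 1.0) == pytest.approx(0.0)

    def test_reduces_to_nb_at_pi_zero(self):
        xs = np.arange(8)
        assert np.allclose(zinb_log_pmf(xs, 0.0, 2.5, 0.9),
                           nb_log_pmf(xs, 2.5, 0.9))

    def test_mixture_at_zero(self):
        # log(0.5 + 0.5·(1/3)) = log(2/3)
        assert np.isclose(zinb_log_pmf(0, 0.5, 2.0, 1.0),
                          math.log(2 / 3), atol=1e-9)

    @pytest.mark.parametrize("pi", [0.0, 0.3, 0.7, 1.0])
    @pytest.mark.parametrize("mu,theta", [(0.5, 0.2), (5.0, 2.0), (20.0, 10.0)])
    def test_pmf_sums_to_one(self, pi, mu, theta):
        xs = np.arange(0, int(mu + 60 * math.sqrt(mu + mu ** 2 / theta)) + 60)
        total = np.exp(zinb_log_pmf(xs, pi, mu, theta)).sum()
        assert np.isclose(total, 1.0, atol=1e-6)

    def test_monotone_in_pi_at_zero_and_continuous(self):
        pis = np.linspace(0, 1, 21)
        vals = zinb_log_pmf(0, pis, 4.0, 2.0)
        assert np.all(np.diff(vals) > 0)
        assert np.isclose(zinb_log_pmf(0, 1e-12, 4.0, 2.0),
                          nb_log_pmf(0, 4.0, 2.0), atol=1e-9)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            zinb_log_pmf(0, 1.2, 1.0, 1.0)


class TestParameterHeads:
    def test_zero_preactivation_gives_unit_params(self):
        D = np.zeros((3, 4))
        W = np.zeros((4, 5))
        p = parameter_heads(D, W, W, W, np.ones(3))
        assert np.all(p.dispersion == 1.0)
        assert np.all(p.mean == 1.0)
        assert np.all(p.dropout == 0.5)

    def test_size_factor_scales_mean_only(self, rng):
        D = rng.normal(size=(3, 4))
        W = rng.normal(size=(4, 5)) * 0.1
        sf = np.ones(3)
        base = parameter_heads(D, W, W, W, sf)
        sf2 = sf.copy()
        sf2[1] = 2.0
        scaled = parameter_heads(D, W, W, W, sf2)
        assert np.allclose(scaled.mean[1], 2.0 * base.mean[1])
        assert np.allclose(scaled.mean[0], base.mean[0])
        assert np.allclose(scaled.dispersion, base.dispersion)
        assert np.allclose(scaled.dropout, base.dropout)

    def test_invariants_hold_for_extreme_preactivations(self, rng):
        D = rng.uniform(-20, 20, size=(6, 3))
        W = np.eye(3)
        p = parameter_heads(D, W, W, W, np.ones(6))
        assert np.all(p.mean >= 0)
        assert np.all(p.dispersion > 0)
        assert np.all((p.dropout >= 0) & (p.dropout <= 1))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ZINBParams(mean=np.ones((2, 2)), dispersion=np.zeros((2, 2)),
                       dropout=np.zeros((2, 2)))


class TestZINBLoss:
    def test_certain_zeros_give_zero_loss(self):
        X = np.zeros((4, 3))
        params = ZINBParams(mean=np.ones((4, 3)), dispersion=np.ones((4, 3)),
                            dropout=np.full((4, 3), 1.0))
        assert zinb_loss(X, params) < 1e-5

    def test_loss_nonnegative(self, rng):
        X = rng.poisson(3.0, size=(5, 4)).astype(float)
        params = ZINBParams(mean=rng.uniform(0.5, 5, (5, 4)),
                            dispersion=rng.uniform(0.5, 5, (5, 4)),
                            dropout=rng.uniform(0, 0.5, (5, 4)))
        assert zinb_loss(X, params) >= 0

    def test_decomposes_into_scalar_calls(self):
        X = np.array([[0, 3], [1, 0], [7, 2]], dtype=float)
        mu = np.array([[1.0, 2.0], [0.5, 3.0], [6.0, 1.5]])
        theta = np.array([[0.7, 1.2], [2.0, 0.4], [1.0, 3.0]])
        pi = np.array([[0.1, 0.2], [0.3, 0.05], [0.0, 0.5]])
        params = ZINBParams(mean=mu, dispersion=theta, dropout=pi)
        oracle = -np.mean([scalar_zinb_oracle(X[i, j], pi[i, j], mu[i, j],
                                              theta[i, j])
                           for i in range(3) for j in range(2)])
        assert np.isclose(zinb_loss(X, params), oracle, atol=1e-8)

    def test_shape_mismatch_rejected(self):
        params = ZINBParams(mean=np.ones((2, 2)), dispersion=np.ones((2, 2)),
                            dropout=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            zinb_loss(np.ones((3, 2)), params)

    def test_excluded_entries_do_not_contribute(self):
        X = np.array([[0.0, 5.0], [2.0, 1.0]])
        params = ZINBParams(mean=np.full((2, 2), 2.0),
                            dispersion=np.ones((2, 2)),
                            dropout=np.full((2, 2), 0.1))
        mask = np.array([[0, 1], [0, 0]])  # exclude the corrupted entry
        expected = -np.mean([zinb_log_pmf(X[i, j], 0.1, 2.0, 1.0)
                             for i, j in [(0, 0), (1, 0), (1, 1)]])
        assert np.isclose(zinb_loss(X, params, exclude_mask=mask), expected)

    def test_tape_gradient_matches_finite_difference(self):
        x = np.array([[0.0, 4.0], [2.0, 0.0]])
        vals = {"mu": np.array([[1.5, 3.0], [2.0, 0.8]]),
                "theta": np.array([[0.9, 2.0], [1.1, 0.6]]),
                "pi_logit": np.array([[-1.0, 0.5], [0.2, -0.3]])}

        def loss_from(v):
            mu = Tensor(v["mu"], requires_grad=True)
            theta = Tensor(v["theta"], requires_grad=True)
            pil = Tensor(v["pi_logit"], requires_grad=True)
            return (mu, theta, pil,
                    _zinb_nll_tape(x, mu, theta, pil.sigmoid()))

        mu_t, th_t, pi_t, loss = loss_from(vals)
        loss.backward()
        eps = 1e-6
        for name, tensor in (("mu", mu_t), ("theta", th_t), ("pi_logit", pi_t)):
            for i in range(2):
                for j in range(2):
                    up = {k: v.copy() for k, v in vals.items()}
                    dn = {k: v.copy() for k, v in vals.items()}
                    up[name][i, j] += eps
                    dn[name][i, j] -= eps
                    fd = (float(loss_from(up)[3].data)
                          - float(loss_from(dn)[3].data)) / (2 * eps)
                    assert np.isclose(tensor.grad[i, j], fd, atol=1e-4)


@pytest.fixture(scope="module")
def trained():
    cfg = SimulationConfig(n_cells=200, n_genes=40, n_clusters=2, seed=3)
    X, _, mu, _ = simulate(cfg)
    dcfg = DenoiserConfig(hidden_sizes=(64,), latent_dim=16, epochs=60,
                          patience=15, seed=5)
    return X, mu, train_denoiser(X, dcfg), dcfg


class TestTrainDenoiser:

    def test_loss_decreases(self, trained):
        _, _, model, _ = trained
        assert model.history[-1] < model.history[0]

    def test_same_seed_same_final_loss(self, trained):
        X, _, model, dcfg = trained
        again = train_denoiser(X, dcfg)
        assert abs(model.history[-1] - again.history[-1]) < 1e-6

    def test_denoised_shape_and_nonnegativity(self, trained):
        X, _, model, _ = trained
        Xz = denoise(model, X)
        assert Xz.shape == X.values.shape
        assert np.all(Xz >= 0)

    def test_untrained_model_rejected(self, trained):
        X, _, model, dcfg = trained
        from scdmac.zinb import ZINBDenoiser
        fresh = ZINBDenoiser(X.n_genes, dcfg)
        with pytest.raises(RuntimeError):
            denoise(fresh, X)

    def test_denoised_closer_to_true_means_than_raw(self, trained):
        X, mu, model, _ = trained
        Xz = denoise(model, X, size_scaled=True)
        assert ((Xz - mu) ** 2).mean() < ((X.values - mu) ** 2).mean()


class TestCheckpoint:
    def test_denoiser_roundtrip(self, tmp_path, trained):
        X, _, model, _ = trained
        path = tmp_path / "denoiser.npz"
        model.save(path)
        loaded = type(model).load(path)
        assert loaded.trained
        assert np.allclose(denoise(loaded, X), denoise(model, X))
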