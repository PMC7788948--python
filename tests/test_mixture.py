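import numpy as np
import pytest
from scipy.stats import binom, norm

from scc import (
    DropoutMixture,
    EMConfig,
    MixtureParams,
    em_estep,
    em_init,
    em_mstep,
    fit_mixture,
    mixture_density,
)
from scc.mixture import batch_fit


def params(l1=1 / 3, l2=1 / 3, l3=1 / 3, mu=5.0, sigma=1.0, N=5, p=0.1):
    return MixtureParams(l1, l2, l3, mu, sigma, N, p)


class TestMixtureDensity:
    def test_closed_form_at_zero(self):
        # (phi(0;5,1) + 0.9^5 + 1) / 3
        expected = (norm.pdf(0, 5, 1) + 0.9**5 + 1.0) / 3.0
        assert mixture_density(0.0, params()) == pytest.approx(expected, abs=1e-9)

    def test_point_mass_only_at_zero(self):
        p_only_zero = params(0.0, 0.0, 1.0)
        assert mixture_density(0.0, p_only_zero) == pytest.approx(1.0)
        assert mixture_density(0.5, p_only_zero) == pytest.approx(0.0)

    def test_degenerate_normal_mixture(self):
        pure = params(1.0, 0.0, 0.0)
        for x in [0.0, 3.3, 7.0]:
            assert mixture_density(x, pure) == pytest.approx(norm.pdf(x, 5, 1), abs=1e-12)

    def test_binomial_support(self):
        pure = params(0.0, 1.0, 0.0, N=5, p=0.3)
        assert mixture_density(7.0, pure) == 0.0  # round(7) > N
        assert mixture_density(3.0, pure) == pytest.approx(binom.pmf(3, 5, 0.3), abs=1e-12)

    def test_invalid_weights_rejected(self):
        bad = MixtureParams(0.5, 0.5, 0.5, 5.0, 1.0, 5, 0.1)
        with pytest.raises(ValueError, match="sum to 1"):
            mixture_density(0.0, bad)


class TestEMInit:
    def test_all_zero_values(self):
        cfg = EMConfig()
        p0 = em_init([0.0, 0.0, 0.0, 0.0], cfg)
        assert p0.mu == 0.0
        assert p0.sigma == cfg.sigma_floor
        assert p0.N == 1 and p0.p == 0.1
        assert np.allclose(p0.weights, 1 / 3)

    def test_nonzero_mean_drives_N(self):
        p0 = em_init([0.0, 0.0, 1.0, 1.0])
        assert p0.mu == pytest.approx(0.5)
        assert p0.N == 9  # clamp(round(1 / 0.1), 1, 9)

    def test_lambdas_equal_thirds(self):
        p0 = em_init([0.0, 2.0, 5.0])
        assert np.allclose(p0.weights, [1 / 3, 1 / 3, 1 / 3])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            em_init([1.0])


class TestEStep:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(3.0, size=12).astype(float)
        resp = em_estep(values, params())
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(resp >= 0) and np.all(resp <= 1)

    def test_value_outside_binomial_support_goes_normal(self):
        resp = em_estep([7.0, 7.0], params(mu=7.0, sigma=1.0, N=5))
        assert resp[0, 0] > 0.999  # only the Normal has positive likelihood

    def test_zero_with_heavy_zero_weight(self):
        pr = params(0.005, 0.005, 0.99)
        resp = em_estep([0.0, 0.0], pr)
        expected = 0.99 / (0.005 * norm.pdf(0, 5, 1) + 0.005 * 0.9**5 + 0.99)
        assert resp[0, 2] == pytest.approx(expected, abs=1e-6)

    def test_nonzero_value_gets_no_zero_mass(self):
        resp = em_estep([4.0, 5.0], params())
        assert resp[:, 2].max() < 1e-12


class TestMStep:
    def test_all_mass_on_normal_constant_values(self):
        cfg = EMConfig()
        values = np.array([10.0, 10.0, 10.0])
        resp = np.zeros((3, 3))
        resp[:, 0] = 1.0
        out = em_mstep(values, resp, params(), cfg)
        assert out.weights == pytest.approx([1.0, 0.0, 0.0])
        assert out.mu == pytest.approx(10.0)
        assert out.sigma == cfg.sigma_floor  # Dev of constants is 0, floored

    def test_uniform_responsibilities_arithmetic(self):
        values = np.array([0.0, 3.0])
        resp = np.full((2, 3), 1 / 3)
        out = em_mstep(values, resp, params())
        assert np.allclose(out.weights, 1 / 3)
        assert out.mu == pytest.approx(1.5)  # Mean_1 = P2/P1 = (0+3)/2

    def test_weights_always_sum_to_one(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(2.0, size=8).astype(float)
        resp = rng.dirichlet(np.ones(3), size=8)
        out = em_mstep(values, resp, params())
        assert out.lambda1 + out.lambda2 + out.lambda3 == pytest.approx(1.0, abs=1e-12)

    def test_empty_component_carries_over(self):
        old = params(mu=42.0, sigma=2.0, N=7, p=0.3)
        values = np.array([0.0, 0.0, 0.0])
        resp = np.zeros((3, 3))
        resp[:, 2] = 1.0  # all mass on the zero component
        out = em_mstep(values, resp, old)
        assert out.mu == 42.0 and out.sigma == 2.0
        assert out.N == 7 and out.p == 0.3


class TestEMOracle:
    """One E+M sweep must match a brute-force transcription of the
    component-moment formulas (P1, P2, P3, Mean_j, Dev_j)."""

    @staticmethod
    def _brute_force_em_step(values, pr, cfg):
        n = len(values)
        unnorm = np.empty((n, 3))
        for i, x in enumerate(values):
            unnorm[i, 0] = pr.lambda1 * norm.pdf(x, pr.mu, pr.sigma) + cfg.component_eps
            k = round(x)
            b = binom.pmf(k, pr.N, pr.p) if 0 <= k <= pr.N else 0.0
            unnorm[i, 1] = pr.lambda2 * b + cfg.component_eps
            unnorm[i, 2] = pr.lambda3 * (1.0 if abs(x) <= cfg.zero_tol else 0.0) + cfg.component_eps
        resp = unnorm / unnorm.sum(axis=1, keepdims=True)
        P1 = resp.sum(axis=0)
        lam = P1 / n
        P2 = np.array([(resp[:, j] * values).sum() for j in range(3)])
        mean = np.where(P1 > 0, P2 / np.maximum(P1, cfg.weight_eps), 0.0)
        P3 = np.array([(resp[:, j] * (values - mean[j]) ** 2).sum() for j in range(3)])
        dev = np.sqrt(P3 / np.maximum(P1, cfg.weight_eps))
        # Normal component
        mu, sigma = pr.mu, pr.sigma
        if P1[0] >= cfg.weight_eps:
            mu = mean[0]
            sigma = max(dev[0], cfg.sigma_floor)
        # Binomial component (method of moments)
        N, p = pr.N, pr.p
        if P1[1] >= cfg.weight_eps and mean[1] > 0:
            p = np.clip(1.0 - dev[1] ** 2 / mean[1], cfg.p_floor, 1 - cfg.p_floor)
            N = int(np.clip(np.rint(mean[1] / p), 1, 9))
            p = np.clip(mean[1] / N, cfg.p_floor, 1 - cfg.p_floor)
        return resp, lam, mu, sigma, N, p

    def test_one_iteration_matches_brute_force(self):
        cfg = EMConfig()
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 7)
            values = np.where(
                rng.random(n) < 0.4, 0.0, rng.poisson(rng.uniform(0.5, 8.0), n)
            ).astype(float)
            pr = em_init(values, cfg)
            resp = em_estep(values, pr, cfg)
            new = em_mstep(values, resp, pr, cfg)
            bresp, blam, bmu, bsigma, bN, bp = self._brute_force_em_step(values, pr, cfg)
            np.testing.assert_allclose(resp, bresp, atol=1e-9)
            np.testing.assert_allclose(new.weights, blam, atol=1e-9)
            assert new.mu == pytest.approx(bmu, abs=1e-9)
            assert new.sigma == pytest.approx(bsigma, abs=1e-9)
            assert new.N == bN
            assert new.p == pytest.approx(bp, abs=1e-9)


class TestFitMixture:
    def test_no_zeros_kills_zero_component(self):
        pr, _, _ = fit_mixture(np.full(10, 10.0))
        assert pr.lambda3 <= 0.01

    def test_normal_recovery(self):
        hits = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            values = np.abs(rng.normal(20.0, 2.0, size=20))
            pr, _, _ = fit_mixture(values)
            hits.append(18.0 <= pr.mu <= 22.0 and pr.lambda1 >= 0.8)
        assert np.median(hits) == 1.0

    def test_zero_inflated_recovery(self):
        lam3 = []
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            nonzero = []
            while len(nonzero) < 10:
                x = rng.binomial(5, 0.5)
                if x > 0:
                    nonzero.append(float(x))
            values = np.array([0.0] * 10 + nonzero)
            pr, _, _ = fit_mixture(values)
            lam3.append(pr.lambda3)
        assert np.median(lam3) >= 0.3

    def test_weight_conservation_every_iteration(self):
        rng = np.random.default_rng(3)
        values = np.where(rng.random(15) < 0.5, 0.0, rng.poisson(4.0, 15)).astype(float)
        cfg = EMConfig(max_iter=1)
        pr = em_init(values, cfg)
        for _ in range(20):
            resp = em_estep(values, pr, cfg)
            pr = em_mstep(values, resp, pr, cfg)
            assert pr.lambda1 + pr.lambda2 + pr.lambda3 == pytest.approx(1.0, abs=1e-9)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(8)
        Z = np.where(rng.random((6, 12)) < 0.5, 0.0, rng.poisson(3.0, (6, 12))).astype(float)
        bp, bni, bcv = batch_fit(Z)
        for g in range(6):
            pr, ni, cv = fit_mixture(Z[g])
            assert np.allclose(bp.row(g).weights, pr.weights, atol=1e-12)
            assert bp.row(g).mu == pytest.approx(pr.mu, abs=1e-12)
            assert bni[g] == ni and bcv[g] == cv


class TestModelResults:
    def test_fit_returns_results_with_summary(self):
        res = DropoutMixture([0, 0, 1, 2, 0, 1, 0, 3]).fit()
        text = res.summary()
        assert "lambda1" in text and "N*p" in text
        assert res.dominant_component in (0, 1, 2)
        assert 0 < res.imputed_value < 9
        np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError):
            DropoutMixture([-1.0, 2.0])

    def test_convergence_flag_and_iterations(self):
        res = DropoutMixture(np.full(10, 5.0)).fit()
        assert res.converged and res.n_iter <= 100
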