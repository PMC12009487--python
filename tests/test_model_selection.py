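"""Criterion battery: conjugate-case oracles, degenerate fits, uniformity test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from stsir import model_selection as ms
from stsir.st_models import ModelSpec, PosteriorFit
from stsir.standardization import SIRMatrix


def make_fit(theta_draws, observed, expected, converged=True):
    """Fabricate a PosteriorFit from raw relative-risk draws."""
    theta_draws = np.asarray(theta_draws, dtype=float)
    S = theta_draws.shape[0]
    observed = np.asarray(observed)
    expected = np.asarray(expected, dtype=float)
    lam = expected.ravel()[None, :] * theta_draws.reshape(S, -1)
    ll = stats.poisson.logpmf(observed.ravel()[None, :], lam)
    n, T = observed.shape
    return PosteriorFit(ModelSpec(), [f"r{i}" for i in range(n)],
                        list(range(2000, 2000 + T)), observed, expected, {},
                        theta_draws.reshape(S, n, T), ll,
                        pd.DataFrame({"param": [], "rhat": [], "ess": []}), converged)


@pytest.fixture(scope="module")
def conjugate_case():
    """Single cell y ~ Poisson(E * theta), theta ~ Gamma(a, b): the posterior,
    and every criterion, has a closed or quadrature form."""
    a, b, E, y = 2.0, 1.5, 3.0, 4
    A, B = a + y, b + E
    rng = np.random.default_rng(1)
    S = 400_000
    theta = rng.gamma(A, 1 / B, size=S)
    fit = make_fit(theta.reshape(S, 1, 1), np.array([[y]]), np.array([[E]]))
    post = lambda t: stats.gamma.pdf(t, A, scale=1 / B)
    f_ll = lambda t: stats.poisson.logpmf(y, E * t)
    Ell = integrate.quad(lambda t: post(t) * f_ll(t), 0, 50)[0]
    Vll = integrate.quad(lambda t: post(t) * (f_ll(t) - Ell) ** 2, 0, 50)[0]
    Elik = integrate.quad(lambda t: post(t) * math.exp(f_ll(t)), 0, 50)[0]
    Elog = special.digamma(A) - math.log(B)
    oracles = {
        "dic": 2 * (-2 * Ell) - (-2 * stats.poisson.logpmf(y, E * math.exp(Elog))),
        "waic": -2 * (math.log(Elik) - Vll),
        "cpo": stats.nbinom.pmf(y, a, b / (b + E)),   # prior predictive
    }
    return fit, oracles


class TestDic:
    def test_degenerate_single_draw(self):
        theta = np.full((1, 2, 2), 1.3)
        f = make_fit(np.repeat(theta, 5, axis=0), np.array([[3, 2], [4, 1]]),
                     np.full((2, 2), 2.5))
        d, p_d = ms.dic(f)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        dev = -2 * stats.poisson.logpmf(f.observed, 2.5 * 1.3).sum()
        assert d == pytest.approx(dev)

    def test_matches_quadrature_oracle(self, conjugate_case):
        fit, oracles = conjugate_case
        d, _ = ms.dic(fit)
        assert d == pytest.approx(oracles["dic"], rel=5e-3)

    def test_extra_dispersion_increases_p_d(self):
        rng = np.random.default_rng(6)
        obs = np.array([[5, 7], [6, 4]])
        E = np.full((2, 2), 5.0)
        base = np.exp(0.05 * rng.normal(size=(400, 2, 2)))
        noisy = np.concatenate([base, np.exp(0.5 * rng.normal(size=(400, 2, 2)))])
        _, pd_base = ms.dic(make_fit(base, obs, E))
        _, pd_noisy = ms.dic(make_fit(noisy, obs, E))
        assert pd_noisy > pd_base

    def test_refuses_flagged_fit(self):
        f = make_fit(np.ones((10, 1, 1)), np.array([[2]]), np.array([[2.0]]),
                     converged=False)
        with pytest.raises(RuntimeError):
            ms.dic(f)
        ms.dic(f, force=True)


class TestWaic:
    def test_degenerate_single_draw_penalty_zero(self):
        f = make_fit(np.full((8, 1, 1), 0.9), np.array([[3]]), np.array([[4.0]]))
        _, p_w = ms.waic(f)
        assert p_w == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature_oracle(self, conjugate_case):
        fit, oracles = conjugate_case
        w, _ = ms.waic(fit)
        assert w == pytest.approx(oracles["waic"], rel=5e-3)

    def test_close_to_dic_for_well_specified_large_counts(self):
        # large-E posterior around truth: both criteria approach the same limit
        rng = np.random.default_rng(3)
        E = np.full((3, 3), 500.0)
        obs = rng.poisson(E)
        theta = np.exp(rng.normal(0, 0.01, size=(2000, 3, 3)))
        f = make_fit(theta, obs, E)
        d, _ = ms.dic(f)
        w, _ = ms.waic(f)
        assert abs(d - w) / abs(w) < 0.05


class TestCpo:
    def test_degenerate_single_draw_equals_likelihood(self):
        f = make_fit(np.full((4, 1, 2), 1.1), np.array([[3, 5]]),
                     np.array([[2.0, 4.0]]))
        vals, _, flagged = ms.cpo(f)
        np.testing.assert_allclose(vals, stats.poisson.pmf([3, 5], [2.2, 4.4]))
        assert not flagged.any()

    def test_matches_negative_binomial_oracle(self, conjugate_case):
        fit, oracles = conjugate_case
        vals, total, _ = ms.cpo(fit)
        assert vals[0] == pytest.approx(oracles["cpo"], rel=0.05)

    def test_sum_log_cpo_nonpositive(self, conjugate_case):
        fit, _ = conjugate_case
        _, total, _ = ms.cpo(fit)
        assert total <= 0


class TestPit:
    def test_values_in_unit_interval(self, conjugate_case):
        fit, _ = conjugate_case
        v = ms.pit(fit)
        assert np.all((v >= 0) & (v <= 1))

    def test_far_tail_observation_near_one(self):
        f = make_fit(np.ones((50, 1, 1)), np.array([[40]]), np.array([[5.0]]))
        assert ms.pit(f)[0] > 0.999

    def test_mid_correction_centers_null(self):
        # y drawn from the predictive itself: mid-PIT has mean ~0.5
        rng = np.random.default_rng(9)
        E = np.full((5, 6), 30.0)
        obs = rng.poisson(E)
        theta = np.exp(rng.normal(0, 0.02, size=(800, 5, 6)))
        f = make_fit(theta, obs, E)
        assert ms.pit(f).mean() == pytest.approx(0.5, abs=0.08)


class TestAndersonDarling:
    def test_near_ideal_grid(self):
        n = 90
        u = (np.arange(1, n + 1) - 0.5) / n
        a2, p = ms.anderson_darling_uniform(u)
        assert a2 < 0.05
        assert p > 0.99

    def test_gross_violation(self):
        a2, p = ms.anderson_darling_uniform(np.full(20, 0.99))
        assert p < 0.001

    def test_sorting_invariance(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(size=40)
        assert ms.anderson_darling_uniform(u) == \
            ms.anderson_darling_uniform(np.sort(u)[::-1])

    def test_null_calibration(self):
        rng = np.random.default_rng(4)
        ps = np.array([ms.anderson_darling_uniform(rng.uniform(size=90))[1]
                       for _ in range(400)])
        assert abs((ps < 0.05).mean() - 0.05) < 0.04
        assert abs((ps < 0.5).mean() - 0.5) < 0.08

    def test_too_few_values_refused(self):
        with pytest.raises(ValueError):
            ms.anderson_darling_uniform([0.1, 0.5, 0.9])


class TestRSquared:
    def test_perfect_agreement(self):
        rng = np.random.default_rng(5)
        sir = rng.uniform(0.5, 1.5, size=(3, 4))
        f = make_fit(np.repeat(sir[None], 50, axis=0), rng.poisson(10, (3, 4)),
                     np.full((3, 4), 10.0))
        assert ms.r_squared(f, SIRMatrix(sir)) == pytest.approx(1.0)

    def test_constant_prediction_explains_nothing(self):
        rng = np.random.default_rng(5)
        sir = rng.uniform(0.5, 1.5, size=(3, 4))
        f = make_fit(np.ones((50, 3, 4)), rng.poisson(10, (3, 4)),
                     np.full((3, 4), 10.0))
        assert ms.r_squared(f, SIRMatrix(sir)) == 0.0

    def test_deviance_variant_bounded_by_one(self):
        rng = np.random.default_rng(7)
        E = np.full((4, 5), 20.0)
        obs = rng.poisson(E * 1.1)
        f = make_fit(np.exp(rng.normal(0, 0.05, (200, 4, 5))), obs, E)
        r2 = ms.r_squared(f, SIRMatrix(obs / E), method="deviance")
        assert r2 <= 1.0


class TestCompareModels:
    def test_table_layout_and_flags(self):
        rng = np.random.default_rng(11)
        E = np.full((3, 4), 15.0)
        obs = rng.poisson(E)
        sir = SIRMatrix(obs / E)
        fits = [make_fit(np.exp(rng.normal(0, s, (300, 3, 4))), obs, E)
                for s in (0.02, 0.05, 0.1)]
        df = ms.compare_models(fits, sir)
        assert len(df) == 3
        assert df["best_waic"].sum() == 1
        assert df.loc[df["best_overall"], "waic"].iloc[0] == df["waic"].min()

    def test_identical_fits_identical_rows(self):
        rng = np.random.default_rng(12)
        E = np.full((2, 3), 10.0)
        obs = rng.poisson(E)
        theta = np.exp(rng.normal(0, 0.05, (200, 2, 3)))
        f1, f2 = make_fit(theta, obs, E), make_fit(theta.copy(), obs, E)
        df = ms.compare_models([f1, f2], SIRMatrix(obs / E))
        cols = ["dic", "waic", "sum_log_cpo", "r2"]
        assert df.loc[0, cols].tolist() == df.loc[1, cols].tolist()
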