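import math

import numpy as np
import pytest
from scipy import stats

import coaldiv as cd
from coaldiv.coalescent import (
    DEFAULT_KAPPA,
    cumulative_rate,
    log_likelihood,
    log_likelihood_hey,
    unit_intensity,
)
from coaldiv.models import MODEL_IDS, ModelSpec
from coaldiv import simulate as sim

from conftest import random_times
from test_models import _random_spec


class TestHandValues:
    def test_unit_rate_single_interval(self, toy_times):
        # rho_2 = kappa * 1 * tau0/N0 = 1 when tau0/N0 = 1/kappa; g_2 = 1
        spec = ModelSpec("M1", n0=DEFAULT_KAPPA, tau0=1.0)
        assert log_likelihood(spec, toy_times) == pytest.approx(-1.0)

    def test_hey_hand_value(self):
        # per-interval rate 2 with g_2 = 0.5: log 2 - 1
        times = cd.CoalescentTimes(n=3, node_depths=[1.0, 0.5])
        ll = log_likelihood_hey(tau0=2.0, n0=DEFAULT_KAPPA, times=times)
        assert ll == pytest.approx(math.log(2) - 1.0)

    def test_hey_depends_only_on_ratio(self, moran_times):
        a = log_likelihood_hey(1.3, 100.0, moran_times)
        b = log_likelihood_hey(2.6, 200.0, moran_times)
        assert a == pytest.approx(b, abs=1e-12)

    def test_hey_rejects_nonpositive(self, moran_times):
        with pytest.raises(ValueError):
            log_likelihood_hey(0.0, 100.0, moran_times)
        with pytest.raises(ValueError):
            log_likelihood_hey(1.0, -1.0, moran_times)


class TestOracleEquivalences:
    def test_hey_equals_generic_on_random_trees(self):
        """Closed-form constant-turnover likelihood vs the generic kernel path."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            times = random_times(rng, n, depth_scale=rng.uniform(0.5, 20))
            tau0 = rng.uniform(0.1, 5.0)
            n0 = rng.uniform(n, 10 * n)
            spec = ModelSpec("M1", n0=n0, tau0=tau0)
            assert log_likelihood(spec, times) == pytest.approx(
                log_likelihood_hey(tau0, n0, times), abs=1e-10
            )

    def test_time_varying_turnover_reduces_to_hey(self, moran_times):
        m1 = ModelSpec("M1", n0=100, tau0=0.8)
        m2 = ModelSpec("M2", n0=100, tau0=0.8, gamma=0.0)
        assert log_likelihood(m2, moran_times) == pytest.approx(
            log_likelihood(m1, moran_times), abs=1e-12
        )

    @pytest.mark.parametrize(
        "big,small",
        [
            (("M3", dict(lam0=0.05, mu0=0.0)), ("M5", dict(lam0=0.05))),
            (
                ("M4c", dict(lam0=0.05, alpha=0.01, eps=0.0)),
                ("M6", dict(lam0=0.05, alpha=0.01)),
            ),
            (("M6", dict(lam0=0.05, alpha=0.0)), ("M5", dict(lam0=0.05))),
        ],
    )
    def test_nested_likelihood_identities(self, moran_times, big, small):
        ll_big = log_likelihood(ModelSpec(big[0], n0=100, **big[1]), moran_times)
        ll_small = log_likelihood(ModelSpec(small[0], n0=100, **small[1]), moran_times)
        assert ll_big == pytest.approx(ll_small, abs=1e-10)

    def test_generic_path_matches_brute_force_quadrature(self):
        """Gauss-Legendre likelihood path vs 1e6-point trapezoid integration."""
        rng = np.random.default_rng(0)
        times = random_times(rng, 20, depth_scale=5.0)
        spec = ModelSpec("M4a", n0=50, lam0=1.2, alpha=0.3, mu0=0.5)
        from coaldiv.models import expected_diversity, rates_at

        js = np.arange(2, times.n)
        up, lo = times.node_depths[:-1], times.node_depths[1:]
        lam_u, _ = rates_at(spec, up)
        n_u = expected_diversity(spec, up)
        brute = float(np.sum(np.log(DEFAULT_KAPPA * js * (js - 1) / 2 * lam_u / n_u)))
        for j, a, b in zip(js, lo, up):
            s = np.linspace(a, b, 55_000)
            lam, _ = rates_at(spec, s)
            brute -= (
                DEFAULT_KAPPA
                * (j * (j - 1) / 2)
                * np.trapezoid(lam / expected_diversity(spec, s), s)
            )
        assert log_likelihood(spec, times) == pytest.approx(brute, abs=1e-6)


class TestCumulativeRate:
    def test_constant_turnover_closed_form(self):
        spec = ModelSpec("M1", n0=40, tau0=1.5)
        j, a, b = 5, 0.3, 2.1
        expected = DEFAULT_KAPPA * (j * (j - 1) / 2) * (1.5 / 40) * (b - a)
        assert cumulative_rate(spec, j, a, b) == pytest.approx(expected, rel=1e-12)
        assert cumulative_rate(spec, j, 1.0, 1.0) == 0.0

    def test_pure_birth_closed_form(self):
        spec = ModelSpec("M5", n0=40, lam0=0.7)
        t = 2.5
        expected = (DEFAULT_KAPPA / 40) * (math.exp(0.7 * t) - 1)
        assert cumulative_rate(spec, 2, 0.0, t) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_additivity(self, model_id):
        rng = np.random.default_rng(MODEL_IDS.index(model_id))
        spec = _random_spec(model_id, rng, n0=80)
        whole = cumulative_rate(spec, 3, 0.0, 2.0)
        split = cumulative_rate(spec, 3, 0.0, 1.0) + cumulative_rate(spec, 3, 1.0, 2.0)
        assert whole == pytest.approx(split, rel=1e-9)

    @pytest.mark.parametrize("model_id", ["M1", "M2", "M3", "M4c", "M5", "M6"])
    def test_closed_form_matches_adaptive_quadrature(self, model_id):
        rng = np.random.default_rng(100 + MODEL_IDS.index(model_id))
        for _ in range(5):
            spec = _random_spec(model_id, rng, n0=80)
            a, b = sorted(rng.uniform(0.0, 3.0, 2))
            closed = unit_intensity(spec, a, b, method="closed")
            quad = unit_intensity(spec, a, b, method="quad")
            assert closed == pytest.approx(quad, rel=1e-8, abs=1e-14)

    def test_invalid_interval(self):
        spec = ModelSpec("M1", n0=10, tau0=1.0)
        with pytest.raises(ValueError):
            cumulative_rate(spec, 2, 2.0, 1.0)
        with pytest.raises(ValueError):
            cumulative_rate(spec, 1, 0.0, 1.0)


class TestLikelihoodProperties:
    def test_rescaling_jacobian(self):
        """Scaling time by c and rates by 1/c shifts logL by exactly (n-2) log c."""
        rng = np.random.default_rng(5)
        times = random_times(rng, 25, depth_scale=3.0)
        c = 3.7
        scaled = cd.CoalescentTimes(n=25, node_depths=times.node_depths * c)
        cases = [
            ModelSpec("M1", n0=60, tau0=1.1),
            ModelSpec("M2", n0=60, tau0=1.1, gamma=0.2),
            ModelSpec("M6", n0=60, lam0=0.9, alpha=0.4),
            ModelSpec("M4a", n0=60, lam0=0.9, alpha=0.2, mu0=0.3),
        ]
        for spec in cases:
            rescaled = spec.with_params(
                **{
                    p: getattr(spec, p) / c
                    for p in spec.params()
                    if p != "eps"
                }
            )
            ll = log_likelihood(spec, times)
            ll_scaled = log_likelihood(rescaled, scaled)
            assert ll_scaled == pytest.approx(ll - (25 - 2) * math.log(c), abs=1e-7)

    def test_constraint_violation_penalized_not_raised(self, moran_times):
        spec = ModelSpec("M3", n0=100, lam0=0.5, mu0=0.9)
        assert log_likelihood(spec, moran_times) == -math.inf

    def test_diversity_underflow_penalized(self, moran_times):
        # net diversification so fast that N(root_age) underflows to zero
        spec = ModelSpec("M5", n0=100, lam0=50.0)
        assert log_likelihood(spec, moran_times) == -math.inf

    def test_simulator_intervals_match_kernel_exponential(self):
        """Root internode distances of constant-turnover simulations follow the
        kernel's exponential law Exp(rho_2) (Kolmogorov-Smirnov)."""
        n0, tau0 = 30, 1.0
        draws = []
        for i in range(400):
            tree = sim.simulate_saturated(n0, tau0, seed=7000 + i).tree
            draws.append(cd.coalescent_times(tree).internode_distances[0])
        rho2 = DEFAULT_KAPPA * tau0 / n0  # j = 2
        res = stats.kstest(draws, "expon", args=(0, 1.0 / rho2))
        assert res.pvalue > 1e-3
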