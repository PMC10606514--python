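"""Priors, posterior sampling, credible intervals, convergence diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from itc_uq import (
    McmcConfig,
    PriorSpec,
    ThermoParams,
    convergence_report,
    credible_interval,
    log_likelihood,
    log_prior,
    sample_posterior,
)
from itc_uq.bayes_regression import PosteriorSamples, _make_log_prob


@pytest.fixture(scope="module")
def prior():
    return PriorSpec(stated_R0=0.1, stated_Ls=1.0, conc_rel_uncertainty=0.10)


@pytest.fixture(scope="module")
def posterior(small_dataset, prior):
    """A converged-enough posterior for one simulated curve (shared)."""
    cfg = McmcConfig(n_warmup=500, n_samples=1000, n_chains=4, thin=5, seed=3)
    return sample_posterior(small_dataset.curves[0], prior, cfg)


class TestLogPrior:
    def test_out_of_bounds_energy_has_zero_density(self, prior):
        theta = ThermoParams(dG=5.0, dH=-5, dH0=0, R0=0.1, Ls=1.0, sigma=1e-6)
        assert log_prior(theta, prior) == -math.inf

    def test_concentration_term_matches_scipy_lognormal(self, prior):
        # difference of two evaluations isolates the R0 lognormal term
        base = dict(dG=-10.0, dH=-5.0, dH0=0.0, Ls=1.0, sigma=1e-6)
        t1 = ThermoParams(R0=0.1, **base)
        t2 = ThermoParams(R0=0.13, **base)
        (mu, s), _ = prior.conc_log_params()
        dist = stats.lognorm(s=s, scale=math.exp(mu))
        expected = dist.logpdf(0.1) - dist.logpdf(0.13)
        got = log_prior(t1, prior) - log_prior(t2, prior)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_jeffreys_prior_halving_property(self, prior):
        base = dict(dG=-10.0, dH=-5.0, dH0=0.0, R0=0.1, Ls=1.0)
        t1 = ThermoParams(sigma=1e-6, **base)
        t2 = ThermoParams(sigma=2e-6, **base)
        assert log_prior(t1, prior) - log_prior(t2, prior) == pytest.approx(
            math.log(2.0), rel=1e-12
        )

    def test_sigma_outside_log_bounds_excluded(self, prior):
        theta = ThermoParams(dG=-10, dH=-5, dH0=0, R0=0.1, Ls=1.0, sigma=10.0)
        assert log_prior(theta, prior) == -math.inf


class TestSamplerTarget:
    def test_sampler_density_proportional_to_likelihood_times_prior(
        self, small_dataset, prior
    ):
        """The vectorized target equals log_lik + log_prior + log-Jacobian
        up to one additive constant (checked via differences)."""
        curve = small_dataset.curves[0]
        lp = _make_log_prob(curve, prior, use_likelihood=True)

        def reference(theta):
            jac = math.log(theta.R0 * theta.Ls * theta.sigma)
            return log_likelihood(curve, theta) + log_prior(theta, prior) + jac

        thetas = [
            ThermoParams(dG=-10.2, dH=-4.6, dH0=3e-7, R0=0.11, Ls=0.95, sigma=1.2e-6),
            ThermoParams(dG=-9.5, dH=-5.5, dH0=-2e-7, R0=0.09, Ls=1.08, sigma=0.8e-6),
            ThermoParams(dG=-12.0, dH=-3.0, dH0=0.0, R0=0.12, Ls=1.0, sigma=2e-6),
        ]
        xs = np.array(
            [
                [t.dG, t.dH, t.dH0, math.log(t.R0), math.log(t.Ls), math.log(t.sigma)]
                for t in thetas
            ]
        )
        vals = lp(xs)
        refs = np.array([reference(t) for t in thetas])
        diffs = vals - refs
        assert np.ptp(diffs) < 1e-10  # constant offset only

    def test_same_seed_reproduces_draws_exactly(self, small_dataset, prior):
        cfg = McmcConfig(n_warmup=50, n_samples=64, n_chains=2, seed=17)
        a = sample_posterior(small_dataset.curves[0], prior, cfg)
        b = sample_posterior(small_dataset.curves[0], prior, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_only_sampling_recovers_uniform_dG(self, noiseless_curve, prior):
        cfg = McmcConfig(n_warmup=200, n_samples=16000, n_chains=2, seed=5)
        s = sample_posterior(noiseless_curve, prior, cfg, use_likelihood=False)
        dg = s.pooled("dG", thin_iterations=40)
        lo, hi = prior.dG_bounds
        p = stats.kstest(dg, stats.uniform(loc=lo, scale=hi - lo).cdf).pvalue
        assert p > 0.01

    def test_parameter_recovery_within_posterior_uncertainty(
        self, small_dataset, posterior
    ):
        truth = small_dataset.truths[0]
        for name in ("dG", "dH"):
            d = posterior.pooled(name)
            assert abs(np.median(d) - getattr(truth, name)) < 3 * d.std()

    def test_titrant_posterior_is_prior_dominated(self, posterior, prior):
        # the data identify only the concentration ratio, so the syringe
        # concentration is resolved by the priors alone: the ratio pinning
        # combines the two iid concentration priors, leaving a posterior SD
        # of prior_sd / sqrt(2) -- never data-sharpened below that
        d = posterior.pooled("Ls")
        prior_sd = prior.conc_rel_uncertainty * prior.stated_Ls
        expected = prior_sd / math.sqrt(2)
        assert abs(d.std() - expected) / expected < 0.20
        assert d.std() > 0.5 * prior_sd


class TestCredibleInterval:
    @staticmethod
    def brute_force_shortest(draws, level):
        s = np.sort(draws)
        M = len(s)
        k = math.ceil(level * M)
        candidates = [(s[i + k - 1] - s[i], s[i], s[i + k - 1]) for i in range(M - k + 1)]
        return min(candidates)[1:]

    @pytest.mark.parametrize("M,level,seed", [
        (100, 0.95, 0), (200, 0.5, 1), (57, 0.8, 2), (10, 0.3, 3),
    ])
    def test_matches_exhaustive_window_enumeration(self, M, level, seed):
        draws = np.random.default_rng(seed).normal(size=M)
        iv = credible_interval(draws, level)
        lo, hi = self.brute_force_shortest(draws, level)
        assert (iv.lower, iv.upper) == (lo, hi)

    def test_integer_ladder_has_minimal_window(self):
        draws = np.arange(1.0, 101.0)
        iv = credible_interval(draws, 0.95)
        assert iv.upper - iv.lower == 94.0

    def test_degenerate_draws_collapse(self):
        iv = credible_interval(np.full(50, 3.14), 0.9)
        assert iv.lower == iv.upper == 3.14

    def test_normal_draws_match_equal_tail_quantiles(self):
        draws = np.random.default_rng(7).normal(size=100_000)
        iv = credible_interval(draws, 0.95)
        assert iv.lower == pytest.approx(-1.96, abs=0.05)
        assert iv.upper == pytest.approx(1.96, abs=0.05)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            credible_interval(np.array([]), 0.95)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_width_nondecreasing_in_level(self, seed):
        draws = np.random.default_rng(seed).normal(size=200)
        widths = [
            credible_interval(draws, level).width
            for level in (0.1, 0.3, 0.5, 0.7, 0.9, 0.99)
        ]
        assert all(b >= a for a, b in zip(widths, widths[1:]))


def _synthetic_samples(chain_means, n=500, seed=0):
    rng = np.random.default_rng(seed)
    n_chains = len(chain_means)
    draws = np.empty((n_chains, n, 6))
    for c, m in enumerate(chain_means):
        draws[c] = rng.normal(m, 1.0, size=(n, 6))
    draws[..., 3:6] = np.abs(draws[..., 3:6]) + 1e-3  # positivity constraints
    prior = PriorSpec(stated_R0=0.1, stated_Ls=1.0)
    cfg = McmcConfig(n_warmup=1, n_samples=n, n_chains=n_chains, seed=0)
    return PosteriorSamples(draws=draws, prior=prior, config=cfg)


class TestConvergenceReport:
    def test_exchangeable_chains_have_unit_rhat(self):
        s = _synthetic_samples([0.0, 0.0, 0.0, 0.0])
        rep = convergence_report(s)
        assert all(v < 1.01 for v in rep.rhat.values())
        assert rep.converged

    def test_shifted_chains_flagged_nonconverged(self):
        s = _synthetic_samples([0.0, 5.0, 0.0, 5.0])
        rep = convergence_report(s)
        assert rep.rhat["dG"] > 1.5
        assert not rep.converged

    def test_single_chain_has_no_rhat(self):
        s = _synthetic_samples([0.0])
        rep = convergence_report(s)
        assert all(math.isnan(v) for v in rep.rhat.values())
        assert not rep.converged

    def test_percentiles_stabilize_early_on_converged_run(self, posterior):
        rep = convergence_report(posterior)
        tr = rep.percentile_traces["dG"]
        fr = rep.fractions
        # median trace moves little after the first 10% of draws
        med = tr[:, 1]
        spread = posterior.pooled("dG").std()
        late = med[fr >= 0.1]
        assert np.ptp(late) < 0.5 * spread
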