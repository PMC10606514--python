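"""Bayesian regression of integrated heat curves.

Posterior model
---------------
The likelihood is the Gaussian observation model of
:func:`itc_uq.binding_model.log_likelihood`.  Priors are independent:

* uniform (bounded) priors on dG, dH and dH0;
* lognormal priors on the cell and syringe concentrations, centered on the
  stated values with relative scale ``delta`` (the analyst's concentration
  uncertainty, typically 5% or 10%) — this is how knowledge that ITC data
  identify only the titrant:titrand *ratio* enters the analysis;
* the Jeffreys prior p(sigma) ∝ 1/sigma for the noise level, made proper by
  bounding log(sigma).

Sampling uses the affine-invariant ensemble sampler (emcee) on the
unconstrained parameterization (dG, dH, dH0, ln R0, ln Ls, ln sigma), with
``n_chains`` fully independent ensembles whose pooled draws yield credible
intervals.  The X% Bayesian credible interval (BCI) is the *shortest*
contiguous interval containing X% of the pooled posterior samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

import emcee

from .binding_model import (
    PARAM_NAMES,
    HeatCurve,
    ThermoParams,
    _true_heats_arrays,
)
from .intervals import IntervalEstimate
from .synthetic_data import lognormal_params

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "log_prior",
    "sample_posterior",
    "credible_interval",
    "convergence_report",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters for one curve's Bayesian fit.

    ``conc_rel_uncertainty`` (delta) sets the lognormal scale of both
    concentration priors relative to the stated values.  ``sigma_log_bounds``
    bound log(sigma/cal) to make the scale-invariant Jeffreys prior proper;
    ``sigma_ref`` only fixes the unit in which sigma is measured.
    """

    stated_R0: float
    stated_Ls: float
    conc_rel_uncertainty: float = 0.10
    dG_bounds: tuple[float, float] = (-40.0, 0.0)  # kcal/mol
    dH_bounds: tuple[float, float] = (-100.0, 100.0)  # kcal/mol
    dH0_bounds: tuple[float, float] = (-1.0, 1.0)  # cal
    sigma_log_bounds: tuple[float, float] = (math.log(1e-8), 0.0)  # log(cal)
    sigma_ref: float = 1.0  # cal

    def __post_init__(self) -> None:
        if not 0 < self.conc_rel_uncertainty < 1:
            raise ValueError("conc_rel_uncertainty must lie in (0, 1)")
        if not (self.stated_R0 > 0 and self.stated_Ls > 0):
            raise ValueError("stated concentrations must be positive")
        for name in ("dG_bounds", "dH_bounds", "dH0_bounds", "sigma_log_bounds"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be a finite interval with lower < upper")

    def conc_log_params(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """((mu, s) for ln R0, (mu, s) for ln Ls) of the lognormal priors."""
        return (
            lognormal_params(self.stated_R0, self.conc_rel_uncertainty),
            lognormal_params(self.stated_Ls, self.conc_rel_uncertainty),
        )


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run sizes: 2000 warm-up moves, then 10,000 stored draws from each
    of four chains by default.

    Each "chain" is an independent walker ensemble; ``n_warmup`` counts
    whole-ensemble moves and ``n_samples`` the stored draws per chain
    (pooled over walkers, iteration-major).
    """

    n_warmup: int = 2000
    n_samples: int = 10_000
    n_chains: int = 4
    n_walkers: int = 16
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_warmup, self.n_samples, self.n_chains, self.thin) < 1:
            raise ValueError("all MCMC counts must be >= 1")
        if self.n_walkers < 14:  # > 2 * ndim, required by the ensemble moves
            raise ValueError("need at least 14 walkers for a 6-parameter model")


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-R-hat per parameter plus running-percentile stability traces."""

    rhat: dict[str, float]
    fractions: np.ndarray
    percentile_traces: dict[str, np.ndarray]  # (len(fractions), 3): 2.5/50/97.5%
    converged: bool
    rhat_threshold: float


@dataclass(frozen=True)
class PosteriorSamples:
    """Posterior draws of (dG, dH, dH0, R0, Ls, sigma).

    ``draws`` has shape (n_chains, n_samples, 6) in natural parameter space
    and the parameter order above.
    """

    draws: np.ndarray
    prior: PriorSpec
    config: McmcConfig
    acceptance_fraction: float = float("nan")

    def __post_init__(self) -> None:
        expected = (self.config.n_chains, self.config.n_samples, 6)
        if tuple(self.draws.shape) != expected:
            raise ValueError(f"draws shape {self.draws.shape} != {expected}")
        if np.any(self.draws[..., 5] <= 0):
            raise ValueError("all sigma draws must be positive")
        if np.any(self.draws[..., 3] <= 0) or np.any(self.draws[..., 4] <= 0):
            raise ValueError("all concentration draws must be positive")

    def pooled(self, parameter: str, thin_iterations: int = 1) -> np.ndarray:
        """All chains' draws of one parameter, concatenated.

        ``thin_iterations`` keeps every k-th ensemble iteration (all walkers
        of that iteration); useful to obtain approximately independent draws
        for distributional tests.
        """
        j = PARAM_NAMES.index(parameter)
        if thin_iterations <= 1:
            return self.draws[..., j].reshape(-1)
        w = self.config.n_walkers
        parts = []
        for c in range(self.config.n_chains):
            d = self.draws[c, :, j]
            full = (d.size // w) * w
            parts.append(d[:full].reshape(-1, w)[::thin_iterations].ravel())
        return np.concatenate(parts)

    def credible_interval(self, parameter: str, level: float) -> IntervalEstimate:
        return credible_interval(self.pooled(parameter), level, parameter=parameter)


def log_prior(theta: ThermoParams, prior: PriorSpec) -> float:
    """Log prior density of theta (natural space), up to an additive constant.

    Returns -inf outside the support; never raises for out-of-support values.
    """
    for value, bounds in (
        (theta.dG, prior.dG_bounds),
        (theta.dH, prior.dH_bounds),
        (theta.dH0, prior.dH0_bounds),
    ):
        if not bounds[0] <= value <= bounds[1]:
            return -np.inf
    log_sigma = math.log(theta.sigma / prior.sigma_ref)
    if not prior.sigma_log_bounds[0] <= log_sigma <= prior.sigma_log_bounds[1]:
        return -np.inf
    (mu_R, s_R), (mu_L, s_L) = prior.conc_log_params()
    total = -math.log(theta.sigma)  # Jeffreys 1/sigma
    for value, mu, s in ((theta.R0, mu_R, s_R), (theta.Ls, mu_L, s_L)):
        z = (math.log(value) - mu) / s
        total += -math.log(value * s) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z
    return total


def _make_log_prob(curve: HeatCurve, prior: PriorSpec, use_likelihood: bool):
    """Vectorized log posterior over x = (dG, dH, dH0, ln R0, ln Ls, ln sigma).

    In the transformed space the concentration priors become Gaussian and the
    Jeffreys prior becomes flat on ln sigma (the log-Jacobians absorb the
    1/x densities), so

        log p(x) = loglik + N(u; mu_R, s_R) + N(v; mu_L, s_L) + const
    """
    (mu_R, s_R), (mu_L, s_L) = prior.conc_log_params()
    lo = np.array([prior.dG_bounds[0], prior.dH_bounds[0], prior.dH0_bounds[0]])
    hi = np.array([prior.dG_bounds[1], prior.dH_bounds[1], prior.dH0_bounds[1]])
    w_lo = prior.sigma_log_bounds[0] + math.log(prior.sigma_ref)
    w_hi = prior.sigma_log_bounds[1] + math.log(prior.sigma_ref)
    heats = curve.heats
    sched = curve.schedule
    N = curve.N

    def log_prob(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        m = x.shape[0]
        out = np.full(m, -np.inf)
        in_box = np.all((x[:, :3] >= lo) & (x[:, :3] <= hi), axis=1)
        in_box &= (x[:, 5] >= w_lo) & (x[:, 5] <= w_hi)
        if not np.any(in_box):
            return out
        xs = x[in_box]
        u, v, w = xs[:, 3], xs[:, 4], xs[:, 5]
        lp = (
            -0.5 * ((u - mu_R) / s_R) ** 2
            - 0.5 * ((v - mu_L) / s_L) ** 2
        )
        if use_likelihood:
            sigma = np.exp(w)
            q_star = _true_heats_arrays(
                xs[:, 0], xs[:, 1], xs[:, 2], np.exp(u), np.exp(v), sched
            )
            ssr = np.sum((heats - q_star) ** 2, axis=-1)
            lp += -N * w - 0.5 * ssr / sigma**2
        out[in_box] = lp
        return out

    return log_prob


def _init_walkers(
    curve: HeatCurve,
    prior: PriorSpec,
    n_walkers: int,
    rng: np.random.Generator,
    use_likelihood: bool,
) -> np.ndarray:
    """Starting positions in the transformed space.

    Posterior runs start in a cloud around a quick maximum-likelihood fit,
    with the unidentified syringe-concentration direction dispersed over its
    full prior; prior-only runs start from exact prior draws.
    """
    (mu_R, s_R), (mu_L, s_L) = prior.conc_log_params()
    if not use_likelihood:
        p0 = np.column_stack(
            [
                rng.uniform(*prior.dG_bounds, n_walkers),
                rng.uniform(*prior.dH_bounds, n_walkers),
                rng.uniform(*prior.dH0_bounds, n_walkers),
                rng.normal(mu_R, s_R, n_walkers),
                rng.normal(mu_L, s_L, n_walkers),
                rng.uniform(*prior.sigma_log_bounds, n_walkers)
                + math.log(prior.sigma_ref),
            ]
        )
        return p0

    from .mle_regression import fit_mle  # local import avoids a cycle

    fit = fit_mle(curve, compute_covariance=False)
    th = fit.theta_hat
    sigma0 = max(th.sigma, 1e-9)
    center = np.array(
        [th.dG, th.dH, th.dH0, math.log(th.R0), mu_L, math.log(sigma0)]
    )
    scales = np.array(
        [
            0.05,
            0.05 * abs(th.dH) + 1e-3,
            0.5 * sigma0,
            0.5 * s_R,
            s_L,
            0.2,
        ]
    )
    p0 = center + rng.normal(size=(n_walkers, 6)) * scales
    # clip into the prior support (open interval margins keep densities finite)
    for j, (lo, hi) in enumerate(
        (prior.dG_bounds, prior.dH_bounds, prior.dH0_bounds)
    ):
        span = hi - lo
        p0[:, j] = np.clip(p0[:, j], lo + 1e-9 * span, hi - 1e-9 * span)
    w_lo = prior.sigma_log_bounds[0] + math.log(prior.sigma_ref)
    w_hi = prior.sigma_log_bounds[1] + math.log(prior.sigma_ref)
    p0[:, 5] = np.clip(p0[:, 5], w_lo + 1e-9, w_hi - 1e-9)
    return p0


def sample_posterior(
    curve: HeatCurve,
    prior: PriorSpec,
    config: McmcConfig,
    use_likelihood: bool = True,
) -> PosteriorSamples:
    """Draw posterior samples of theta for one heat curve.

    Runs ``config.n_chains`` independent walker ensembles, discards
    ``config.n_warmup`` whole-ensemble warm-up moves each, and stores
    ``config.n_samples`` draws per chain.  Fully deterministic given
    ``config.seed``.  ``use_likelihood=False`` is a test hook that samples
    the prior through the identical machinery.

    Raises ``RuntimeError`` with diagnostics if the sampler fails to move or
    produces non-finite draws.
    """
    log_prob = _make_log_prob(curve, prior, use_likelihood)
    keep_iters = -(-config.n_samples // config.n_walkers)  # ceil division
    chain_seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws = np.empty((config.n_chains, config.n_samples, 6))
    acc = []
    for c, seq in enumerate(chain_seeds):
        rng = np.random.default_rng(seq)
        p0 = _init_walkers(curve, prior, config.n_walkers, rng, use_likelihood)
        # differential-evolution moves mix far better than the default
        # stretch move on this posterior (wide flat priors, correlated
        # concentration/energy directions)
        moves = [
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ]
        sampler = emcee.EnsembleSampler(
            config.n_walkers, 6, log_prob, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(
            int(seq.generate_state(1)[0])
        ).get_state()
        state = sampler.run_mcmc(p0, config.n_warmup)
        sampler.reset()
        sampler.run_mcmc(state, keep_iters, thin_by=config.thin)
        chain = sampler.get_chain()  # (keep_iters, walkers, 6)
        acc.append(float(np.mean(sampler.acceptance_fraction)))
        flat = chain.reshape(-1, 6)[: config.n_samples]
        if not np.all(np.isfinite(flat)):
            raise RuntimeError(
                f"chain {c}: non-finite posterior draws "
                f"(acceptance fraction {acc[-1]:.3f})"
            )
        draws = flat.copy()
        draws[:, 3:6] = np.exp(draws[:, 3:6])  # ln R0, ln Ls, ln sigma -> natural
        all_draws[c] = draws
    mean_acc = float(np.mean(acc))
    if mean_acc < 0.02:
        raise RuntimeError(
            f"ensemble sampler is stuck: mean acceptance fraction {mean_acc:.4f}; "
            "check initialization and prior bounds"
        )
    return PosteriorSamples(
        draws=all_draws, prior=prior, config=config, acceptance_fraction=mean_acc
    )


def credible_interval(
    draws: np.ndarray, level: float, parameter: str = ""
) -> IntervalEstimate:
    """Shortest interval containing ``level`` of the posterior samples.

    Among all contiguous windows of k = ceil(level * M) sorted draws, returns
    the narrowest (the sample highest-posterior-density interval).
    """
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size == 0:
        raise ValueError("cannot form a credible interval from zero draws")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    M = draws.size
    k = min(int(math.ceil(level * M)), M)
    s = np.sort(draws)
    widths = s[k - 1 :] - s[: M - k + 1]
    i = int(np.argmin(widths))
    return IntervalEstimate(
        lower=float(s[i]),
        upper=float(s[i + k - 1]),
        level=level,
        method="BCI",
        parameter=parameter,
    )


def convergence_report(
    samples: PosteriorSamples,
    rhat_threshold: float = 1.01,
    fractions: np.ndarray | None = None,
) -> ConvergenceReport:
    """Split-R-hat per parameter and running-percentile stability traces.

    A run is flagged converged when split-R-hat < ``rhat_threshold`` for all
    parameters.  The percentile traces show the pooled 2.5/50/97.5 sample
    percentiles as a function of the fraction of draws used; for a converged
    run they flatten out well before the full sample is used.

    With a single chain, R-hat is unavailable: all values are NaN and the
    run is flagged not converged.
    """
    single_chain = samples.config.n_chains < 2
    import arviz as az

    if fractions is None:
        fractions = np.linspace(0.05, 1.0, 20)
    fractions = np.asarray(fractions, dtype=float)
    rhat: dict[str, float] = {}
    traces: dict[str, np.ndarray] = {}
    for j, name in enumerate(PARAM_NAMES):
        chains = samples.draws[..., j]  # (n_chains, n_samples)
        if single_chain:
            rhat[name] = float("nan")
        else:
            rhat[name] = float(
                az.rhat(az.convert_to_dataset(chains), method="split")["x"]
            )
        tr = np.empty((len(fractions), 3))
        for i, f in enumerate(fractions):
            m = max(int(math.ceil(f * chains.shape[1])), 1)
            tr[i] = np.percentile(chains[:, :m], [2.5, 50.0, 97.5])
        traces[name] = tr
    converged = (not single_chain) and all(
        v < rhat_threshold for v in rhat.values()
    )
    return ConvergenceReport(
        rhat=rhat,
        fractions=fractions,
        percentile_traces=traces,
        converged=converged,
        rhat_threshold=rhat_threshold,
    )
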