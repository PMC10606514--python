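"""Maximum-likelihood fitting, asymptotic standard errors, and the
titrant-concentration error-propagation correction.

The "standard procedure" for ITC analysis is nonlinear least squares with the
syringe (titrant) concentration treated as a known constant — the data only
identify the titrant:titrand concentration ratio, so freeing both would leave
a flat likelihood direction.  The default :func:`fit_mle` therefore fixes
``Ls`` at its stated value and fits (dG, dH, dH0, R0, sigma); this is exactly
the assumption whose consequences the error-propagation correction
(:func:`propagate_error`) is meant to patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .binding_model import (
    HeatCurve,
    ThermoParams,
    _true_heats_arrays,
    log_likelihood,
)
from .intervals import IntervalEstimate

__all__ = [
    "MleFit",
    "EpSpec",
    "fit_mle",
    "ase_covariance",
    "hessian_fd",
    "normal_ci",
    "propagate_error",
]


@dataclass(frozen=True)
class EpSpec:
    """Relative concentration errors fed to the error-propagation formula.

    ``rel_err_Ls`` is s_[L]s / [L]s and ``rel_err_R0`` is s_[R]0 / [R]0;
    typical values are 0.05 or 0.10.
    """

    rel_err_Ls: float
    rel_err_R0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rel_err_Ls", "rel_err_R0"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")


@dataclass(frozen=True)
class MleFit:
    """Result of a maximum-likelihood fit.

    ``free_names`` lists the fitted parameters in the order used by
    ``covariance`` (rows/columns).  ``covariance`` is the inverse observed
    Fisher information at the maximizer, or None if it was not computable
    (e.g. a noiseless curve with sigma-hat at the boundary).
    """

    theta_hat: ThermoParams
    free_names: tuple[str, ...]
    covariance: np.ndarray | None
    log_likelihood_at_max: float
    converged: bool
    n_obs: int

    def ase(self, name: str) -> float:
        """Asymptotic standard error of one fitted parameter."""
        if self.covariance is None:
            raise ValueError("covariance unavailable for this fit")
        i = self.free_names.index(name)
        return float(np.sqrt(self.covariance[i, i]))


def _initial_guess(curve: HeatCurve) -> tuple[float, float, float]:
    """Heuristic (dG, dH, dH0) start from the curve shape.

    dH0 from the post-saturation tail, dH from the total binding heat
    assuming full receptor saturation, dG at a moderately tight -9 kcal/mol.
    """
    q = curve.heats
    dH0 = float(np.mean(q[-2:]))
    # Q_total ~ 1e-3 * V0 * dH * R0 at saturation (cal); undo bookkeeping roughly.
    total = float(np.sum(q - dH0))
    dH = total / (1e-3 * curve.schedule.V0 * curve.stated_R0)
    if abs(dH) < 1e-3:
        dH = -1.0
    return -9.0, dH, dH0


def fit_mle(
    curve: HeatCurve,
    start: ThermoParams | None = None,
    fix_Ls: bool = True,
    compute_covariance: bool = True,
) -> MleFit:
    """Maximize the Gaussian log-likelihood over (dG, dH, dH0, R0, sigma).

    Concentrations are initialized at their stated values; ``Ls`` is fixed
    there by default (set ``fix_Ls=False`` to free it, accepting the flat
    ratio direction).  The mean parameters are fit by least squares; the
    noise level then has the closed-form profile maximizer
    ``sigma_hat^2 = SSR / N``, which makes the joint optimum exact.
    """
    sched = curve.schedule
    N = curve.N
    if start is None:
        dG0, dH0_guess, off0 = _initial_guess(curve)
        start = ThermoParams(
            dG=dG0,
            dH=dH0_guess,
            dH0=off0,
            R0=curve.stated_R0,
            Ls=curve.stated_Ls,
            sigma=max(np.std(curve.heats) * 0.1, 1e-9),
        )

    heat_scale = max(float(np.max(np.abs(curve.heats))), 1e-9)

    if fix_Ls:
        names = ("dG", "dH", "dH0", "R0")
        x0 = np.array([start.dG, start.dH, start.dH0, start.R0])

        def unpack(x):
            return x[0], x[1], x[2], x[3], curve.stated_Ls
    else:
        names = ("dG", "dH", "dH0", "R0", "Ls")
        x0 = np.array([start.dG, start.dH, start.dH0, start.R0, start.Ls])

        def unpack(x):
            return x[0], x[1], x[2], x[3], x[4]

    def residuals(x):
        dG, dH, dH0, R0, Ls = unpack(x)
        if R0 <= 0 or Ls <= 0:
            return np.full(N, 1e3)
        q_star = _true_heats_arrays(dG, dH, dH0, R0, Ls, sched)
        return (curve.heats - q_star) / heat_scale

    x_scale = np.abs(x0)
    x_scale[x_scale < 1e-8] = 1e-8
    sol = optimize.least_squares(residuals, x0, x_scale=x_scale, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    # A second pass from the solution guards against early termination on
    # poorly scaled starts.
    sol = optimize.least_squares(residuals, sol.x, x_scale=x_scale, xtol=1e-15, ftol=1e-15, gtol=1e-15)

    ssr = float(np.sum(residuals(sol.x) ** 2)) * heat_scale**2
    sigma_hat = max(math.sqrt(ssr / N), 1e-12)
    dG, dH, dH0, R0, Ls = unpack(sol.x)
    theta_hat = ThermoParams(dG=dG, dH=dH, dH0=dH0, R0=R0, Ls=Ls, sigma=sigma_hat)
    free_names = names + ("sigma",)
    fit = MleFit(
        theta_hat=theta_hat,
        free_names=free_names,
        covariance=None,
        log_likelihood_at_max=log_likelihood(curve, theta_hat),
        converged=bool(sol.success),
        n_obs=N,
    )
    if compute_covariance and sol.success:
        try:
            cov = ase_covariance(fit, curve)
        except (ValueError, np.linalg.LinAlgError):
            cov = None
        if cov is not None:
            fit = MleFit(
                theta_hat=theta_hat,
                free_names=free_names,
                covariance=cov,
                log_likelihood_at_max=fit.log_likelihood_at_max,
                converged=fit.converged,
                n_obs=N,
            )
    return fit


def hessian_fd(
    f,
    x: np.ndarray,
    rel_step: float = 1e-4,
    abs_floor: float | np.ndarray = 1e-6,
) -> np.ndarray:
    """Symmetrized central finite-difference Hessian of a scalar function.

    Per-coordinate steps are ``max(rel_step * |x_i|, abs_floor_i)``; pass an
    array floor when coordinates live on very different scales (e.g. kcal/mol
    energies next to cal-scale heats).
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = np.maximum(rel_step * np.abs(x), abs_floor)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def ase_covariance(
    fit: MleFit, curve: HeatCurve, strict_printed_form: bool = False
) -> np.ndarray:
    """Asymptotic covariance: inverse of the negative log-likelihood Hessian.

    The Hessian is taken at the maximizer over the fitted parameters (in
    ``fit.free_names`` order) by central finite differences with relative
    step 1e-4.  The absolute step floor is 1e-6 *per parameter scale*: the
    fitted parameters span ~10 orders of magnitude (kcal/mol energies vs.
    cal-scale heats), so a single absolute floor would overstep the
    cal-scale coordinates entirely.  The default is the standard
    observed-information form ``(-H)^{-1}``; ``strict_printed_form=True``
    instead inverts ``-(1/N) H``, i.e. scales the covariance by N, for
    comparison with that alternative convention.

    Raises ``ValueError`` naming the offending directions when the negative
    Hessian is not positive definite.
    """
    if not fit.converged:
        raise ValueError("cannot compute ASE covariance for a non-converged fit")
    theta = fit.theta_hat
    values = {name: getattr(theta, name) for name in fit.free_names}
    x0 = np.array([values[n] for n in fit.free_names])

    def negll(x):
        kw = {name: float(v) for name, v in zip(fit.free_names, x)}
        full = {
            "dG": theta.dG,
            "dH": theta.dH,
            "dH0": theta.dH0,
            "R0": theta.R0,
            "Ls": theta.Ls,
            "sigma": theta.sigma,
        }
        full.update(kw)
        if full["sigma"] <= 0 or full["R0"] <= 0 or full["Ls"] <= 0:
            return np.inf
        return -log_likelihood(curve, ThermoParams(**full))

    # characteristic scale per parameter: energies ~1 kcal/mol, concentrations
    # ~stated values, heat offset and noise ~sigma-hat (cal)
    scale = {
        "dG": 1.0,
        "dH": 1.0,
        "dH0": max(theta.sigma, 1e-9),
        "R0": curve.stated_R0,
        "Ls": curve.stated_Ls,
        "sigma": max(theta.sigma, 1e-9),
    }
    floors = np.array([1e-6 * scale[n] for n in fit.free_names])
    H = hessian_fd(negll, x0, abs_floor=floors)
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite Hessian entries; fit may be at a boundary")
    if strict_printed_form:
        H = H / fit.n_obs
    eigvals, eigvecs = np.linalg.eigh(H)
    if np.any(eigvals <= 0):
        bad = []
        for idx in np.where(eigvals <= 0)[0]:
            dominant = fit.free_names[int(np.argmax(np.abs(eigvecs[:, idx])))]
            bad.append(dominant)
        raise ValueError(
            "negative log-likelihood Hessian is not positive definite along "
            f"directions dominated by: {sorted(set(bad))}"
        )
    return np.linalg.inv(H)


def normal_ci(
    estimate: float, se: float, level: float, parameter: str = "", method: str = "ASE"
) -> IntervalEstimate:
    """Normal-theory interval: estimate +/- z * se at the given level.

    ``z`` is the standard-normal quantile at (1 + level) / 2, so the bounds
    are the (1-level)/2 and (1+level)/2 quantiles of N(estimate, se^2).
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return IntervalEstimate(
        lower=estimate - z * se,
        upper=estimate + z * se,
        level=level,
        method=method,
        parameter=parameter,
    )


def propagate_error(theta_hat: float, se_ase: float, ep: EpSpec) -> float:
    """First-order error propagation of titrant-concentration uncertainty.

    Combines the relative asymptotic standard error with the relative error
    of the ligand concentration in quadrature,

        (s / theta)^2 = (s_ASE / theta)^2 + (s_Ls / Ls)^2,

    and returns ``s = |theta_hat| * sqrt(...)``.  Applies to the binding free
    energy and enthalpy, whose estimates scale with the assumed titrant
    concentration.  A nonzero ``ep.rel_err_R0`` is added in quadrature as
    well (optional receptor term).
    """
    if theta_hat == 0:
        raise ValueError("propagate_error undefined at theta_hat = 0 (relative form)")
    if se_ase < 0:
        raise ValueError("se_ase must be non-negative")
    if ep.rel_err_Ls == 0 and ep.rel_err_R0 == 0:
        return se_ase  # exact identity, no round-trip through the relative form
    rel2 = (se_ase / theta_hat) ** 2 + ep.rel_err_Ls**2 + ep.rel_err_R0**2
    # rounding in the relative form must never undercut the plain ASE
    return max(abs(theta_hat) * math.sqrt(rel2), se_ase)
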