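"""Simulation of integrated heat curves with concentration and heat noise.

The simulation design mirrors a standard calibration study for ITC
uncertainty quantification: the thermodynamic truth (dG, dH, dH0) is fixed,
while the *true* cell and syringe concentrations of each replicate are drawn
from lognormal distributions centered on the stated values, emulating the
5-10% inter-laboratory concentration error observed in practice.  Gaussian
noise with standard deviation ``sigma`` is then added to every injection
heat.  Fitting procedures only ever see the stated concentrations; the
realized truths are kept separately for coverage scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .binding_model import (
    HeatCurve,
    InjectionSchedule,
    ThermoParams,
    default_schedule,
    true_heats,
)

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "lognormal_params",
    "sample_concentrations",
    "simulate_curve",
    "simulate_dataset",
]


def lognormal_params(mean: float, rel_error: float) -> tuple[float, float]:
    """Log-scale (mu, s) of a lognormal with arithmetic mean ``mean`` and
    arithmetic coefficient of variation ``rel_error``.

    s^2 = log(1 + cv^2), mu = log(mean) - s^2 / 2.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if not 0 < rel_error < 1:
        raise ValueError("rel_error must lie in (0, 1)")
    s2 = np.log1p(rel_error**2)
    return float(np.log(mean) - 0.5 * s2), float(np.sqrt(s2))


def sample_concentrations(
    mean: float, rel_error: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` positive concentrations (mM) from the lognormal error model.

    The draws have arithmetic mean ``mean`` and arithmetic standard deviation
    ``rel_error * mean`` (i.e. coefficient of variation ``rel_error``).
    """
    mu, s = lognormal_params(mean, rel_error)
    return rng.lognormal(mean=mu, sigma=s, size=n)


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for one batch of simulated titrations.

    Defaults are the reference calibration design: dG = -10 kcal/mol,
    dH = -5 kcal/mol, dH0 = 0.5 ucal, stated concentrations 0.1 mM
    (receptor, cell) and 1.0 mM (ligand, syringe), concentration CV of
    10%, heat noise sigma = 1 ucal, 24 x 10 uL injections, 1000 replicates.
    """

    true_dG: float = -10.0  # kcal/mol
    true_dH: float = -5.0  # kcal/mol
    true_dH0: float = 0.5e-6  # cal (0.5 ucal)
    mean_R0: float = 0.1  # mM
    mean_Ls: float = 1.0  # mM
    conc_rel_error: float = 0.10
    sigma: float = 1e-6  # cal (1 ucal)
    n_curves: int = 1000
    schedule: InjectionSchedule = field(default_factory=default_schedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.conc_rel_error < 1:
            raise ValueError("conc_rel_error must lie in (0, 1)")
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (self.mean_R0 > 0 and self.mean_Ls > 0):
            raise ValueError("mean concentrations must be positive")


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated curves paired with their realized true parameters.

    ``curves[i].stated_R0/.stated_Ls`` always equal the design means (what a
    fitter is told); ``truths[i]`` holds the sampled true concentrations.
    """

    curves: tuple[HeatCurve, ...]
    truths: tuple[ThermoParams, ...]
    design: SimulationDesign

    def __post_init__(self) -> None:
        if not len(self.curves) == len(self.truths) == self.design.n_curves:
            raise ValueError("curves/truths length must equal design.n_curves")


def simulate_curve(
    design: SimulationDesign, rng: np.random.Generator, label: str = ""
) -> tuple[HeatCurve, ThermoParams]:
    """Simulate one curve: sample true concentrations, add Gaussian heat noise.

    Returns the noisy curve (carrying the *stated* design-mean concentrations)
    and the realized truth.  Noise is applied to every injection, including
    the first.
    """
    R0 = float(sample_concentrations(design.mean_R0, design.conc_rel_error, 1, rng)[0])
    Ls = float(sample_concentrations(design.mean_Ls, design.conc_rel_error, 1, rng)[0])
    truth = ThermoParams(
        dG=design.true_dG,
        dH=design.true_dH,
        dH0=design.true_dH0,
        R0=R0,
        Ls=Ls,
        sigma=design.sigma,
    )
    q_star = true_heats(truth, design.schedule)
    heats = q_star + rng.normal(0.0, design.sigma, size=design.schedule.N)
    curve = HeatCurve(
        heats=heats,
        schedule=design.schedule,
        stated_R0=design.mean_R0,
        stated_Ls=design.mean_Ls,
        label=label,
    )
    return curve, truth


def simulate_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Simulate ``design.n_curves`` independent curves, deterministically.

    A master :class:`numpy.random.SeedSequence` spawned from ``design.seed``
    provides one independent substream per curve, so datasets are
    reproducible and individual curves can be regenerated in isolation.
    """
    children = np.random.SeedSequence(design.seed).spawn(design.n_curves)
    curves, truths = [], []
    for i, child in enumerate(children):
        curve, truth = simulate_curve(
            design, np.random.default_rng(child), label=f"sim-{i:04d}"
        )
        curves.append(curve)
        truths.append(truth)
    return SimulatedDataset(curves=tuple(curves), truths=tuple(truths), design=design)
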