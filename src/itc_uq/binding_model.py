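"""Deterministic 1:1 binding heat model for isothermal titration calorimetry.

An ITC experiment titrates a ligand solution (concentration ``Ls`` in the
syringe) into a sample cell of volume ``V0`` containing the receptor
(concentration ``R0``).  After each injection the instrument reports the
integrated heat ``q_n``.  For simple 1:1 binding the expected heat of
injection ``n`` follows from the mass-action equilibrium between receptor,
ligand and complex at the post-injection cell concentrations, corrected for
the material displaced out of the (constant-volume) cell, plus a constant
per-injection heat of dilution and stirring ``dH0``.

Canonical internal units: heats in cal, energies in kcal/mol, concentrations
in mM, cell volume in mL, injection volumes in uL, temperature in K.  All
unit conversions happen inside :func:`true_heats`; I/O layers display ucal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_GAS_KCAL",
    "ThermoParams",
    "InjectionSchedule",
    "HeatCurve",
    "default_schedule",
    "association_constant",
    "equilibrium_complex",
    "true_heats",
    "log_likelihood",
]

#: Gas constant in kcal/(mol K).
R_GAS_KCAL = 1.9872e-3

CAL_PER_UCAL = 1e-6
UCAL_PER_CAL = 1e6


@dataclass(frozen=True)
class ThermoParams:
    """Full parameter vector of the observation model.

    Parameters
    ----------
    dG : float
        Free energy of binding, kcal/mol.  Must be finite.
    dH : float
        Enthalpy of binding, kcal/mol.
    dH0 : float
        Heat of dilution and stirring per injection, cal (an additive
        offset on every injection heat, despite the enthalpy-like symbol).
    R0 : float
        Receptor (titrand) concentration in the cell, mM.  Positive.
    Ls : float
        Ligand (titrant) concentration in the syringe, mM.  Positive.
    sigma : float
        Standard deviation of the Gaussian measurement error, cal.  Positive.
    """

    dG: float
    dH: float
    dH0: float
    R0: float
    Ls: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG):
            raise ValueError("dG must be finite")
        for name in ("R0", "Ls", "sigma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        """Return (dG, dH, dH0, R0, Ls, sigma) as a float array."""
        return np.array([self.dG, self.dH, self.dH0, self.R0, self.Ls, self.sigma])


PARAM_NAMES = ("dG", "dH", "dH0", "R0", "Ls", "sigma")


@dataclass(frozen=True)
class InjectionSchedule:
    """Instrument geometry and per-injection volumes.

    ``V0`` is the calorimeter cell volume in mL, ``volumes`` the ordered
    injection volumes in uL.  Dilution factors ``1 - v/V0`` must stay in
    (0, 1), which holds whenever the total injected volume is small relative
    to the cell.
    """

    V0: float
    volumes: tuple[float, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "volumes", tuple(float(v) for v in self.volumes))
        if self.V0 <= 0:
            raise ValueError("cell volume V0 must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.volumes) == 0:
            raise ValueError("schedule needs at least one injection")
        if any(v <= 0 for v in self.volumes):
            raise ValueError("all injection volumes must be positive")
        if sum(self.volumes) * 1e-3 >= self.V0:
            raise ValueError("total injected volume must stay below the cell volume")

    @property
    def N(self) -> int:
        return len(self.volumes)

    @property
    def dilution_factors(self) -> np.ndarray:
        """Cumulative dilution d_n = prod_{i<=n} (1 - v_i / V0)."""
        v_mL = np.asarray(self.volumes) * 1e-3
        return np.cumprod(1.0 - v_mL / self.V0)


def default_schedule(
    n_injections: int = 24,
    injection_volume_uL: float = 10.0,
    V0_mL: float = 1.43,
    temperature_K: float = 298.15,
) -> InjectionSchedule:
    """Equal-volume schedule for a MicroCal VP-ITC style cell (V0 = 1.43 mL)."""
    return InjectionSchedule(
        V0=V0_mL,
        volumes=(injection_volume_uL,) * n_injections,
        temperature=temperature_K,
    )


@dataclass(frozen=True)
class HeatCurve:
    """An observed or simulated integrated heat curve.

    ``heats`` are in cal (internally; file formats display ucal).  The
    *stated* concentrations are what the experimenter believes was loaded;
    they are the anchor of the concentration priors and of the default MLE,
    and may differ from the (unknown) true concentrations.
    """

    heats: np.ndarray
    schedule: InjectionSchedule
    stated_R0: float
    stated_Ls: float
    label: str = ""

    def __post_init__(self) -> None:
        heats = np.asarray(self.heats, dtype=float)
        object.__setattr__(self, "heats", heats)
        if heats.ndim != 1 or len(heats) != self.schedule.N:
            raise ValueError(
                f"expected {self.schedule.N} heats, got array of shape {heats.shape}"
            )
        if not (self.stated_R0 > 0 and self.stated_Ls > 0):
            raise ValueError("stated concentrations must be positive")

    @property
    def N(self) -> int:
        return self.schedule.N


def association_constant(dG: float | np.ndarray, temperature: float) -> float | np.ndarray:
    """Association constant Ka = exp(-dG / (R T)) in 1/M, for dG in kcal/mol."""
    return np.exp(-np.asarray(dG) / (R_GAS_KCAL * temperature))


def equilibrium_complex(Rtot, Ltot, Ka):
    """Equilibrium concentration of the 1:1 complex RL, in mM.

    Solves ``Ka (Rtot - RL)(Ltot - RL) = RL`` for the root in
    ``[0, min(Rtot, Ltot)]``.  ``Rtot``/``Ltot`` are total concentrations in
    mM; ``Ka`` is in 1/M.  Broadcasts over array inputs.

    The quadratic root is evaluated as ``2 R L / (S + sqrt(S^2 - 4 R L))``
    with ``S = R + L + Kd``, which avoids the catastrophic cancellation the
    textbook ``(S - sqrt(...)) / 2`` form suffers at high affinity.
    """
    Rtot = np.asarray(Rtot, dtype=float)
    Ltot = np.asarray(Ltot, dtype=float)
    Ka = np.asarray(Ka, dtype=float)
    if np.any(Rtot < 0) or np.any(Ltot < 0):
        raise ValueError("total concentrations must be non-negative")
    if np.any(~(Ka > 0)):
        raise ValueError("association constant must be positive and finite")
    Kd_mM = 1e3 / Ka  # dissociation constant in mM
    S = Rtot + Ltot + Kd_mM
    disc = S * S - 4.0 * Rtot * Ltot  # >= (Rtot - Ltot)^2 + Kd terms, never negative
    out = 2.0 * Rtot * Ltot / (S + np.sqrt(disc))
    return out if out.ndim else float(out)


def _true_heats_arrays(dG, dH, dH0, R0, Ls, schedule: InjectionSchedule) -> np.ndarray:
    """Vectorized q* computation; parameter arrays broadcast over leading axes.

    Returns heats in cal with shape ``broadcast_shape + (N,)``.
    """
    dG, dH, dH0, R0, Ls = np.broadcast_arrays(
        *(np.asarray(a, dtype=float)[..., None] for a in (dG, dH, dH0, R0, Ls))
    )
    d = schedule.dilution_factors  # (N,)
    v_mL = np.asarray(schedule.volumes) * 1e-3
    Ka = association_constant(dG, schedule.temperature)
    R_n = R0 * d
    L_n = Ls * (1.0 - d)
    RL = equilibrium_complex(R_n, L_n, Ka)
    # Q in cal: V0[mL] * dH[kcal/mol] * RL[mM] * 1e-3
    Q = 1e-3 * schedule.V0 * dH * RL
    Q_prev = np.concatenate([np.zeros(Q.shape[:-1] + (1,)), Q[..., :-1]], axis=-1)
    return Q - (1.0 - v_mL / schedule.V0) * Q_prev + dH0


def true_heats(theta: ThermoParams, schedule: InjectionSchedule) -> np.ndarray:
    """Expected integrated heats q_n*(theta), in cal, one per injection.

    After ``n`` injections the cell retains a cumulative dilution
    ``d_n = prod_{i<=n}(1 - v_i/V0)`` of its original content, so the total
    concentrations are ``R_n = R0 d_n`` and ``L_n = Ls (1 - d_n)``.  The
    cumulative binding heat is ``Q_n = V0 dH [RL]_n`` and the injection heat
    is the first-order carryover difference

        q_n* = Q_n - (1 - v_n/V0) Q_{n-1} + dH0,   Q_0 = 0.
    """
    return _true_heats_arrays(
        theta.dG, theta.dH, theta.dH0, theta.R0, theta.Ls, schedule
    )


def log_likelihood(curve: HeatCurve, theta: ThermoParams) -> float:
    """Gaussian log-likelihood of an integrated heat curve, in nats.

    Observed heats are modeled as independent N(q_n*(theta), sigma^2):

        log p(D|theta) = -(N/2) log(2 pi) - N log sigma
                         - (1 / (2 sigma^2)) sum_n (q_n - q_n*)^2
    """
    if theta.sigma <= 0:
        raise ValueError("sigma must be positive")
    resid = curve.heats - true_heats(theta, curve.schedule)
    N = curve.N
    return float(
        -0.5 * N * math.log(2.0 * math.pi)
        - N * math.log(theta.sigma)
        - 0.5 * np.dot(resid, resid) / theta.sigma**2
    )
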