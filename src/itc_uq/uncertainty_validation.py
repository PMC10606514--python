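"""Coverage calibration of uncertainty intervals.

An interval procedure is calibrated when its X% intervals contain the true
value X% of the time.  Given per-curve intervals from the three procedures
(Bayesian credible intervals, asymptotic-standard-error intervals, and ASE
with concentration error propagation) and per-curve reference truths, this
module computes observed coverage over a grid of nominal levels, bootstrap
standard deviations of each coverage estimate, and the comparison figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalEstimate

__all__ = [
    "TruthReference",
    "CoverageTable",
    "observed_coverage",
    "coverage_curve",
    "bootstrap_sd",
    "interval_comparison_figure",
    "coverage_plot",
]


@dataclass(frozen=True)
class TruthReference:
    """Reference values that intervals are scored against.

    ``mode`` is "simulated" when per-curve realized truths are known, or
    "experimental-proxy" when a per-dataset proxy (e.g. the pooled median of
    posterior medians) stands in for the unknown truth.  ``values`` maps a
    parameter name to one reference value per curve.
    """

    mode: str
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.mode not in ("simulated", "experimental-proxy"):
            raise ValueError("mode must be 'simulated' or 'experimental-proxy'")
        object.__setattr__(
            self,
            "values",
            {k: np.asarray(v, dtype=float) for k, v in self.values.items()},
        )


@dataclass(frozen=True)
class CoverageTable:
    """Observed coverage per (parameter, method, level), with bootstrap SDs.

    ``table`` columns: parameter, method, level, coverage, boot_sd, n_curves.
    """

    table: pd.DataFrame

    def coverage(self, parameter: str, method: str) -> pd.DataFrame:
        sub = self.table[
            (self.table.parameter == parameter) & (self.table.method == method)
        ]
        return sub.sort_values("level").reset_index(drop=True)


def observed_coverage(
    intervals: list[IntervalEstimate], truths: np.ndarray
) -> float:
    """Fraction of intervals containing their reference truth."""
    truths = np.asarray(truths, dtype=float)
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    if len(intervals) != len(truths):
        raise ValueError(
            f"{len(intervals)} intervals but {len(truths)} truths"
        )
    hits = [iv.contains(t) for iv, t in zip(intervals, truths)]
    return float(np.mean(hits))


def _containment_matrix(
    intervals_by_level: dict[float, list[IntervalEstimate]],
    truths: np.ndarray,
    levels: np.ndarray,
) -> np.ndarray:
    """(n_levels, n_curves) boolean matrix of truth containment."""
    truths = np.asarray(truths, dtype=float)
    mat = np.empty((len(levels), len(truths)), dtype=bool)
    for i, level in enumerate(levels):
        key = float(level)
        if key not in intervals_by_level:
            raise ValueError(f"no intervals provided for level {key}")
        ivs = intervals_by_level[key]
        if len(ivs) != len(truths):
            raise ValueError(f"level {key}: interval/truth length mismatch")
        mat[i] = [iv.contains(t) for iv, t in zip(ivs, truths)]
    return mat


def coverage_curve(
    intervals_by_level: dict[float, list[IntervalEstimate]],
    truths: np.ndarray,
    levels: np.ndarray | None = None,
    n_boot: int = 100,
    seed: int = 0,
    parameter: str = "",
    method: str = "",
) -> CoverageTable:
    """Observed coverage at each nominal level, with bootstrap SDs.

    Calibrated procedures put every point on the diagonal
    (observed == nominal) up to binomial noise.  The default level grid is
    10%..95% in steps of 5%.
    """
    if levels is None:
        levels = np.arange(0.10, 0.951, 0.05)
    levels = np.round(np.asarray(levels, dtype=float), 10)
    mat = _containment_matrix(intervals_by_level, truths, levels)
    rng = np.random.default_rng(seed)
    rows = []
    for i, level in enumerate(levels):
        sd = bootstrap_sd(mat[i], n_boot=n_boot, rng=rng)
        rows.append(
            {
                "parameter": parameter,
                "method": method,
                "level": float(level),
                "coverage": float(np.mean(mat[i])),
                "boot_sd": sd,
                "n_curves": mat.shape[1],
            }
        )
    return CoverageTable(table=pd.DataFrame(rows))


def bootstrap_sd(
    contains: np.ndarray,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Bootstrap SD of an observed-coverage estimate.

    Resamples *curves* with replacement (coverage is a per-curve Bernoulli
    outcome) and returns the SD of the resampled coverage fractions.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    contains = np.asarray(contains, dtype=float)
    n = contains.size
    idx = rng.integers(0, n, size=(n_boot, n))
    return float(np.std(contains[idx].mean(axis=1), ddof=1))


def interval_comparison_figure(
    intervals_by_method: dict[str, list[IntervalEstimate]],
    proxy_truths: np.ndarray,
    endpoint_sds: dict[str, np.ndarray] | None = None,
    parameter: str = "",
    unit: str = "",
):
    """Side-by-side 95% interval panels for the three procedures.

    One panel per method; each curve is one horizontal interval, the proxy
    truth is a vertical line, and optional ``endpoint_sds`` (per method,
    shape (n_curves, 2)) draw error bars on the interval endpoints.
    Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    proxy_truths = np.asarray(proxy_truths, dtype=float)
    methods = list(intervals_by_method)
    fig, axes = plt.subplots(
        1, len(methods), figsize=(4 * len(methods), 4), sharex=True, sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, method in zip(axes, methods):
        ivs = intervals_by_method[method]
        if len(ivs) != len(proxy_truths):
            raise ValueError(f"{method}: interval/truth length mismatch")
        for row, (iv, truth) in enumerate(zip(ivs, proxy_truths)):
            ax.plot([iv.lower, iv.upper], [row, row], color="C0", lw=2)
            ax.plot([truth, truth], [row - 0.35, row + 0.35], color="green", lw=1.5)
            if endpoint_sds is not None and method in endpoint_sds:
                sd_lo, sd_hi = endpoint_sds[method][row]
                ax.errorbar(
                    [iv.lower, iv.upper],
                    [row, row],
                    xerr=[sd_lo, sd_hi],
                    fmt="none",
                    ecolor="red",
                    capsize=2,
                )
        ax.set_title(method)
        ax.set_xlabel(f"{parameter} [{unit}]" if unit else parameter)
        ax.set_ylabel("experiment")
    fig.tight_layout()
    return fig


def coverage_plot(tables: list[CoverageTable], title: str = ""):
    """Nominal vs. observed coverage for several procedures on one axis."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 100], [0, 100], "k--", lw=1, label="diagonal")
    for tab in tables:
        df = tab.table
        label = f"{df.method.iloc[0]} {df.parameter.iloc[0]}".strip()
        ax.errorbar(
            df.level * 100,
            df.coverage * 100,
            yerr=df.boot_sd * 100,
            marker="o",
            ms=4,
            lw=1,
            label=label,
        )
    ax.set_xlabel("predicted rate (%)")
    ax.set_ylabel("observed rate (%)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
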