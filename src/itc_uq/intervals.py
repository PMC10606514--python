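"""Interval estimates shared by the Bayesian and maximum-likelihood routes."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["IntervalEstimate"]


@dataclass(frozen=True)
class IntervalEstimate:
    """A (lower, upper) uncertainty interval for one parameter.

    ``method`` identifies the construction: "BCI" (shortest sample interval
    from the Bayesian posterior), "ASE" (normal-theory interval from the
    asymptotic standard error), or "ASE+EP" (ASE inflated by
    titrant-concentration error propagation).
    """

    lower: float
    upper: float
    level: float
    method: str
    parameter: str = ""

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("interval requires lower <= upper")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower
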