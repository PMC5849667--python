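"""Trough extrapolation and therapeutic-window classification.

A concentration measured at a known time after dosing is extrapolated
to the trough (the concentration just before the next dose) assuming
log-linear elimination with a population half-life:

    C_trough = C * exp(-ln 2 / t_half * (tau - t)),

with tau the dosing interval (24 h for once-daily dosing) and a default
population half-life of 30 h.  Samples drawn before the absorption
phase has finished (default cutoff 2 h) are flagged as unreliable.

Troughs are classified against the proposed therapeutic window
(11.9–26.3 µg/L, bounds inclusive); the window bounds are defaults,
not constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "TroughEstimate",
    "WindowSummary",
    "extrapolate_trough",
    "classify_window",
    "cohort_window_summary",
    "WINDOW_LOW",
    "WINDOW_HIGH",
]

WINDOW_LOW = 11.9
WINDOW_HIGH = 26.3
DEFAULT_TAU_H = 24.0
DEFAULT_HALF_LIFE_H = 30.0
DEFAULT_ABSORPTION_CUTOFF_H = 2.0


@dataclass(frozen=True)
class TroughEstimate:
    c_measured: float
    time_after_dose: float
    tau: float
    half_life: float
    c_trough: float
    window_class: str
    unreliable: bool = False


def extrapolate_trough(
    c: float,
    t: float,
    tau: float = DEFAULT_TAU_H,
    half_life: float = DEFAULT_HALF_LIFE_H,
    *,
    absorption_cutoff: float = DEFAULT_ABSORPTION_CUTOFF_H,
    window: tuple[float, float] = (WINDOW_LOW, WINDOW_HIGH),
) -> TroughEstimate:
    """Extrapolate a measured concentration to the end of the dosing interval."""
    if not c > 0:
        raise ValueError("measured concentration must be > 0")
    if not 0 < t <= tau:
        raise ValueError(
            f"time after dose {t} h must lie in (0, tau={tau} h]; a sample "
            "beyond tau would postdate the next dose"
        )
    if not half_life > 0:
        raise ValueError("half_life must be > 0")
    c_trough = float(c * np.exp(-np.log(2.0) / half_life * (tau - t)))
    return TroughEstimate(
        c_measured=c,
        time_after_dose=t,
        tau=tau,
        half_life=half_life,
        c_trough=c_trough,
        window_class=classify_window(c_trough, *window),
        unreliable=t < absorption_cutoff,
    )


def classify_window(
    c_trough: float, low: float = WINDOW_LOW, high: float = WINDOW_HIGH
) -> str:
    """'below', 'within' (bounds inclusive) or 'above' the window."""
    if not low < high:
        raise ValueError("window bounds must satisfy low < high")
    if c_trough < low:
        return "below"
    if c_trough > high:
        return "above"
    return "within"


@dataclass(frozen=True)
class WindowSummary:
    """Cohort window classification; percentages sum to exactly 100."""

    n: int
    n_below: int
    n_within: int
    n_above: int

    def _pct(self, k: int) -> Fraction:
        return Fraction(100 * k, self.n)

    @property
    def pct_below(self) -> float:
        return float(self._pct(self.n_below))

    @property
    def pct_within(self) -> float:
        return float(self._pct(self.n_within))

    @property
    def pct_above(self) -> float:
        return float(self._pct(self.n_above))

    @property
    def pct_outside(self) -> float:
        return float(self._pct(self.n_below + self.n_above))

    def exact_percentages(self) -> tuple[Fraction, Fraction, Fraction]:
        """(below, within, above) as exact rationals (sum is exactly 100)."""
        return self._pct(self.n_below), self._pct(self.n_within), self._pct(self.n_above)


def cohort_window_summary(classes: Sequence[str]) -> WindowSummary:
    """Tally window classes into cohort percentages."""
    if not classes:
        raise ValueError("empty class list")
    bad = set(classes) - {"below", "within", "above"}
    if bad:
        raise ValueError(f"unknown window class(es): {sorted(bad)}")
    return WindowSummary(
        n=len(classes),
        n_below=sum(c == "below" for c in classes),
        n_within=sum(c == "within" for c in classes),
        n_above=sum(c == "above" for c in classes),
    )
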