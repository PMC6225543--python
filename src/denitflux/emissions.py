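"""Cumulative N2O emissions, emission factors, and FDR adjustment.

Per-plot flux time series are integrated over the monitoring window with
trapezoid weights — the same weight vectors that serve as contrast
coefficients when cumulative emissions are estimated inside a gamma
GLMM. Emission factors are background-corrected ratios: the cumulative
emission of a zero-N reference treatment is subtracted before dividing
by N input (area-based EF) or by plant N uptake (yield-scaled EF).
Multiple-comparison adjustment uses the Benjamini–Yekutieli step-up,
which controls the false discovery rate under arbitrary dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EmissionSeries",
    "EmissionFactor",
    "trapezoid_weights",
    "cumulative_emission",
    "emission_factor",
    "yield_scaled_ef",
    "by_fdr",
]

#: supported flux unit tags and their conversion to kg N ha-1 per (unit * day)
_UNIT_TO_KG_HA_PER_DAY = {
    # ug N m-2 h-1: x24 h/d, x1e-9 kg/ug, x1e4 m2/ha
    "ug_n_m2_h": 24.0 * 1e-9 * 1e4,
    "g_n_ha_d": 1e-3,
}


@dataclass
class EmissionSeries:
    """One plot's flux time series over a monitoring window."""

    plot_id: str
    treatment: str
    year: int
    dates: np.ndarray  # day of year
    fluxes: np.ndarray
    unit: str  # "ug_n_m2_h" or "g_n_ha_d"

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        self.fluxes = np.asarray(self.fluxes, dtype=float)
        if self.dates.shape != self.fluxes.shape:
            raise ValueError("dates and fluxes must have equal length")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")
        if self.unit not in _UNIT_TO_KG_HA_PER_DAY:
            raise ValueError(
                f"unit tag must be one of {sorted(_UNIT_TO_KG_HA_PER_DAY)}, got {self.unit!r}"
            )


def trapezoid_weights(dates: np.ndarray) -> np.ndarray:
    """Trapezoid-rule quadrature weights for irregular sampling dates.

    w_1 = (t_2 - t_1)/2, w_i = (t_{i+1} - t_{i-1})/2,
    w_n = (t_n - t_{n-1})/2; the weights sum to the window length and,
    applied to fluxes, give the piecewise-linear integral. The same
    vector serves as GLMM contrast coefficients for cumulative
    emissions.
    """
    t = np.asarray(dates, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 dates")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("dates must be strictly increasing (no ties)")
    w = np.empty(t.size)
    w[0] = dt[0] / 2
    w[-1] = dt[-1] / 2
    w[1:-1] = (t[2:] - t[:-2]) / 2
    return w


def cumulative_emission(series: EmissionSeries) -> float:
    """Trapezoid integral of the flux series, in kg N ha-1."""
    w = trapezoid_weights(series.dates)
    return float(w @ series.fluxes) * _UNIT_TO_KG_HA_PER_DAY[series.unit]


def emission_factor(cum: float, background: float, n_input: float) -> float:
    """Area-based EF: background-corrected emission per unit N input.

    (cum - background) / n_input, all in kg N ha-1; negative values are
    reported as such (a treatment can emit less than the reference).
    """
    if n_input <= 0:
        raise ValueError("n_input must be positive")
    return (cum - background) / n_input


def yield_scaled_ef(cum: float, background: float, plant_n: float) -> float:
    """Yield-scaled EF: background-corrected emission per kg plant N uptake."""
    if plant_n <= 0:
        raise ValueError("plant_n must be positive")
    return (cum - background) / plant_n


def by_fdr(pvalues) -> np.ndarray:
    """Benjamini–Yekutieli step-up FDR adjustment.

    adj_(i) = min over j >= i of min(1, p_(j) * m * c(m) / j) with
    c(m) = sum_{k=1..m} 1/k; valid under arbitrary dependence of the
    tests. Input order is preserved in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


@dataclass
class EmissionFactor:
    """Background-corrected emission factors for one treatment-year."""

    treatment: str
    year: int
    cumulative: float  # kg N ha-1
    background: float  # kg N ha-1
    n_input: float  # kg N ha-1 (catch-crop N + fertilizer N as applicable)
    plant_n: float  # kg N ha-1

    @property
    def ef_area(self) -> float:
        return emission_factor(self.cumulative, self.background, self.n_input)

    @property
    def ef_yield(self) -> float:
        return yield_scaled_ef(self.cumulative, self.background, self.plant_n)
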