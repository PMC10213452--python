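"""Magnesium dose-response analysis.

Elevated extracellular Mg2+ suppresses neuronal excitability and synaptic
transmission.  The assay raises the bath concentration stepwise from the
0.81 mM medium baseline by nominal 2.5 mM increments (2.75 ul of 1 M MgCl2
into 1.1 ml of medium per step) up to 10.81 mM, recording spontaneous and
stimulation-evoked activity at every step, then exchanges the medium and
records a recovery point.  This module provides the addition arithmetic
(exact dilution and nominal bookkeeping values), dose-response curve
construction, the exponential decay fit of the mean trace, the
initial-vs-recovery comparison, and the coefficient of variation used to
compare the stability of spontaneous and evoked metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import stats

__all__ = [
    "BASELINE_MG_MM",
    "concentration_after_addition",
    "addition_schedule",
    "DoseResponseCurve",
    "build_curve",
    "ExponentialFit",
    "fit_exponential",
    "recovery_comparison",
    "stability_cv",
]

#: Baseline Mg2+ concentration of the Neurobasal-based medium (mM).
BASELINE_MG_MM = 0.81


def concentration_after_addition(baseline: float, medium_volume: float,
                                 added_volume: float, stock: float
                                 ) -> tuple[float, float]:
    """Concentration (mM) after adding stock solution to the bath.

    Returns ``(exact, nominal)``: the exact dilution
    (baseline * V_medium + stock * V_added) / (V_medium + V_added) and the
    protocol bookkeeping value baseline + stock * V_added / V_medium,
    which ignores the added volume.  Volumes in ul, concentrations in mM.
    """
    if baseline < 0 or stock < 0:
        raise ValueError("concentrations must be >= 0")
    if medium_volume <= 0 or added_volume < 0:
        raise ValueError("volumes must be positive (added volume may be 0)")
    exact = (baseline * medium_volume + stock * added_volume) / (medium_volume + added_volume)
    nominal = baseline + stock * added_volume / medium_volume
    return float(exact), float(nominal)


def addition_schedule(n_steps: int = 4, baseline: float = BASELINE_MG_MM,
                      medium_volume: float = 1100.0, added_volume: float = 2.75,
                      stock: float = 1000.0) -> pd.DataFrame:
    """Cumulative addition table for the standard protocol.

    Default: four additions of 2.75 ul of 1 M MgCl2 into 1.1 ml, nominal
    +2.5 mM per step, 0.81 -> 10.81 mM nominal.  Exact concentrations track
    the growing bath volume.
    """
    exact = baseline
    nominal = baseline
    volume = medium_volume
    rows = [{"step": 0, "exact_mm": exact, "nominal_mm": nominal, "volume_ul": volume}]
    for step in range(1, n_steps + 1):
        exact, _ = concentration_after_addition(exact, volume, added_volume, stock)
        nominal = nominal + stock * added_volume / medium_volume
        volume += added_volume
        rows.append({"step": step, "exact_mm": exact, "nominal_mm": nominal,
                     "volume_ul": volume})
    return pd.DataFrame(rows)


@dataclass
class DoseResponseCurve:
    """Mean metric (MFR or induced spikes/stimulus) per Mg2+ concentration."""

    concentrations: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    ns: np.ndarray
    recovery_mean: float = np.nan
    recovery_sem: float = np.nan


def build_curve(sessions: list[tuple[float, np.ndarray]],
                recovery_values: np.ndarray | None = None) -> DoseResponseCurve:
    """Dose-response curve from (concentration, per-electrode values) pairs.

    Concentrations must be strictly increasing; the post-medium-change
    recovery point is kept separate from the curve.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 concentrations")
    concs = np.asarray([c for c, _ in sessions], dtype=float)
    if np.any(np.diff(concs) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    means, sems, ns = [], [], []
    for _, values in sessions:
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("each concentration needs at least one electrode")
        means.append(v.mean())
        sems.append(v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan)
        ns.append(v.size)
    rec_mean = rec_sem = np.nan
    if recovery_values is not None:
        rv = np.asarray(recovery_values, dtype=float)
        rec_mean = float(rv.mean())
        rec_sem = float(rv.std(ddof=1) / np.sqrt(rv.size)) if rv.size > 1 else np.nan
    return DoseResponseCurve(concs, np.asarray(means), np.asarray(sems),
                             np.asarray(ns, dtype=int), rec_mean, rec_sem)


@dataclass
class ExponentialFit:
    """Least-squares fit of mean(c) = A * exp(-c / tau)."""

    amplitude: float
    tau_mm: float
    rss: float
    no_decay: bool = False


def fit_exponential(curve: DoseResponseCurve) -> ExponentialFit:
    """Fit A * exp(-c / tau) to the mean trace.

    Deterministic initialization (A0 = mean at the lowest concentration,
    tau0 = concentration span) with least-squares refinement to relative
    tolerance 1e-8.  All-equal means are reported as no-decay (tau = inf);
    non-positive means trigger a warning but the direct nonlinear fit is
    still attempted.
    """
    c = curve.concentrations
    y = curve.means
    if c.size < 3:
        raise ValueError("need at least 3 concentration points")
    if np.allclose(y, y[0]):
        return ExponentialFit(float(y[0]), np.inf, 0.0, no_decay=True)
    if np.any(y <= 0):
        warnings.warn("non-positive means: log-scale fit impossible, "
                      "using direct nonlinear fit", stacklevel=2)
    a0 = max(float(y[0]), 1e-12)
    tau0 = float(c[-1] - c[0])

    def residuals(params):
        a, tau = params
        return a * np.exp(-c / tau) - y

    result = least_squares(residuals, x0=[a0, tau0], xtol=1e-8, ftol=1e-8, gtol=1e-8)
    a, tau = result.x
    return ExponentialFit(float(a), float(tau), float(np.sum(result.fun**2)))


def recovery_comparison(initial_values, recovery_values,
                        sided: str = "two-sided") -> stats.TestResult:
    """Mann-Whitney U comparing initial vs post-medium-change values."""
    a = np.asarray(initial_values, dtype=float)
    b = np.asarray(recovery_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per sample")
    return stats.mann_whitney_u(a, b, sided=sided)


def trend_test(curve: DoseResponseCurve, sided: str = "less") -> stats.TestResult:
    """Mann-Kendall trend test on the curve means (default: downward)."""
    return stats.mann_kendall(curve.means, sided=sided)


def stability_cv(values) -> float:
    """Coefficient of variation, 100 * sd / mean (sd with n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)
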