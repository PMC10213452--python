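"""Spontaneous-activity metrics: mean firing rate and active-electrode rule.

An electrode's mean firing rate (MFR) is its spike count divided by the
recording time; an electrode is active if its MFR exceeds 0.1 Hz (strict).
Condition-level aggregation reports percent active electrodes and the mean
MFR over active electrodes only, with the SEM over electrodes.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .core import CircuitLayout, SpikeEvents

__all__ = [
    "ACTIVE_THRESHOLD_HZ",
    "mean_firing_rate",
    "classify_active",
    "firing_rate_table",
    "aggregate_condition",
]

ACTIVE_THRESHOLD_HZ = 0.1


def mean_firing_rate(events: SpikeEvents, electrode: int) -> float:
    """Spike count on one electrode divided by the recording duration (Hz)."""
    if events.duration <= 0:
        raise ValueError("recording duration must be positive")
    return float(events.times_of(electrode).size / events.duration)


def classify_active(mfr: float, threshold: float = ACTIVE_THRESHOLD_HZ) -> bool:
    """Active means MFR strictly above the threshold ("above 0.1 Hz")."""
    if mfr < 0:
        raise ValueError("MFR must be >= 0")
    return mfr > threshold


def firing_rate_table(events: SpikeEvents, electrodes: Iterable[int],
                      threshold: float = ACTIVE_THRESHOLD_HZ) -> pd.DataFrame:
    """Per-electrode MFR and active flag for one session."""
    rows = []
    for e in electrodes:
        mfr = mean_firing_rate(events, e)
        rows.append({"electrode": int(e), "mfr_hz": mfr,
                     "active": classify_active(mfr, threshold)})
    return pd.DataFrame(rows, columns=["electrode", "mfr_hz", "active"])


def included_electrodes(layout: CircuitLayout,
                        independent_circuits: Iterable[int] | None) -> list[int]:
    """Electrodes of the circuits passing the independence mask (all if None)."""
    if independent_circuits is None:
        return layout.electrodes
    keep: list[int] = []
    for cid in independent_circuits:
        keep.extend(layout.electrodes_of(cid))
    return sorted(keep)


def aggregate_condition(table: pd.DataFrame,
                        grouping: list[str] = ("condition", "div")) -> pd.DataFrame:
    """Group per-electrode rows into condition/DIV summaries.

    ``table`` needs columns ``mfr_hz`` and ``active`` plus the grouping
    columns.  Percent active uses all included electrodes as denominator;
    mean MFR and its SEM are computed over active electrodes only and are
    reported as NaN (absent) when the active set is empty or a single
    electrode (SEM undefined at n = 1).
    """
    grouping = list(grouping)
    if table.empty:
        warnings.warn("empty table: nothing to aggregate", stacklevel=2)
        return pd.DataFrame(columns=grouping + [
            "n_electrodes", "n_active", "percent_active", "mean_mfr_hz", "sem_mfr_hz"])
    rows = []
    for keys, grp in table.groupby(grouping):
        keys = keys if isinstance(keys, tuple) else (keys,)
        active = grp.loc[grp["active"], "mfr_hz"].to_numpy()
        row = dict(zip(grouping, keys))
        row["n_electrodes"] = len(grp)
        row["n_active"] = active.size
        row["percent_active"] = 100.0 * active.size / len(grp)
        row["mean_mfr_hz"] = float(active.mean()) if active.size else np.nan
        row["sem_mfr_hz"] = (float(active.std(ddof=1) / np.sqrt(active.size))
                             if active.size > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
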