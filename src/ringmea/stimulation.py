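"""Stimulation-evoked response extraction and classification.

After each of the 480 pulses of a stimulation set, spikes on all four
electrodes of the circuit within the following 250 ms window are assigned
to that pulse (the window equals the 4 Hz inter-pulse interval, so windows
tile the set and every spike belongs to at most one repeat).  Stacking the
repeats vertically gives the raster in which consistent latencies appear
as vertical bands.  A stimulated electrode is "activity-inducing" when the
set evokes at least as many spikes as pulses, i.e. at least one spike per
stimulus on average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import SpikeEvents, StimulationProtocol

__all__ = [
    "POST_STIMULUS_WINDOW_MS",
    "StackedRaster",
    "build_raster",
    "classify_activity_inducing",
    "group_stimulation_summary",
]

POST_STIMULUS_WINDOW_MS = 250.0


@dataclass
class StackedRaster:
    """Per-repeat post-stimulus spike latencies for one stimulated electrode.

    ``table`` has columns ``repeat`` (0-based pulse index), ``electrode``
    and ``latency_ms`` in (0, window].
    """

    stimulated_electrode: int
    n_repeats: int
    window_ms: float
    table: pd.DataFrame

    @property
    def total_spikes(self) -> int:
        return int(len(self.table))

    def row(self, repeat: int) -> pd.DataFrame:
        return self.table.loc[self.table["repeat"] == repeat]


def build_raster(events: SpikeEvents, circuit_electrodes: Iterable[int],
                 protocol: StimulationProtocol,
                 window_ms: float = POST_STIMULUS_WINDOW_MS) -> StackedRaster:
    """Assign each circuit spike to the pulse whose window contains it.

    Latency is open at 0 (a spike at the exact pulse sample is
    indistinguishable from artifact) and closed at ``window_ms``.  Raises
    if the window exceeds the inter-pulse interval, which would
    double-assign spikes.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    if protocol.n_repeats > 1:
        min_gap = float(np.min(np.diff(protocol.pulse_times)))
        if window_ms * 1e-3 > min_gap + 1e-12:
            raise ValueError(
                f"window {window_ms} ms exceeds the {min_gap * 1e3:.1f} ms "
                "inter-pulse interval: spikes would be double-assigned"
            )
    sub = events.restrict(circuit_electrodes)
    pulses = protocol.pulse_times
    idx = np.searchsorted(pulses, sub.times, side="left") - 1
    rows = []
    for e, t, i in zip(sub.electrodes, sub.times, idx):
        if i < 0:
            continue  # before the first pulse
        latency_ms = (t - pulses[i]) * 1e3
        if 0.0 < latency_ms <= window_ms:
            rows.append({"repeat": int(i), "electrode": int(e),
                         "latency_ms": float(latency_ms)})
    table = pd.DataFrame(rows, columns=["repeat", "electrode", "latency_ms"])
    return StackedRaster(protocol.stimulated_electrode, protocol.n_repeats,
                         window_ms, table)


def classify_activity_inducing(raster: StackedRaster,
                               n_repeats: int | None = None) -> dict[str, float]:
    """Per-electrode summary row: total evoked spikes and the inducing flag.

    ``activity_inducing`` is exact at total == n_repeats (integer
    comparison, no floating point involved).
    """
    if n_repeats is None:
        n_repeats = raster.n_repeats
    total = raster.total_spikes
    return {
        "stimulated_electrode": int(raster.stimulated_electrode),
        "total_spikes": int(total),
        "n_repeats": int(n_repeats),
        "activity_inducing": bool(total >= n_repeats),
        "mean_induced_per_stimulus": total / n_repeats if n_repeats else np.nan,
    }


def group_stimulation_summary(rows: pd.DataFrame,
                              grouping: list[str] | None = None) -> pd.DataFrame:
    """Group per-electrode rows: percent inducing, mean spikes over inducing.

    The mean induced spikes per stimulus and its SEM are computed over
    activity-inducing electrodes only (absent when there are none); the
    SEM treats electrodes as independent.
    """
    if rows.empty:
        warnings.warn("empty stimulation summary: nothing to aggregate", stacklevel=2)
        return pd.DataFrame()

    def summarize(grp: pd.DataFrame) -> dict[str, float]:
        inducing = grp.loc[grp["activity_inducing"], "mean_induced_per_stimulus"]
        return {
            "n_electrodes": len(grp),
            "n_inducing": int(len(inducing)),
            "percent_inducing": 100.0 * len(inducing) / len(grp),
            "mean_induced_per_stimulus": (float(inducing.mean())
                                          if len(inducing) else np.nan),
            "sem_induced_per_stimulus": (float(inducing.std(ddof=1)
                                               / np.sqrt(len(inducing)))
                                         if len(inducing) > 1 else np.nan),
        }

    if not grouping:
        return pd.DataFrame([summarize(rows)])
    out = []
    for keys, grp in rows.groupby(list(grouping)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(grouping, keys))
        row.update(summarize(grp))
        out.append(row)
    return pd.DataFrame(out)
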