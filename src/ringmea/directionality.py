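"""Spike-pair directionality on the 4-electrode ring circuits.

The statistic asks whether consecutive spikes propagate clockwise around a
circuit.  Per circuit: merge the spike trains of its active electrodes into
one time-sorted stream; every pair of consecutive spikes closer than 5 ms
(strict, an upper bound on the synaptic latency) is one spike pair.  Pairs
on adjacent electrodes are classified clockwise (positions 1-2, 2-3, 3-4,
4-1) or counter-clockwise (the reverse); pairs on the same electrode or on
diagonally opposed electrodes (1-3, 2-4) carry no direction and are
discarded from the clockwise percentage but counted in the non-directional
fraction.  The group statistic is the unweighted mean of the per-circuit
clockwise percentages.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import ADJACENT_CLOCKWISE, CircuitLayout, SpikeEvents

__all__ = [
    "PAIR_WINDOW_MS",
    "classify_pair",
    "extract_pairs",
    "frequency_map",
    "circuit_counts",
    "clockwise_summary",
]

PAIR_WINDOW_MS = 5.0

PAIR_COLUMNS = ["pre_electrode", "post_electrode", "pre_pos", "post_pos",
                "pre_time_s", "delta_ms", "klass", "ambiguous"]


def classify_pair(pre_pos: int, post_pos: int) -> str:
    """Direction class of a (pre, post) position pair on the ring."""
    if pre_pos not in (1, 2, 3, 4) or post_pos not in (1, 2, 3, 4):
        raise ValueError("positions must be in 1..4")
    if pre_pos == post_pos:
        return "same_electrode"
    if (pre_pos, post_pos) in ADJACENT_CLOCKWISE:
        return "clockwise"
    if (post_pos, pre_pos) in ADJACENT_CLOCKWISE:
        return "counterclockwise"
    return "diagonal"


def extract_pairs(events: SpikeEvents, circuit_electrodes: Iterable[int],
                  layout: CircuitLayout, window_ms: float = PAIR_WINDOW_MS,
                  active_electrodes: Iterable[int] | None = None) -> pd.DataFrame:
    """Consecutive spike pairs (< window) in one circuit's merged stream.

    Inactive electrodes are removed before merging when
    ``active_electrodes`` is given.  Pairs overlap: in a chain of three
    close spikes the middle one is post of the first pair and pre of the
    second.  Spikes with identical timestamps on different electrodes are
    ordered by ascending ring position and flagged ``ambiguous`` (their
    direction is undefined; they are excluded from clockwise counts).
    """
    if window_ms <= 0:
        raise ValueError("pairing window must be positive")
    keep = set(circuit_electrodes)
    if active_electrodes is not None:
        keep &= set(active_electrodes)
    sub = events.restrict(keep)
    e = sub.electrodes
    t = sub.times
    pos = np.asarray([layout.position_of[int(x)] for x in e], dtype=int)
    # stable sort by (time, position) realizes the tie-break rule
    order = np.lexsort((pos, t))
    e, t, pos = e[order], t[order], pos[order]
    rows = []
    for i in range(len(t) - 1):
        delta_ms = (t[i + 1] - t[i]) * 1e3
        if delta_ms < window_ms:
            rows.append({
                "pre_electrode": int(e[i]),
                "post_electrode": int(e[i + 1]),
                "pre_pos": int(pos[i]),
                "post_pos": int(pos[i + 1]),
                "pre_time_s": float(t[i]),
                "delta_ms": float(delta_ms),
                "klass": classify_pair(int(pos[i]), int(pos[i + 1])),
                "ambiguous": bool(delta_ms == 0.0 and e[i] != e[i + 1]),
            })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frequency_map(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """4x4 pre/post-position counts and pre-normalized percentages.

    ``counts[pre-1, post-1]`` counts pairs; ``percent`` normalizes each
    pre-electrode's row of counts to sum to 100% (the frequency of each
    post-electrode given the pre-electrode), NaN where a pre-electrode has
    no pairs.
    """
    counts = np.zeros((4, 4), dtype=int)
    if len(pairs):
        for pre, post in zip(pairs["pre_pos"], pairs["post_pos"]):
            counts[pre - 1, post - 1] += 1
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(sums > 0, 100.0 * counts / sums, np.nan)
    return counts, percent


def circuit_counts(pairs: pd.DataFrame) -> dict[str, float]:
    """Directional tallies and percentages for one circuit's pair table."""
    usable = pairs.loc[~pairs["ambiguous"]] if len(pairs) else pairs
    n_cw = int((usable["klass"] == "clockwise").sum()) if len(usable) else 0
    n_ccw = int((usable["klass"] == "counterclockwise").sum()) if len(usable) else 0
    n_same = int((pairs["klass"] == "same_electrode").sum()) if len(pairs) else 0
    n_diag = int((pairs["klass"] == "diagonal").sum()) if len(pairs) else 0
    n_total = int(len(pairs))
    directional = n_cw + n_ccw
    return {
        "n_cw": n_cw,
        "n_ccw": n_ccw,
        "n_same": n_same,
        "n_diag": n_diag,
        "n_total": n_total,
        "n_ambiguous": int(pairs["ambiguous"].sum()) if len(pairs) else 0,
        "percent_clockwise": 100.0 * n_cw / directional if directional else np.nan,
        "percent_nondirectional": (100.0 * (n_same + n_diag) / n_total
                                   if n_total else np.nan),
    }


def clockwise_summary(pairs_by_circuit: Mapping[int, pd.DataFrame]) -> pd.DataFrame:
    """Per-circuit directional tallies, one row per circuit.

    Callers restrict ``pairs_by_circuit`` to independent, closed circuits
    before the call (the masks come from microscopy review and are inputs).
    """
    rows = []
    for cid, pairs in sorted(pairs_by_circuit.items()):
        row = {"circuit": int(cid)}
        row.update(circuit_counts(pairs))
        rows.append(row)
    return pd.DataFrame(rows)


def group_clockwise(summary: pd.DataFrame) -> dict[str, float]:
    """Unweighted group mean of per-circuit clockwise percentages.

    Circuits without directional pairs are excluded from the mean and
    tallied in ``n_excluded``.  The non-directional fraction pools all
    pairs across circuits.
    """
    valid = summary.loc[summary["percent_clockwise"].notna(), "percent_clockwise"]
    n_total = int(summary["n_total"].sum()) if len(summary) else 0
    n_nondir = int((summary["n_same"] + summary["n_diag"]).sum()) if len(summary) else 0
    return {
        "mean_percent_clockwise": float(valid.mean()) if len(valid) else np.nan,
        "sem_percent_clockwise": (float(valid.std(ddof=1) / np.sqrt(len(valid)))
                                  if len(valid) > 1 else np.nan),
        "n_circuits": int(len(valid)),
        "n_excluded": int(len(summary) - len(valid)),
        "percent_nondirectional": 100.0 * n_nondir / n_total if n_total else np.nan,
    }
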