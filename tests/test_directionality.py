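"""Spike-pair extraction, classification, frequency maps, group summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from ringmea.core import SpikeEvents
from ringmea.directionality import (circuit_counts, classify_pair, clockwise_summary,
                                    extract_pairs, frequency_map, group_clockwise)
from ringmea.simulate import SimulationConfig, simulate_spontaneous
from ringmea.spontaneous import firing_rate_table
from conftest import make_layout


def events_on(one_circuit, spikes, duration=1.0):
    """spikes: list of (electrode, time_s)."""
    return SpikeEvents([e for e, _ in spikes], [t for _, t in spikes], duration)


class TestClassifyPair:
    @pytest.mark.parametrize("pre,post,expected", [
        (1, 2, "clockwise"), (2, 3, "clockwise"), (3, 4, "clockwise"),
        (4, 1, "clockwise"),
        (2, 1, "counterclockwise"), (3, 2, "counterclockwise"),
        (4, 3, "counterclockwise"), (1, 4, "counterclockwise"),
        (1, 3, "diagonal"), (3, 1, "diagonal"), (2, 4, "diagonal"),
        (4, 2, "diagonal"),
        (2, 2, "same_electrode"),
    ])
    def test_all_position_pairs(self, pre, post, expected):
        assert classify_pair(pre, post) == expected

    def test_invalid_position_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(0, 1)


class TestExtractPairs:
    def test_clockwise_chain(self, one_circuit):
        """Spikes on 1,2,3,4 at 0,2,4,6 ms: three overlapping clockwise pairs."""
        ev = events_on(one_circuit, [(1, 0.000), (2, 0.002), (3, 0.004), (4, 0.006)])
        pairs = extract_pairs(ev, [1, 2, 3, 4], one_circuit)
        assert len(pairs) == 3
        assert (pairs["klass"] == "clockwise").all()

    def test_window_is_strict(self, one_circuit):
        ev = events_on(one_circuit, [(1, 0.000), (2, 0.005)])
        assert len(extract_pairs(ev, [1, 2, 3, 4], one_circuit)) == 0
        ev = events_on(one_circuit, [(1, 0.000), (2, 0.00499)])
        assert len(extract_pairs(ev, [1, 2, 3, 4], one_circuit)) == 1

    def test_inactive_electrodes_removed_first(self, one_circuit):
        """Dropping an inactive middle electrode can merge its neighbors' spikes."""
        ev = events_on(one_circuit, [(1, 0.000), (2, 0.002), (3, 0.004)])
        pairs = extract_pairs(ev, [1, 2, 3, 4], one_circuit,
                              active_electrodes={1, 3})
        assert len(pairs) == 1
        assert pairs.iloc[0]["klass"] == "diagonal"
        assert pairs.iloc[0]["delta_ms"] == pytest.approx(4.0)

    def test_identical_timestamps_flagged_ambiguous(self, one_circuit):
        ev = events_on(one_circuit, [(2, 0.001), (1, 0.001)])
        pairs = extract_pairs(ev, [1, 2, 3, 4], one_circuit)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["ambiguous"]
        assert (row["pre_pos"], row["post_pos"]) == (1, 2)  # ordered by position
        counts = circuit_counts(pairs)
        assert counts["n_cw"] == 0 and counts["n_ccw"] == 0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(stn.integers(0, 10**6))
    def test_matches_brute_force(self, seed):
        """Pair list equals an exhaustive sort-and-scan oracle."""
        layout = make_layout(1)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 200))
        electrodes = rng.integers(1, 5, size=n)
        times = np.round(rng.uniform(0, 0.5, size=n), 5)  # coarse grid forces ties
        ev = SpikeEvents(electrodes, times, duration=0.5)
        pairs = extract_pairs(ev, [1, 2, 3, 4], layout)
        # oracle: stable sort by (time, electrode==position here), scan gaps
        order = sorted(range(n), key=lambda i: (times[i], electrodes[i]))
        expected = []
        for a, b in zip(order[:-1], order[1:]):
            delta = (times[b] - times[a]) * 1e3
            if delta < 5.0:
                expected.append((int(electrodes[a]), int(electrodes[b]),
                                 pytest.approx(delta)))
        got = [(r["pre_electrode"], r["post_electrode"], r["delta_ms"])
               for _, r in pairs.iterrows()]
        assert [(g[0], g[1]) for g in got] == [(e[0], e[1]) for e in expected]
        assert all(g[2] == e[2].expected for g, e in zip(got, expected))


class TestFrequencyMap:
    def test_empty_pairs_zero_matrix(self):
        counts, percent = frequency_map(pd.DataFrame(columns=["pre_pos", "post_pos"]))
        assert counts.sum() == 0
        assert np.isnan(percent).all()

    def test_single_combination(self, one_circuit):
        pairs = pd.DataFrame({"pre_pos": [1] * 10, "post_pos": [2] * 10})
        counts, percent = frequency_map(pairs)
        assert counts[0, 1] == 10
        assert percent[0, 1] == 100.0

    def test_normalization_identity(self, rng):
        pre = rng.integers(1, 5, size=100)
        post = rng.integers(1, 5, size=100)
        counts, percent = frequency_map(pd.DataFrame({"pre_pos": pre, "post_pos": post}))
        sums = np.nansum(percent, axis=1)
        defined = counts.sum(axis=1) > 0
        assert np.allclose(sums[defined], 100.0)
        assert counts.sum() == 100


class TestClockwiseSummary:
    def test_all_clockwise_circuits(self, one_circuit):
        pairs = pd.DataFrame({
            "pre_pos": [1, 2], "post_pos": [2, 3],
            "klass": ["clockwise"] * 2, "ambiguous": [False] * 2,
            "pre_electrode": [1, 2], "post_electrode": [2, 3],
            "pre_time_s": [0, 0.001], "delta_ms": [1.0, 1.0],
        })
        summary = clockwise_summary({1: pairs, 2: pairs})
        group = group_clockwise(summary)
        assert group["mean_percent_clockwise"] == 100.0

    def test_unweighted_mean_over_circuits(self):
        """60% (5 pairs) and 80% (100 pairs) average to 70%, not pooled."""
        def fake(n_cw, n_ccw):
            klass = ["clockwise"] * n_cw + ["counterclockwise"] * n_ccw
            return pd.DataFrame({
                "pre_pos": 1, "post_pos": 2, "klass": klass,
                "ambiguous": False, "pre_electrode": 1, "post_electrode": 2,
                "pre_time_s": 0.0, "delta_ms": 1.0,
            })
        summary = clockwise_summary({1: fake(3, 2), 2: fake(80, 20)})
        group = group_clockwise(summary)
        assert group["mean_percent_clockwise"] == pytest.approx(70.0)

    def test_circuit_without_directional_pairs_excluded(self):
        diag = pd.DataFrame({
            "pre_pos": [1], "post_pos": [3], "klass": ["diagonal"],
            "ambiguous": [False], "pre_electrode": [1], "post_electrode": [3],
            "pre_time_s": [0.0], "delta_ms": [1.0],
        })
        summary = clockwise_summary({1: diag})
        group = group_clockwise(summary)
        assert np.isnan(group["mean_percent_clockwise"])
        assert group["n_excluded"] == 1
        assert group["percent_nondirectional"] == 100.0


class TestRecoveryProperties:
    def simulate_percent_clockwise(self, p_forward, p_backward, seed,
                                   n_circuits=6, duration=120.0):
        layout = make_layout(n_circuits)
        config = SimulationConfig(seed=seed, background_rate=2.0,
                                  p_forward=p_forward, p_backward=p_backward)
        truth = simulate_spontaneous(config, layout, duration)
        fr = firing_rate_table(truth.spikes, layout.electrodes)
        active = set(fr.loc[fr["active"], "electrode"])
        pairs = {c: extract_pairs(truth.spikes, layout.electrodes_of(c), layout,
                                  5.0, active)
                 for c in layout.circuit_ids}
        return group_clockwise(clockwise_summary(pairs))["mean_percent_clockwise"]

    def test_swapping_propagation_probabilities_mirrors_percentage(self):
        """p_forward <-> p_backward maps percent clockwise p to 100 - p."""
        fwd = self.simulate_percent_clockwise(0.3, 0.1, seed=1)
        bwd = self.simulate_percent_clockwise(0.1, 0.3, seed=1)
        assert fwd > 60 > 40 > bwd
        assert fwd + bwd == pytest.approx(100.0, abs=6.0)

    def test_monotone_in_p_forward(self):
        """Expected percent clockwise grows with p_forward at fixed p_backward."""
        means = [np.mean([self.simulate_percent_clockwise(p, 0.1, seed)
                          for seed in range(3)])
                 for p in (0.1, 0.25, 0.4)]
        assert means[0] < means[1] < means[2]
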