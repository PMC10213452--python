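"""Simulator behavior: determinism, propagation, suppression, rendering."""

import numpy as np
import pytest

from ringmea import detect
from ringmea.core import RawRecording, StimulationProtocol
from ringmea.simulate import (EvokedBand, SimulationConfig, apply_mg_suppression,
                              render_channel, render_raw, simulate_spontaneous,
                              simulate_stimulation, spike_template)
from conftest import make_layout


class TestSpontaneous:
    def test_zero_rate_zero_spikes(self, one_circuit):
        config = SimulationConfig(seed=0, background_rate=0.0)
        truth = simulate_spontaneous(config, one_circuit, 10.0)
        assert len(truth.spikes) == 0

    def test_deterministic_under_seed(self, one_circuit):
        config = SimulationConfig(seed=7)
        a = simulate_spontaneous(config, one_circuit, 20.0)
        b = simulate_spontaneous(config, one_circuit, 20.0)
        assert a.spikes == b.spikes
        assert np.array_equal(a.parent_kind, b.parent_kind)

    def test_deterministic_forward_cascade(self, one_circuit):
        """p_forward = 1 from a single seed spike walks the ring clockwise."""
        config = SimulationConfig(seed=0, background_rate=0.0, p_forward=1.0,
                                  p_backward=0.0)
        with pytest.warns(UserWarning, match="supercritical"):
            truth = simulate_spontaneous(config, one_circuit, 0.05,
                                         seed_spikes=[(1, 0.0)])
        t = truth.spikes.times
        e = truth.spikes.electrodes
        assert len(truth.spikes) >= 4
        assert np.all(np.diff(t) > 0)
        gaps_ms = np.diff(t) * 1e3
        assert np.all(gaps_ms < 5.0)
        # clockwise walk 1 -> 2 -> 3 -> 4 -> 1 -> ...
        expected = [(i % 4) + 1 for i in range(len(truth.spikes))]
        assert e.tolist() == expected
        assert truth.true_clockwise_fraction == 1.0

    def test_poisson_background_rate(self):
        """Mean count per electrode matches the Poisson expectation."""
        layout = make_layout(1)
        counts = []
        for seed in range(50):
            config = SimulationConfig(seed=seed, background_rate=2.0,
                                      p_forward=0.0, p_backward=0.0)
            truth = simulate_spontaneous(config, layout, 300.0)
            for e in layout.electrodes:
                counts.append(truth.spikes.times_of(e).size)
        counts = np.asarray(counts)
        expected = 2.0 * 300.0
        se = np.sqrt(expected / counts.size)
        assert abs(counts.mean() - expected) < 3 * se

    def test_supercritical_branching_rejected(self, one_circuit):
        config = SimulationConfig(seed=0, p_forward=0.9, p_backward=0.7)
        with pytest.raises(ValueError, match="1.5"):
            simulate_spontaneous(config, one_circuit, 1.0)

    def test_propagated_parent_latency_in_support(self, one_circuit):
        """Every propagated spike trails an adjacent-electrode parent within support."""
        config = SimulationConfig(seed=5, background_rate=2.0,
                                  p_forward=0.4, p_backward=0.2)
        truth = simulate_spontaneous(config, one_circuit, 60.0)
        propagated = np.isin(truth.parent_kind, ["forward", "backward"])
        assert propagated.sum() > 0
        # conservation: each propagated spike has a possible parent on the
        # correct neighbor within the latency support
        for i in np.flatnonzero(propagated):
            e, t = int(truth.spikes.electrodes[i]), truth.spikes.times[i]
            direction = +1 if truth.parent_kind[i] == "forward" else -1
            parent_electrode = one_circuit.neighbor(e, -direction)
            deltas = (t - truth.spikes.times_of(parent_electrode)) * 1e3
            assert np.any((deltas >= 0.5) & (deltas <= 4.5))


class TestStimulation:
    def test_silent_config_gives_no_spikes(self, one_circuit):
        config = SimulationConfig(seed=0, evoked_bands=(), late_response_rate=0.0)
        protocol = StimulationProtocol.standard(electrode=2)
        truth = simulate_stimulation(config, one_circuit, protocol)
        assert len(truth.spikes) == 0

    def test_deterministic_band(self, one_circuit):
        """p = 1, no jitter: one spike per electrode exactly 5 ms after each pulse."""
        config = SimulationConfig(seed=0, evoked_bands=(EvokedBand(5.0, 0.0, 1.0),),
                                  late_response_rate=0.0)
        protocol = StimulationProtocol.standard(electrode=2)
        truth = simulate_stimulation(config, one_circuit, protocol)
        assert len(truth.spikes) == 4 * 480
        for e in (1, 2, 3, 4):
            latencies = truth.spikes.times_of(e)[:, None] - protocol.pulse_times[None, :]
            nearest = np.min(np.abs(latencies - 0.005), axis=1)
            assert np.allclose(nearest, 0.0, atol=1e-9)

    def test_band_probability_binomial_mean(self, one_circuit):
        """Mean evoked count per electrode over seeds matches 480 * p."""
        protocol = StimulationProtocol.standard(electrode=2)
        counts = []
        for seed in range(50):
            config = SimulationConfig(seed=seed,
                                      evoked_bands=(EvokedBand(5.0, 0.5, 0.5),),
                                      late_response_rate=0.0)
            truth = simulate_stimulation(config, one_circuit, protocol)
            counts.append(len(truth.spikes) / 4)
        counts = np.asarray(counts)
        expected = 480 * 0.5
        se = np.sqrt(480 * 0.5 * 0.5 / counts.size)
        assert abs(counts.mean() - expected) < 3 * se

    def test_band_beyond_window_rejected(self, one_circuit):
        config = SimulationConfig(seed=0, evoked_bands=(EvokedBand(300.0, 0.0, 1.0),))
        with pytest.raises(ValueError, match="250"):
            simulate_stimulation(config, one_circuit,
                                 StimulationProtocol.standard(electrode=1))


class TestMgSuppression:
    def test_zero_concentration_unchanged(self):
        config = SimulationConfig(seed=0)
        assert apply_mg_suppression(config, 0.0) == config

    def test_one_tau_scales_by_inverse_e(self):
        config = SimulationConfig(seed=0, background_rate=2.0, mg_tau_mm=3.0)
        suppressed = apply_mg_suppression(config, 3.0)
        assert suppressed.background_rate == pytest.approx(2.0 / np.e)
        assert suppressed.late_response_rate == pytest.approx(
            config.late_response_rate / np.e)

    def test_multiplicative_in_concentration(self):
        """rate(2 tau) * rate(0) == rate(tau)^2."""
        config = SimulationConfig(seed=0, background_rate=2.0, mg_tau_mm=3.0)
        r0 = config.background_rate
        r1 = apply_mg_suppression(config, 3.0).background_rate
        r2 = apply_mg_suppression(config, 6.0).background_rate
        assert r2 * r0 == pytest.approx(r1**2)

    def test_early_band_exemption(self):
        config = SimulationConfig(seed=0, mg_exempt_early_bands=True,
                                  evoked_bands=(EvokedBand(5.0, 0.5, 0.8),
                                                EvokedBand(40.0, 2.0, 0.5)))
        suppressed = apply_mg_suppression(config, 10.0)
        assert suppressed.evoked_bands[0].probability == 0.8  # early: exempt
        assert suppressed.evoked_bands[1].probability < 0.5   # late: suppressed

    def test_bad_tau_rejected(self):
        config = SimulationConfig(seed=0, mg_tau_mm=-1.0)
        with pytest.raises(ValueError):
            apply_mg_suppression(config, 1.0)


class TestRender:
    def test_silent_noiseless_recording_is_zero(self, one_circuit):
        config = SimulationConfig(seed=0, background_rate=0.0, noise_sd_uv=0.0)
        truth = simulate_spontaneous(config, one_circuit, 0.1)
        raw = render_raw(truth, config, one_circuit)
        assert np.all(raw.samples == 0.0)

    def test_peak_sample_at_spike_time(self, one_circuit):
        config = SimulationConfig(seed=0, noise_sd_uv=0.0)
        rng = config.rng(0)
        x = render_channel(np.array([0.05]), config, 2000, 20_000.0, rng)
        assert np.argmax(x) == 1000
        assert x.max() == pytest.approx(config.waveform.amplitude_uv)

    def test_edge_spike_truncated_not_error(self, one_circuit):
        config = SimulationConfig(seed=0, noise_sd_uv=0.0)
        rng = config.rng(0)
        x = render_channel(np.array([0.0]), config, 100, 20_000.0, rng)
        assert np.isfinite(x).all() and x.max() > 0

    def test_mad_recovers_noise_sd(self):
        """MAD/0.6745 on a noise-only rendering estimates noise_sd within 5%."""
        config = SimulationConfig(seed=1, noise_sd_uv=4.0)
        rng = config.rng(3)
        x = render_channel(np.array([]), config, 300 * 20_000, 20_000.0, rng)
        sigma = detect.estimate_noise_sigma(x)
        assert sigma == pytest.approx(4.0, rel=0.05)

    def test_render_deterministic(self, one_circuit):
        config = SimulationConfig(seed=9)
        truth = simulate_spontaneous(config, one_circuit, 1.0)
        a = render_raw(truth, config, one_circuit)
        b = render_raw(truth, config, one_circuit)
        assert np.array_equal(a.samples, b.samples)

    def test_template_positive_peak(self):
        config = SimulationConfig(seed=0)
        template, peak = spike_template(config.waveform, 20_000.0)
        assert template[peak] == template.max() > 0
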