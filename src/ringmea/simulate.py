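"""Synthetic MEA recordings with the statistical structure the analysis assumes.

The generator emulates the features the downstream stages measure:

* background firing -- independent homogeneous Poisson trains per electrode;
* directional propagation -- each spike independently elicits a spike on the
  clockwise ring neighbor with probability ``p_forward`` and on the
  counter-clockwise neighbor with ``p_backward``, after a latency drawn from
  a uniform distribution supported strictly below the 5 ms pairing window.
  Propagated spikes can propagate again (a subcritical branching cascade),
  so the ground-truth clockwise fraction is exactly
  ``p_forward / (p_forward + p_backward)`` in expectation;
* stimulus-locked responses -- latency "bands": for each pulse, each band
  fires once per circuit electrode with its per-pulse probability at its
  mean latency plus Gaussian jitter, plus Poisson "late" activity in the
  15-250 ms post-stimulus window;
* magnesium suppression -- rates and response probabilities scale by
  exp(-concentration / tau), optionally exempting early (< 15 ms) bands,
  which in the modeled biology persist because they are driven directly by
  the stimulus rather than by Mg-blocked synapses;
* raw-trace rendering -- a biphasic template (positive peak at the spike
  time) stamped onto each channel plus additive white Gaussian noise, at
  20 kHz, to exercise the detector.

Every operation draws from its own RNG stream derived from
``(config.seed, operation tag)``, so stages are individually reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CircuitLayout, RawRecording, SpikeEvents, StimulationProtocol

__all__ = [
    "EvokedBand",
    "Waveform",
    "SimulationConfig",
    "GroundTruth",
    "simulate_spontaneous",
    "simulate_stimulation",
    "apply_mg_suppression",
    "render_raw",
    "spike_template",
]

_TAG_SPONTANEOUS = 1
_TAG_STIMULATION = 2
_TAG_RENDER = 3
_EARLY_BAND_MS = 15.0


@dataclass(frozen=True)
class EvokedBand:
    """One stimulus-locked response band."""

    mean_latency_ms: float
    jitter_sd_ms: float
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("band probability must be in [0, 1]")
        if self.mean_latency_ms <= 0:
            raise ValueError("band latency must be positive")


@dataclass(frozen=True)
class Waveform:
    """Triphasic extracellular spike template.

    A small leading negative dip (the capacitive phase of a real
    extracellular waveform) precedes the positive peak, followed by a
    larger repolarization lobe.  The positive peak carries
    ``amplitude_uv`` exactly and sits at the spike time.
    """

    amplitude_uv: float = 40.0
    width_ms: float = 0.6
    negative_fraction: float = 0.4  # trailing lobe amplitude / positive peak
    lead_fraction: float = 0.25     # leading dip amplitude / positive peak

    def __post_init__(self) -> None:
        if self.amplitude_uv <= 0:
            raise ValueError("positive-peak amplitude must be positive")
        if self.width_ms <= 0:
            raise ValueError("waveform width must be positive")
        if not 0.0 <= self.lead_fraction < 1.0:
            raise ValueError("lead_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic recordings.

    Rates and probabilities are per electrode / per spike; latency support
    is capped below the 5 ms pairing window so that ground truth and the
    pair statistic coincide in the noiseless limit.
    """

    seed: int = 0
    background_rate: float = 2.0           # Hz per electrode
    p_forward: float = 0.3                 # clockwise propagation probability
    p_backward: float = 0.1                # counter-clockwise
    latency_low_ms: float = 0.5
    latency_high_ms: float = 4.5
    evoked_bands: tuple[EvokedBand, ...] = (EvokedBand(5.0, 0.5, 0.8),)
    late_response_rate: float = 4.0        # Hz in the 15-250 ms post-stimulus window
    mg_tau_mm: float = 3.0                 # Mg2+ suppression decay constant (mM)
    mg_exempt_early_bands: bool = False
    waveform: Waveform = field(default_factory=Waveform)
    noise_sd_uv: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_forward <= 1 and 0 <= self.p_backward <= 1):
            raise ValueError("propagation probabilities must be in [0, 1]")
        if self.background_rate < 0 or self.late_response_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0 < self.latency_low_ms < self.latency_high_ms < 5.0):
            raise ValueError("latency support must lie within (0, 5) ms")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(tag)])


@dataclass
class GroundTruth:
    """Simulated spikes with full parentage, the oracle for recovery tests.

    ``parent_kind`` holds one entry per spike: ``"background"``,
    ``"forward"`` / ``"backward"`` (propagated), ``"evoked"`` or ``"late"``.
    """

    spikes: SpikeEvents
    parent_kind: np.ndarray
    n_forward: int = 0
    n_backward: int = 0

    @property
    def true_clockwise_fraction(self) -> float:
        total = self.n_forward + self.n_backward
        return self.n_forward / total if total else float("nan")


def simulate_spontaneous(config: SimulationConfig, layout: CircuitLayout,
                         duration: float,
                         seed_spikes: list[tuple[int, float]] | None = None
                         ) -> GroundTruth:
    """Poisson background plus branching directional propagation.

    ``seed_spikes`` injects deterministic (electrode, time) parent spikes in
    addition to the Poisson background (useful with background_rate = 0 to
    study a single cascade).  Raises if the expected offspring per spike
    (p_forward + p_backward) reaches 1.5; warns from 1.0 upward
    (supercritical cascade).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    offspring = config.p_forward + config.p_backward
    if offspring >= 1.5:
        raise ValueError(f"expected offspring {offspring:.2f} >= 1.5: cascade diverges")
    if offspring >= 1.0:
        warnings.warn(f"expected offspring {offspring:.2f} >= 1: supercritical cascade",
                      stacklevel=2)
    rng = config.rng(_TAG_SPONTANEOUS)
    electrodes: list[int] = []
    times: list[float] = []
    kinds: list[str] = []
    n_forward = n_backward = 0
    for e in layout.electrodes:
        n = rng.poisson(config.background_rate * duration)
        for t in np.sort(rng.uniform(0.0, duration, size=n)):
            electrodes.append(e)
            times.append(float(t))
            kinds.append("background")
    for e, t in seed_spikes or []:
        electrodes.append(int(e))
        times.append(float(t))
        kinds.append("background")
    # branching propagation, breadth-first over the seed spikes
    queue = list(range(len(times)))
    low, high = config.latency_low_ms * 1e-3, config.latency_high_ms * 1e-3
    while queue:
        i = queue.pop(0)
        e, t = electrodes[i], times[i]
        for direction, kind in ((+1, "forward"), (-1, "backward")):
            p = config.p_forward if direction == 1 else config.p_backward
            if p > 0 and rng.random() < p:
                child_t = t + rng.uniform(low, high)
                if child_t > duration:
                    continue
                electrodes.append(layout.neighbor(e, direction))
                times.append(float(child_t))
                kinds.append(kind)
                if kind == "forward":
                    n_forward += 1
                else:
                    n_backward += 1
                queue.append(len(times) - 1)
    order = np.lexsort((electrodes, times))
    spikes = SpikeEvents(np.asarray(electrodes)[order], np.asarray(times)[order], duration)
    return GroundTruth(spikes, np.asarray(kinds, dtype=object)[order],
                       n_forward, n_backward)


def simulate_stimulation(config: SimulationConfig, layout: CircuitLayout,
                         protocol: StimulationProtocol) -> GroundTruth:
    """Stimulus-locked bands plus late Poisson activity on one circuit."""
    for band in config.evoked_bands:
        if band.mean_latency_ms > 250.0:
            raise ValueError(f"band latency {band.mean_latency_ms} ms exceeds the "
                             "250 ms post-stimulus window")
    rng = config.rng(_TAG_STIMULATION)
    circuit = layout.circuit_of[protocol.stimulated_electrode]
    ring = layout.electrodes_of(circuit)
    duration = float(protocol.pulse_times[-1] + 0.25) if protocol.n_repeats else 0.25
    electrodes: list[int] = []
    times: list[float] = []
    kinds: list[str] = []
    late_window = (250.0 - _EARLY_BAND_MS) * 1e-3
    for pulse_t in protocol.pulse_times:
        for band in config.evoked_bands:
            if band.probability > 0 and rng.random() < band.probability:
                for e in ring:
                    lat = band.mean_latency_ms
                    if band.jitter_sd_ms > 0:
                        lat += rng.normal(0.0, band.jitter_sd_ms)
                    lat = min(max(lat, 1e-3), 250.0)  # keep inside (0, 250] ms
                    electrodes.append(e)
                    times.append(float(pulse_t + lat * 1e-3))
                    kinds.append("evoked")
        if config.late_response_rate > 0:
            for e in ring:
                n_late = rng.poisson(config.late_response_rate * late_window)
                for lat in rng.uniform(_EARLY_BAND_MS * 1e-3, 0.25, size=n_late):
                    electrodes.append(e)
                    times.append(float(pulse_t + lat))
                    kinds.append("late")
    times_arr = np.asarray(times)
    keep = times_arr <= duration if times_arr.size else np.zeros(0, dtype=bool)
    order = np.lexsort((np.asarray(electrodes)[keep], times_arr[keep]))
    spikes = SpikeEvents(np.asarray(electrodes)[keep][order], times_arr[keep][order],
                         duration)
    return GroundTruth(spikes, np.asarray(kinds, dtype=object)[keep][order])


def apply_mg_suppression(config: SimulationConfig, concentration: float) -> SimulationConfig:
    """Scale rates and response probabilities by exp(-concentration / tau).

    With ``mg_exempt_early_bands`` set, bands earlier than 15 ms keep their
    probability (direct, non-synaptic responses persist under Mg block).
    """
    if config.mg_tau_mm <= 0:
        raise ValueError("mg_tau_mm must be positive")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    factor = float(np.exp(-concentration / config.mg_tau_mm))
    bands = tuple(
        band if (config.mg_exempt_early_bands and band.mean_latency_ms < _EARLY_BAND_MS)
        else replace(band, probability=band.probability * factor)
        for band in config.evoked_bands
    )
    return replace(config,
                   background_rate=config.background_rate * factor,
                   late_response_rate=config.late_response_rate * factor,
                   evoked_bands=bands)


def spike_template(waveform: Waveform, sampling_rate: float) -> tuple[np.ndarray, int]:
    """Sampled triphasic template and the index of its positive peak."""
    n_pos = max(int(round(0.4 * waveform.width_ms * 1e-3 * sampling_rate)), 3)
    n_pos += (n_pos + 1) % 2  # odd length so the sampled peak equals amplitude_uv
    n_neg = max(int(round(0.6 * waveform.width_ms * 1e-3 * sampling_rate)), 3)
    a = waveform.amplitude_uv
    lead = -waveform.lead_fraction * a * np.sin(np.pi * np.arange(n_pos) / (n_pos - 1))
    pos = a * np.sin(np.pi * np.arange(n_pos) / (n_pos - 1))
    neg = -waveform.negative_fraction * a * \
        np.sin(np.pi * np.arange(1, n_neg) / (n_neg - 1))
    template = np.concatenate([lead[:-1], pos, neg])
    return template, int(np.argmax(template))


def render_channel(spike_times: np.ndarray, config: SimulationConfig,
                   n_samples: int, sampling_rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Render one channel: stamped templates plus white Gaussian noise.

    Templates overhanging the recording edge are truncated, not an error.
    """
    if config.noise_sd_uv > 0:
        x = rng.normal(0.0, config.noise_sd_uv, size=n_samples)
    else:
        x = np.zeros(n_samples)
    template, peak = spike_template(config.waveform, sampling_rate)
    for t in np.asarray(spike_times, dtype=float):
        center = int(round(t * sampling_rate))
        start = center - peak
        lo, hi = max(start, 0), min(start + template.size, n_samples)
        if hi <= lo:
            continue
        x[lo:hi] += template[lo - start: hi - start]
    return x


def render_raw(truth: GroundTruth | SpikeEvents, config: SimulationConfig,
               layout: CircuitLayout, duration: float | None = None) -> RawRecording:
    """Render a full multichannel recording from simulated spikes."""
    spikes = truth.spikes if isinstance(truth, GroundTruth) else truth
    if duration is None:
        duration = spikes.duration
    fs = 20_000.0
    n_samples = int(round(duration * fs))
    rng = config.rng(_TAG_RENDER)
    channels = layout.electrodes
    samples = np.empty((len(channels), n_samples), dtype=np.float64)
    for i, e in enumerate(channels):
        samples[i] = render_channel(spikes.times_of(e), config, n_samples, fs, rng)
    return RawRecording(channels=channels, samples=samples, sampling_rate=fs)
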