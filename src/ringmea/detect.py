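"""Spike detection from raw extracellular voltage.

Pipeline per electrode: 2nd-order Butterworth 300 Hz high-pass (causal
forward pass by default, mimicking the online acquisition chain), robust
noise scale from the median absolute deviation (MAD / 0.6745, the Quiroga
convention), then positive peaks above ``threshold_multiplier`` (default 7)
times the noise scale.  Successive events within the dead time (default
2 ms) are discarded, keeping the earliest.  When a stimulation protocol is
supplied, a short blanking window after each pulse is excluded from the
peak search so the stimulus artifact cannot masquerade as spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import RawRecording, SpikeEvents, StimulationProtocol

__all__ = [
    "DetectionParams",
    "NoiseEstimate",
    "highpass",
    "estimate_noise",
    "detect_spikes",
    "detect",
    "MAD_GAUSSIAN_SCALE",
]

#: MAD of a unit Gaussian; dividing the MAD by this estimates sigma.
MAD_GAUSSIAN_SCALE = 0.6745


@dataclass(frozen=True)
class DetectionParams:
    highpass_cutoff: float = 300.0
    filter_order: int = 2
    threshold_multiplier: float = 7.0
    dead_time_ms: float = 2.0
    artifact_blank_ms: float = 2.0
    zero_phase: bool = False
    raw_mad_threshold: bool = False  # threshold on raw MAD instead of MAD/0.6745

    def __post_init__(self) -> None:
        if self.highpass_cutoff <= 0:
            raise ValueError("highpass_cutoff must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        if self.dead_time_ms < 0:
            raise ValueError("dead_time_ms must be >= 0")


@dataclass
class NoiseEstimate:
    """Per-electrode noise scale sigma (uV), MAD-based."""

    sigma: dict[int, float]

    def __post_init__(self) -> None:
        for e, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"negative sigma for electrode {e}")


def highpass(raw: RawRecording, params: DetectionParams = DetectionParams()) -> RawRecording:
    """High-pass filter every channel; returns a new recording."""
    nyquist = raw.sampling_rate / 2.0
    if params.highpass_cutoff >= nyquist:
        raise ValueError(
            f"cutoff {params.highpass_cutoff} Hz >= Nyquist {nyquist} Hz"
        )
    sos = signal.butter(params.filter_order, params.highpass_cutoff,
                        btype="highpass", fs=raw.sampling_rate, output="sos")
    if params.zero_phase:
        filtered = signal.sosfiltfilt(sos, raw.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, raw.samples, axis=1)
    return RawRecording(channels=list(raw.channels), samples=filtered,
                        sampling_rate=raw.sampling_rate, t0=raw.t0)


def estimate_noise_sigma(samples: np.ndarray, raw_mad: bool = False) -> float:
    """Noise scale of one filtered channel: median(|x - median(x)|) / 0.6745.

    With ``raw_mad`` the division is skipped (plain MAD).
    """
    x = np.asarray(samples, dtype=float)
    mad = np.median(np.abs(x - np.median(x)))
    sigma = float(mad if raw_mad else mad / MAD_GAUSSIAN_SCALE)
    if sigma == 0.0:
        warnings.warn("MAD is 0 (constant channel?); detection threshold would be 0",
                      stacklevel=2)
    return sigma


def estimate_noise(filtered: RawRecording,
                   params: DetectionParams = DetectionParams()) -> NoiseEstimate:
    return NoiseEstimate({
        int(e): estimate_noise_sigma(filtered.samples[i], raw_mad=params.raw_mad_threshold)
        for i, e in enumerate(filtered.channels)
    })


def _find_peaks_channel(x: np.ndarray, threshold: float, dead_samples: int,
                        blank: np.ndarray | None = None) -> np.ndarray:
    """Indices of positive peaks above threshold with dead-time enforcement.

    A peak is a strict local maximum (plateaus keep their first sample).
    Among peaks closer than the dead time, the earliest survives.
    """
    if x.size < 3:
        return np.empty(0, dtype=np.int64)
    mid = x[1:-1]
    cand = np.flatnonzero((mid > threshold) & (mid > x[:-2]) & (mid >= x[2:])) + 1
    if blank is not None and cand.size:
        cand = cand[~blank[cand]]
    if cand.size == 0:
        return cand
    kept = [int(cand[0])]
    for idx in cand[1:]:
        if idx - kept[-1] >= dead_samples:
            kept.append(int(idx))
    return np.asarray(kept, dtype=np.int64)


def _blank_mask(n_samples: int, fs: float, t0: float,
                protocol: StimulationProtocol, blank_ms: float) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    blank_samples = int(np.ceil(blank_ms * 1e-3 * fs))
    for t in protocol.pulse_times:
        start = int(np.floor((t - t0) * fs))
        if start >= n_samples or start + blank_samples < 0:
            continue
        mask[max(start, 0): min(start + blank_samples + 1, n_samples)] = True
    return mask


def detect_spikes(filtered: RawRecording, noise: NoiseEstimate,
                  params: DetectionParams = DetectionParams(),
                  protocol: StimulationProtocol | None = None) -> SpikeEvents:
    """Threshold-crossing spike detection on an already filtered recording.

    Event time is the peak sample time.  Raises if any channel's noise
    estimate is zero (the threshold would be degenerate).
    """
    fs = filtered.sampling_rate
    dead_samples = max(int(np.ceil(params.dead_time_ms * 1e-3 * fs)), 1)
    blank = None
    if protocol is not None:
        blank = _blank_mask(filtered.n_samples, fs, filtered.t0, protocol,
                            params.artifact_blank_ms)
    electrodes: list[np.ndarray] = []
    times: list[np.ndarray] = []
    for i, e in enumerate(filtered.channels):
        sigma = noise.sigma[int(e)]
        if sigma == 0.0:
            raise ValueError(
                f"electrode {e}: noise sigma is 0; inspect the channel before detection"
            )
        idx = _find_peaks_channel(filtered.samples[i], params.threshold_multiplier * sigma,
                                  dead_samples, blank)
        electrodes.append(np.full(idx.size, int(e), dtype=np.int64))
        times.append(filtered.t0 + idx / fs)
    return SpikeEvents(np.concatenate(electrodes) if electrodes else [],
                       np.concatenate(times) if times else [],
                       duration=filtered.t0 + filtered.duration)


def detect(raw: RawRecording, params: DetectionParams = DetectionParams(),
           protocol: StimulationProtocol | None = None
           ) -> tuple[SpikeEvents, NoiseEstimate]:
    """Convenience wrapper: high-pass -> noise estimate -> spike detection."""
    filtered = highpass(raw, params)
    noise = estimate_noise(filtered, params)
    return detect_spikes(filtered, noise, params, protocol), noise
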