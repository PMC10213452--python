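"""Readers and writers for the package's on-disk formats.

All formats are plain text or flat binary with a JSON sidecar, chosen to be
locale-proof and byte-deterministic:

* spike events -- tab-separated text, header ``# duration_s=<float>``, then
  ``electrode<TAB>time_s`` rows sorted by (time, electrode);
* raw recordings -- flat little-endian float32 payload (channel-major) plus
  a JSON sidecar ``{channels, sampling_rate_hz, n_samples, units}``;
* circuit layouts -- JSON ``{circuits: [{id, electrodes: {"1": id, ...}}]}``;
* stimulation protocols -- JSON mirroring :class:`~ringmea.core.StimulationProtocol`.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from .core import CircuitLayout, RawRecording, SpikeEvents, StimulationProtocol

__all__ = [
    "FormatError",
    "read_spike_events",
    "write_spike_events",
    "read_raw_recording",
    "write_raw_recording",
    "load_layout",
    "save_layout",
    "default_layout",
    "read_protocol",
    "write_protocol",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# spike events

def write_spike_events(events: SpikeEvents, path: str | Path) -> None:
    """Write a spike-event table; byte-identical output for identical input.

    Times use Python's shortest round-trip float representation, so
    ``read_spike_events(write_spike_events(x)) == x`` exactly.
    """
    lines = [f"# duration_s={events.duration!r}"]
    for e, t in zip(events.electrodes.tolist(), events.times.tolist()):
        lines.append(f"{e}\t{t!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_events(path: str | Path) -> SpikeEvents:
    path = Path(path)
    duration = None
    electrodes: list[int] = []
    times: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("duration_s="):
                    try:
                        duration = float(body.split("=", 1)[1])
                    except ValueError:
                        raise FormatError(f"{path}:{lineno}: bad duration header") from None
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                e = int(parts[0])
                t = float(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from None
            if t < 0:
                raise FormatError(f"{path}:{lineno}: negative spike time {t}")
            electrodes.append(e)
            times.append(t)
    if duration is None:
        raise FormatError(f"{path}: missing '# duration_s=' header")
    if times and max(times) > duration:
        bad = times.index(max(times))
        raise FormatError(
            f"{path}: spike time {max(times)} (event {bad + 1}) exceeds duration {duration}"
        )
    return SpikeEvents(electrodes, times, duration)


# ---------------------------------------------------------------------------
# raw recordings

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raw_recording(rec: RawRecording, path: str | Path) -> None:
    """Write the float32 payload to ``path`` and metadata to ``path + '.json'``."""
    path = Path(path)
    payload = np.ascontiguousarray(rec.samples, dtype="<f4")
    payload.tofile(path)
    meta = {
        "channels": [int(c) for c in rec.channels],
        "sampling_rate_hz": rec.sampling_rate,
        "n_samples": int(rec.n_samples),
        "units": "uV",
        "t0_s": rec.t0,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")


def read_raw_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    try:
        meta = json.loads(_sidecar_path(path).read_text())
    except FileNotFoundError:
        raise FormatError(f"missing sidecar {_sidecar_path(path)}") from None
    channels = [int(c) for c in meta["channels"]]
    n_samples = int(meta["n_samples"])
    data = np.fromfile(path, dtype="<f4")
    if data.size != len(channels) * n_samples:
        raise FormatError(
            f"{path}: payload has {data.size} samples, sidecar expects "
            f"{len(channels)} x {n_samples} = {len(channels) * n_samples}"
        )
    return RawRecording(
        channels=channels,
        samples=data.reshape(len(channels), n_samples),
        sampling_rate=float(meta["sampling_rate_hz"]),
        t0=float(meta.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# layouts

def load_layout(path: str | Path) -> CircuitLayout:
    spec = json.loads(Path(path).read_text())
    try:
        circuits = {int(c["id"]): {int(p): int(e) for p, e in c["electrodes"].items()}
                    for c in spec["circuits"]}
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed layout ({exc})") from None
    return CircuitLayout(circuits)


def save_layout(layout: CircuitLayout, path: str | Path) -> None:
    spec = {
        "circuits": [
            {"id": cid, "electrodes": {str(p): e for p, e in ring.items()}}
            for cid, ring in sorted(layout.circuits.items())
        ]
    }
    Path(path).write_text(json.dumps(spec, indent=1) + "\n")


def default_layout() -> CircuitLayout:
    """The packaged 60-electrode layout: 15 circuits x 4 electrodes."""
    with resources.files("ringmea.data").joinpath("default_layout.json").open() as fh:
        spec = json.load(fh)
    circuits = {int(c["id"]): {int(p): int(e) for p, e in c["electrodes"].items()}
                for c in spec["circuits"]}
    return CircuitLayout(circuits)


# ---------------------------------------------------------------------------
# stimulation protocols

def write_protocol(protocol: StimulationProtocol, path: str | Path) -> None:
    meta = {
        "stimulated_electrode": int(protocol.stimulated_electrode),
        "pulse_times_s": protocol.pulse_times.tolist(),
        "pulse_width_s": protocol.pulse_width,
        "amplitude_mv": protocol.amplitude_mv,
        "frequency_hz": protocol.frequency,
        "inter_set_idle_s": protocol.inter_set_idle,
    }
    Path(path).write_text(json.dumps(meta, indent=1) + "\n")


def read_protocol(path: str | Path) -> StimulationProtocol:
    meta = json.loads(Path(path).read_text())
    return StimulationProtocol(
        stimulated_electrode=int(meta["stimulated_electrode"]),
        pulse_times=np.asarray(meta["pulse_times_s"], dtype=float),
        pulse_width=float(meta.get("pulse_width_s", 400e-6)),
        amplitude_mv=float(meta.get("amplitude_mv", 500.0)),
        frequency=float(meta.get("frequency_hz", 4.0)),
        inter_set_idle=float(meta.get("inter_set_idle_s", 30.0)),
    )
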