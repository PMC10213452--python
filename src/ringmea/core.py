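"""Domain types shared by every analysis stage.

The experimental system is a 60-electrode microelectrode array (MEA) overlaid
with a PDMS microstructure that partitions the cultured neurons into 15
four-node ring circuits.  Each circuit's nodes sit on four electrodes,
numbered 1 (top-left), 2 (top-right), 3 (bottom-right), 4 (bottom-left) in
clockwise order; the microchannel geometry biases axon growth clockwise
(1 -> 2 -> 3 -> 4 -> 1).  All stages exchange spike data as ``SpikeEvents``:
a flat table of (electrode id, spike time) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ADJACENT_CLOCKWISE",
    "DIAGONAL_PAIRS",
    "CircuitLayout",
    "RawRecording",
    "SpikeEvents",
    "StimulationProtocol",
    "SessionManifest",
    "LayoutError",
]

#: Position pairs (pre, post) that correspond to clockwise propagation.
ADJACENT_CLOCKWISE = frozenset({(1, 2), (2, 3), (3, 4), (4, 1)})
#: Diagonally opposed positions: direction undefined, always discarded.
DIAGONAL_PAIRS = frozenset({(1, 3), (3, 1), (2, 4), (4, 2)})


class LayoutError(ValueError):
    """Raised when a circuit layout violates its structural invariants."""


@dataclass(frozen=True)
class CircuitLayout:
    """Maps electrode ids onto (circuit id, clockwise position 1-4).

    Parameters
    ----------
    circuits : mapping of circuit id -> {position: electrode id}
        Every circuit must define exactly the four positions 1..4 with
        distinct electrodes, and no electrode may appear in two circuits.
    """

    circuits: Mapping[int, Mapping[int, int]]
    circuit_of: Mapping[int, int] = field(init=False, repr=False)
    position_of: Mapping[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        circuit_of: dict[int, int] = {}
        position_of: dict[int, int] = {}
        frozen: dict[int, dict[int, int]] = {}
        for cid, electrodes in self.circuits.items():
            positions = {int(p): int(e) for p, e in electrodes.items()}
            if sorted(positions) != [1, 2, 3, 4]:
                raise LayoutError(
                    f"circuit {cid} must define positions 1..4, got {sorted(positions)}"
                )
            if len(set(positions.values())) != 4:
                raise LayoutError(f"circuit {cid} has duplicate electrodes")
            for pos, eid in positions.items():
                if eid in circuit_of:
                    raise LayoutError(
                        f"electrode {eid} appears in circuits {circuit_of[eid]} and {cid}"
                    )
                circuit_of[eid] = cid
                position_of[eid] = pos
            frozen[int(cid)] = positions
        object.__setattr__(self, "circuits", frozen)
        object.__setattr__(self, "circuit_of", circuit_of)
        object.__setattr__(self, "position_of", position_of)

    @property
    def electrodes(self) -> list[int]:
        """All electrode ids, sorted."""
        return sorted(self.circuit_of)

    @property
    def circuit_ids(self) -> list[int]:
        return sorted(self.circuits)

    def electrodes_of(self, circuit_id: int) -> list[int]:
        """Electrodes of one circuit in clockwise position order 1..4."""
        ring = self.circuits[circuit_id]
        return [ring[p] for p in (1, 2, 3, 4)]

    def neighbor(self, electrode: int, direction: int) -> int:
        """Ring neighbor of ``electrode``: direction +1 clockwise, -1 counter."""
        cid = self.circuit_of[electrode]
        pos = self.position_of[electrode]
        nxt = (pos - 1 + direction) % 4 + 1
        return self.circuits[cid][nxt]


@dataclass
class RawRecording:
    """A block of multichannel sampled extracellular voltage.

    ``samples`` is a (n_channels, n_samples) float array in microvolts;
    ``channels`` gives the electrode id of each row.  Acquisition in the
    modeled system runs at 20 kHz on all 60 electrodes.
    """

    channels: list[int]
    samples: np.ndarray
    sampling_rate: float = 20_000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel ids but {self.samples.shape[0]} sample rows"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, electrode: int) -> np.ndarray:
        return self.samples[self.channels.index(electrode)]


@dataclass
class SpikeEvents:
    """Detected (or simulated) spike timestamps, the pipeline's lingua franca.

    Events are stored sorted by (time, electrode).  Times are seconds from
    the start of the recording; ``duration`` is the recording span.
    """

    electrodes: np.ndarray
    times: np.ndarray
    duration: float

    def __init__(self, electrodes: Iterable[int], times: Iterable[float], duration: float):
        electrodes = np.asarray(list(electrodes) if not isinstance(electrodes, np.ndarray) else electrodes, dtype=np.int64)
        times = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=np.float64)
        if electrodes.shape != times.shape:
            raise ValueError("electrodes and times must have equal length")
        if duration < 0:
            raise ValueError("duration must be non-negative")
        if times.size:
            if times.min() < 0 or times.max() > duration:
                raise ValueError("spike times must lie within [0, duration]")
            order = np.lexsort((electrodes, times))
            electrodes = electrodes[order]
            times = times[order]
        self.electrodes = electrodes
        self.times = times
        self.duration = float(duration)

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeEvents):
            return NotImplemented
        return (
            self.duration == other.duration
            and np.array_equal(self.electrodes, other.electrodes)
            and np.array_equal(self.times, other.times)
        )

    def times_of(self, electrode: int) -> np.ndarray:
        return self.times[self.electrodes == electrode]

    def restrict(self, electrodes: Iterable[int]) -> "SpikeEvents":
        """Events on the given electrodes only (duration preserved)."""
        keep = np.isin(self.electrodes, np.asarray(sorted(set(electrodes))))
        return SpikeEvents(self.electrodes[keep], self.times[keep], self.duration)

    def electrode_ids(self) -> list[int]:
        return sorted(np.unique(self.electrodes).tolist())


@dataclass
class StimulationProtocol:
    """One electrode's stimulus train.

    The study protocol is a 400 us biphasic square pulse (+500 mV then
    -500 mV) applied at 4 Hz for 2 min, i.e. 480 repeats per stimulated
    electrode, with 30 s idle between the sets of a circuit's four
    electrodes.
    """

    stimulated_electrode: int
    pulse_times: np.ndarray
    pulse_width: float = 400e-6
    amplitude_mv: float = 500.0
    frequency: float = 4.0
    inter_set_idle: float = 30.0

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=np.float64)
        if self.pulse_times.size and np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse_times must be strictly increasing")

    @property
    def n_repeats(self) -> int:
        return int(self.pulse_times.size)

    @property
    def inter_pulse_interval(self) -> float:
        return 1.0 / self.frequency

    @classmethod
    def standard(cls, electrode: int, start: float = 0.0, frequency: float = 4.0,
                 duration: float = 120.0) -> "StimulationProtocol":
        """The standard set: ``frequency`` Hz for ``duration`` s (default 480 pulses)."""
        n = int(round(frequency * duration))
        times = start + np.arange(n) / frequency
        return cls(stimulated_electrode=electrode, pulse_times=times, frequency=frequency)


@dataclass
class SessionManifest:
    """Bookkeeping for one recording session.

    ``independent_circuits`` / ``closed_circuits`` are the microscopy-derived
    inclusion masks: circuits with stray connections to neighbors are
    excluded from all activity analyses, and the directionality statistic
    additionally requires a closed ring (axon bundle on all four electrodes).
    """

    condition: str
    div: int
    mg_concentration: float = 0.0
    spike_file: str | None = None
    raw_file: str | None = None
    protocol_file: str | None = None
    independent_circuits: list[int] | None = None
    closed_circuits: list[int] | None = None

    def __post_init__(self) -> None:
        if self.mg_concentration < 0:
            raise ValueError("mg_concentration must be >= 0")


def node_volume_nl(diameter_um: float = 170.0, height_um: float = 120.0) -> float:
    """Volume of one cylindrical PDMS node in nanoliters.

    The default geometry (170 um diameter, 120 um height) holds roughly
    2.7 nl -- negligible against the ~1 ml bath, which is why medium
    changes dilute added compounds by >1:1000 while barely disturbing the
    circuits.
    """
    if diameter_um <= 0 or height_um <= 0:
        raise ValueError("dimensions must be positive")
    volume_m3 = np.pi * (diameter_um * 1e-6 / 2.0) ** 2 * height_um * 1e-6
    return float(volume_m3 * 1e12)  # 1 m^3 = 1e12 nl


def replace_config(obj, **kwargs):
    """dataclasses.replace re-exported for convenience."""
    return replace(obj, **kwargs)
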