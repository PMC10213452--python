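"""End-to-end orchestration: simulate -> detect -> analyze -> report.

A single :class:`PipelineConfig` drives every stage.  The top-level seed
fans out deterministically to per-stage streams, so re-running an identical
config reproduces identical spike tables and statistics, and any stage can
be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect as detect_mod
from . import directionality as dir_mod
from . import dose_response as dr_mod
from . import io as io_mod
from . import simulate as sim_mod
from . import spontaneous as spont_mod
from . import stimulation as stim_mod
from .core import StimulationProtocol

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "derive_seed"]


def derive_seed(base: int, *keys: int) -> int:
    """Deterministic per-stage seed below 2**31 derived from the base seed."""
    ss = np.random.SeedSequence([int(base), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "ringmea_out"
    layout_path: str | None = None        # packaged default layout when None
    duration: float = 60.0                # spontaneous recording span (s)
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    detection: dict = field(default_factory=dict)    # DetectionParams overrides
    use_raw: bool = False                 # render raw traces and run the detector
    pairing_window_ms: float = 5.0
    post_stimulus_window_ms: float = 250.0
    independent_circuits: list[int] | None = None
    closed_circuits: list[int] | None = None
    stimulate_electrodes: list[int] = field(default_factory=list)
    stimulation_duration: float = 120.0
    mg_concentrations: list[float] = field(default_factory=list)
    analyze: bool = True

    def __post_init__(self) -> None:
        if self.pairing_window_ms <= 0 or self.post_stimulus_window_ms <= 0:
            raise ValueError("analysis windows must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        spec = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**spec)

    def sim_config(self, **extra) -> sim_mod.SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.update(extra)
        kwargs.setdefault("seed", self.seed)
        if "evoked_bands" in kwargs and kwargs["evoked_bands"] and \
                not isinstance(kwargs["evoked_bands"][0], sim_mod.EvokedBand):
            kwargs["evoked_bands"] = tuple(
                sim_mod.EvokedBand(*b) for b in kwargs["evoked_bands"])
        if "waveform" in kwargs and isinstance(kwargs["waveform"], dict):
            kwargs["waveform"] = sim_mod.Waveform(**kwargs["waveform"])
        return sim_mod.SimulationConfig(**kwargs)

    def detection_params(self) -> detect_mod.DetectionParams:
        return detect_mod.DetectionParams(**self.detection)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = (io_mod.load_layout(config.layout_path) if config.layout_path
              else io_mod.default_layout())
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": []}

    # --- simulate spontaneous activity -------------------------------------
    sim_config = config.sim_config(seed=derive_seed(config.seed, 1))
    truth = sim_mod.simulate_spontaneous(sim_config, layout, config.duration)
    io_mod.write_spike_events(truth.spikes, outdir / "spikes_true.tsv")
    (outdir / "ground_truth.json").write_text(json.dumps({
        "n_spikes": len(truth.spikes),
        "n_forward": truth.n_forward,
        "n_backward": truth.n_backward,
        "true_clockwise_fraction": truth.true_clockwise_fraction,
    }, indent=1) + "\n")
    manifest["stages"].append("simulate")
    events = truth.spikes

    # --- optional raw rendering + detection --------------------------------
    if config.use_raw:
        raw = sim_mod.render_raw(truth, sim_config, layout)
        filtered = detect_mod.highpass(raw, config.detection_params())
        noise = detect_mod.estimate_noise(filtered, config.detection_params())
        events = detect_mod.detect_spikes(filtered, noise, config.detection_params())
        io_mod.write_spike_events(events, outdir / "spikes_detected.tsv")
        (outdir / "noise_sigma.json").write_text(
            json.dumps({str(k): v for k, v in sorted(noise.sigma.items())}, indent=1) + "\n")
        manifest["stages"].append("detect")

    if not config.analyze:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        return manifest

    # --- spontaneous metrics ------------------------------------------------
    included = spont_mod.included_electrodes(layout, config.independent_circuits)
    fr = spont_mod.firing_rate_table(events, included)
    _write_tsv(fr, outdir / "spontaneous_electrodes.tsv")
    fr_grouped = fr.assign(condition="simulated", div=0)
    _write_tsv(spont_mod.aggregate_condition(fr_grouped),
               outdir / "spontaneous_summary.tsv")
    manifest["stages"].append("spontaneous")

    # --- directionality -----------------------------------------------------
    active = set(fr.loc[fr["active"], "electrode"].tolist())
    circuits = (config.closed_circuits if config.closed_circuits is not None
                else (config.independent_circuits
                      if config.independent_circuits is not None
                      else layout.circuit_ids))
    pairs_by_circuit = {
        cid: dir_mod.extract_pairs(events, layout.electrodes_of(cid), layout,
                                   config.pairing_window_ms, active)
        for cid in circuits
    }
    summary = dir_mod.clockwise_summary(pairs_by_circuit)
    _write_tsv(summary, outdir / "directionality_circuits.tsv")
    group = dir_mod.group_clockwise(summary)
    (outdir / "directionality_group.json").write_text(
        json.dumps(group, indent=1, default=float) + "\n")
    fmap_rows = []
    for cid, pairs in pairs_by_circuit.items():
        counts, _ = dir_mod.frequency_map(pairs)
        for pre in range(4):
            for post in range(4):
                fmap_rows.append({"circuit": cid, "pre_pos": pre + 1,
                                  "post_pos": post + 1, "count": int(counts[pre, post])})
    _write_tsv(pd.DataFrame(fmap_rows), outdir / "frequency_maps.tsv")
    manifest["stages"].append("directionality")

    # --- stimulation --------------------------------------------------------
    if config.stimulate_electrodes:
        rows = []
        raster_rows = []
        for k, electrode in enumerate(config.stimulate_electrodes):
            protocol = StimulationProtocol.standard(
                electrode, duration=config.stimulation_duration)
            stim_config = config.sim_config(seed=derive_seed(config.seed, 2, k))
            stim_truth = sim_mod.simulate_stimulation(stim_config, layout, protocol)
            cid = layout.circuit_of[electrode]
            raster = stim_mod.build_raster(stim_truth.spikes,
                                           layout.electrodes_of(cid), protocol,
                                           config.post_stimulus_window_ms)
            rows.append(stim_mod.classify_activity_inducing(raster))
            raster_rows.append(raster.table.assign(stimulated_electrode=electrode))
        per_electrode = pd.DataFrame(rows)
        _write_tsv(per_electrode, outdir / "stimulation_electrodes.tsv")
        _write_tsv(pd.concat(raster_rows, ignore_index=True),
                   outdir / "stimulation_raster.tsv")
        _write_tsv(stim_mod.group_stimulation_summary(per_electrode),
                   outdir / "stimulation_summary.tsv")
        manifest["stages"].append("stimulation")

    # --- dose response ------------------------------------------------------
    if config.mg_concentrations:
        sessions = []
        for k, conc in enumerate(config.mg_concentrations):
            step_config = config.sim_config(seed=derive_seed(config.seed, 3, k))
            # suppression scales with concentration above the medium baseline
            suppressed = sim_mod.apply_mg_suppression(
                step_config, max(conc - dr_mod.BASELINE_MG_MM, 0.0))
            step_truth = sim_mod.simulate_spontaneous(suppressed, layout,
                                                      config.duration)
            mfr = np.asarray([spont_mod.mean_firing_rate(step_truth.spikes, e)
                              for e in included])
            sessions.append((float(conc), mfr))
        curve = dr_mod.build_curve(sessions)
        fit = dr_mod.fit_exponential(curve)
        trend = dr_mod.trend_test(curve)
        _write_tsv(pd.DataFrame({
            "mg_mm": curve.concentrations, "mean": curve.means,
            "sem": curve.sems, "n": curve.ns}), outdir / "dose_response.tsv")
        (outdir / "dose_response_fit.json").write_text(json.dumps({
            "amplitude": fit.amplitude, "tau_mm": fit.tau_mm, "rss": fit.rss,
            "no_decay": fit.no_decay,
            "trend_p": trend.p_value, "trend_S": trend.statistic,
        }, indent=1, default=float) + "\n")
        manifest["stages"].append("dose_response")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def make_report(outdir: str | Path) -> list[Path]:
    """Render figures/tables from a pipeline output directory.

    Emits PNG figures next to the tables; returns the paths written.
    Requires at least one analysis table in ``outdir``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: list[Path] = []
    found_any = False

    circuits_path = outdir / "directionality_circuits.tsv"
    if circuits_path.exists():
        found_any = True
        summary = pd.read_csv(circuits_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3))
        valid = summary.dropna(subset=["percent_clockwise"]) if len(summary) else summary
        if len(valid):
            ax.bar(valid["circuit"].astype(str), valid["percent_clockwise"])
            ax.axhline(50, color="gray", ls="--", lw=0.8)
            ax.set_ylabel("% clockwise pairs")
            ax.set_xlabel("circuit")
        else:
            ax.text(0.5, 0.5, "no directional pairs", ha="center", va="center")
            ax.set_axis_off()
        fig.tight_layout()
        path = outdir / "directionality.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    raster_path = outdir / "stimulation_raster.tsv"
    if raster_path.exists():
        found_any = True
        raster = pd.read_csv(raster_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        if len(raster):
            ax.plot(raster["latency_ms"], raster["repeat"], ".", ms=1.5)
        ax.set_xlabel("latency after stimulus (ms)")
        ax.set_ylabel("stimulus repeat")
        ax.invert_yaxis()
        fig.tight_layout()
        path = outdir / "stacked_raster.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    dr_path = outdir / "dose_response.tsv"
    if dr_path.exists():
        found_any = True
        curve = pd.read_csv(dr_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.errorbar(curve["mg_mm"], curve["mean"], yerr=curve["sem"], marker="o")
        ax.set_xlabel("Mg2+ (mM)")
        ax.set_ylabel("mean firing rate (Hz)")
        fig.tight_layout()
        path = outdir / "dose_response.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if not found_any:
        raise FileNotFoundError(f"no analysis tables found in {outdir}")
    return written
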