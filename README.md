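# ringmea

Spike-train analysis for small, topologically constrained neuronal circuits
on microelectrode arrays (MEAs).

## The problem

Cultured neurons can be confined by PDMS microstructures into small ring
circuits: four nodes of somata sit on four MEA electrodes, connected by
microchannels whose geometry biases axon growth clockwise
(1 → 2 → 3 → 4 → 1). Because action potentials travel from soma to synapse,
clockwise wiring should produce predominantly clockwise spike propagation —
a property that makes such circuits attractive, reproducible readouts for
pharmacology. `ringmea` implements the analysis chain for this kind of
preparation:

* **Spike detection** — 2nd-order Butterworth 300 Hz high-pass, per-electrode
  noise scale σ = MAD/0.6745 (Quiroga convention), positive peaks above 7σ,
  2 ms dead time, optional stimulus-artifact blanking.
* **Spontaneous activity** — mean firing rate MFR = spike count / duration;
  an electrode is *active* if MFR > 0.1 Hz; per-condition percent-active and
  mean MFR over active electrodes (± SEM).
* **Directionality** — merge a circuit's active-electrode spike trains;
  every consecutive pair with Δt < 5 ms (≈ one synaptic latency) is a spike
  pair. Adjacent-electrode pairs are clockwise (1–2, 2–3, 3–4, 4–1) or
  counter-clockwise; same-electrode and diagonal (1–3, 2–4) pairs carry no
  direction. Per circuit: % clockwise = 100·n_cw/(n_cw+n_ccw); group
  statistics average circuits unweighted.
* **Stimulation** — 480 biphasic pulses at 4 Hz per electrode; spikes on all
  four circuit electrodes within 250 ms of each pulse form a stacked raster;
  an electrode is *activity-inducing* if the set evokes ≥ 480 spikes
  (≥ 1 per stimulus on average).
* **Mg²⁺ dose-response** — stepwise MgCl₂ additions (0.81 → 10.81 mM nominal),
  MFR / evoked-count curves per concentration, exponential decay fit
  A·exp(−c/τ), Mann–Kendall trend test, recovery comparison after medium
  exchange.
* **Statistics** — self-contained two-proportion Z, Mann–Whitney U (exact
  permutation tail on small samples, tie-aware), Mann–Kendall (exact tail
  for n ≤ 10), Fisher's method.
* **Simulator** — Poisson background firing, clockwise-biased branching
  propagation with sub-5 ms latencies, stimulus-locked response "bands",
  exponential Mg²⁺ suppression, and raw-trace rendering (triphasic spike
  template + Gaussian noise) with full ground truth, used to validate every
  stage by parameter recovery.

## Worked example

```python
import ringmea
from ringmea import simulate, spontaneous, directionality

layout = ringmea.default_layout()            # 15 ring circuits, 60 electrodes
config = simulate.SimulationConfig(seed=1)   # 2 Hz background, p_fwd/p_bwd = 3:1
truth = simulate.simulate_spontaneous(config, layout, duration=300.0)

fr = spontaneous.firing_rate_table(truth.spikes, layout.electrodes)
active = set(fr.loc[fr["active"], "electrode"])
pairs = {c: directionality.extract_pairs(truth.spikes, layout.electrodes_of(c),
                                         layout, active_electrodes=active)
         for c in layout.circuit_ids}
group = directionality.group_clockwise(
    directionality.clockwise_summary(pairs))
print(f"{truth.true_clockwise_fraction:.1%} of propagations were clockwise")
print(f"recovered {group['mean_percent_clockwise']:.1f}% "
      f"± {group['sem_percent_clockwise']:.1f}% clockwise pairs "
      f"over {group['n_circuits']} circuits")
```

prints

```
74.7% of propagations were clockwise
recovered 74.0% ± 0.3% clockwise pairs over 15 circuits
```

i.e. with the default 3:1 clockwise propagation bias the pair statistic
recovers the generating asymmetry to within a point; background
coincidences (classified 50/50) pull it slightly toward chance.

The same stages are exposed as a CLI: `ringmea simulate | detect |
spontaneous | directionality | stimulate-analyze | stats | report`, plus
`ringmea run` which drives the full chain (including the Mg²⁺ dose-response
sweep) from a YAML config.

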