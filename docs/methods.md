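# Methods

This note documents the models implemented in `ringmea`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Data model

Recordings come from 60-electrode MEAs sampled at 20 kHz, partitioned by a
PDMS microstructure into 15 four-node ring circuits (positions 1–4 in
clockwise order; position 1 top-left). Electrode ids are opaque integers;
the analysis never uses MEA geometry beyond the ring adjacency, so
physical coordinates are not modeled. All stages exchange `SpikeEvents`
tables of (electrode, time) pairs; times are seconds, defined as the time
of the detected peak sample. On-disk formats are plain text (TSV with a
duration header for spike events, JSON for layouts/protocols) or flat
little-endian float32 with a JSON sidecar for raw voltage; vendor
acquisition formats are out of scope.

## Spike detection

Each channel is high-pass filtered (Butterworth, 2nd order, 300 Hz cutoff)
as a **causal forward pass** by default, mimicking an online acquisition
chain; the sub-millisecond phase lag is irrelevant at the 5 ms pairing
scale. A zero-phase (forward–backward) option exists behind
`DetectionParams.zero_phase` for users who prefer symmetric filtering.

The per-electrode noise scale is σ = median(|x − median(x)|)/0.6745 — the
MAD normalized to estimate a Gaussian standard deviation. The threshold is
7σ by convention; whether the original convention normalized the MAD is
ambiguous in the field, so `raw_mad_threshold` switches to 7·MAD without
the 0.6745 division. Spikes are **positive** strict local maxima above
threshold (plateaus keep their first sample, a deterministic tie-break);
among events closer than the 2 ms dead time the earliest survives, scanning
in time order. Detection with a zero σ (a dead or clipped channel) is a
hard error rather than a silent empty result. When a stimulation protocol
is supplied, 2 ms after each pulse onset is blanked from the peak search;
without blanking, a rendered ±500 mV artifact would dominate detection.
Multiunit activity per electrode is treated as one stream — no spike
sorting, no negative-peak detection.

## Spontaneous metrics

MFR = count/duration per electrode; *active* means MFR strictly above
0.1 Hz. Group summaries report percent active over all included electrodes
and mean MFR over **active electrodes only**; an empty active set yields an
absent (NaN) mean, never 0, so condition curves are not biased downward.
SEM uses n−1 and is absent for n = 1. Circuit independence (stray
connections to neighbors) is assessed by microscopy in this kind of
experiment and cannot be automated from spike data; it enters the analysis
as an explicit per-circuit inclusion mask.

## Directionality statistic

Within one circuit, the spike trains of the active electrodes are merged
into a single time-sorted stream. Every pair of **consecutive** spikes with
Δt strictly below 5 ms — an upper bound for one synaptic latency between
these neurons — is a spike pair; pairs overlap, so a chain of k close
spikes yields k−1 pairs. Classification depends only on ring positions:
clockwise (1→2, 2→3, 3→4, 4→1), counter-clockwise (reverse), same-electrode
or diagonal (1↔3, 2↔4); the latter two carry no direction and are excluded
from the clockwise percentage but pooled into the non-directional fraction.
Spikes with identical timestamps on different electrodes (possible after
20 kHz discretization) are ordered by ascending position, flagged
ambiguous, and excluded from directional counts, since their order is
genuinely undefined. Per circuit, % clockwise = 100·n_cw/(n_cw + n_ccw);
the group statistic is the **unweighted** mean over circuits (not pooled
counts), with circuits lacking directional pairs excluded and tallied. The
statistic describes propagation asymmetry only; it supports no causal
claims about information flow between electrodes.

## Stimulation analysis

A stimulation set is 480 repeats of a biphasic pulse at 4 Hz on one
electrode (2 min), with 30 s idle between the four electrodes of a circuit.
Spikes on all four circuit electrodes with latency in (0, 250] ms after a
pulse belong to that pulse; 250 ms equals the inter-pulse interval, so
windows tile the set and assignment is unique. The interval is open at 0
because a spike at the exact pulse sample is indistinguishable from
artifact. The stimulated electrode's own spikes are included in the
four-electrode sum; its trace is protected by artifact blanking instead of
exclusion. An electrode is *activity-inducing* iff the set total reaches
480 spikes — an exact integer comparison. Automated detection of latency
"bands" in the stacked raster is deliberately out of scope.

## Mg²⁺ dose-response

The addition arithmetic carries both the exact dilution
(c·V + c_stock·v)/(V + v) and the nominal bookkeeping value
c + c_stock·v/V; curves are indexed by the nominal concentrations
(0.81, 3.31, 5.81, 8.31, 10.81 mM) because those are the protocol's printed
values. The exact value is always ≤ nominal and agrees within 1% when the
added volume is below 1% of the bath.

The mean trace is fitted with A·exp(−c/τ) by least squares with a
deterministic initialization (A₀ = mean at the lowest concentration,
τ₀ = concentration span) refined to relative tolerance 1e−8; with 5-point
traces this is well conditioned. All-equal means are reported as a no-decay
flag (τ = ∞) rather than a huge number; non-positive means warn and fall
back to the direct nonlinear fit (no log transform). A no-offset decay is
fitted; an offset term could absorb a Mg-resistant activity floor but is
not identifiable from 5 points. Trend over concentrations uses the
Mann–Kendall test on the means (default one-sided, downward); recovery
after the final medium exchange is compared to the initial session with
the Mann–Whitney U test. The coefficient of variation, 100·sd/mean (n−1),
quantifies stability of a metric across repeated perturbations.

## Statistical tests

Implemented self-contained so every reported number is auditable; scipy
supplies only Φ and the χ² survival function.

* **Two-proportion Z** — pooled variance; a pooled proportion of 0 or 1 is
  degenerate and returns p = 1 with a warning. The unpooled variant is not
  implemented; pooled is the standard form for a shared-null comparison.
* **Mann–Whitney U** — midranks for ties. For n·m ≤ 400 the p-value is
  exact: a dynamic program over the observed (doubled) midranks counts all
  C(n+m, n) assignments, so ties are handled exactly, conditional on the
  observed values. Larger samples use the normal approximation with tie
  correction and continuity correction. Two-sided p = 2·min(tails), capped
  at 1.
* **Mann–Kendall** — S = Σ_{i<j} sign(x_j − x_i), applied to short ordered
  sequences of group means (weekly development, concentration steps). For
  n ≤ 10 without ties the exact null tail comes from the classical
  inversion-count recursion (S = n(n−1)/2 − 2·inversions under the
  permutation null); otherwise the tie-corrected normal approximation with
  continuity correction.
* **Fisher's method** — χ² = −2Σ ln p on 2k df. A zero input p-value warns
  and returns 0.

No multiple-testing correction is applied by default, matching how such
pairwise comparisons are conventionally reported in this setting.

## Synthetic-recording generator

The generator produces data with exactly the statistical structure the
analysis assumes, plus full ground truth, enabling parameter-recovery
validation of every stage.

* **Background**: homogeneous Poisson per electrode, default 2 Hz — within
  the 2–4 Hz range typical of mature glia-containing circuits and low
  enough that chance coincidences only mildly dilute the pair statistic.
* **Propagation**: each spike independently triggers its clockwise neighbor
  with p_forward (default 0.3) and counter-clockwise with p_backward
  (default 0.1) after a U(0.5, 4.5) ms latency; propagated spikes propagate
  again (branching cascade; expected offspring ≥ 1 warns, ≥ 1.5 is an
  error). The defaults give a generating clockwise fraction of exactly
  0.75, matching the strong clockwise bias such microstructures produce.
  The latency support is capped at 4.5 ms — strictly inside the 5 ms
  pairing window — so the ground truth and the statistic coincide in the
  noiseless limit, with the 0.5 ms gap absorbing detection timing error.
* **Evoked responses**: per pulse and per band, all four circuit electrodes
  fire with the band's probability at its mean latency plus Gaussian
  jitter; independent Poisson "late" activity covers 15–250 ms. The default
  band (5 ms, 0.5 ms jitter, p = 0.8) plus 4 Hz late rate makes a healthy
  circuit activity-inducing, as mature circuits typically are.
* **Mg²⁺ suppression**: rates and band probabilities scale by
  exp(−c/τ), default τ = 3 mM, which reproduces the qualitative
  observation that activity is nearly abolished around 8 mM above baseline.
  The functional form is a modeling choice — it mirrors the exponential
  *fit* used in the analysis, not a measured dose-response law. A flag
  exempts bands earlier than 15 ms, emulating direct (non-synaptic)
  responses that persist under Mg²⁺ block.
* **Rendering**: each spike stamps a triphasic template — small leading
  dip (25% of the peak), positive peak of 40 µV exactly at the spike time,
  40% repolarization lobe, 0.6 ms total — onto its channel, plus white
  Gaussian noise (default 4 µV), at 20 kHz. Edge-overhanging templates are
  truncated. The stimulus artifact is **not** rendered by default; the
  detector's blanking exists for data that contains one.

Every operation draws from its own RNG stream derived from
(config seed, operation tag), so identical inputs reproduce identical
outputs stage by stage, and the full pipeline fans one top-level seed out
to per-stage streams.

What the generator does **not** emulate: bursting and network
synchronization, rate non-stationarity over minutes, electrode-to-electrode
gain differences, correlated or non-Gaussian noise, waveform diversity and
overlapping multiunit waveforms, and real synaptic dynamics (the cascade is
memoryless). Passing recovery tests therefore demonstrates that the
analysis correctly measures the quantities it defines — not that those
quantities capture every property of biological recordings.

## Validation studies and problem sizes

`ringmea.validation` runs the recovery studies the test suite asserts on
and the reproduction script reports: detector recall/precision on 60
rendered channels × 300 s at a 10× peak-to-noise ratio (recall and
precision both ≥ 95%, timing error ≤ 0.25 ms in practice ≤ 0.08 ms);
clockwise recovery over 20 circuits × 300 s (recovered ≈ 74–75% against
the generating 75%, null ≈ 50%); the activity-inducing sweep over response
probabilities {0.1, 0.5, 1.0} (boundary at p = 0.25, configurations ≥ 3 SD
from it); type-I error of the three tests over 2000 null replicates
(Binomial(100, ½) proportions, Gaussian 10-vs-10 samples, Gaussian
length-10 sequences — length 10 chosen because the exact Mann–Kendall test
attains its least conservative size there, 0.047); and τ recovery from 10
simulated five-concentration sessions with 20 electrodes × 300 s each
(median within a few percent of the generating 3 mM). These sizes keep the
entire suite under a minute of simulation while leaving comfortable
statistical margins.

## Known limitations

* Detection assumes positive spike peaks; preparations with
  negative-dominant waveforms need inverted input.
* The exact Mann–Whitney path is quadratic in rank-sum support and is
  capped at n·m ≤ 400; beyond that the normal approximation is used.
* The pair statistic is a descriptive asymmetry measure; it does not
  estimate connectivity, latency distributions, or causality.
* The dose-response fit assumes a monotone exponential; non-monotone
  pharmacology (e.g. biphasic modulators) would need a different model.
* Circuit inclusion masks are inputs; the package does not attempt to
  infer circuit independence or closedness from electrophysiology.
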