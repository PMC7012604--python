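# Methods

This note records the models implemented in `olivenet`, the parameters that
matter, and the design choices made where the underlying procedures were
genuinely open.

## Network model

Neurons are point somata placed i.i.d. uniformly in a 3D box (defaults:
1134 neurons in 250 × 500 × 200 µm, i.e. 0.045 neurons per (10 µm)³; the
smaller validation network uses 180 neurons in 125 × 250 × 100 µm, 0.057 per
(10 µm)³ — densities are reported truncated to three decimals, and "per
10 µm³" is read as per (10 µm)³ = 1000 µm³, the only reading consistent with
both printed densities). Spatial clusters come from k-means on positions
with `k = round(n / cluster_size)` (minimum 1), k-means++ seeding and 10
restarts keeping the best inertia. Each unordered pair `(i, j)` at Euclidean
distance `x` µm is then connected independently with probability

P(x) = Σ · exp(−x² / (2σ²)) / 100,

with `Σ` in percent (the probability at zero distance) and `σ` in µm, using
the within-cluster `(Σ_w, σ_w)` when the two neurons share a cluster label
and `(Σ_b, σ_b)` otherwise. The defaults Σ_w/σ_w = 77/45, Σ_b/σ_b = 15/20,
clusters of 40, give a mean degree of ~13 (range ~11–21 over seeds). A
distance-only network is the special case Σ_w = Σ_b, σ_w = σ_b.

`matched_distance_only_profile` solves, in closed form, the single-profile Σ
that reproduces a target mean degree at a chosen σ (the expected degree is
linear in Σ given the sampled positions). Matching is only feasible when the
target degree is reachable with Σ ≤ 100; for the default clustered network
this requires σ ≳ 29 µm. **The zero-common-neighbor contrast between
architectures depends on this σ**: for a steep distance-only profile
(σ ≤ ~35 µm, as in experimentally measured connection-probability curves)
the clustered network has a clearly larger fraction of nearby (≤ 40 µm)
pairs with no shared neighbor, while for shallow profiles (σ ≥ 45 µm) the
distance-only network catches up. The package therefore uses σ = 35 µm as
the matched distance-only reference; the Monte Carlo Fisher comparison of
full common-neighbor histograms separates the two architectures across this
whole σ range regardless.

## Event-based simulation

Firing rates are drawn per neuron from a normal distribution truncated at
zero by redrawing (defaults 0.058 ± 0.04 Hz); spike trains are independent
homogeneous Poisson processes over the recording duration (default 15 min).
A second firing mode, `uniform_count`, gives every neuron exactly
`round(rate · duration)` spikes at uniform times: under equal per-neuron
counts and source-resolved grouping the connection estimator is *exactly*
the true degree (T·N/C = r·(deg − coupled)·N/(r·N), plus the coupled flag),
an identity the tests exercise exhaustively on small graphs. Under Poisson
firing the identity holds only on average, and per-pair error shrinks with
recording duration.

Spikelet transmission is phenomenological: an action potential appears
instantaneously in every coupled neighbor as an event of amplitude
`cc(edge) × 60 mV`, with one symmetric coupling coefficient per edge drawn
from N(0.03, 0.019) truncated below at 0.001. No membrane dynamics,
subthreshold-oscillation coupling or spike interactions are modeled — the
estimator's logic depends only on event times, amplitudes and source
identities. Spikelets sourced from the recorded partner are excluded from a
cell's spikelet table; the direct connection enters only through the
`coupled` flag and the estimator's +1 term.

## The connections-per-cell estimator

`estimate_connections(T, N, C, coupled)` returns
`floor(T·N/C + coupled)`. Flooring is the only rounding consistent with both
printed worked examples (7 from raw 7.25 and 13 from raw 13.0). Pairs with
`C = 0` are *flagged undefined*, never silently dropped; population averages
are taken over defined pairs only.

In realistic (amplitude-based) grouping, matched common spikelets are
clustered in the (amplitude in A, amplitude in B) plane. Chance coincidences
— independent spikelets landing within the 8 ms window — scatter in this
plane, and even a single surviving chance "group" grossly inflates T·N/C.
Real shared sources instead repeat: over a 15-minute recording at 0.058 Hz a
source contributes ~50 common spikelets. Groups smaller than
`max(2, ceil(0.1 · rate · duration))` members are therefore discarded as
chance (in `analyze_pair` the default floor is 2, matching the 2–7 member
groups seen in short experimental recordings, and is configurable). This
plays the role of the manual verification applied to experimental groups.

## Synthetic traces

Event waveforms use a gamma-family kernel `g(t) ∝ (t/t_p)^m e^{−m(t/t_p − 1)}`
(peak 1 at `t_p = m·τ`). The 10–90% rise to half-width ratio of this family
is monotone in `m` and spans ~0–0.7, covering both event classes; a
difference-of-two-exponentials kernel was rejected because its ratio is
bounded by ~0.233, below the fast-event target of 1.4/4.2 = 0.33. The shape
`m` is solved by bisection on the rise/half-width ratio and the time scale
set from the half-width; round-trip error of measured indices is well under
5% at 10–20 kHz sampling.

Default populations follow the measured statistics: slow events
(spikelets) 1.2 ± 0.3 mV, rise 2.5 ± 0.6 ms, half-width 12.7 ± 3.9 ms; fast
events uniform 4.5–15.3 mV, rise 1.4 ± 0.4 ms, half-width 4.2 ± 1.3 ms.
Traces are linear superpositions of kernels plus white Gaussian noise
(default SD 0.1 mV at 10 kHz — SNR ≈ 12 for a default slow event; the
recorded noise floor is not published, so this is a convention). Paired
traces give every (source, recorder) edge a single fixed waveform so
amplitude grouping is possible; action potentials are rendered as 60 mV
fast deflections (truncated in plots only). Oscillating traces superpose a
sinusoid (default 5 Hz, i.e. 200 ms period) and confine spikelets to
±25 ms around its peaks.

What the generator does *not* emulate: correlated/oscillation-locked firing
across neurons, voltage-dependent waveform changes, electrode artifacts,
baseline drift, or amplitude attenuation variability within an edge.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under the stated noise model, not performance on real recordings.

## Detection and classification

Events are peaks of the Gaussian-smoothed (SD 0.5 ms), baseline-subtracted
trace exceeding `threshold_sd` (default 5) times the smoothed-noise SD in
both height and prominence, separated by ≥ 5 ms. The baseline is a running
median (median of 5 ms block medians over a 50 ms window); noise SD is
estimated robustly from the MAD. The detector design is this package's own —
thresholds live in `DetectorConfig`. For oscillation-dominated traces a
low-pass-filtered copy (default cutoff 20 Hz for detection; 2 Hz for the
autocorrelation detrending, both configurable since no published value
exists) is subtracted first.

Shape indices are measured on raw samples with linear interpolation:
amplitude from a local pre-event median baseline to the peak, 10–90% rise,
width at 50% and at 20% of amplitude; events whose crossings run off the
trace are flagged `clipped`. Classification runs k-means on standardized
(amplitude, rise, half-width) with k chosen by silhouette over 2..max_k;
below a silhouette of 0.5 the events are treated as one population. Multiple
waveform clusters are merged into the two physiological classes (fast /
slow) by 2-means on their kinetics centroids, slow = longer rise and width.

## Statistics

The Monte Carlo Fisher exact test samples tables from the margin-conditional
null (vectorized multivariate hypergeometric for 2×K tables; label
shuffling for general R×C) and uses the table's hypergeometric probability
as the extremity statistic, counting ties as extreme (criterion ≤, with a
small numerical tolerance). The observed table joins the replicate pool, so
p = (1 + #extreme)/(R + 1) ∈ (0, 1]; the default is 100,000 replicates. The
per-distance-bin comparison applies scipy's exact 2×2 Fisher test per 10 µm
bin (empty bins skipped with a warning) and combines with Fisher's method
(−2Σln p ~ χ² on 2·bins df). The goodness-of-fit route rescales expected
counts to the observed totals per column and merges sparse far-distance
cells (connected: 60–100 µm pooled; non-connected: 80–100 µm pooled) before
a χ² test, warning if any expected cell stays below 5.

## Problem sizes and tolerances

Simulation-based tests use the study conditions (15 min, 0.058 Hz,
CC 0.03 ± 0.019) on the 180-neuron validation network, with 20 recorded
pairs and 3–10 seeds per property; architecture comparisons use the
full-size 1134-neuron network with 300 sampled pairs per seed and 20 seeds.
Stochastic assertions use 3-standard-error bands against closed-form
oracles; the estimator-validation band (±30% on the mean) reflects the
estimator's intrinsic Poisson-count variance at these rates.

## Known limitations

- Coupling coefficients are symmetric per edge; real gap junctions can be
  asymmetric.
- The chance-group filter assumes roughly stationary firing; bursty sources
  would need a different null.
- `fit_gaussian_profile` treats per-bin probabilities as homoscedastic;
  for small tested-pair counts a weighted fit would be preferable.
- Detection operates on depolarizing events only.
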