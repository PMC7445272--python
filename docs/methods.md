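# Methods

This note documents the models, statistics and numerical choices behind
`gridhead`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic benchmarks do and do not
demonstrate.

## Scientific setting

Medial entorhinal grid cells fire at the vertices of a triangular lattice
covering the environment. "Pure" grid cells have classically been treated
as omnidirectional, in contrast to conjunctive grid × head-direction
cells, which fire only around one preferred head direction. The analyses
implemented here quantify a subtler phenomenon: individual firing fields
of pure grid cells can each be tuned to their own set of head directions
(multidirectional, local tuning). The package provides

1. the classification scores used to separate grid, head-direction,
   conjunctive and other cells;
2. firing-field segmentation;
3. circular statistics for directional tuning, including a shuffle test
   that controls for the *distributive hypothesis* — apparent directional
   tuning created purely by uneven directional sampling across a
   location-tuned field;
4. a generative model in which a downstream integrator neuron receives
   input from co-aligned conjunctive cells, with per-field input rates
   either uniform or non-uniform — the mechanism that reproduces local
   directional tuning;
5. a synthetic-session generator so all of the above is testable without
   recorded data.

## Session model and synthetic data

A session is a video-rate trajectory (time, x, y, head direction; default
30 Hz) plus per-cell spike times. Spike kinematics are attached by linear
interpolation of position and circular-linear interpolation of head
direction. Occupancy time is counted as frames/frame-rate.

Cleaning rules (real tracking data is imperfect; defaults are stated, not
claimed to match any published pipeline): samples outside the arena are
clipped to its bounds; missing-sample gaps up to 0.5 s are interpolated
(circularly for head direction); longer gaps are rejected so the caller
can segment the session. Running speed uses central differences smoothed
with a 250 ms boxcar.

The trajectory generator is a minimal forager model: speed is an
Ornstein–Uhlenbeck process around a mean running speed (default
25 cm/s, SD 8 cm/s, relaxation 1 s); heading performs a circular random
walk whose circular autocorrelation decays exponentially with the
persistence time τ (default 2 s) — a wrapped Brownian rotation with
diffusion D = 2/τ, the simplest process with controllable persistence
(an Ornstein–Uhlenbeck pull toward a fixed mean heading would be
unnatural for a forager and was rejected). Walls reflect position and
heading. Head direction is heading plus wrapped Gaussian noise (15° SD),
reflecting that head and movement direction are aligned only
approximately. The defaults were chosen once so that a 25-minute session
visits every bin of the 42 × 42 occupancy grid with an occupancy
coefficient of variation well below 1, the regime the analyses assume.
What the generator does **not** emulate: rest periods, thigmotaxis
(border over-sampling), place preferences, and systematic coupling
between position and head direction. Tests passing on this generator
therefore demonstrate correctness of the statistics under clean sampling,
not robustness to every behavioural bias of real animals; the
distributive-shuffle machinery exists precisely because real sampling is
biased.

Ground-truth cells define rate as
`baseline + Σ_f peak_f · G(‖r−c_f‖) · H_f(hd)` with G a circular Gaussian
parameterised by its spatial FWHM and H_f a per-field directional gain
(1 for omnidirectional fields; one Gaussian bump for conjunctive cells; a
bump mixture for multidirectional cells, normalised to max 1 per field).
All directional Gaussians throughout the package are evaluated on the
minimal circular difference. Spikes are Bernoulli draws on a 1 ms grid
(p = rate·dt), which is Poisson-like at the rates used; parameterisations
with rate·dt > 1 are rejected.

## Classification scores

*Rate map*: 42 × 42 bins over the arena; spike-count and occupancy
surfaces are separately smoothed with a Gaussian kernel (σ = 1 bin,
truncated at 3σ, zero-padded) and divided. Bins never visited are
undefined (NaN). One map scheme serves classification and field
detection.

*Autocorrelogram*: Pearson correlation of the map with itself at every
integer (row, col) shift, using unmasked overlapping bins; shifts with
fewer than 20 overlapping bins are undefined.

*Grid score*: the autocorrelogram is normalised to its peak and
binarised at 20% of the peak (a min–max rescaling would put the cut near
r ≈ −0.56 and fuse the surface into one component, leaving the score
undefined even for a perfect lattice). Local maxima are connected
components of the binary array, each represented by its highest bin. If
more than seven maxima exist, the annulus [0.25·d̄, 1.25·d̄] around the
six centre-proximal maxima (mean distance d̄) is correlated with bilinear
rotations of itself; the score is min(r₆₀, r₁₂₀) − max(r₃₀, r₉₀, r₁₅₀).
Grid cells: score ≥ 0.4.

*Head-direction score*: the 360-bin spike-direction histogram is smoothed
with a circular 23° rolling sum; the score is the length of the mean
vector of the smoothed histogram. Head-direction cells: score ≥ 0.5.
Conjunctive cells pass both criteria.

*Speed score*: Pearson correlation between running speed and an
instantaneous rate estimate (per-frame spike counts smoothed with a
σ = 250 ms Gaussian). Speed cells: score ≥ 0.1 (used as a confound
check, not a primary class).

## Field detection

Iterative peak-growing: the global maximum seeds a field if it exceeds
the mean + SD of the rest of the unclaimed map (excluding the peak bin);
the field grows by recursively absorbing 8-neighbours whose rate exceeds
35% of the field peak; a field is accepted if it covers more than 45 bins
and less than half the arena; accepted bins are removed and the search
repeats. Two automated guards replace the visual screening such
procedures otherwise need: (i) a candidate 8-adjacent to an already
accepted (or already rejected) region is discarded as a *remnant* — the
sub-35% skirt of a strong field would otherwise re-enter, shell by
shell, as spurious fields, whereas genuine neighbouring grid fields at
50 cm spacing are separated by low-rate valleys at this binning;
(ii) a candidate hugging an exactly-zero region is likewise discarded,
which makes re-detection on a map whose fields were zeroed return
nothing. An explicit per-cell exclusion list is also supported. Border
fields are those with a member bin in the outermost ring. Cells enter
per-field analyses only with at least two accepted fields.

## Directional statistics

*Classic curve*: 1° bins; spike and trajectory head-direction histograms
are smoothed with the circular 23° rolling sum before division; the
ratio × frame rate gives Hz. *Distributive curve*: 20 bins of 18°,
unsmoothed.

*Distributive shuffle*: each trajectory sample gets probability
proportional to the rate-map value in its spatial bin (restricted to the
field's samples for per-field tests); a shuffle draws the observed
number of spikes with replacement and bins their head directions into
the 20-bin curve; 1000 shuffles by default, summarised per bin by the
median and the 5th/95th percentiles.

*Bin significance*: per-bin two-tailed p from shuffle ranks using the
(r+1)/(n+1) convention (never exactly zero); Benjamini–Hochberg across
the 20 bins; significant bins have adjusted p < 0.05. The null for the
*count* of significant bins scores each shuffle against the full
ensemble the same way (leave-in: each shuffle's self-comparison plays the
role of the +1 pseudo-count; leave-one-out is available). A field is
**directional** when the observed count exceeds the 97.5th percentile of
that null. The leave-in BH counting for the 1000 nulls uses a vectorised
BH implementation verified to agree exactly with statsmodels.

*Watson two-sample U²* compares spike directions with trajectory
directions (or any two circular samples): computed from the centred
difference of the two empirical CDFs over the pooled sample, with tied
blocks averaged. p is reported as a band from the classical asymptotic
critical values (0.152/0.187/0.268/0.385 for 0.1/0.05/0.01/0.001); an
exact permutation p is available for small samples. No implementation of
this test exists in the scientific Python stack used here, so it is
implemented directly and pinned against an independent brute-force
oracle and a permutation test.

*Correlations*: Pearson r between directional curves over unmasked bins;
curves with more than 25% masked bins are excluded. Between-field and
within-field (first vs second half-session) analyses use fields with
more than 500 spikes. *Stability percentile*: the observed
half-vs-half distributive-curve r is placed within the distribution of
shuffleᵢ-vs-shuffleⱼ correlations (up to 1000 × 1000 pairs; 10⁵ random
pairs by default, exhaustive mode available).

Half-session splits are at the temporal midpoint; events exactly at the
midpoint go to the second half.

## Conjunctive-cell input model

Input cells share one triangular lattice (50 cm spacing, common spatial
phase) and have 20.0 cm FWHM circular-Gaussian fields and 141° FWHM
head-direction tuning of height 1. Per-field peaks are either all equal
(uniform model) or scaled by i.i.d. uniform(0, 1) draws (non-uniform
model); each cell's spatial map is renormalised to a peak of 1 over the
arena. Per-millisecond firing probability is
`p = 0.28 · G(x,y) · 0.12 · H(hd)`, realised as independent Bernoulli
draws at 1 ms. Preferred directions are evenly spaced across the
population (default five inputs). The lattice phase is not a published
quantity; the default (12.5, 12.5) cm places four essentially complete
fields inside the 1 m arena, the most a 50 cm lattice admits, which
maximises the number of usable within-cell field pairs.

The downstream neuron is a conductance-based leaky integrate-and-fire
point neuron (τ_m = 10 ms, R_in = 50 MΩ, rest −70 mV, threshold −50 mV,
reset −65 mV, refractory 2 ms, E_syn = 0 mV), advanced with the exact
exponential update per 1 ms step. It stands in for a morphologically
detailed stellate-cell model; consequences of this substitution:

- Absolute synaptic conductances tuned for a dendritic tree do not
  transfer to a point neuron. The low-regime maximal conductance was
  calibrated once so the simulated grid cell's peak in-field rate
  (~20–30 Hz) and session spike yield match recorded grid cells and
  leave enough spikes per field for the 500-spike correlation gate; the
  high regime multiplies it by the original high/low ratio (250/0.603 ≈
  415), with conjunctive rates additionally scaled by 2.33 to mimic the
  faster-firing high-conductance operating point.
- Each input connects through nine synapses whose dendritic placement
  cannot be represented; placement variability is summarised as a
  lognormal per-synapse efficacy jitter (20% CV, redrawn per trial)
  averaged over the nine synapses (~7% per-input CV). A larger *shared*
  per-input spread would impose one directional mixture on every field
  of the output cell and destroy the between-field decorrelation that
  the non-uniform model exists to produce, so the jitter is deliberately
  sub-dominant to the per-field rate variation.

Synapses have instantaneous rise and 2 ms exponential decay; the total
conductance is the causal exponential filter of the weighted input spike
trains (computed by an IIR filter, pinned against direct convolution).

Each model experiment runs 20 trials on a 25-minute synthetic session;
every trial redraws per-field peaks and synaptic jitter, simulates the
output cell, detects its fields and computes: between-field classic-curve
correlations (summarised as per-cell means, median across cells),
within-field and whole-cell half-session correlations (medians across
fields/cells), and optionally the per-field distributive shuffle test.
With three to six usable fields per cell and 20 trials, the
between-field median carries a standard error of roughly 0.1; it is a
population-level summary, not a per-seed constant.

## Numerical and statistical conventions

- All randomness flows from one root seed through named
  `SeedSequence` substreams; identical (config, seed) gives identical
  output tables.
- Percentiles by linear-interpolated ranks; percentile-of-score uses the
  mean rank for ties.
- Pearson correlations are undefined (NaN) for constant inputs and
  excluded from medians.
- Ties in field growth are irrelevant (set semantics); ties in
  binary-array maxima resolve to the first bin in row-major order.
- Degenerate inputs (empty trajectories, empty spike trains, all-masked
  maps, zero-rate shuffle regions) raise `ValueError` with a stated
  reason rather than returning silent NaNs, except where an empty result
  is scientifically meaningful (zero fields detected, empty correlation
  lists).

## Problem sizes of the shipped benchmarks

The test-suite and the reproduction script use 20–25-minute synthetic
sessions, 100 simulated conjunctive cells for the rate survey, 20 trials
per model configuration, 1000 shuffles per field and 200 fields for the
type-I calibration of the directionality verdict. These sizes match the
study's own simulation protocol where one exists (trials, shuffles,
session length) and are otherwise chosen as the smallest sizes at which
the statistics stabilise.

## Known limitations

- The surrogate integrator reproduces the qualitative phenomenology
  (decorrelated per-field tuning under non-uniform input; correlated
  under uniform input) but not the quantitative operating point of a
  fitted compartmental model; model-derived quantities should be read as
  scaled-down analogues.
- The trajectory generator's clean sampling understates the
  distributive-hypothesis confound present in real data.
- Grid-score annulus bounds follow the [0.25·d̄, 1.25·d̄] reading of the
  ring rule; other readings exist and would shift scores slightly.
- The Watson U² p-value bands assume the asymptotic null; for very small
  samples use the permutation mode.
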