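# Methods

This note records the models, conventions and numerical choices behind
`evtopo`, in the order the pipeline runs them, together with what the
synthetic data do and do not emulate.

## Data model and conventions

Potentials are in microvolt, time in seconds, sample indexing 0-based,
and every time window half-open `[start, end)`. A *topography* is the
vector of potentials over all electrodes at one instant, always
average-referenced (instantaneous spatial mean zero). The design is a
complete 2×2 within-subject factorial — congruency × synchrony — and the
canonical cell order is CS, CA, IS, IA everywhere (contrast weights,
tables, permutation schedules).

The canonical on-disk format is a directory of JSON metadata plus one
`.npy` float64 array per subject × condition cell, with a SHA-256
manifest; it round-trips bit-exactly. EDF/BrainVision/EEGLAB import is a
convenience delegated to mne and converts to µV/seconds on entry.

## Preprocessing

Fixed order: downsample (polyphase, only when the input rate exceeds
512 Hz) → zero-phase band-pass → average reference → baseline
subtraction over the pre-stimulus interval → amplitude rejection.

- Band-pass: Butterworth, 1–40 Hz, order 5, applied forward–backward
  (`sosfiltfilt`). Order 5 gives ≥ 20 dB attenuation at 50 Hz relative
  to mid-band after the double pass; order 4 falls short of that at
  512 Hz, which is why 5 is the default.
- Rejection: an epoch is dropped when any channel/sample magnitude
  exceeds 20 µV *after* referencing and baseline — the strictest
  consistent reading of a bare amplitude criterion. The per-epoch
  report (max |amplitude|, kept flag) makes the rule auditable, and
  rejection is monotone in the threshold by construction.
- Bad channels: robust z-score (median/MAD) of log channel variance,
  |z| > 3; repaired by Perrin spherical-spline interpolation
  (stiffness m = 4, 50 Legendre terms, 1e−8 ridge on the spline
  system). The spline reproduces constants exactly through its fitted
  constant term; leave-one-out error on noiseless single-dipole maps is
  a few percent of the map GFP.
- ICA-based residual cleanup is deliberately an external hook, not a
  tested stage: component selection is a judgment call that cannot be
  reproduced from a seed.

## Topographic analysis

GFP is the population (1/N) spatial standard deviation. Spatial
correlation is signed Pearson correlation across channels: evoked
polarity is meaningful, so a map and its inverse are distinct states.

AAHC starts from one cluster per time point of the group-average series
(all four conditions concatenated over the post-stimulus window). Each
iteration removes the cluster with the smallest GEV contribution
Σₜ∈cluster (GFP·corr)², reassigns its members to the remaining template
with the highest signed correlation, and recomputes affected templates
as the GFP-weighted mean of member topographies, renormalized to unit
norm. Ties break to the first (lowest) index throughout, making the
whole hierarchy deterministic. GEV is non-decreasing in q along the
hierarchy on the data we generate; the suite asserts it.

The operative map-count rule is the smallest q with GEV ≥ 0.90. A
modified Krzanowski–Lai score is reported as advisory only, with the
within-cluster dispersion W\_q taken as 1 − GEV on the normalized scale
— the exact "modified" variant used by legacy tools is not documented
anywhere, so no selection decision rests on it.

Fitting is winner-take-all: per subject, condition and window sample,
the template with the highest signed spatial correlation wins; duration
is won-samples/sfreq and mean GFP is averaged over won samples (NaN when
a map wins nothing, flagged rather than silently zeroed). No
low-correlation samples are excluded, so durations sum exactly to the
window length in every cell — the suite asserts sample-count
conservation exactly and milliseconds to 1e−9.

### Analysis-window selection

Candidate segments are the maximal runs between label change points of
any condition. The selected window is the part of the segment containing
the global GFP peak over which every sample is TCT-significant
(p < 0.05) in all four conditions — the overlap of the stable-topography
period with the consistency window, rather than requiring the entire
segment to be consistent. The stricter all-segment rule turned out to be
brittle in exactly the high-SNR regime where segments grow long and
extend past the evoked response; the overlap rule is stable in both
regimes and still returns a deterministic, contiguous window. When the
peak sample itself is not consistent everywhere, no window is returned
and downstream stages are skipped with a warning.

## Topographic consistency test

Per condition and time point: observed statistic is the GFP of the
across-subject mean topography; the null independently permutes channel
values within each subject's topography (which preserves each subject's
own GFP exactly — only cross-subject alignment is destroyed);
p = (1 + #{null ≥ observed}) / (1 + n\_perm), so p can never fall below
the permutation floor. Default 1000 permutations, configurable; runs per
condition with no cross-condition or cross-time correction — consecutive
significant runs are exposed so callers can impose duration criteria.

## Forward model and source imaging

Anatomy is replaced by a configurable geometry: a regular grid (default
26-connectivity) clipped to a sphere, optionally cut below a horizontal
plane (`zmin_mm`) to form a brain-like cap under the sensor net. The
lead field is the analytic quasi-static potential of a current dipole in
a homogeneous conducting sphere (default radius 85 mm, σ = 0.33 S/m),
computed as the Legendre series truncated when the geometric term falls
below 1e−12 (≤ 200 terms); rows are average-referenced so every column
sums to zero. A user-supplied lead field can replace it.

The inverse is a LAURA-type weighted minimum norm: the weight operator A
has unit diagonal and off-diagonal −d⁻²/Σd⁻² over grid neighbours
(exponent configurable; 2 reflects the squared-distance decay of the
potential). A annihilates spatially uniform source fields — its rows sum
to zero — so M = AᵀA is a seminorm; a ridge of 1e−6 × mean diagonal
makes it invertible while leaving smooth fields cheap. Auto-α is 0.01 ×
the **median** eigenvalue of L M⁻¹Lᵀ: the mean (trace/C) is inflated by
orders of magnitude by the near-free uniform mode and would oversmooth.

Current density is the Euclidean norm of the 3-component moment after
averaging the evoked over the analysis window first (one inversion per
cell). Two distinct uses are kept apart deliberately:

- **Condition contrasts** (the node-wise ANOVA) use raw density. The
  depth bias of weighted-minimum-norm estimates is a fixed property of
  each node's point-spread and cancels when conditions are compared at
  a fixed node.
- **Localization** uses the resolution-standardized power
  sᵢ = JᵢᵀRᵢᵢ⁺Jᵢ (Rᵢᵢ the node's 3×3 diagonal resolution block), the
  standard remedy for the depth bias. On a ~250-node cap grid (60 mm
  radius, 14 mm spacing, z ≥ −24 mm) every interior node of a noiseless
  single-source field localizes within one grid spacing, at α → 0 and
  at auto-α; the raw-density argmax errs by several grid steps for deep
  sources, which the acceptance report states explicitly. Localization
  accuracy is on the order of the grid step at this node count; finer
  grids sharpen superficial sources but not deep ones.

## Statistics

For a 2×2 within-subject design every effect has df = (1, n−1) and its
classical F equals the squared paired t of the per-subject contrast
(weights ±½ over the four cells): F = n·c̄²·(n−1)/Σ(c−c̄)², and
η²ₚ = SS\_eff/(SS\_eff+SS\_err) on the same contrast scale. This is
verified against a textbook sum-of-squares oracle and against pingouin.
The permutation null relabels the four cells independently within each
subject (uniform over 4!ⁿ schedules, sampled), the simplest valid
within-subject exchangeability scheme; one schedule serves all three
effects, and node-wise tests share a single schedule across nodes so the
spatial structure of the null is coherent. p = (1 + #{F\* ≥ F})/(1 + P).
Default 10,000 resamplings (scalar outcomes), 1,000 node-wise.

Spatial cluster rule: connected components of p < 0.05 nodes under the
grid adjacency; components under 17 nodes are reported but flagged
non-significant. Post-hoc paired t tests (d = mean/SD of differences)
are uncorrected. Pearson r carries the two-sided t-based p. Missing
ratings (an explicit NaN) drop the subject listwise for that outcome
only; a structurally absent design cell is an error.

## Synthetic data

The generator emulates the statistical structure of the target study:
10 subjects × 4 conditions × 480 epochs at 512 Hz over [−50, 300) ms;
two Gaussian-burst dipoles — a left-central source at 45 ms (P45-like)
and a right-posterior source at 38 ms whose amplitude gains 1.5× in the
congruent cells, so congruent and incongruent conditions differ in early
topography and in posterior current density; per-subject gain (SD 0.1×)
and latency jitter (SD 2 ms) drawn once per subject, consistent with
evoked averaging; sensor noise (3 µV) plus spatially correlated
background (2 µV, squared-exponential over the cap) drawn from one
combined covariance; 2% of epochs receive a 40 µV focal artifact burst
to exercise the rejection rule. Behaviour: truncated-normal ratings
(agency = 4 + 2·congruent + 2·synchronous, SD 1; control flat at 5) and
sinusoidal left-right hand paths matched to a 10.6 cm sweep norm and
6.7 cm/s mean speed. A ground-truth record (configs, seed, per-subject
parameters, true nodes, per-cell gains) suffices to rebuild every epoch.

What it does not emulate: realistic anatomy or conductivity layering,
physiological artifact morphology (blinks, muscle), overlapping
responses at 2 Hz stimulation, non-Gaussian rating distributions, or
learning/order effects. Passing tests therefore demonstrate that the
algorithms recover known structure under the study's statistical design
and realistic SNR — not that the pipeline is robust to every failure
mode of real recordings.

## Problem sizes

Monte-Carlo tests and the acceptance script run the same study design at
sizes chosen once for desk-scale runtime: 64 epochs/condition (the
evoked SNR scales as √epochs; planted effects remain comfortably
detectable), a 925-node source grid (60 mm sphere, 10 mm spacing),
199/1,999/499 permutations for TCT/scalar/node-wise tests, and 50
replicate studies for recovery rates; calibration uses 500 (TCT) and
1,000 (ANOVA) replicate null studies at 99/199 permutations, where the
rejection rule p ≤ 0.05 is exact by construction of the permutation
p-value. Full-scale defaults (480 epochs, 10,000 resamplings, 8 mm grid)
remain the package defaults for real use.

## Behavioural feature extraction

Positions are smoothed with a 0.2 s moving average; the principal axis
is the direction of maximal positional variance; reversals are turning
points detected with 5% hysteresis of the range, so jitter near the
extremes does not fragment sweeps. The trajectory norm is the mean
displacement magnitude of *complete* sweeps (reversal to reversal; the
partial stretches before the first and after the last reversal would
bias it low); with no reversal the whole trial is one sweep, with a
warning. "Norm of each left-right path" is read as displacement, not arc
length, because the feature is contrasted with velocity, which already
carries path length (path/duration on the smoothed trajectory). Features
are translation-invariant, and velocity is also reflection-invariant.

## Known limitations

- The fixed ≥ 17-contiguous-node cluster rule does not control the
  study-wise false-positive rate on these data. The per-node permutation
  test is exactly calibrated, but weighted-minimum-norm density maps are
  spatially smooth, so chance sub-threshold nodes clump into clusters
  that frequently exceed any fixed extent; in effect-free simulations at
  desk scale roughly four in ten studies retain a spurious cluster. The
  rule is kept because it is the field's convention for this analysis
  family; the acceptance report states the measured specificity, and a
  retained cluster should be read together with the converging
  sensor-level (map duration) evidence rather than as stand-alone proof.

- The homogeneous sphere under-models skull attenuation; absolute
  current-density scales are arbitrary (statistics are scale-free).
- The AAHC objective is greedy; no global optimality is claimed, only
  agreement with its own step definition and recovery of planted
  structure.
- The TCT and node-wise tests are uncorrected across time points/nodes
  by design (windows and cluster extent are the controlling devices, as
  is conventional in this analysis family).
- EDF/BrainVision/EEGLAB import paths are thin mne wrappers and are not
  exercised by the offline test suite, which has no recordings in those
  formats.
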