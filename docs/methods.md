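# Methods

This note documents the models, parameter choices, and numerical
decisions behind `hrfprobe`, and what the synthetic validation does and
does not show about real data.

## Synthetic BOLD model

**Ground-truth HRF.** The generator uses a difference of two gamma
densities, each reparameterized by its mode: a lobe with mode `m` and
scale `θ` has shape `k = m/θ + 1`, and is normalized to unit maximum so
that the parameters read directly in response units and seconds.

`h(t) = A · [ g(t − δ; p, σ_p) − r · g(t − δ; u, σ_u) ]`, `h(t) = 0` for `t < δ`

| parameter | meaning | default |
| --- | --- | --- |
| `A` (amplitude) | maximum of the positive lobe before undershoot subtraction | 1.0 |
| `p` (time_to_peak) | mode of the positive lobe, s | 5.0 |
| `u` (undershoot_delay) | mode of the undershoot lobe, s | 15.0 |
| `σ_p`, `σ_u` (dispersions) | gamma scales, s | 1.0, 1.0 |
| `r` (undershoot_ratio) | undershoot depth relative to the peak | 0.25 |
| `δ` (latency_shift) | rigid delay, s | 0.0 |

With `σ_u = 1` the undershoot lobe is ≈ 4 s wide (SD of the underlying
gamma) and contributes < 0.2% of its own peak at `t = 5 s`, so the
nominal `time_to_peak` is also the realized argmax of the composite
kernel — a property the tests rely on. The patient group applies
multiplicative/additive offsets (defaults: amplitude ×0.7, latency
+2.5 s, undershoot ×0.4), realizing the three qualitative alterations
the pipeline is built to detect: a lower, delayed response with an
attenuated undershoot.

**Study design.** Runs sample 116+ volumes at TR 2500 ms. Each run
interleaves 2 conditions (threshold / sub-maximum stimulus contrast) ×
2 hemifields × 10 repetitions of 400 ms events, each followed by a
baseline drawn uniformly from {4600, 7100, 9600} ms. Gaps are therefore
5000/7500/10000 ms = 2/3/4 TRs, so onsets are TR-locked by construction;
off-grid user-supplied onsets are rounded to the nearest TR with a
logged warning. Whether the 40 drawn events fit in 116 volumes depends
on the drawn baselines; when a schedule (plus the 20 s response
coverage) overruns, the run is extended with a warning rather than
truncating events — the alternative (dropping tail events) would bias
per-cell repetition counts. Whether conditions are interleaved or
blocked within a run is an open design point; the generator interleaves
in randomized order.

**Signal and noise.** An active voxel's course is
`baseline + effect · (sticks ∗ h)|_TR + ε`, with the kernel sampled on
the TR grid over the same 20 s support the FIR model covers. Defaults:
two 4³ hemifield-selective regions in opposite hemispheres (the left
visual hemifield projects to the right hemisphere), condition gains 1.0
(sub-maximum) and 0.6 (threshold) mirroring the stimulus-contrast
ordering, baseline 100, white Gaussian noise SD 1.0 (peak SNR ≈ 1 at
effect 1), optional linear drift. Subject-level variability: Gaussian
jitter of 5% on amplitude and 0.25 s on latency. Temporal
autocorrelation, physiological noise, motion, and scanner drift
structure are deliberately absent (real pipelines high-pass filter and
motion-correct upstream); passing tests therefore demonstrate
correctness of the estimators under white noise, not robustness to
colored noise. Registration across subjects is the identity (a shared
synthetic space), so heatmap averaging needs no spatial transform.

**Staircase.** The behavioral simulator implements the descending
logarithmic staircase: delta starts at 24 − 5 = 19 °/s, moves down after
correct and up after incorrect responses by the current step in dB
(multiplicative, `δ ← δ·10^(±s/20)`), with the step interpolated
geometrically from 1 dB to 0.05 dB across the six reversals (the source
protocol states only the range; geometric interpolation is the standard
choice for log staircases). Termination is at 6 reversals, the
threshold is the mean of the last 4 reversal deltas, and hitting
`max_trials` first sets a truncation flag rather than raising.

## Epoching and augmentation

Epochs take 8 volumes starting one volume before onset. The nominal
window −2.5 to +10 s spans only 6 samples at TR 2.5 s, which conflicts
with the 8-TR epoch shape the pipeline is defined around; the 8-volume
reading (−2.5 to +15 s) is used since it matches the stated matrix
shape, and the extra tail helps the undershoot reach the classifier.
Normalization to zero mean/unit variance is computed per epoch, never
per cohort, so no statistics leak from training into test subjects.

Augmentation is applied per training batch only (re-drawn every step,
never to tuning or test inputs): a repetition subset of size 7–9 drawn
uniformly from all 175 such subsets is averaged instead of all 10;
then a rigid shift (≤ 1 voxel) and rotation (≤ 5°, trilinear, borders
padded with the epoch mean to stay in-distribution) identical across
lags; then i.i.d. Gaussian noise (SD 0.1 in normalized units).

## Classifier

The network is deliberately slim: stem 3×3×3 convolution (8 channels),
four residual blocks of widths (8, 16, 16, 32) — each
conv–BN–ReLU–conv–BN with an additive shortcut (1×1×1 projection when
widths change), ReLU, then 2×2×2 max pooling halving all three spatial
axes — flatten, dropout, and a single-logit dense head; ≈ 72k
parameters at 16³ input. The 8 epoch lags enter as input channels,
preserving 3D spatial convolution semantics. Weights are Glorot-uniform,
biases zero; training is SGD with momentum on binary cross-entropy
(sigmoid folded into the loss). Defaults: learning rate 0.02, momentum
0.9, dropout 0.2, batch 8, 150 steps — selected as a stable operating
point for 16³ inputs; `grid_search` tunes them on a 10% subject-level
holdout (selection metric: tuning AUC, ties broken by accuracy then
grid order) when a sweep is wanted. Everything is seeded and
single-threaded, so training is bit-reproducible.

The cohort split forces equal class proportions in train and test and
assembles the test set from matched cross-group pairs (gender exact,
then minimal age gap; age-only with a warning when a gender pool is
exhausted). With unequal class sizes those two constraints cannot both
hold exactly; pairs fill the smaller class quota and the larger class's
remainder is drawn unmatched. One averaged epoch per subject per
condition × hemifield is the classification unit, and each cell gets
its own model.

## Relevance propagation

Deep Taylor decomposition is seeded at the positive part of the
pre-sigmoid logit (the method is defined for positive outputs; the
probability would saturate the scale). Batch-normalization layers are
folded into the adjacent convolution weights/biases first, so every
learned layer is linear + ReLU. Hidden convolutions and the dense head
use the z⁺ rule — relevance redistributed proportional to positive
pre-activation contributions, biases excluded from the redistribution
(the standard choice; the alternative of letting biases absorb
relevance breaks the conservation audit) — max-pooling routes
winner-take-all to the pooled maximum (first winner on ties), and
residual additions split relevance between branches in proportion to
their positive parts. The stem convolution sees signed z-normalized
input, where z⁺ alone is invalid; it uses the bounded-input z^B rule
with bounds taken from the observed min/max of the epoch being
explained. Denominators carry a 1e−12 stabilizer; with zero biases the
per-layer relevance sum is conserved to ≈ 1e−13 in practice (the test
bound is 1e−4). Lag-channel relevances are summed into a single 3D map
per decision, and maps are scaled to unit sum before averaging so every
decision contributes equal total relevance.

## Cluster ROIs and deconvolution

The average heatmap is thresholded at the 95th percentile of its
strictly positive entries (standing in for a manually tuned cutoff),
opened with the minimal 6-connected unit-cross element, labeled with
26-connectivity (configurable 6/18), filtered at 20 voxels, and
relabeled 1..K by descending size for stable reports. Peak voxels
break ties to the lowest lexicographic coordinate.

FIR deconvolution uses `ceil(20 s / TR) = 8` stick lags per event type
(default event types: the four condition × hemifield cells), lag 0 at
the onset volume (no pre-stimulus lag; the intercept and optional
linear drift column carry baseline), ordinary least squares without
prewhitening (the synthetic noise is white), and standard errors from
the normal-equations inverse. Events within coverage of the run end
keep their truncated columns. Sparse designs (≲ 2 events per type) can
be genuinely rank-deficient through cross-lag dependencies among stick
columns; the builder detects this and names the collinear columns
rather than returning unstable estimates. Per-subject fits are
averaged within group × event type × ROI (rather than concatenated
group-level fits), which is what a mean ± SD band across subjects
requires. Shape features search for the peak from lag 1 (the onset
volume is excluded to avoid onset artifacts) and report both the raw
lag time and a parabolic 3-point refinement; undershoot depth is the
deepest post-peak negative excursion, clipped at zero.

## Validation design and its limits

The acceptance battery checks, at the sizes given: exact subset
combinatorics (175); layer-wise relevance conservation (< 1e−4) and
agreement with a brute-force root-finding Taylor oracle on ≤ 8-unit
positive-weight networks (< 1e−6); noiseless simulate → extract → fit
recovery of the TR-sampled kernel (< 1e−6) and OLS agreement with an
independent least-squares solve; correct contrast signs for the
injected group differences in ≥ 9/10 cohorts of 20 + 20 subjects at
peak SNR ≈ 1, with control group-mean HRFs correlating > 0.95 with
truth; held-out AUC ≥ 0.9 on a strong-effect cohort (patient amplitude
×0.5) versus a permuted-label AUC inside [0.3, 0.7] — pooled across the
four cell models, since a single 8-subject test set makes the null AUC
too coarse (SD ≈ 0.22 vs ≈ 0.10 pooled); and flood-fill agreement of
the cluster machinery on 100 random masks. Simulations run at 16³
voxels (configurable up to 90³) with 10–20 subjects per group so the
full battery completes in minutes on one CPU; these sizes are the
package's validation conditions, not estimates of real-data effect
sizes. None of this certifies performance on scanner data with colored
noise, motion residuals, or inter-subject anatomical variability — it
certifies that every stage computes what it claims on data whose truth
is known.
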