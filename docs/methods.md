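# Methods

`axonspace` implements the analysis chain used to ask how much auditory
(and visual) spatial information reaches primary visual cortex through
axonal projections from auditory cortex, as measured with two-photon
calcium imaging of axonal boutons, together with the somatic analyses of
audiovisual interaction. This note describes the models, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the procedures were genuinely open.

## Stimulus space

Stimulus positions live on a grid in (azimuth, elevation) degrees.
Negative azimuths are ipsilateral to the recorded (left) hemisphere,
positive azimuths contralateral; elevation 0 is head level. The default
array has 39 positions: 13 azimuths from −20° to +100° in 10° steps × 3
elevations (−20°, 0°, +20°). A single-row motorized-arm geometry covers
−90° to +100° (20° steps to −30°, then 10° steps), 17 positions.

Distance between positions is Euclidean in the degree plane. This is
exact for single-row geometries and accurate over the 120° × 40° section
the array spans; it is also the natural domain for the decoder's error
metric. Chance-level decoding error is defined by exact enumeration: the
mean pairwise distance over all ordered position pairs when the true and
decoded positions are independent and uniform on the grid (50.4° for the
default array). Chance is a definition, not an estimate; the shuffle null
(below) is the empirical counterpart.

## Preprocessing

ΔF/F = (F − F0)/F0 with F0 the mean fluorescence over the trial baseline,
fixed as the 1 s immediately preceding stimulus onset for all analyses.
The onset frame is the first frame whose start time is at or after the
stimulus onset; windows are half-open `[start, end)` and a frame belongs
to a window when its start time does. The bouton response window is
0.2–1.8 s from onset (9 frames at 6 Hz); somata use onset to one frame
past offset. Optional neuropil correction is F − 0.7·Fneu.

Because F0 is the baseline-window mean, each trial's baseline-window mean
ΔF/F is identically zero, so the paired responsiveness tests reduce to
tests of the response values against zero. A bouton is responsive when
the position with the strongest median response rejects a two-sided
Wilcoxon signed-rank test at α = 0.01 *and* its mean response exceeds
0.15 ΔF/F (the amplitude gate applies to the mean by default; a config
switch uses the median). A bootstrap variant resamples baseline frames
within trials to build a null for the median-response statistic. Somata
are kept when the trial-baseline fluorescence exceeds the neuropil by
more than 3% and the best trial type passes a paired t-test at p < 0.05
with mean response > 0.05 ΔF/F.

## Spatial modulation index

For a response map r_1..r_n over n positions with grand mean R,

    SMI = Σ_i (r_i − R)² / Σ_i r_i²

the fraction of the map's energy not explained by its spatial mean. A
uniform map scores exactly 0. A one-hot map scores (n−1)/n — not 1: the
single-location limit approaches 1 only as n grows. The formula is
implemented exactly as written; negative map entries (noise-driven) are
allowed as-is, with an optional rectify-at-zero switch (default off).
SMI is scale-invariant and increases under mean-preserving concentration.
The population SMI is the SMI of the position-wise mean map across
boutons; it is at most the typical individual SMI when preferences are
spread.

## Reliability, best azimuth, tuning curves

All resampling analyses share one scheme: trials of each position are
randomly split in half, tuning maps computed per half, and the Pearson
correlation between half-maps defines reliable boutons (r > 0.3); the
loop runs 100 iterations for means and percentile 95% CIs. Azimuth
preference marginalizes over elevation by averaging. The session best
azimuth is the median best azimuth over the boutons reliable in each
iteration (best azimuth itself from all trials); sessions with fewer than
10 reliable boutons are excluded. Distance-tuning curves take the
preferred position from one half, normalize the other half's map at that
position, and pool by distance from preferred. The resampling unit is the
random half-split (trial-level), not a bootstrap over boutons.

Azimuth-vs-elevation modulation is compared on virtual isotropic arrays:
every 3-azimuth subset at 20° spacing (40° span) crossed with the 3
elevations — 9 sub-arrays for the default grid — with a two-way
fixed-effects ANOVA (azimuth × elevation) per bouton and significant
fractions averaged across sub-arrays. The balanced two-way ANOVA is
vectorized over boutons for speed and is verified against statsmodels'
`anova_lm` in the test suite.

Onset/offset classification uses the deconvolved event traces: best
position from median activity over onset to 1 s past offset; onset means
the stimulus-window rate beats the 1 s baseline (Wilcoxon, α = 0.01);
offset means the post-offset window beats baseline while the stimulus
window does not differ from it. Frequency tuning declares a bouton
tone-responsive when its best frequency passes a paired t-test at
α = 0.01 with mean response > 0.1 ΔF/F, and frequency-tuned when a
one-way repeated-measures ANOVA across frequencies (repetitions as
subjects) also rejects at α = 0.05.

## Axon clustering

Bayesian population decoding assumes conditional independence across
units, which boutons of one axon violate. ROI pairs whose full-trace
Pearson correlation reaches 0.3 (a threshold established on anatomically
verified same-axon pairs; taken as given here) are agglomerated in random
order: the first pair seeds a cluster; each following pair joins a
cluster when at least one of its ROIs correlates at threshold with at
least one current member (reading the published "only one of the ROIs"
rule as "at least one"), otherwise it seeds a new cluster; unpaired ROIs
stay singletons. The order-dependence of this rule is preserved and
controlled by a seed; a pair matching two clusters joins the one matched
by its first-drawn ROI. Zero-variance traces are treated as
below-threshold and reported. Each cluster's activity is the member with
the largest mean ΔF/F, not an average. A config switch allows clustering
on trial responses instead of full traces.

## Naive-Bayes decoder

Per axon i and position s the trial response is modeled as normal with
training mean R_is and training s.d. σ_is (n−1 denominator). The
population log-likelihood of response vector n is Σ_i log N(n_i; R_is,
σ_is); the decoded position maximizes it. The uniform stimulus prior and
the evidence term cancel in the argmax and are not stored. σ is floored
at 1e−3 ΔF/F because the density is undefined at σ = 0 (constant
training responses); the floor is configurable. Exact likelihood ties are
broken uniformly at random under a seeded generator.

Cross-validation is 5-fold, stratified by position so every fold trains
on every position (the published description says only "selected at
random"); every trial is decoded exactly once. Errors are averaged within
position, then across positions. Sessions contribute only when clustering
yields more than 10 axons. The shuffle null permutes position labels and
repeats the full CV decode. The error-vs-population-size analysis draws
axons without replacement, 100 draws per size, with the fold assignment
held fixed across draws so the full-pool size has a zero-width interval.
Somatic sessions use leave-one-out cross-validation, which is
deterministic given the data. The decoder requires at least 2 training
trials per position (3 for leave-one-out).

## Receptive fields and retinotopy

The V1 population RF averages baseline-subtracted, repetition-averaged,
stimulus-window-averaged responses over the field of view into a map
R(az, el) and fits an elliptical 2D Gaussian — amplitude, center, two
widths, orientation, offset — by bounded least squares (orientation and
offset are included because population maps are visibly tilted;
initialization at the response-weighted centroid with range-based widths,
restart from the map peak on failure; center bounded to the grid span
± 20°). A fit is flagged unreliable when |amplitude| fails to exceed 5×
the residual s.d. — pure-noise maps otherwise overfit small bumps.

Retinotopic alignment is tested two ways: (1) ordinary least squares of
session best azimuth on session RF azimuth center, with residual-bootstrap
95% CIs (resample residuals with replacement, refit); (2) decoding error
binned by |stimulus azimuth − RF azimuth center| in 10° bins, with
shuffle-subtracted bins when a null decode is supplied; empty bins are
reported missing, never zero. A session-size-controlled profile along the
retinotopic map subsamples every session to the common minimum axon count
(10 draws, averaged) and applies a 20° moving average in 5° steps.

## Audiovisual modulation

Somatic sessions present V (LED inside the population RF), A (speaker at
an azimuth offset from the LED; offsets −40° to +40° in 20° steps, plus
two elevation-offset speakers), and AV trials, 7 repetitions per
combination. Aggregation follows the recorded analysis: per neuron the
LED eliciting the maximal visual response is selected, elevation-offset
speakers are excluded, intensities are averaged (a stratified mode keeps
brightness and loudness as ANOVA factors), and the mouse is the
repeated-measures subject. Enhancement is the paired t-test of AV vs. V
across mouse means (both AV − V and AV/V are reported: the ratio is
gain-invariant, the difference is not). Offset dependence is the
repeated-measures ANOVA (statsmodels AnovaRM) on mouse means. Speaker
offset is decoded from A and AV trials separately with the leave-one-out
decoder and a 100-permutation shuffle null.

## Synthetic sessions

The generator produces the statistical structure the analyses assume,
not images: block-randomized interleaved auditory/visual sequences
(every position once per block and modality, independent modality
orders), axon populations with Gaussian spatial tuning of varying width
plus flat-responsive and nonresponsive units, several boutons per axon
sharing a trial-level latent, a mono-exponential indicator kernel sampled
at 6 Hz, and additive white frame noise. All generators are
bit-reproducible from their seeds.

Per trial, an axon's latent response is the tuning amplitude at the
stimulus position (unnormalized Gaussian falloff in the degree plane — a
functional form chosen for the observed monotonic distance falloff, which
has no published parametric shape) times a lognormal trial gain. Bouton
responses add independent noise calibrated in closed form so the expected
within-axon bouton-bouton Pearson correlation equals the target r: with
latent variance v, the noise variance is v(1−r)/r. The split applies only
to multi-bouton axons. Trial signals enter a deconvolved-event trace as
boxcars over the stimulus window and pass through the normalized
first-order filter c[n] = g·c[n−1] + (1−g)·s[n], g = exp(−1/(rate·τ)),
which `deconvolve` inverts exactly; white noise is added after the
filter. The kernel attenuates window-mean responses by a factor
computable by exact enumeration (`kernel_attenuation`, ≈ 0.45 for τ = 1 s
at 6 Hz), and benchmark sessions set frame noise from a target
trial-response SNR via this factor.

Defaults follow the recorded designs: 20 repetitions per trial type, 1 s
stimuli, 2 s offset-to-onset intervals, 6 Hz frames, τ = 1 s for the slow
indicator. The audiovisual generator differs in two deliberate ways: its
inter-stimulus interval is 5 s (the pacing implied by the recorded AV
session durations) and its indicator decay is 0.4 s, emulating the fast
indicator used for the somatic AV recordings. Both matter: a slow
indicator with short ISIs leaves carry-over fluorescence that is coherent
across neurons and tied to the fixed trial order, which a population
decoder can exploit as spurious "information" about the previous trial's
condition — with the fast indicator and 5 s spacing the offset-decoding
null is clean. The same mechanism is why single-session simulations of
several mice share a trial sequence: mice are neuron subsets of one
session here, a simplification relative to per-mouse recordings.

What the generator does not emulate: imaging per se (pixels, point-spread
functions, motion), neuropil contamination beyond a schematic shared
signal, non-Gaussian noise, adaptation or slow drift, eye movements, and
behavioral covariates. Tests passing on synthetic sessions therefore
demonstrate the correctness and calibration of the *analysis* under the
stated generative assumptions, not properties of any recorded dataset.

## Benchmark conditions and problem sizes

The clustering benchmark uses 20 axons × 3 boutons, within-axon r = 0.6,
narrow (8°) tuning with centers at least 20° apart, and a strong trial
gain (σ = 0.6): flat-responsive axons would all share the stimulus boxcar
(cross-axon correlations far above threshold), whereas spaced narrow
tuning yields cross-axon trace correlations near zero — the regime the
published threshold was calibrated for. Recovery is exact (adjusted Rand
index 1.0) at these settings.

Decoding benchmarks use 50 axons, width 30°, SNR 3, 20 repetitions × 39
positions (observed error ≈ 10–12° vs. 50.4° chance); null calibration
uses 15 flat-responsive axons and a 50-permutation shuffle. The
retinotopy-null property runs 10 replicates of 40 small single-row
sessions (12 axons, 6 repetitions); the audiovisual property runs 20
replicates of the full AV session. These sizes were chosen to estimate
each property with comfortable margins while keeping the whole suite
around a minute of compute.

## Known limitations

* The greedy, order-dependent clustering rule is faithful to its
  published description, including its sensitivity to pair order when
  correlation structure is ambiguous; the seed makes this reproducible
  rather than removing it.
* The decoder's Gaussian observation model is used as published; no
  Poisson or kernel-density variants are provided.
* Chance level is a definition (enumerated uniform guessing); published
  figures plot "chance" without a formula, so small differences from any
  original dashed line are possible.
* The one-hot SMI equals (n−1)/n by the formula, although the index is
  sometimes described as reaching 1 for single-location responses; the
  formula wins here.
* With few repetitions per position (< 6), the Wilcoxon responsiveness
  test cannot reach α = 0.01 and no bouton can be declared responsive;
  this is a property of the test, not a bug.
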