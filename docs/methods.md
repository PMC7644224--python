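# Methods

This note documents the models, estimators and numerical conventions the
package implements, the reasoning behind the open design choices, and
what the synthetic data do and do not establish about real recordings.

## Coordinate and angle conventions

All modules share one orientation convention: angles in degrees on
(−180°, 180°], with 0° pointing toward warmer temperatures along the
gradient axis and ±180° toward colder. Trajectories are in mm with
0-based frames and uniformly spaced timestamps; gradient geometry is
specified in cm; run and event intervals are half-open [start, end).

## Klinokinesis random walk

Each worm is a point agent with heading h(t) and a per-worm speed drawn
once from N(speed_mean, speed_sd). Between turns the heading diffuses
with variance `heading_diffusion` (deg²/s). Turns fire as a Poisson
process with heading-dependent rate

    λ(θ) = λ₀ (1 + β cos θ),   θ = h − (warm direction),

the simplest smooth turn-rate law producing klinokinesis: β > 0 lowers
the rate while the animal moves down the gradient, lengthening cold-bound
runs. A turn is a reversal with probability `reversal_prob` (heading flip
of 180° plus von Mises jitter, κ = 20) and otherwise a sharp turn whose
new heading comes from the mixture p·vonMises(cold, κ) + (1−p)·Uniform.

Sharp turns are genuinely sharp: candidate headings are redrawn until the
reorientation is at least `min_turn_angle` (default 60°). Reorientations
smaller than that are indistinguishable from within-run heading drift —
no detector operating on a centroid track can score them — and tracker
pipelines in this field only score large reorientations as turns. By
symmetry the rejection leaves the *marginal* post-turn heading
distribution intact: under the null (p = 0, uniform pre-headings) the
marginal stays exactly uniform, which the orientation-uniformity tests
verify.

**Boundaries: censoring, not reflection.** A worm reaching the plate edge
ends its trajectory there. We initially implemented specular reflection
and also wall-following, and both systematically corrupt the bias
statistic: near the cold edge, cold-bound runs are truncated by geometry
while warm-bound excursions run their full exponential length, so any
model that keeps animals bouncing at the wall drives the measured bias
toward zero or below even for a strongly cryophilic walker. Real
worm-tracking pipelines terminate tracks when animals hit the plate wall,
climb it, or collide and aggregate — exactly the fate of animals reaching
the cold end — so censoring at the boundary is both the realistic choice
and the one that keeps the bias statistic interpretable. Trajectory
timestamps still increment by exactly 1/frame_rate and positions never
leave the plate.

Reproducibility: each worm runs on its own child stream spawned from the
root seed (`SeedSequence.spawn`), so worm i's path is invariant to
`n_worms`.

### Behavioral presets

Defaults encode the standard assay: a 10 cm plate with a 23–28 °C,
0.5 °C/cm gradient, worms started at the 25.5 °C centre, 1 Hz sampling,
35 min recordings of which the first 5 min are discarded, 15 worms per
assay. Speeds use the measured values (fed 117 µm/s, starved 106 µm/s).
No quantitative turn-rate or post-turn-bias values exist for fed animals,
so preset magnitudes are calibrated once to reproduce the qualitative
phenotype pattern: `fed` (β = 0.7, p = 0.6, κ = 2, λ₀ = 1/30 s⁻¹)
produces a strong negative-thermotaxis bias (~0.6); `starved` (β = 0,
p = 0, λ₀ = 1/15 s⁻¹ — turning elevated globally, in the absence of
evidence for a purely local elevation) is athermotactic (bias ≈ 0);
`starved_awc_silenced` pairs starved speed with fed-like navigation,
emulating the rescue of negative thermotaxis when AWC is silenced in
starved animals.

## Reduced two-state model (analytic oracle)

A 1-D caricature of the walk: runs point warm or cold only, terminate at
rates λ_w and λ_c, and each new run is cold with probability
q = (1+p)/2. By renewal-reward, the expected fraction of time per
direction gives

    E[bias] = (q/λ_c − (1−q)/λ_w) / (q/λ_c + (1−q)/λ_w),

which reduces to (λ_w−λ_c)/(λ_w+λ_c) when p = 0 and to 2q−1 when the
rates are equal. Because this bias is computed by the *same*
`thermotaxis_bias` code used for real tracks, the closed form provides an
independent end-to-end check of the statistic at finite sample sizes
(200 worms × 1800 s leaves a small O(mean-run/duration) truncation
transient, well inside 3 Monte-Carlo SE).

## Run/turn segmentation

Centroid tracks are boxcar-smoothed (default 1 s) before headings are
computed; stationary steps inherit the previous heading. A turn fires
where the heading change across a 2 s sliding window exceeds 50°, with
contiguous suprathreshold frames collapsed into one event placed where
the new heading takes over; changes ≥ 135° are classed as reversals (a
kinematic stand-in for posture-scored backward movement — the centroid
alone cannot distinguish a tight 160° forward turn from a true
reversal). Runs shorter than 2 s are discarded and counted in the log.
None of these thresholds are printed in the field's methods sections
(segmentation is delegated to tracker software); they are free,
documented parameters of `SegmentationParams`, and the defaults recover
≥ 93% of simulated ground-truth turns within ±1 s for both fed-like and
starved-like parameter regimes.

Direction classes use the sign of cos φ relative to the gradient axis
with a configurable orthogonal band (default 0°: only exact ±90°
orientations are orthogonal, and those fall out of the bias numerator
while remaining in the denominator). A switch to exclude orthogonal runs
from the denominator entirely is provided but off by default, since the
bias formula as stated normalises by total run duration.

## Mardia-Watson-Wheeler test

Implemented from scratch on uniform scores (the statistic is the
package's own): pooled circular ranks with ties averaged, β_j = 2πr_j/N,
W = 2Σ(Cᵢ²+Sᵢ²)/nᵢ, asymptotic p from χ²_{2(k−1)}. The asymptotic
p-value is the default (matching common usage); for group sizes below
~10 the exhaustive enumeration (`exact=True`, k = 2) or the random
permutation p with the add-one estimator (never exactly zero) is
recommended. Random tie-breaking is not used; ties get averaged ranks.
Type-I error at n = 30/group calibrates to 0.05 within Monte-Carlo error,
and the null W distribution matches χ²₂ (KS distance < 0.05 at 5000
replicates).

## Calcium trace model and quantification

Synthetic fluorescence is F(t) = F₀·e^{−t/τ_bleach}·(1 + Σ kernels) +
ε(t), ε ~ N(0, (noise_sd·F₀)²). Events are instantaneous-rise,
exponential-decay kernels (relative amplitude 0.25, τ = 3 s for AWC-like
presets); in stochastic mode onsets follow an inhomogeneous Poisson
process with rate r₀ + r₁·max(0, T(t) − T_thresh), thinned per-frame
(rate·dt ≪ 1 at 2 Hz); in deterministic mode a single sustained step
begins at the first frame where the ramp reaches the programmed onset
temperature (AFD-style threshold response). Onsets are restricted to
after the 10-frame baseline window so ΔF/F baselines stay event-free.

Ground truth is defined as the suprathreshold set of the *noiseless*
ΔF/F trace (what an ideal noise-free measurement would classify), so
truth remains exact under photobleaching, and with noise_sd = 0 detection
recovers it identically. The raw programmed kernel onsets are kept
separately in `meta["kernel_onsets"]`.

Quantification follows the standard definitions: ΔF/F in percent
relative to the mean of the first 10 frames (a non-positive baseline
raises, signalling failed background subtraction); responses are maximal
intervals of ΔF/F strictly > 10%, with intervals separated by ≤ 1
subthreshold frame merged and intervals < 2 frames discarded (both
configurable; the merge/minimum values are package defaults, as the
convention leaves them unstated). An optional exponential
bleach-correction pre-step exists but is off by default. T* is the ramp
temperature at the earliest onset; with a 0.05 °C/s ramp at 2 Hz its
granularity is 0.025 °C, and round-trip error at 2% noise stays within
one frame because the deterministic step amplitude (150%) dwarfs the
noise floor. Peri-T_c scoring detrends the 18–22 °C window by
least-squares line subtraction and applies the 10% threshold to the
*detrended* trace (the convention does not state which trace the
threshold applies to in that window; detrended is the default here since
drift otherwise dominates), optionally requiring a minimum first
derivative — an automated approximation of what is traditionally a
manual call with a derivative overlay.

## Group statistics

Statistics operate only on assay-level tables (one value per assay;
per-worm data never reach group tests). Two-group comparisons default to
Welch's unequal-variance t-test — sources typically say only "Student's
t-test", and Welch is the safer default — with the classic pooled test
behind `equal_var=True`. More than two groups use one-way ANOVA with
Tukey HSD. The feeding-state contrast fits the two-factor OLS
`value ~ genotype * feeding_state` with treatment coding and reports the
Wald F of the interaction (equal to t² in the 2×2 case, asserted
numerically to 1e-9) plus the difference of (fed − starved) differences
as the effect size; estimated-marginal-means machinery reduces to this
in the balanced 2×2 design.

## Problem sizes

The test suite and the acceptance script run the behavioral conditions at
their native sizes (8 assays × 15 worms × 35 min per condition; the
closed-form grid at 200 worms × 1800 s per setting; 100 null replicates
for orientation uniformity; 2000 replicates for test calibrations; 200
noisy calcium traces), chosen so every Monte-Carlo check retains ≥ 3σ
margins while the whole suite completes in about a minute of simulation
time.

## What the synthetic data do not establish

The generator emulates point-worm kinematics, not posture: omega bends,
head swings and backward crawling are represented only through heading
kinematics, so reversal *classification* (as opposed to turn detection)
is approximate by construction. It contains no tracking noise model
(centroid jitter, dropped frames, identity swaps), no worm-worm
interactions before track censoring, and its calcium model has no motion
artifacts, no indicator nonlinearity and no slow baseline drift other
than exponential bleaching. Passing recovery tests therefore demonstrate
correctness of the analysis chain under the stated generative
assumptions — they do not certify performance on tracker output with
qualitatively different noise. The T* definition (ramp temperature at
earliest onset) is a documented stand-in for a previously published
procedure whose details are not restated in this field's methods
sections.
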