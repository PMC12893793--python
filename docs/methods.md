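# Methods

## Response model and preprocessing

Raw fluorescence traces F (cells × frames) are converted to fractional
change on a single-trial basis: ΔF/F = (F(t) − p)/p, where p is the mean F
over the `baseline_ms` (default 200 ms) preceding each stimulus onset.
Cell-trials with p ≤ 0 are flagged invalid and excluded, never imputed; the
count is logged via a warning and the invalid mask on the segment object.
ΔF/F is stored as a fraction and rendered as percent only for display.

The scalar single-trial response is the mean ΔF/F over post-onset frames
whose **centers** fall in the half-open window [450, 1300) ms. Frame d
(d = 0 at onset) covers [d, d+1)/rate, so its center is (d + 0.5)/rate; the
half-open center rule makes the frame set unambiguous at any frame rate and
is checked in the tests against a brute-force enumeration. For natural
movies the same rule selects frames per `movie_bin_ms` (default 166 ms,
about five frames of a 30 fps movie) bin; only complete bins are kept, so a
10 s movie yields 60 bins, each a condition whose trials are the repeats.

Quality control retains cells satisfying all of: (a) adjusted Fisher–Pearson
sample skewness of the raw trace > 2 (`scipy.stats.skew(bias=False)`;
zero-variance traces are failed with reason "degenerate trace"); (b) evoked
response above baseline by a one-sided, equal-variance two-sample t test at
p < 0.001, with per-trial window means as the sample unit (n equals trial
count for both the evoked and baseline samples); (c) presence in the matched
cell set of the companion session when one is given. The criteria are
conjunctive, hence order-independent. Cross-session ROI matching is a greedy
one-to-one pairing by ascending centroid distance (defaults: max 10 px,
mask IoU ≥ 0.3), ties broken by higher IoU then lower index. This matcher is
an explicit, simple approximation to location-plus-morphology matching.

## Decoding space and discriminability

For two conditions with response matrices A, B (cells × trials):

* signal axis dU = mean(B) − mean(A) (sign convention: second minus first;
  luminance ordered scotopic → photopic, orientations ascending);
* noise matrix: each condition's trials minus its own trial mean,
  concatenated (cells × (n_A + n_B)); e1 is its first principal component
  (PCA over trials; the blocks are zero-mean per cell so feature centering
  is a no-op and e1 equals the first left singular vector), sign-fixed so
  e1 · **1** ≥ 0;
* n1 = normalize(e1 − (e1·dU_unit) dU_unit). If e1 is numerically parallel
  to dU (residual norm < 1e-8) the second noise PC is used with a warning;
  a zero dU raises a degenerate-basis error.

Projected trials (2 × n per condition) are summarized by
d′ = sqrt(ΔU Σ⁻¹ ΔUᵀ), with Σ the pooled covariance of the mean-centered
projected trials of both conditions (denominator n_A + n_B − 2). The
package's literal quadratic form ΔU Σ ΔUᵀ is exposed as
`method="raw_quadratic"` for comparison; the Mahalanobis form is the
default because it is the standard discriminability index for this
decoding construction and is scale-invariant. A singular Σ is
ridge-regularized with ε = 1e-6 · trace(Σ)/2 (scale-aware, negligible for
well-conditioned data) and a warning; ΔU = 0 returns d′ = 0.

Cross-validation: per iteration, `n_train` (default 40) trials per condition
are sampled without replacement, the basis is fitted on them, the held-out
trials are projected, and d′ is computed on the held-out projections only
(both ΔU and Σ from the test set by default; `cov_source="train"` pools Σ
from the projected training trials instead — the choice of held-out
covariance was genuinely open and both are provided). The reported d′ is the mean over
`n_iterations` (default 50) iterations; one seed drives the whole schedule.
For movie bins and other small repeat counts the split scales to
floor(0.8·n) training trials, clipped so at least 2 trials remain on each
side.

Shuffled-label nulls pool both conditions' trials and reassign them at
random before rerunning the cross-validated procedure; observed values are
referenced to percentiles of that null.

## Coding-axis geometry

dμ per cell is the same second-minus-first trial-mean difference as dU's
entries. The pairwise statistics are: Pearson correlation of dμ_a and dμ_b
across cells (NaN-flagged if either has zero variance); the cosine of the
raw dU vectors; the overlap of the top round(0.1·n) |dμ| sets, reported as
100·|A∩B|/|A| with |A| = |B| (the denominators coincide; Jaccard
|A∩B|/|A∪B| is available as an option since the denominator convention for
this statistic is a genuine free choice), with threshold ties broken by
cell index; and per-cell log response ratios ln(mean_B/mean_A), excluding
cells below `min_mean` in either condition (natural log by default — the
base is configurable and recorded in the output).

The grid-level report computes these for every valid level pair of each
requested variable pair — orientations 45° apart, scotopic/photopic,
contrast pairs, SF/TF pairs one octave apart — at every fixed setting of
the remaining attributes, with dμ for one variable always computed holding
the other at its first level. Per-combination results are averaged only at
report level, never before the correlation. When cross-validation
parameters are supplied the var_a discrimination d′ is attached to each
combination, giving the |axis dot| versus d′ pairs for the
orthogonality-versus-fidelity analysis (absolute values are taken before
averaging).

## Scalar-gain test

`normalize_by_condition_max` divides every trial in a condition by that
condition's maximum **trial-averaged** response across cells (single-trial
maxima are noise-dominated, so the constant is always computed from trial
means). The operation is idempotent. With `by="luminance"` all conditions
at one light level share a constant — the form used for dataset d′ ratios,
so that within-light-level (e.g. orientation) discrimination is untouched:
a common positive scalar cancels in the scale-invariant d′.

`gain_sim_dprime` draws scotopic trials from N(μ, Σ) and photopic trials
from N(g·μ, g·Σ) (variance, not SD, scaled; default two neurons with
μ = (1, 0.5), Σ = 0.01·I, g = 2, 200 trials) and reports cross-validated d′
before and after normalization plus the ratio. `dataset_dprime_ratio`
applies the same pre/post comparison per stimulus setting on any dataset.
When the pre-normalization d′ does not exceed the shuffled-null 95th
percentile, the ratio is reported as NaN (undefined: there was no luminance
information to erase). Post-normalization the two conditions retain unequal
variances (Σ versus Σ/g after scaling); this is deliberate — the statistic
targets mean separation, which is what the gain hypothesis predicts should
vanish. The construction is parameterized by population size; the package
demonstrates it at 2 and 200 cells.

## Synthetic population generator

The generator defines the study conditions for all simulation-based
checks. Per-cell sensitivities (dμ per variable) are drawn from a zero-mean
multivariate normal whose pairwise correlations are the model parameter:
ρ = 0 is the random encoding model, |ρ| = 1 the shared model (the singular
case is handled by eigenvalue factorization). Condition means are
baseline ± dμ/2 over a full factorial grid of two-level variables. Trial
noise is diag(noise_sd²) plus one shared rank-1 component
loading·loadingᵀ, sampled structurally (mean + sd·z + loading·u), which
realizes the covariance exactly and makes every draw reproducible from the
seed. Under the scalar-gain mode the photopic mean column is exactly
g × the scotopic column and the photopic covariance is g × scotopic.

Defaults, chosen once as representative of GCaMP6s population imaging:
baseline mean 1.0 ΔF/F; dμ SD 0.5 (only the correlation structure carries
the headline geometry; the scale is free); private trial-noise SD 0.3
(trial-to-trial variability ≈ 30% of the mean response); shared loading
0.15 per cell (half the private SD, so the shared dimension dominates the
population covariance — e.g. eigenvalue 1000·0.15² ≫ 0.3² at 1000 cells —
and e1 is well defined, as the decoding construction assumes); 50 trials
per condition; default grid 2 orientations (0°, 45°) × 2 luminances.

Trace synthesis renders each trial's scalar response a as an exponential
transient a·exp(−t/τ) (τ default 1.0 s, a single-exponential stand-in for
GCaMP6s decay) starting at the onset frame on a constant raw baseline, plus
optional white noise; overlapping transients add linearly. With zero noise,
the full preprocessing pipeline recovers a × w, where
w = mean over response-window frames of exp(−d/(rate·τ)) is the
closed-form window kernel factor exposed as `window_kernel_factor`.

What the generator does **not** emulate: real calcium nonlinearity and
saturation, neuropil contamination, slow drift and motion artifacts,
non-Gaussian (e.g. lognormal) rate distributions, stimulus-dependent noise
correlations beyond one global shared dimension, and temporal structure of
movie responses beyond bin means. Passing tests therefore certify the
analysis machinery and its statistical contracts under the stated
multivariate-normal conditions, not the biology of any particular dataset.

## Problem sizes and runtime

The test suite and the acceptance script run at desk scale: closed-form d′
recovery uses 2-cell populations with 500 train/500 test trials and 50
iterations; encoding-model recovery uses 1000 cells × 50 trials over 20
seeds; the gain-regime separation uses 200 cells × 50 trials over 20 seeds;
the overlap baseline uses 1000 cells over 100 seeds; population-size
scaling uses 50/200/800 cells over 20 seeds. These sizes put every
Monte-Carlo check several standard errors away from its decision boundary
while keeping the whole suite under a minute of compute.

## Known limitations

* The d′ of the raw quadratic form grows with the square of response scale
  and is provided only for comparison; all invariance guarantees hold for
  the Mahalanobis form.
* With very small held-out sets (2–3 trials per side) the null distribution
  of d′ is heavy-tailed; null-referenced conclusions need adequate repeats
  (the movie decoder warns and skips below 4 repeats, but 10+ is advisable).
* At population scale the max-normalization constant is estimated from
  finite trials, leaving a small residual luminance d′ even under a perfect
  gain code; the d′ *ratio* remains far below the random-encoding regime
  (complete separation in the tests), but "post ≈ null" holds exactly only
  as trial counts grow.
* ROI matching is centroid/IoU greedy matching, not a morphological model;
  it is intended for simulated or well-registered data.
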