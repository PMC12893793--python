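# popax — population coding-axes analysis for calcium imaging

`popax` asks how a neural population jointly encodes two stimulus variables —
for example, whether mouse primary visual cortex (V1) represents grating
orientation and mean luminance along *orthogonal* population axes, so that a
luminance-invariant orientation code coexists with an explicit luminance
signal. It is aimed at systems neuroscientists working with two-photon
calcium imaging (suite2p-style fluorescence traces plus stimulus event
tables) who want cross-validated population decoding and coding-axis
geometry without writing the plumbing each time.

## What it computes

**Responses.** Single-trial responses are ΔF/F = (F(t) − p)/p with p the mean
raw fluorescence in the 200 ms before stimulus onset, averaged over frames
whose centers fall 450–1,300 ms after onset (the GCaMP6s response peak); for
natural movies, the mean ΔF/F per 166 ms time bin per repeat. Cells are kept
if their trace skewness exceeds 2, their evoked response beats baseline in a
one-sided two-sample t test at p < 0.001, and they are matched across
sessions.

**Decoding (dDR + d′).** For two conditions A and B with trial matrices
(cells × trials), the decoding plane is spanned by

- the signal axis `dU = mean_B − mean_A` (unit-normalized), and
- the noise axis `n1`: the first principal component `e1` of the noise
  matrix (per-condition mean-centered trials, concatenated,
  N_cells × 2·N_trials), orthogonalized against dU.

Trials are projected into (dU, n1) and discriminability is the Mahalanobis
index

    d′ = sqrt(ΔU Σ⁻¹ ΔUᵀ)

with ΔU the projected mean difference and Σ the pooled 2×2 covariance of the
mean-centered projected trials (the raw quadratic form ΔU Σ ΔUᵀ is available
as a documented variant). d′ is cross-validated: fit the plane on 40 of 50
trials per condition, evaluate on the held-out 10, average over 50
iterations.

**Geometry.** Per-cell sensitivities dμ_a, dμ_b (change in trial-averaged
response across the two levels of each variable), their Pearson correlation,
the cosine `dU_a · dU_b` between decoding axes, the overlap of the top-10%
|dμ| ("most informative") cell sets, and response log-ratios.

**Scalar-gain control.** If luminance were a pure gain g (photopic ~
N(g·μ, g·Σ)), dividing each light condition by its maximum trial-averaged
response would erase luminance information. The d′ ratio (post/pre
normalization) is ≈ 0 under a gain code and ≈ 1 under heterogeneous,
bidirectional (high-dimensional) luminance modulation.

**Synthetic populations.** A generator produces multivariate-normal trial
responses with per-cell sensitivities drawn at a chosen correlation ρ
between variables (ρ = 0: random encoding model, orthogonal axes; |ρ| = 1:
shared model, parallel axes), diagonal-plus-rank-1 trial noise, an optional
scalar-gain luminance mode, and GCaMP6s-like exponential-transient traces
for end-to-end testing.

## Worked example

```python
import popax

# 500-cell population, orientation and luminance encoded independently
pop = popax.make_population(n_cells=500, dmu_rho=0.0, seed=1)
ds = popax.sample_trials(pop, n_trials=50, seed=2)

scot0 = ds.responses.single(orientation_deg=0.0, luminance="scotopic")
phot0 = ds.responses.single(orientation_deg=0.0, luminance="photopic")
scot45 = ds.responses.single(orientation_deg=45.0, luminance="scotopic")

res = popax.cv_dprime(scot0, phot0, n_train=40, n_iterations=50, seed=3)
print(f"luminance d' (0 deg gratings): {res.mean_dprime:.2f} +/- {res.sd_dprime:.2f}")

dmu_ori = popax.dmu_per_cell(scot0, scot45)
dmu_lum = popax.dmu_per_cell(scot0, phot0)
print(f"dmu Pearson r:   {popax.dmu_correlation(dmu_ori, dmu_lum):+.3f}")
print(f"dU_ori . dU_lum: {popax.axis_alignment(dmu_ori, dmu_lum):+.3f}")
print(f"top-10% overlap: {popax.informative_overlap(dmu_ori, dmu_lum)[0]:.1f}%")

ratio = popax.dataset_dprime_ratio(ds.responses, n_iterations=20, seed=4)
print(f"d' ratio after max normalization: {ratio.dprime_ratio:.2f}")
```

prints

```
luminance d' (0 deg gratings): 32.58 +/- 4.77
dmu Pearson r:   -0.029
dU_ori . dU_lum: -0.030
top-10% overlap: 12.0%
d' ratio after max normalization: 1.00
```

Read: luminance is strongly decodable from this population (d′ ≈ 33), yet
the orientation and luminance sensitivities are uncorrelated across cells
(r ≈ 0), the decoding axes are orthogonal (cosine ≈ 0), the most-informative
cell sets overlap at roughly the 10% chance level, and max normalization
leaves luminance d′ intact (ratio ≈ 1) — the signature of independent,
high-dimensional joint coding rather than a shared axis or a scalar gain.

A `popax` command-line tool wraps the same steps:
`popax simulate`, `popax preprocess`, `popax decode`, `popax axes`,
`popax gainsim`, `popax ratio` (see `popax --help`).

For estimator-style composition with scikit-learn, `popax.DDRBasis` is a
transformer (fit on trials × cells with binary condition labels; transform
projects into the decoding plane) and `popax.DPrimeDecoder` runs the
cross-validated d′ procedure with `get_params`/`set_params` support.

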