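# Methods

## Model

Each gene is modelled independently. Let `y` be the `p`-vector of that gene's
standardized measurements for one sample — one entry per platform in
gene-level mode, one per probe (across all platforms) in probe-level mode —
with rows standardized to sample mean 0 and sample variance 1 (denominator
`n − 1`) across the `n` samples. The single-factor model is

```
y = λ f + e,   f ~ N(0, 1),   e ~ N(0, Ψ),   f ⟂ e,   Ψ diagonal,
```

with implied covariance `Σ = λλᵀ + Ψ` constrained to unit diagonal, so
`ψⱼ = 1 − λⱼ²` and `λⱼ` is the correlation between measurement `j` and the
latent expression `f`. The model is scale invariant: any per-feature
rescaling of the raw data is absorbed by standardization, and the unified
score is unchanged (asserted to 1e-10 in the tests). The sign of `λ` is not
identified; the fit resolves it deterministically as `sum(λ) ≥ 0` (ties:
first nonzero loading positive).

The unified expression measure is the Thomson (regression) factor score

```
E[f | y] = λᵀ Σ⁻¹ y = (1 + λᵀ Ψ⁻¹ λ)⁻¹ λᵀ Ψ⁻¹ y,
```

computed through the right-hand form, which inverts only the diagonal `Ψ`.
The two forms are algebraically identical (checked to 1e-10). The weights
`λᵀΣ⁻¹` grow with the corresponding loading, need not sum to one, and can be
negative when a loading is negative.

## Estimation

The likelihood is the Gaussian likelihood of the standardized vectors. Two
scatter matrices appear and are deliberately distinguished:

- fitting uses the sample correlation matrix `R = YYᵀ/(n−1)`, which has an
  exactly unit diagonal — the standard choice for correlation-matrix factor
  analysis, and the reason the fitted `λ̂, ψ̂` satisfy `λ̂ⱼ² + ψ̂ⱼ = 1`
  exactly (the ML stationarity conditions reproduce the scatter's diagonal);
- `loglik(model, data)` reports the exact Gaussian log-density of the data
  (scatter `YYᵀ/n`), e.g. collapsing to the sum of iid standard-normal
  log-densities when `λ = 0`.

The estimates maximize the `R`-based likelihood by EM. The E-step uses
`E[f|y] = λᵀΣ⁻¹y` and `E[f²|y] = 1 − λᵀΣ⁻¹λ + (λᵀΣ⁻¹y)²`; the M-step is the
usual factor-analysis update, all in O(p²) per iteration via the rank-one
Woodbury identities. Three numerical devices address EM's known slowness for
this model, none of which changes the fixed point:

1. **Safeguarded extrapolation (SQUAREM-style).** Each cycle takes two plain
   EM steps, extrapolates along the observed contraction, then stabilizes
   with one more EM step; the extrapolated iterate is kept only if it does
   not decrease the likelihood. The recorded likelihood trace is therefore
   non-decreasing (tests allow 1e-9 slack for floating-point noise).
2. **Boundary test.** Convergence toward a Heywood solution (`ψⱼ → 0`) is
   sublinear for EM, so every 8th cycle the smallest uniqueness, if below
   0.3 with a loading above 0.7, is tentatively pinned at the floor; the pin
   is kept only if the likelihood improves.
3. **Profile polish.** Fits that remain unconverged (interior optima with a
   uniqueness near 0.01 — EM can need >10⁵ iterations there) are finished by
   a monotone projected-gradient (Barzilai–Borwein steps with backtracking)
   minimization of the profile discrepancy `log det Σ + tr(Σ⁻¹R)` over `λ`
   with `ψ = 1 − λ²`. This is the package's own code; the test suite's
   independent oracle is a separate multi-start bounded quasi-Newton run.

Defaults: initialization from the leading principal component of `R` scaled
to the unit-diagonal parameterization and clipped to magnitude 0.9
(deterministic; avoids symmetric stalls); convergence when the loading error
estimated from the plain-EM contraction rate is ≤ `xtol = 1e-8` on three
consecutive cycles (a likelihood-change rule is too loose near a perfect fit,
where the surface is flat); `max_iter = 2000` EM steps before the polish
takes over; uniqueness floor `psi_floor = 1e-3`, so loadings are bounded by
`√(1−10⁻³) ≈ 0.9995`. A coordinate at the floor is flagged as a Heywood case
(an improper solution: the optimizer wants `ψ < 0`); such fits are returned
and flagged, never silently dropped, since on weak genes they carry real
information (their frequency falls as the sample size grows). With `p = 3`
the model is just-identified and Heywood fits are common on weak genes —
the triad solution `λ₁² = r₁₂r₁₃/r₂₃` amplifies a small denominator — which
is why genes flagged Heywood, low-expression or low-IQR deserve caution.

Missing values are rejected, as are zero-variance rows (named in the error);
`n > p` is required. Non-convergence is recorded per gene, reported in the
QC output, and counted (never fatal).

## Pipeline modes and QC

Gene-level mode requires a gene on ≥ 3 platforms (with `p = 3` the factor
model is exactly identified by the three correlations; fewer leaves it
underdetermined) and aligns samples by ID, not column order. Probe-level
mode pools all of a gene's probes (each replicate-spotted probe is its own
row), requires `2 ≤ p < n`, and reports a per-platform median loading as the
platform-level summary. Genes that cannot be fitted land in a skipped-genes
report with a reason.

QC flags are deterministic functions of the fit and the raw summaries:
`negative_loading` (any `λ̂ⱼ < 0`), `low_loading` (any `λ̂ⱼ` below the
cutoff, default 0.3), `low_expression` (a platform's median raw value below
its cutoff — default 4.0 log2 units for intensity platforms, 0.0 for
log-ratio platforms, configurable per platform), and `low_iqr` (a platform's
inter-quartile range below 0.5 log2 units). The expression/IQR defaults are
this package's documented choices for where background and dynamic range
make the per-gene covariance unreliable; they are configuration, not claims.

## Bootstrap

Standard errors for loadings resample whole samples (columns) with
replacement — any other unit would break the cross-platform pairing the
model describes — re-standardize, refit, sign-align each replicate to the
point estimate by the sign of the dot product, and take per-coordinate SDs.
Default `B = 100`. Replicates that fail (zero-variance resample, no
convergence) are excluded and counted. Calibration: the bootstrap SE agrees
with the empirical SD of `λ̂` across independent datasets within 30% per
coordinate in the acceptance checks.

## Simulation study

`simulate_gene` draws `λⱼ` uniformly and independently from per-platform
ranges, `f ~ N(0,1)` per sample, and noise with variance `1 − λⱼ²`, so every
platform has unit theoretical variance and `λ = 1` reproduces the truth
exactly. Twelve bundled range configurations cover two-strong/one-weak
platforms, uniformly moderate, uniformly near-noise and mixed regimes;
defaults are 200 genes × 200 samples per configuration. The comparison
pits the factor estimate against the plain mean of the three standardized
platforms. Because an expression estimate's scale and sign are arbitrary,
both estimators are standardized to unit variance and the factor scores are
sign-aligned to the truth before the per-gene sum of squared errors is
taken; this convention is the package's explicit choice. One master seed
spawns independent per-gene streams, so runs are bit-reproducible.

Expected pattern (reproduced by `scripts/acceptance.py`): the factor
estimate wins for ≥ 90% of genes when two loadings are high and one low
(configurations 1, 2, 5); the plain average wins a majority when all
loadings are below 0.3 (configuration 11), where estimated weights only add
noise to an already-equal-weight-optimal problem; when all loadings are
uniformly moderate (configuration 9) the two methods' median SSEs agree
within a few percent. When loadings span 0.7–0.98 (configuration 8) optimal
weighting retains a genuine ~25% median advantage — that gap is a property
of the generative model itself (it persists when the true loadings are used
with no estimation at all), so the two methods should not be expected to
tie there.

## Evaluation statistics

All comparisons run on per-gene standardized values so differently-scaled
summaries are comparable. Pooled replicate variance is
`Σᵢ Σᵣ (y_ir − ȳᵢ)² / Σᵢ (nᵢ − 1)` over disjoint replicate sets of size
≥ 2 (reported as its square root, a pooled SD). Accuracy is the per-gene sum
of squared differences to a standardized reference matrix; for standardized
vectors `SSD = 2(n−1)(1−r)`, so ranking by SSD is ranking by correlation
with the reference (used as a cross-check oracle in the tests). Fold changes
are differences of group means of log2 values. For ROC construction the
truth labels (positive/negative/excluded) and the two-group design are
inputs; the ranking statistic is a Welch t (any monotone statistic yields
the same ROC family; Welch avoids assuming equal group variances), with
zero-variance degenerate genes reported as ±inf/0 sentinels rather than
errors. AUC is trapezoidal over all thresholds of |t|. A `log2(count + 1)`
helper and per-sample median centering are provided for preparing a
count-based reference.

## Synthetic data and what the tests do not show

The fixture generator and simulator produce exactly the model the estimator
assumes: Gaussian factors and noise, loadings constant across samples,
samples independent (fixture replicate sets are near-copies by
construction). Real multi-platform data violate all of these —
normalization artifacts, probe-specific biases correlated across samples,
outliers, batch structure — so green tests demonstrate correctness of the
algorithms and internal consistency of the statistics, not robustness to
real-data pathology. Model-fit QC (Heywood, low-expression, low-IQR flags)
exists precisely because real genes stray from the model.

## Problem sizes

Defaults throughout are the study conditions: n = 200 samples and 200
genes/replicates per simulation condition, B = 100 bootstrap replicates,
500 genes per Heywood-rate estimate, fixture data at 40 genes × 60 samples
with a 31-sample reference. `scripts/acceptance.py` runs the full battery in
about a minute on one CPU.
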