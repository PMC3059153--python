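# unifyexpr

Unified gene-expression measures from multi-platform measurements via
single-factor maximum-likelihood factor analysis.

## The problem

Large expression studies often measure the same samples on several microarray
platforms (and each platform with several probes per gene). The platforms
disagree: probes hybridize differently, dynamic ranges differ, and sometimes
one platform's probes simply measure the wrong thing. Analysts want a single
expression value per gene per sample that uses all platforms, trusts the
concordant ones, and down-weights the discordant one — not a plain average
that gives a broken platform a full vote.

## The model

For one gene, let `y` be the vector of its standardized measurements (mean 0,
variance 1 per platform across samples). The single-factor model is

```
y = λ f + e,       f ~ N(0, 1),   e ~ N(0, Ψ),   Ψ diagonal
```

so the implied covariance `Σ = λλᵀ + Ψ` is a correlation matrix with unit
diagonal (`ψⱼ = 1 − λⱼ²`). The latent factor `f` is the gene's true
expression level in each sample; the loading `λⱼ` is the correlation between
platform `j` and that latent level. Loadings and uniquenesses are estimated
by maximum likelihood with an EM algorithm (extrapolation-accelerated, with a
monotone profile-likelihood polish for near-boundary fits). The unified
expression (UE) is the Thomson (regression) factor score

```
E[f | y] = λᵀ Σ⁻¹ y = (1 + λᵀΨ⁻¹λ)⁻¹ λᵀΨ⁻¹ y
```

— a weighted average of the platforms in which a platform's weight grows with
its loading. A fitted uniqueness driven to its floor (loading pinned near 1)
is a **Heywood case**, flagged rather than hidden, as are genes whose low
expression or tiny dynamic range makes the covariance unreliable.

The package provides:

- `fa_core` — standardization, EM fit, log-likelihood, Thomson scores, sign
  convention;
- `pipeline` — gene-level mode (p = platforms, ≥ 3 required) and probe-level
  mode (p = all probes of a gene across platforms, with a median loading per
  platform), plus QC flags and skipped-gene reports;
- `uncertainty` — bootstrap standard errors for loadings (resampling whole
  samples, keeping cross-platform pairing);
- `simulator` — data generation from the model under 12 bundled loading
  configurations and the factor-analysis-vs-plain-average comparison;
- `evaluation` — pooled replicate variance (precision), sum of squared
  differences to a standardized reference (accuracy), log2 fold changes,
  Welch t ranking and ROC/AUC against supplied truth labels;
- `io` / `cli` — TSV I/O, deterministic fixture generation and the
  `unifyexpr` command-line tool.

## Worked example

```sh
unifyexpr fixtures --out fx --seed 5
unifyexpr unify-gene \
    --platform u133=fx/platform_u133.tsv \
    --platform exon=fx/platform_exon.tsv \
    --platform agilent=fx/platform_agilent.tsv \
    --config fx/qc_thresholds.yaml \
    --out out
```

The log reports `fitted 40 genes (0 non-converged), skipped 0`, and
`out/unified.tsv` holds the gene × sample matrix of unified scores. The QC
table `out/unified.qc.tsv` shows, for example, a concordant gene next to the
planted discordant gene:

```
gene_id  loadings                      qc_flags
CONC00   0.944173,0.839919,0.889368
DISC00   0.819179,0.975864,-0.127132   low_expression,low_loading,negative_loading
```

— the two concordant platforms keep loadings near 0.9 while the platform
that does not correlate with the rest gets a loading near zero (here slightly
negative), a negligible weight in the score, and QC flags marking the gene
for review. The same library calls are available in Python:

```python
import numpy as np
from unifyexpr import standardize, fit_em, thomson_scores
from unifyexpr.simulator import simulate_from_loadings

y, truth = simulate_from_loadings([0.9, 0.9, 0.1], 200, np.random.default_rng(4))
data = standardize(y)
model = fit_em(data)
print(np.round(model.loadings, 2))                       # [0.98 0.82 0.27]
print(np.round(thomson_scores(model, data).weights, 2))  # [0.91 0.08 0.01]
```

Because loadings enter the weights as `λ/ψ`, a loading close to 1 dominates
the score; when sampling noise pushes a loading all the way to the boundary
the fit is flagged as a Heywood case in the QC table.

Running `unifyexpr simulate --out sim --seed 0` reproduces the simulation
study: `sim/summary.tsv` shows the factor estimate beating the
three-platform average for ~100% of genes when two loadings are in
[0.90, 0.98] and one in [0, 0.30] (configuration 1), and losing the majority
when all three loadings are below 0.3 (configuration 11).

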