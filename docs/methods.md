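# Methods

This note documents the models behind `gwasim`, the defaults and why
they were chosen, what the synthetic populations do and do not emulate,
and the numerical decisions that matter when reading results.

## 1. Synthetic populations

### Generative model

Each panel is a samples × variants matrix of biallelic allele counts
(haploid `{0,1}` by default; diploid `{0,1,2}` supported — clonal yeast
isolates behave as inbred lines, so haploid is the natural default, and
all frequency-based formulas are written on allele counts so both modes
share code).

Per-variant site frequencies are drawn from a **folded Beta spectrum**:
`p = 0.5 · Beta(a, b)`, truncated away from 0. A coalescent simulator
would give a mechanistic frequency spectrum, but the populations we
emulate are summarized by *observed* quantities — singleton fraction,
MAF histogram, π — so a directly parameterized spectrum is both simpler
and easier to match to data.

Structure follows a **Balding–Nichols model**: clade *c* draws its own
frequency `p_c ~ Beta(p(1−F_c)/F_c, (1−p)(1−F_c)/F_c)` around the
ancestral `p`, with drift `F_c ∈ [0, 1)`. An optional **recent-clone
subclade** (fraction *f* of the samples, carved out of clade 0) copies a
single ancestral haplotype with within-clone mutation rate ≈ 0. This is
the mechanism behind the characteristic excess of variants at MAF
exactly ≈ *f*: whenever the clone ancestor carries an allele that is
rare elsewhere, the variant's frequency is pinned at the clone fraction.
With *f* = 23/47 ≈ 0.489 (the sake-like preset) roughly 12% of the
MAF-filtered markers land at MAF ≥ 0.45.

**Singletons** are an explicit mass: `singleton_rate · m` variants get
exactly one carrier; all other sites are rejection-sampled to be
polymorphic with ≥ 2 minor-allele carriers, so the singleton fraction is
controlled exactly by one parameter.

**Missingness** is missing-completely-at-random at `missing_rate` (we
know of no defensible missingness mechanism for these panels; MCAR is
the neutral choice and the filters are exercised either way).

**π targeting.** Nucleotide diversity is
`π = Σ_sites [pairwise differences / pairs] / L`. Given a target π, the
genome length `L` is solved from a deterministic pilot draw of the
generator itself (expected per-site diversity × m / π). Realized π then
lands within a few percent of target; tests allow 15% for sampling
noise.

### Presets

Six bundled presets emulate real yeast cohorts at 1/100 of their raw
marker counts (so a full study runs in seconds): sample sizes 47–1011,
π from 0.0008 (sake-like) to 0.0049 (diversity-like), singleton
fractions 2.8–54.2%, and structure ranging from panmictic
(diversity-like) to a half-clonal cohort (sake-like, clone fraction
23/47). The Beta spectrum shapes are approximations chosen per preset to
reproduce the summary statistics; the true per-population MAF histograms
are not tabulated anywhere, so presets should be read as "populations
with these summary characteristics", not replicas.

### What the generator does *not* emulate

Markers are **unlinked**: there is no recombination map and no LD beyond
what relatedness induces (clone-fixed variants are perfectly correlated
with each other, which is LD of the most extreme kind, but there is no
distance-decaying haplotype structure). Consequences: (i) power
estimates on synthetic panels are upper bounds relative to a real,
LD-saturated matrix, where tags compete with causal variants and
significant neighbours are counted as false positives; (ii) the
`linkage_window` option of `confusion_rates` is only meaningful on real
data. Passing calibration tests here demonstrates statistical
correctness of the machinery, not field performance on any particular
real cohort.

## 2. Trait simulation

`simulate_trait` implements the standard additive model: effects
`b_j ~ N(0, 1)` i.i.d. on **standardized** genotypes
`w = (x − c·p̂)/√(c·p̂(1−p̂))` (c = ploidy), genetic value `g = W b`,
residuals `e ~ N(0, Var(g)·(1−h²)/h²)`, phenotype `y = g + e`.

Decisions:

- **Standardized effects** mean the variance a causal variant explains
  is independent of its MAF — which is why detection propensity depends
  on effect size but not on causal-variant MAF.
- **Residual variance scales to the realized (sample) genetic
  variance**, not its expectation, so finite panels hit the target
  heritability on average; the mean realized h² over replicates is 0.8
  to within 0.01 at the default settings.
- Missing causal genotypes are mean-imputed before computing `g`
  (simplest unbiased choice).
- `h² = 0` yields a pure N(0,1) trait (used for null calibration);
  `h² = 1` returns the genetic values exactly.
- Defaults mirror the study design: heritability 0.8, one causal SNP
  for Mendelian traits, ten for complex traits, causal variants drawn
  uniformly among MAF ≥ 5% markers.

## 3. The mixed model

### GRM

`K = W Wᵀ / m` from the same standardized, mean-imputed genotypes.
The diagonal averages ≈ 1; column-centering puts an exact zero
eigenvalue along the all-ones vector (the intercept direction), which
the REML profile handles because the intercept is projected out.
Monomorphic variants are an error — filter first.

### Spectral REML

`K = U Λ Uᵀ` once per panel; rotating y, X and all genotypes by `Uᵀ`
diagonalizes the covariance `σ²_g(Λ + δI)`, so the restricted
likelihood profiles down to a 1-D function of `δ = σ²_e/σ²_g`,
maximized by a 41-point grid followed by bounded Brent search
(`xatol = 1e-6`) on `log δ ∈ [−10, 10]` (natural log, i.e.
`δ ∈ [4.5e-5, 2.2e4]`, h² estimable in `[4.5e-5, 0.99995]`). The
bounds are deliberate: wider ranges put enormous weight `1/δ` on the
GRM's null space and destroy the scan's numerical accuracy at the
h² → 1 boundary, while h² outside the representable range is not
scientifically distinguishable from the boundary anyway. Optima at the
bounds are flagged (`boundary=True`). The spectral likelihood is
tested identical (to 1e-8) to a dense-matrix restricted likelihood on
small instances.

### Per-variant test

Each variant is tested by generalized least squares in the rotated
space with δ **fixed at the null-model optimum** — the EMMAX /
"population parameters previously determined" approximation. The
statistic is a Wald 1-d.f. `b̂²/Var(b̂)` with residual variance on
n−2 degrees of freedom, referred to χ²(1). A likelihood-ratio variant
would be asymptotically equivalent; the Wald form makes a full
permutation scan one matrix product. At `σ²_g = 0` the scan reduces
exactly to per-variant OLS (tested against statsmodels).

The tested variant is **not excluded from the GRM** (proximal
contamination). This mirrors the common practice of passing one marker
set to both the association and the similarity matrix; it costs a
small, documented amount of power, and on strongly heritable traits it
can leave residual association between the phenotype and the GRM's
leading directions that permutations do not reproduce — visible as
occasional FPR outliers even in unstructured panels.

Degenerate variants (collinear with the intercept after rotation) get
statistic 0, p = 1, and a flag. A relative floor on the per-variant
residual variance (`1e-12 · Σ w y²`) guards the exact-collinearity
limit. p-values are floored at 1e-300 to stay in (0, 1].

## 4. Evaluation

- **Permutation threshold**: shuffle phenotype values across samples
  `n_perm` times (default 100), re-scan with the unpermuted δ, record
  each genome-wide minimum p-value; the threshold is the
  `ceil(fwer·n_perm)`-th smallest (5th of 100 at defaults). δ is *not*
  refit per permutation: permutation destroys the genetic covariance,
  making per-permutation REML degenerate, and reusing δ keeps the
  permutation distribution exchangeable with the real scan.
  Significance uses `p ≤ threshold` (the permutation minimum is itself
  attainable), which makes the family-wise error rate under
  exchangeability exactly 5/101 ≈ 4.95% at defaults — measured at
  5–8% over 200-run calibrations, inside the binomial band.
- **λ**: median observed statistic divided by the *analytic* χ²(1)
  median 0.45494 (not the conventional rounding 0.456; the difference
  is < 0.3%).
- **Confusion rates**: TP/(TP+FN), TN/(TN+FP), FP/(FP+TN), FN/(FN+TP)
  with `p ≤ threshold` significance; counts always sum to the tested
  marker count. `linkage_window` (off by default, 25 kb suggested when
  on) excludes non-causal variants within the window of a causal one
  from the FP/TN tally and reports them separately — headline FPRs
  deliberately count linked markers as false positives, matching how
  such rates are usually reported.

## 5. Studies

`run_study` chains sample-causal → simulate-trait → REML → scan →
permutation threshold → confusion summary, reusing one eigendecomposed
engine per panel. Per-run seeds are counter-based
(`SeedSequence(master, spawn_key=(1, i))`): runs are independent and
individually replayable, and `(config, seed)` determines every output.
A failing run is logged and skipped without aborting the study.

Default scale is deliberately desk-sized — 100 runs × ~10⁴ markers ×
100 permutations — which keeps a full study in the minutes range while
leaving Monte-Carlo error on median rates at a few percent. The
calibration and power summaries recomputed by `scripts/acceptance.py`
use: n=200/m=5000×200 runs (FWER, λ), n=500/m=5000×100 traits (h²
recovery), n=1011/m=10⁴×50 runs (complex-trait power), n=300/m=10⁴×100
runs (Mendelian FPR).

Measured at these scales: FWER ≈ 5–8%, median λ ≈ 1.0, mean ĥ² ≈ 0.80,
median Mendelian FPR = 0. Median complex-trait TPR on the idealized
1011-sample panel is ≈ 0.6 — higher than the ≈ 0.5 seen on real
1011-isolate data, as expected from Section 1's caveat: independent
markers (and a 10⁴- rather than ~10⁵-marker multiple-testing burden)
flatter per-SNP power relative to an LD-saturated, structured matrix.

## 6. Known limitations

- No linkage maps, no LD decay, no selection or demography beyond the
  clade/clone drift model.
- Additive traits only — no dominance, epistasis or gene–environment
  terms.
- The LMM uses a single full-rank eigendecomposition (no low-rank
  speedups), fine up to a few thousand samples.
- Only intercept covariates in the bundled studies (the engine accepts
  a covariate matrix in `fit_null_reml`, but the scan is
  intercept + variant).
- Multiallelic VCF records are carried only for filtering accounting;
  their genotypes are not representable in the biallelic call matrix.
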