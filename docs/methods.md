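# Methods

`multiprs` implements a three-cohort, sixteen-trait polygenic-score analysis
of general and specific child psychopathology, together with a synthetic-data
generator that stands in for the cohorts. This note records the models, the
parameter choices that matter, the numerical decisions, and what the synthetic
tests do and do not establish about real data.

## C+T polygenic scores

Scores follow the clumping + thresholding algorithm as implemented by
PRSice-style tools. Summary statistics are first filtered on target-panel
minor allele frequency (≥ 0.01) and imputation INFO (≥ 0.80), then harmonized
to the panel's counted allele: a swapped allele pair negates the effect and
complements the frequency; strand-ambiguous A/T and C/G variants are dropped
outright (safer than frequency-based resolution; every drop is tallied in the
harmonization report). Clumping is greedy: the smallest-p unclaimed variant
becomes an index SNP and claims all unclaimed variants within ±`window_kb`
whose dosage r² with it exceeds `r2_max`; p ties break by (chromosome,
position) ascending so the result is independent of input row order. LD is
measured in the target panel itself (no external reference), and undefined r²
at monomorphic variants is treated as 0 with a warning. Scores at threshold T
sum `dosage × β̂` over index SNPs with p ≤ T; missing dosages are mean-imputed
per variant. The default grid is the standard 15 cutoffs from 1 to 1e-8.
Scores are z-standardized per column by default; because the association
stage standardizes the PRS anyway, this only affects the written profiles,
not coefficients.

## Bifactor outcomes

Symptom subscales y (standardized internally) follow
`y = Λ_g g + Λ_s s + ε`, with one general factor loading on every subscale,
two orthogonal specific factors (internalizing, externalizing) each loading
only on their domain, unit-variance orthogonal factors, and diagonal
uniquenesses Ψ ⇒ `Σ = Λ_g Λ_gᵀ + Λ_s Λ_sᵀ + Ψ`. The fit minimizes the Gaussian
ML discrepancy `log|Σ| + tr(RΣ⁻¹) − log|R| − p` on the sample correlation
matrix by L-BFGS-B over (Λ_g, Λ_s, log Ψ) with an analytic gradient
(`dF/dΣ = Σ⁻¹(Σ−R)Σ⁻¹`), a gradient tolerance of 1e-8, and uniquenesses
floored at 1e-4 (Heywood cases clamped with a warning; non-convergence is
flagged on the fit object, not raised). Two deterministic starts are tried
and the better kept: the first principal component, and a centroid start that
estimates Λ_g from the cross-domain correlation block (for subscales i, j in
different domains, R_ij = λ_gi λ_gj involves no specific factor). The second
start matters: when general and specific loadings are proportional within a
domain the bifactor solution is empirically underidentified — a one-parameter
family mixing g with a specific factor fits almost equally well — and a PC
start can land in the Heywood member of that family. Signs are fixed by
making the mean general loading and the mean per-domain specific loading
positive.

Factor scores are regression (Thurstone) scores `Λᵀ Σ⁻¹ y` — linear,
minimum-MSE, and testable in closed form. A caveat inherent to this choice:
regression scores for orthogonal factors are mutually correlated, so a
specific-factor score retains general-factor variance (population
cross-correlation ≈ 0.2–0.3 at the default loadings; we verified no loading
pattern with communalities below one brings it under 0.15). Bartlett scores
(`(ΛᵀΨ⁻¹Λ)⁻¹ ΛᵀΨ⁻¹ y`, `method="bartlett"`) are conditionally unbiased and
uncorrelated with the *other* true factors; they are provided for users who
need that orthogonality, while the pipeline default stays with regression
scores.

## Association stage

Each factor score is regressed on each PRS at every threshold (separate
models) and, for the general factor, on all 16 PRSs jointly (mutually
adjusted model), always adjusting for sex, age and four ancestry components.
Outcome and PRS are z-scored before OLS so coefficients are standardized (SD
units); covariates are left on their own scales, which does not affect the
PRS coefficient. Rank-deficient designs raise an error naming the collinear
columns. ΔR² for separate models is in-sample (R² of the full model minus
the covariates-only model); the joint model's incremental prediction is
additionally estimated by repeated (default 100×) 10-fold cross-validation:
per repeat, out-of-fold predictions are pooled and `R² = 1 − SSE/SST` is
compared between the full and covariates-only models, then averaged over
repeats (the pooled variant has lower variance than per-fold averaging).
Folds are simple random partitions; everything is deterministic given the
seed. In-sample ΔR² exceeds the cross-validated estimate in expectation, and
pure-noise predictors give a slightly negative CV estimate — both are
asserted in the tests.

The general-vs-specific comparison uses the Clogg z-test on the pooled
estimates, `z = (β_gen − β_spec)/√(SE²_gen + SE²_spec)`, treating the two
estimates as independent. The covariance between the two coefficient
estimates is ignored: the factors are orthogonal by construction, and this
independent-estimates form reproduces the published Δp values within
input-rounding error. Cohort-average explained variance uses sample-size
weighted R values, `(Σ nᵢrᵢ / Σ nᵢ)²`, signed r entering the mean.

## Meta-analysis and multiplicity

Per-cohort standardized coefficients are pooled per trait × threshold ×
outcome. The reported (β, τ, SE) use the DerSimonian–Laird moment estimator
(`τ² = max(0, (Q − (k−1))/C)`) with inverse-variance weights
`1/(s²ᵢ + τ²)`; the p-value is the Han–Eskin RE2 likelihood-ratio test:
maximize the normal random-effects log-likelihood over (β, τ² ≥ 0) — β
profiled analytically, τ² by bounded scalar search with a τ²=0 boundary
check and a grid fallback — and refer `S = 2(l(β̂,τ̂²) − l(0,0))` to the
asymptotic equal mixture ½χ²₁ + ½χ²₂. This DL-for-estimates / RE2-for-p
combination reproduces the published pooled cells within input-rounding
error, whereas pure ML estimates do not. The asymptotic mixture is mildly
conservative for few studies: under a simulated 10-study global null the
empirical type-I error at α = .05 is ≈ 0.033 (20 000 replicates), rising to
≈ 0.045 by 50 studies. Han–Eskin's tabulated small-sample corrections are
deliberately out of scope; with three cohorts the reported p-values should
be read as slightly conservative.

Multiplicity over the trait × threshold grid uses the Li–Ji effective number
of tests: with eigenvalues λᵢ of the PRS-column correlation matrix (taken
from the largest cohort; zero-variance columns — thresholds admitting no
SNPs — are dropped), `Meff = ⌈Σ f(|λᵢ|)⌉` with
`f(x) = 𝟙(x ≥ 1) + (x − ⌊x⌋)`; eigenvalues are rounded to 9 decimals first so
a numerical 2.9999… does not split across the floor. The Bonferroni
threshold is the exact quotient α/Meff. A trait counts as an *independent*
contributor if its separate-model meta p clears α/Meff and its mutually
adjusted p stays below .05. For the joint model each trait enters at the
threshold minimizing its separate-model meta p (ties toward the larger,
more inclusive threshold).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, with
every stage's ground truth exposed.

**Genotypes.** Haplotypes come from a Gaussian copula: within an LD block,
latent normals with Toeplitz correlation are thresholded at the
allele-frequency quantile and two haplotypes sum to a dosage. Thresholding
attenuates correlation, so the latent scale is calibrated (bivariate-normal
orthant probability inverted by Brent's method) to make the realized
adjacent-SNP haplotype correlation equal `within_block_rho`. Allele
frequencies are drawn per block (tightly linked variants share frequencies;
unequal thresholds would cap the attainable correlation below the target).
Blocks are independent; alleles are drawn from non-ambiguous pairs.

**Discovery GWAS.** A shared causal set (`causal_fraction` of SNPs) receives
per-allele effects that are multivariate normal across traits with
correlation `genetic_corr`, each trait rescaled so Σβ²·2f(1−f) = `h2`. The
*reported* effect of a SNP is its marginal association — the LD-implied
convolution `Rβ` of the causal effects in its block — plus Wald noise with
`SE = 1/√(2N f(1−f))`. Reporting marginal rather than causal effects is what
makes C+T coherent: the clump index inherits its pruned neighbours' tagged
signal, as in a real GWAS. For unlinked SNPs the two notions coincide.

**Phenotypes.** The general factor is `Σ w_t u_t + residual` (u_t the true
standardized polygenic values, weights `prs_effects_general`, residual sized
for unit variance using the configured genetic correlation); specific factors
are built the same way from independent residuals, giving orthogonality in
expectation. Subscales apply the bifactor loadings plus unique noise;
covariates are sex, age uniform in a cohort-specific window, and four
standard-normal ancestry proxies with an optional confounding path
(default 0) into the general factor.

**Default conditions and why.** 2 000 SNPs in 5-SNP blocks; `rho = 0.25`;
MAF ~ U(0.05, 0.5); `causal_fraction = 0.25`; `h2 = 0.3`;
`discovery_n = 100 000`; 6 + 6 subscales with general loadings 0.75–0.90 and
specific loadings 0.35–0.20 (heterogeneous and non-proportional — constant
loadings would leave the bifactor rotationally underidentified, see above);
one trait planted at 0.10 SD on the general factor; genetic correlation 0.4
(compound) by default, identity in the null-calibration study. Two
constraints shaped these numbers, both worked out analytically before the
end-to-end test was frozen. First, recovering a planted latent effect within
the meta-analytic sampling band (±2·SE ≈ ±0.015 at 3 × 6 000) requires the
product of PRS validity (corr of the score with the true polygenic value)
and factor-score validity (corr of ĝ with g) to exceed ≈ 0.93. C+T with
marginal weights double-counts residual LD below the clump cutoff, capping
PRS validity near 0.94 under strong blocks (rho = 0.7) but ≈ 0.97 at
rho = 0.25 — where sample r² still crosses the 0.1 cutoff often enough to
exercise clumping — and the default loadings put factor-score validity at
0.967. Second, null traits are only null if their realized polygenic values
are uncorrelated with the planted trait's; with a shared causal set that
realized correlation has sd ≈ 1/√(causal count), so 500 causal SNPs keep it
near 0.045 and nominal false-positive behaviour intact.

**What the synthetic tests do not show.** Realistic human LD (long-range,
variable-strength), pedigree structure, imputation artifacts, binary-trait
log-odds subtleties (binary GWASs are emulated on the linear scale),
age-varying genetic effects, informant-specific method factors, and
non-European portability are all outside the generator. Passing tests
establish that the pipeline's algebra, calibration and accounting are
correct under the assumed structure — not that a real study of this design
would achieve the same validity products.

## Orchestration and reproducibility

A master seed derives per-stage seeds by CRC-hashing the stage name
(`(crc32(name) XOR seed) mod 2³¹`), so cohorts and stages are isolated but
the whole study is bit-reproducible. The per-cohort stage writes factor
scores, PRS profiles and association tables; the study stage writes the
best-threshold meta table, the mutually adjusted table with independence
flags, the Meff report and CV ΔR². Cohort-specific clumping defaults mirror
the two settings used by the real cohorts (250 kb / r² 0.1 for the first
two cohorts, 500 kb / 0.25 for the third). The end-to-end test runs 3 × 6 000
individuals at 2 000 SNPs with CV repeats reduced to 10, sizes chosen to
exercise every stage at full fidelity while keeping the suite fast;
`CvConfig(repeats=100)` remains the analysis default.
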