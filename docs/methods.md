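# Methods

## Scientific setting

`proxymr` implements the analysis ladder used to contrast two ways of
instrumenting a pharmacological exposure in two-sample Mendelian
randomization (MR): a **behavioral proxy** (self-reported caffeine
consumption, in SD units of drinks per day) versus the **biomarker**
itself (plasma caffeine, SD units).  The two choices can produce
opposite-signed estimates for the same outcome (BMI, SD units) because
of the genetic architecture of consumption behavior: variants in
caffeine-metabolism genes *raise* plasma caffeine per cup and therefore
make carriers *drink less* — a titration feedback that inverts the
variant–consumption association at metabolism loci — while other
consumption-associated variants act through behavioral/lifestyle
pathways that can violate the exclusion restriction.

The package provides, as separately usable modules: summary-statistic
I/O and allele harmonization (`gwas_io`), instrument selection and
greedy LD clumping with r²/F strength statistics (`instruments`), the
univariable estimators Wald ratio, IVW, MR-Egger, weighted median and
simple/weighted mode (`mr_core`), Steiger directionality testing with
mechanism stratification and exposure re-weighting (`steiger`),
two-exposure MVMR by Q-heterogeneity minimization (`mvmr`), a two-way
fixed-effects panel estimator with two-way cluster-robust errors
(`twfe`), a structural-equation generator with analytic ground truth
(`synthetic_data`), and workflow orchestration plus a CLI
(`pipeline`, `cli`).

## Estimators and numerical choices

**Harmonization** aligns the outcome (and any second exposure) to the
primary exposure's effect allele, resolving swaps and strand flips.
Palindromic (A/T, C/G) variants default to frequency inference with an
ambiguity window of 0.08 around 0.5: kept only when both frequencies
fall outside the window and agree in direction after alignment; a
palindrome with a missing frequency on either side is always dropped.
These defaults mirror common two-sample MR tooling.  All removals carry
a reason in a drop-log, making the choices auditable.

**IVW** is computed in closed form as the zero-intercept
weighted-least-squares slope with weights `beta_x²/se_y²`; the default
variance model is multiplicative random effects (fixed-effect SE scaled
by `max(1, sqrt(Q/(n−1)))`), the common default in two-sample MR
software.  **MR-Egger** re-orients each SNP to non-negative exposure
beta, fits WLS with intercept, scales SEs by the same `max(1, ·)`
overdispersion rule and uses t(n−2) p-values.  **Weighted median** uses
the cumulative-weight-midpoint interpolation rule; **mode** estimators
use a weighted gaussian KDE with bandwidth
`phi·0.9·min(sd, IQR/1.349)·n^(−1/5)` evaluated on a fixed 512-point
grid spanning the ratio range ± one bandwidth, so the argmax is
deterministic.  Median/mode SEs come from a parametric bootstrap
(default 1000 resamples; the same seed reproduces the SE bit-for-bit).

**Steiger stratification** compares the variance a SNP explains in the
two exposures.  The default r² formula is the t-statistic form
`t²/(t²+n−2)`, which needs no allele frequencies (outcome meta-analyses
often lack them).  The default policy is the strict point comparison of
r²; a significance-gated variant (Z test on Fisher-transformed
correlations) is provided since the underlying test is a Z test.
Exact ties are excluded rather than assigned arbitrarily.

**MVMR-Qhet** minimizes
`Q(β₁,β₂) = Σ (by − β₁bx − β₂bx₂)² / (sy² + β₁²sx² + β₂²sx₂²)`,
whose effect-dependent denominator keeps the estimator consistent under
conditionally weak instruments.  Minimization is Nelder-Mead from the
per-exposure IVW initialization plus four perturbed restarts (best
minimum kept; descent from the IVW start is asserted).  Profile CIs
invert the Q statistic at the χ²₁ 95% cutoff (3.84) by outward
bracketing and Brent root-finding to |ΔQ| < 1e-4 at the endpoints; a
percentile parametric bootstrap is the alternative.  Exposure–exposure
sampling covariance is taken as zero because the exposures come from
non-overlapping cohorts.

**TWFE** builds the consumption index by z-scoring coffee and tea cups
separately within each visit (population SDs), summing, and
re-standardizing within visit (a pooled-scale option exists; the
combination rule is genuinely underdetermined and both are exposed).
The slope is estimated by alternating demeaning over individuals and
visits — which handles unbalanced panels — iterated to a 1e-10
tolerance on the coefficient.  The two-way cluster-robust variance is
the inclusion–exclusion `V_ind + V_visit − V_intersection` of one-way
sandwich estimators with per-component small-sample corrections
`G/(G−1)·(N−1)/(N−k)`; since (individual, visit) cells hold single
observations the intersection term is the heteroskedasticity-robust
meat.  A negative combined variance is clamped to the
individual-clustered component with a warning; when one dimension
collapses to a single level the estimator degenerates to the one-way
problem and one-way clustering on the remaining dimension is reported.

## The synthetic generator

The generator is a linear-Gaussian structural model chosen over an
explicit pharmacokinetic titration model because it reproduces every
qualitative phenomenon of interest — the sign flip, the Steiger split,
the MVMR direct effect, the confounded panel — with exactly computable
reduced forms:

    L = Σ c_j g_j + ε_L                (latent lifestyle)
    D = λ_L·L − λ_M·Σ a_j g_j + ε_D    (consumption)
    P = π_D·D + Σ a_j g_j + ε_P        (plasma caffeine)
    B = θ_P·P + θ_L·L + θ_S·D + ε_B    (BMI)

Reduced-form per-allele effects: `effect_D = λ_L c_j − λ_M a_j`,
`effect_P = π_D effect_D + a_j`,
`effect_B = θ_P effect_P + θ_L c_j + θ_S effect_D`.  Stability requires
`π_D λ_M < 1`.  All phenotype variances and covariances are available
in closed form, so the ground truth carries population SDs and the
reduced forms on the standardized scale that GWAS betas live on.

Default parameters (one choice, made from power arithmetic, not tuned):

| parameter | default | meaning |
|---|---|---|
| m_metab / m_behav | 16 / 8 | variant panel sizes (24 instruments) |
| maf | U(0.2, 0.5) | common variants, decent genotype variance |
| a_j | 0.20–0.35 | metabolism allele effects on biomarker (SD) |
| c_j | 0.14–0.26 | behavioral allele effects on lifestyle |
| λ_M / λ_L / π_D | 0.4 / 0.6 / 0.3 | titration, lifestyle loading, transfer |
| θ_P / θ_L / θ_S | −0.15 / 0.15 / 0.075 | biomarker, pleiotropy, direct effect |
| σ (all) | 1.0 | unit noise SDs |
| cohorts | 50k / 10k / 50k | consumption / biomarker / outcome GWAS |
| panel | 2000 × 4 visits, ρ = 0.5 | TWFE panel, confounding strength |

The cohort sizes are desk-scale stand-ins for the real studies (UK
Biobank-scale consumption GWAS, a ~10k biomarker meta-analysis, a large
outcome consortium); effect sizes were chosen so the weakest variant
reaches association z ≳ 8 at the 5×10⁻⁷ selection threshold (all 24
instruments recovered with high probability) and the weakest behavioral
variant has a Steiger margin of z ≈ 2.5 (≲1% misclassification).
θ_S = |θ_P|/2 makes the exclusion-restriction violation detectable by
MVMR while keeping the metabolism-stratum sign flip dominant.

Each of the three cohorts is simulated independently from sub-seeds,
phenotypes are standardized within cohort, and per-SNP betas come from
simple regression — so the summary statistics carry realistic sampling
error, winner's-curse-free selection does not hold by construction, and
the biomarker and outcome studies deliberately report scrambled allele
orientations (swaps and strand flips, avoiding palindromic pairs) that
harmonization must undo.

The panel generator draws latent per-visit consumption
`z_it = μ_i + v_it` (unit variance, half individual, half transient),
an individual outcome effect correlated with μ_i at strength ρ (so
pooled OLS is biased by ≈ ρ/2 while the within estimator is not), visit
effects, and decomposes z into coffee and tea cups as affine functions
(1 SD ≈ 2 cups coffee ≈ 3 cups tea) with small beverage noise.  Cups
are kept continuous rather than rounded, so panel tests measure the
estimator, not discretization.  Individuals always attend the first
visit and revisit with probability 0.7, making the panel unbalanced
like real repeat-assessment data.

### What the generator does *not* emulate

Linkage disequilibrium between causal variants (the emitted LD matrix
is the identity; a compound-symmetric block LD matrix constructor
exists to exercise clumping), realistic allele-frequency and
effect-size spectra, sample overlap between cohorts, population
structure, assortative mating, non-linear or threshold consumption
behavior, and feedback of the outcome on consumption.  Passing tests
therefore demonstrate correctness of the estimators and the workflow
under the stated linear model, not robustness to those real-data
complications.

## Degenerate inputs and tie-breaks

P-value ties in selection and clumping break lexically by rsid.  A SNP
whose ratio denominator is exactly zero raises rather than being
silently dropped.  Identical ratios short-circuit the mode bandwidth
rule (zero bandwidth returns the common ratio).  Exact Steiger ties are
excluded from both strata.  Exact-fit panels (zero residuals) report an
SE floored at machine-tiny rather than zero.  Missing second-exposure
records are either dropped or filled with beta 0 and a 10⁶ SE sentinel,
by policy.

## Problem sizes used in the test suite

Replicate studies run at the default cohort sizes with 50–300
replicates per property (100 for the sign flip, 200 for estimator bias,
300 for MVMR null coverage, 200 for TWFE bias, 50 for Steiger
accuracy); these sizes give Monte-Carlo error comfortably below each
asserted margin.  The acceptance script runs one full workflow
realization plus 25–50-replicate summaries of the stochastic rates.

## Known limitations

MR-Egger SEs are not bootstrap-based and rely on the overdispersion
scaling convention; the mode estimator's grid resolution (512 points)
bounds its precision at ~1/500 of the ratio range; profile CIs assume a
locally quadratic Q near the minimum and can return an infinite bound
when Q plateaus; MVMR is limited to two exposures by design; the TWFE
module models no dynamic treatment effects or staggered-adoption
heterogeneity.
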