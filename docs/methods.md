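# Methods

`gremlkit` implements the analytic machinery for testing genetic overlap
between a psychiatric disease liability (a schizophrenia-like case-control
trait) and a quantitative reproductive-timing trait, age at first birth
(AFB), using two non-overlapping cohorts genotyped on a shared SNP panel.
This note records the models, the generator that produces the synthetic
study data, the numerical choices, and what the tests do and do not
establish.

## The variance-component model

For traits t = 1..T (T ≤ 3) measured on pairwise-disjoint sample sets, the
linear mixed model is

    y_t = X_t b_t + Z_t g_t + e_t,
    Cov(g_t, g_t') = σ_g(t,t') G,      e_t ~ N(0, I σ_e(t)²),

with G the genomic relationship matrix over the union of samples,

    G_jk = (1/m_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

summed over variants non-missing in both individuals (m_jk counts them;
no mean imputation, which keeps the diagonal unbiased).  Because the
cohorts share no samples, residual cross-trait covariances are structurally
zero and only the T(T−1)/2 genetic covariances are estimated — the key
identifiability property of the split-cohort design.  The binary trait is
analysed on the observed 0/1 scale; `observed_to_liability_h2` applies the
standard threshold-model correction
h²_lia = h²_obs · K²(1−K)² / (P(1−P) φ(Φ⁻¹(1−K))²) separately (off by
default, since which scale a published h² refers to is often ambiguous).

In the three-trait configuration the traits are: disease status (cases 1,
controls 0, pre-adjusted), AFB among women with AFB < 26, and AFB among
women with AFB ≥ 26.  The cut-point 26 is fixed (the cohort-mean
convention) rather than recomputed, favouring reproducibility over
self-reference; `stratify_by_afb` accepts any other cut-point.

## AI-REML

`GREML.fit()` maximizes the restricted likelihood by average-information
updates: gradient dL/dθ_i = −½[tr(P A_i) − y'P A_i P y] and
AI_ij = ½ y'P A_i P A_j P y, with P the usual projection
V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹.  Traces use the identity tr(P A) = Σ (P ∘ A)
on the structured blocks, so each iteration costs one Cholesky
factorization of V plus O(n²) per parameter.

Boundary handling matters more than textbook presentations suggest; the
scheme here is:

* **Variance floors.** Proposals below 10⁻⁶ of the trait's phenotypic
  variance clamp to that floor and the component joins an active set; the
  AI system is re-solved for the free components conditional on the
  boundary move (cross-curvature term included).  A floored component is
  released when its gradient points back into the interior.
* **Covariances are projected, never pinned.** Genetic covariances are
  clipped at a loose rail |σ_g(t,t')| ≤ 1.5·√(σ_g(t)²σ_g(s)²).  The rail
  is deliberately outside the correlation cone: the restricted likelihood
  itself diverges to −∞ as V approaches singularity, so estimates near
  |r_g| = 1 remain unconstrained and the Wald test of r_g = 1 keeps
  two-sided behaviour.  Proposals that make V indefinite (e.g. a jointly
  infeasible covariance pattern in the trivariate model) are rejected by
  step-halving, not silently regularized.
* **Trust region and damping.** The first 3 iterations are damped
  (step scale 0.3) and every component's move is capped at one
  phenotypic-variance unit, because early AI proposals can be wildly out
  of scale.
* **Convergence.** Maximum relative parameter change < 10⁻⁶ (default), or
  — only while a boundary constraint is active — two consecutive accepted
  steps that change the restricted log-likelihood by less than 10⁻⁷·n
  (a boundary optimum can otherwise crawl along a moving constraint).

The sampling covariance of the estimates is the inverse AI matrix at the
optimum.  Genetic correlations r_g = σ_g(t,t')/√(σ_g(t)²σ_g(t')²) carry
delta-method standard errors from the full sampling covariance, including
the covariance between the two variance terms.  The reported `rg` is
clipped to [−1, 1]; the raw estimate is retained and used for Wald tests.
Starting values are half the adjusted phenotypic variance for each
variance, zero for covariances.

A deliberate limitation of any local climber: on small, noisy problems the
restricted likelihood can be bimodal (the single-trait grid-search oracle
exposes fixtures where the global optimum sits at σ_g ≈ 0 while a local
mode exists at high σ_g).  The oracle-equivalence tests use unimodal
fixtures; multi-start is out of scope.

## GBLUP and profile scores

Single-trait GBLUP predicts genetic values for phenotype-missing
individuals (the PRS-GBLUP):

    û_target = σ_u² G_{target,obs} V_obs⁻¹ (y_obs − X_obs b̂),
    V_obs = σ_u² G_obs + σ_e² I,

with GLS fixed effects, and prediction error variance
σ_u² G_jj − σ_u⁴ G_{j,obs} P_obs G_{obs,j} as a per-individual reliability
proxy.  `henderson_mme` solves the full mixed-model equations directly and
serves as the reference implementation in tests (it requires an invertible
G, hence test fixtures build G against the true panel frequencies —
in-sample centering makes G exactly singular along the ones vector).

The profile score (PRS-score) is the weighted allele-count sum over every
QC-surviving SNP: no p-value thresholding and no LD clumping, matching the
dense-polygenic scoring strategy the mixed model assumes.  Per-SNP weights
come from simple linear regression of the pre-adjusted 0/1 phenotype on
dosage (linear rather than logistic, because the weights feed a linear
score and the phenotype is residualized beforehand).  Missing genotypes
contribute the variant's mean dosage, keeping scores comparable across
samples with unequal call rates.  Scores are z-standardized within cohort
by default; standardization changes R² bookkeeping, not p-values.

## The response transform and its regression

The epidemiological U-shape — elevated offspring psychiatric risk for both
young and old mothers — is encoded by the fixed registry-derived quadratic

    z = 2.7214 − 0.1105·X + 0.0018·X²      (X = AFB in years),

decreasing up to its vertex at X = 30.69 years and increasing after.  The
coefficients are taken as given; deriving them is out of scope.  `z` is
regressed on a PRS plus covariates (complete cases, collinear columns
dropped).  The reported R² is the *incremental* R² of the PRS term (full
minus covariate-only model), because covariates explain almost all of the
variance of z and the full-model R² would be uninformative about the PRS;
both are returned.  AFB bin summaries use the fixed bins
[0,20), [20,25), [25,30), [30,35), [35,∞) and Welch's unequal-variance
t-test for pairwise comparisons.

## LD scores and LDSC

LD scores are bias-adjusted sums of squared correlations within a
physical window (default 1000 kb, self-term included):
r̃² = r² − (1−r²)/(n−2).  Univariate LDSC regresses per-variant χ² on
(n/m)·l_j; cross-trait LDSC regresses z₁z₂ on √(n₁n₂)/m·l_j.  Regression
weights are 1/max(l_j, 1) — a deliberate simplification of the full
heteroskedasticity weighting, adequate because validation is
recovery-based rather than implementation-replicating.  Standard errors
come from a delete-a-block jackknife (default 200 contiguous blocks,
shrunk automatically for small panels); the r_g jackknife deletes blocks
jointly from all three regressions so the SE reflects the correlated
numerator and denominators.

Intercept constraints are two independent knobs: the cross-trait intercept
(absorbs sample overlap; constrain to 0 only for provably disjoint
cohorts) and the univariate intercepts (absorb confounding; constrained to
1 by default in r_g, since free univariate slopes are very noisy at desk
scale and can go negative, leaving r_g undefined).

## The synthetic-cohort generator

The generator emulates the study's data structure, not human genetics in
general:

* **Genotypes.** Latent-Gaussian haplotypes: within blocks of 20 adjacent
  variants the latent variables follow an AR(0.7) process (independent
  across blocks); allele = indicator(latent < Φ⁻¹(p)), dosage = sum of two
  haplotypes.  Frequencies uniform on [0.05, 0.5]; variants sit 5 kb apart
  on one chromosome.  This gives realistic short-range LD and exact
  Hardy–Weinberg marginals but no recombination maps, demography, or MAF
  spectrum realism.
* **Effects.** Per causal variant, a trivariate normal draw (disease
  liability, younger-AFB architecture, older-AFB architecture) with
  covariance diag(√h²) R diag(√h²)/m_causal, R holding the target genetic
  correlations (validated PSD at construction).  Defaults encode the
  reciprocal pattern: h² = 0.30/0.10/0.03 and r_g = −0.16 (liability with
  younger AFB), +0.14 (with older), 0.47 (between strata).
* **Case-control cohort.** Liability = genetic value + normal residual;
  case iff liability > Φ⁻¹(1−K), K = 0.01 by default; the population is
  drawn in batches until the case/control quotas (1500/1500 by default)
  fill, i.e. cases are heavily oversampled relative to K.
* **AFB cohort.** Each woman's stratum is assigned by a latent propensity
  that is only weakly genetic (weight 0.1 on the averaged stratum genetic
  values), so stratum-specific architectures — not selection — drive the
  between-stratum r_g below 1; within-stratum AFB is stratum mean
  (26 ∓ 4 years) plus that stratum's genetic value plus residual, scaled
  to the stratum h², with within-stratum SD 2 years.  An optional
  truncation interval implements truncation-selection experiments.  This
  two-architecture device is one admissible generative mechanism for
  heterogeneity, not a claim about the true one.
* **Relatedness.** `inject_relatedness` turns chosen cross-cohort pairs
  into parent-offspring relatives (one transmitted haplotype plus one
  population haplotype), producing GRM entries near 0.5 for the
  relatedness-pruning integration tests.

Passing tests on these data show that the estimators recover the
parameters of this generative model; they do not certify behaviour under
population stratification, assortative mating, dominance, rare-variant
architectures, or genotyping artifacts, none of which the generator
produces.

## Problem sizes

Dense single-CPU linear algebra sets the practical scale: one AI iteration
factorizes an n×n matrix, so fits beyond a few thousand samples are
minutes each.  The test suite and `scripts/acceptance.py` therefore run
desk-scale configurations chosen to preserve the information density
(n²/m) of larger designs:

* trivariate recovery: 400 cases + 400 controls + 1200 AFB women,
  m = 500 variants (160 causal), 30 seeded replicates;
* heterogeneity-test calibration: 450 women per stratum, m = 500,
  200 replicates (stratum size chosen so the Wald statistic is in its
  asymptotic regime — smaller strata leave the test conservative);
* truncation robustness: 50 seeds at n = 320 + 420, m = 400;
* LDSC/GREML concordance: 50 seeds, two cohorts of 400, m = 800;
* the acceptance script: one replicate at 500 + 500 + 1500, m = 800.

At these scales the well-powered quantities (h² of each trait, r_g between
liability and younger AFB) are recovered essentially unbiased, while the
sign of the weak r_g(+0.14) against the h² = 0.03 stratum is detected in
well under 80% of replicates — its per-replicate detection probability is
approximately Φ(σ_g(t,t')·√(n_t n_t'/m)), which stays below 0.8 until the
stratum samples reach several thousand.  The full trivariate sign pattern
is therefore reported but not reliably reproduced at desk scale; the
corresponding recovery check documents this as its expected failure mode.

## Known limitations

* Local optimizer; no multi-start (bimodal small-sample likelihoods).
* LDSC weighting is the simplified 1/l form; absolute SEs differ from the
  full iterative weighting, comparisons between constrained and free fits
  do not.
* The QC battery treats imputation-quality metrics as supplied columns
  (pass-through filter); no imputation is performed.
* Binary traits are modelled on the observed scale; ascertainment is
  handled only through the liability-scale transformation of h², not
  inside the REML itself.
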