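# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## 1. The causal chain and its assumptions

The package analyzes a one-sample Mendelian-randomization design on
individual-level data: genotypes at seven *LPA*-region variants instrument
plasma Lp(a); the proximal outcome is arterial basal superoxide (log RLU,
lucigenin chemiluminescence); the distal outcome is cardiovascular death
over follow-up. Three instrumental-variable assumptions are screened, not
assumed silently:

- **relevance** — the first-stage F of log-Lp(a) on the carrier-count score,
  single-predictor form F = (n−2)R²/(1−R²), with F > 10 the conventional
  threshold (an exactly deterministic first stage reports F = +∞);
- **independence** — per-confounder two-group contrasts across the
  reference/alternative score groups;
- **exclusion restriction** — structurally encouraged by the *cis* design
  (all instruments at the locus that determines the exposure) and probed by
  the MR-Egger intercept.

Because the per-variant exposure and outcome associations feeding MR-Egger
are estimated in the same cohort as the causal estimate, the Egger
diagnostics are winner's-curse-prone; they are a sensitivity analysis and
are documented as such.

Mediation is by nested Cox models — the design's own procedure — not a
counterfactual natural-effects decomposition: the exposure log-HR is fit
with and without log basal superoxide, and attenuation is
100·(1 − ln HR_adj / ln HR_unadj), defined only when HR_unadj ≠ 1. The
exposure–mediator Spearman ρ is reported as collinearity context.

## 2. The synthetic cohort generator

The generator is first-class, tested code: it encodes the causal structure
the analysis assumes so every downstream stage has a ground truth.

**Genotypes.** Each subject receives two haploid draws from a multivariate
normal with unit diagonal and latent correlation matrix C; the draw at locus
j becomes an alternative allele when it exceeds the Φ⁻¹(1−p_j) quantile.
A scalar C (default 0.75, equicorrelated) tunes pairwise LD without a
haplotype reference panel: identity gives independent variants (r̂² < 0.01 at
n = 50000), higher correlation gives the high-D′/modest-r² pattern expected
for rare variants on a shared haplotype background. Non-PSD matrices are
rejected at configuration time.

**Lp(a).** log Lp(a) = 2.3 + Σ β_j·dosage_j − 0.25·diabetes + ε. Defaults:
alt-allele frequencies 0.02–0.15 and per-allele log effects 0.20–0.60 across
the seven variants, sized so the alternative score group runs roughly 3–6×
the reference group's Lp(a) (reference median ≈ 10 mg/dL); diabetics run
~22% lower (the inverse Lp(a)–diabetes association). The noise SD is
derived at simulation time from the realized genetic variance so that the
genetic fraction of var(log Lp(a)) hits a configured target, default 0.90
("over 90% genetically determined"); a target that the variant effects
cannot produce (e.g. all betas zero) is a configuration error with a
diagnostic. The tests verify the realized fraction lands within ±0.05 of
the target at n = 20000.

**Redox panel.** log basal O2·− = 1.0 + θ_d·Lp(a) + ε with noise SD 0.28
(the design's stated SD of log basal superoxide) and θ_d = 0.01 log-RLU per
mg/dL in nondiabetics, 0 in diabetics — the moderation structure. The
L-NAME arm is multiplicative, post = basal·exp(−0.2 + θ_d·Lp(a) + ε'), so
all readouts stay positive while the L-NAME delta (post − basal) is negative
at low Lp(a) (recoupled eNOS) and rises with Lp(a) in nondiabetics only.
NADPH-stimulated superoxide is lognormal and independent of Lp(a); the
Vas2870 arm multiplies it by a sub-unity inhibition factor. The BH4/BH2
ratio declines in Lp(a) (slope −0.004 per mg/dL on the log ratio). hsCRP,
MDA and ApoB are lognormal and independent of Lp(a) — the generator encodes
a locally vascular, not systemic-inflammatory, mechanism.

**Covariates** (age, sex, hypertension, smoking, family history, prior MI,
urgency, BMI, diabetes at prevalence 0.209) are generated independent of
genotype, which *is* the MR independence assumption by construction.

**Survival.** Exponential hazards λ·exp(β_O2·log basal + β_direct·log Lp(a)),
with independent exponential censoring (rate 0.1367, median ≈ 5.07 y)
truncated at 10 y. Defaults β_O2 = 2.0 per log-RLU, β_direct = 0 — full
mediation — and baseline rate 4×10⁻⁴/y, giving ≈ 2–3% events (≈ 25–30
deaths at n = 1027, ≈ 450–500 at n = 20000). A direct-effect knob exists
for partial/no-mediation robustness studies.

All scale choices above were fixed a priori as the package's study
conditions; seeds fan out from a single configured seed through
`numpy.random.SeedSequence` spawn keys, so identical configurations give
byte-identical files and reports.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: kringle-IV repeat copy number, assay drift and
batch effects, competing risks, genotyping error, population stratification,
and any real LD structure beyond an exchangeable copula. Recovery of θ by
two-stage MR here demonstrates internal consistency of the estimator chain,
not robustness to those field artifacts.

## 3. The statistical core

Estimators are written from their definitions; scipy supplies only
distribution functions and the auxiliary KS/Levene trigger tests.

- **Two-group tests.** Auto-selection mirrors applied practice: KS
  normality (against the fitted normal) on each group at 0.05 chooses the
  pooled-variance t test or Mann-Whitney U. U uses midranks; p is by full
  enumeration of the C(n, n₁) arrangements when n₁+n₂ ≤ 12 (two-sided:
  arrangements at least as far from n₁n₂/2) and otherwise a tie-corrected,
  continuity-corrected normal approximation.
- **Correlation.** Spearman is Pearson on midranks; p by the t
  approximation with n−2 df.
- **FDR.** Benjamini–Hochberg step-up, monotone, capped at 1.
- **Linear models.** OLS with an intercept; standardized betas rescale
  slopes by sd(x)/sd(y), so a univariate standardized beta equals Pearson r.
  A Levene test across terciles of the fitted values significant at 0.05
  flags heteroscedasticity and switches the intervals to a seeded percentile
  bootstrap (default 2000 replicates). Rank deficiency is an error naming
  the aliased columns.
- **Moderation.** y ~ x + m + x·m (+ covariates) with a binary moderator
  (each stratum n ≥ 10); the interaction coefficient gets a percentile-
  bootstrap CI and an OLS t p-value (the p is what calibration checks use).
- **Cox.** Newton–Raphson on the partial likelihood with step-halving;
  Efron ties by default, Breslow by flag; columns are mean-centered for
  conditioning (estimates unaffected); convergence at max |score| < 10⁻⁹;
  |β| > 20 is reported as non-identifiable (monotone likelihood / complete
  separation); zero events is an error. Untied event times are processed
  fully vectorized via suffix sums, tied blocks in a short loop. Wald CIs
  use exp(β ± z₀.₉₇₅·se).
- **Wald utilities.** A printed (HR, CI, p) triple is completed from any
  sufficient subset: HR = exp((ln lo + ln hi)/2), se = (ln hi − ln lo)/(2z),
  p = 2(1−Φ(|ln HR|/se)); an identity-scale variant serves printed
  regression coefficients. z₀.₉₇₅ = Φ⁻¹(0.975) throughout.
- **Power.** Two-sided normal approximation
  Φ(|δ|/se − z) + Φ(−|δ|/se − z), se = sd·√(1/n₁+1/n₂). The design check
  uses the 1:2 allocation (bottom tertile vs upper two) of 100 subjects;
  a 1:1 split also clears the 90% bound, so the check is a bound, not an
  equality.

**EM haplotypes.** For two biallelic loci, only double heterozygotes carry
latent phase; the EM E-step splits them between AB/ab and Ab/aB by the
current odds. Convergence at max |Δfreq| < 10⁻¹⁰ or 1000 iterations; the
observed-data log-likelihood is tracked and is nondecreasing; a sample that
is entirely double-heterozygous has a symmetric bimodal likelihood and is
flagged non-identifiable. D = p_AB − p_A p_B, D′ = |D|/D_max, r² = D²/(p_A
p_a p_B p_b); monomorphic loci are errors.

## 4. Design choices where the design was open

- **Score form.** The "unweighted summative" score counts variant-carrier
  indicators (0–7), not alt alleles (0–14): carrier counting is the only
  form consistent with grouping by "any alternative allele at ≥3 variants".
  The dominant-model choice also matches the stated rationale of improving
  power in a modest cohort. Subjects carrying 1–2 variants are unassigned
  for the dichotomy; the continuous per-SD score is standardized within the
  ≥2-carrier stratum.
- **Missingness.** A subject is reference only with an observed 0 at all
  seven instruments; carrier counts are computed over nonmissing calls with
  a per-subject completeness flag.
- **Association model.** Per-variant simple additive regression of
  log-Lp(a) on dosage, unadjusted; monomorphic variants are flagged and
  excluded rather than aborting.
- **Tertiles.** Linear-interpolation empirical quantiles at 1/3 and 2/3;
  values on a cut point go to the lower group; an empty tertile (heavy
  ties) is an error naming the tie mass. The default contrast is bottom
  tertile vs upper two (the design's power-calculation contrast); the
  top-vs-bottom-two form is available by flag since the two readings both
  appear in applied use.
- **Egger weights and inference.** First-order weights 1/se_y² with the
  fixed-weight covariance (X′WX)⁻¹ and a normal p for the intercept — no
  overdispersion scaling. Level calibration of that test is run under
  independent instruments (latent_corr = 0): with strongly LD-correlated
  variants the per-variant summaries are cross-correlated and the
  fixed-weight null does not apply, so the default high-LD generator is not
  a valid null for the *level* check (it remains the study condition
  everywhere else).
- **MR recovery population.** The two-stage estimate targets the
  nondiabetic slope θ because the default generator sets the diabetic slope
  to zero; the full-cohort estimand is a mixture. Mechanistic MR checks
  therefore condition on nondiabetics, mirroring the analysis focus.
- **Mediator adjustment.** The adjusted Cox model enters the true
  log-hazard scale mediator (log basal superoxide), so under full mediation
  the exposure coefficient is consistently ≈ 0 up to non-collapsibility,
  which at these event rates is negligible relative to the CI width.

## 5. Numerical details and degenerate inputs

- p-values are clipped to (10⁻³⁰⁰, 1]; q ≥ p elementwise by construction.
- The copula Cholesky adds 10⁻¹⁰ jitter so exactly singular PSD latent
  correlations remain usable.
- Zero-residual OLS flags se → 0 rather than dividing by zero; constant
  inputs to correlation are errors.
- Survival with max follow-up 0 produces zero events and the downstream Cox
  fit raises "no events".
- Problem sizes in the checks: direction/mediation properties at
  n = 20000; calibration at 1000 replicates (n = 500 per test, n = 5000 for
  Egger); recovery over 200 replicates at n = 2000; oracle equivalence
  against a 10⁻⁴/10⁻⁵ grid search and a reference Cox implementation on 50
  random small datasets. These sizes make the large-sample identities
  visible while keeping the default suite fast.

## 6. Known limitations

- One-sample MR with in-sample instrument selection is winner's-curse-prone;
  no correction is applied (out of scope), it is only flagged.
- No weighted-median/mode estimators, multivariable MR, competing risks,
  frailty, time-varying covariates, or proportional-hazards diagnostics.
- The Egger intercept's nominal level under correlated instruments is not
  established by this package (see §4); treat the intercept p under the
  default high-LD generator as descriptive.
- The synthetic cohort is a structural stand-in, not a calibrated replica
  of any real population; per-variant frequencies and effects are
  placeholders chosen for realistic orders of magnitude.
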