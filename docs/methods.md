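# Methods

## Design and estimand

`famgxe` fits conditional logistic regression (CLR) over family strata to
estimate multiplicative interactions between a polygenic risk score (PRS)
and non-genetic risk factors in young-onset (before age 50) breast cancer.
Conditioning on the stratum removes the family's baseline risk, and — for
the genotype contrast — conditioning on the parents makes transmitted
alleles independent of the sisters' risk factors under a weak assumption:
that genetic differences between full sisters do not track the studied
non-genetic factors in any systematic way. The interaction parameter is a
ratio of odds ratios (ROR): the PRS odds ratio in the exposed category over
that in the category one unit below.

The pseudo-sibling construction needs no phasing: because the PRS is linear
in dosage, `g_pseudo = g_F + g_M − g_C` per SNP implies
`PRS_pseudo = PRS_F + PRS_M − PRS_C` exactly, including for fractional
imputed dosages. Hard-call trios are Mendelian-checked first (dosages
within 0.1 of an integer are rounded for checking, a configurable
threshold; softer dosages are reported as unchecked). Pseudo-sib dosages
computed from fractional inputs may fall outside [0, 2]; they are passed
through unclamped and flagged, since downstream arithmetic is linear.

## Coding rules

* Interaction models: categorical main effects are saturated (indicators
  against the lowest/never/nulliparous reference level), so the model stays
  correctly specified under a no-interaction null; the PRS × factor product
  uses integer trend scores 0,1,2,… over the ordered levels. Smoking is
  the one unordered factor and gets per-level product columns.
  Risk-factor-only models use the trend coding for ordered main effects.
  Trend scores are consecutive integers from 0 because no published scoring
  exists for these categories.
* The PRS is centered on the *actual genotyped control sisters* (never
  pseudo-sisters); a configuration switch (`centering_scope`) includes
  pseudo-sisters for sensitivity analyses, since the source description is
  ambiguous on this point. Continuous exposure targets are centered at the
  control mean in interaction models so the PRS main effect refers to a
  woman at the controls' average exposure; this does not change the ROR.
* Birth order enters every model as an indicator for being the elder
  sister, attached to the *exposure source* (a pseudo-sibling member
  inherits the elder flag of whichever sister supplied its risk factors).
  No coding was published for this adjustment; the elder indicator is the
  design choice here, and it is exactly the term that absorbs the
  ascertainment requirement that the control must have aged past the case's
  diagnosis age.
* Confounder sets follow the analysis plan: parity and age at first birth
  for breastfeeding; smoking and alcohol mutually; age at menarche for
  years of hormonal birth control; age at first birth for parity. Parity
  models are restricted to parous women (levels 1/2/≥3) because the age at
  first birth adjustment is undefined for nulliparous women.
* Complete-case per model: a matched set any of whose members lacks the
  target factor or a confounder is dropped whole and logged, mirroring the
  per-variable denominators of interview data.
* No multiple-testing correction is applied; per-factor Wald p-values are
  reported as-is.

## Numerical notes

Newton–Raphson with exact gradient/Hessian, gradient-norm tolerance 1e-8,
at most 100 iterations, step-halving on any likelihood decrease. Standard
errors come from the inverse observed information; 95% CIs are
`exp(β̂ ± 1.96·SE)`. Columns with no within-set variation carry no
conditional information and are excluded up front and reported as
*unidentifiable* — this is structural for the 1:1 designs: case-plus sets
share the case's genotype (no PRS main-effect information) and case-parents
sets share the case's exposures (no exposure main-effect information).
Remaining within-set rank deficiency raises an estimation error.
Separation (monotone likelihood) is flagged when any coefficient passes 10
on the log scale; near that boundary the conditional likelihood flattens,
so the magnitude itself, not the gradient, is the signal. The conditional
likelihood is invariant to per-set constant shifts of any covariate, which
the tests exploit as an invariance check.

## Synthetic data generator

The generator exists so every stage is verifiable without restricted data.
It emulates an ascertained sister study:

* **Genotypes.** Parents under Hardy–Weinberg equilibrium per panel SNP;
  daughters by independent Mendelian transmission. The default panel (10
  SNPs for fast tests; a 77-SNP configuration by the same recipe) is
  calibrated so the population PRS has mean 5.0 and SD 0.45 exactly,
  matching the reported control-sister distribution (5.01, SD 0.46); with
  10 SNPs that requires common, moderately weighted alleles (frequencies
  ≈ 0.80–0.92, ORs ≈ 1.31–1.37), while the 77-SNP version has the
  realistic many-small-weights shape (frequencies ≈ 0.39–0.50, ORs ≈ 1.07).
* **Exposures.** The 14 risk factors are drawn with marginals matching the
  reported control characteristics (smoking 0.65/0.26/0.09, ever-use of
  hormonal birth control 0.89, parity 0.25/0.17/0.35/0.23, menopause age
  normal with mean 51.8 calibrated to give ~89% premenopausal at index,
  and so on). Sister–sister correlation uses a shared-family Gaussian
  latent (Gaussian copula for categorical draws) with ρ = 0.3 — no
  within-family correlation was published; this moderate default is a
  convention and is configurable.
* **Disease and ascertainment.** A single family index age T (the eventual
  case's diagnosis age) is drawn from a normal truncated below 50
  (calibrated to a case mean near 44.9, SD near 3.9); both sisters'
  exposures are aligned at T and affection is Bernoulli with
  `logit P = α + β_prs(PRS−5) + Σ β_e E + Σ β_ge (PRS−5)·E`.
  Families are rejection-sampled to exactly one affected daughter, and the
  control must have aged past T (recruitment lag uniform 0–4 years, sister
  age gap 2 + Exp(2) years), which skews controls toward being the elder —
  the artifact the birth-order covariate adjusts for. An acceptance-rate
  floor of 1e-4 guards against hopeless configurations.
* **Defaults as study conditions.** α = logit(0.02) (≈2% cumulative
  young-onset risk to age 50, which also keeps the rare-disease
  approximation behind the pseudo-sibling likelihood accurate),
  β_prs = ln 2.33, and an ever-use-of-hormonal-birth-control effect
  ln 1.31 with interaction ln 0.56 — the benchmark interaction row.
  Design proportions default to the published 384/32/432/304 split; exact
  counts can be requested.

What the generator does **not** emulate: hormone replacement therapy,
survival/recall bias, population stratification, genotyping error or
imputation uncertainty (dosages are exact), and within-family exposure
dynamics beyond the shared latent. Passing tests therefore demonstrate
correctness of the estimator under the stated model, not robustness to
those real-data complications.

## Verification strategy and problem sizes

* CLR fits are cross-checked against statsmodels' conditional logit and
  against direct Nelder–Mead maximisation of the package's own conditional
  log-likelihood on 20 random small datasets (1e-5 relative agreement);
  1:1 designs are checked against intercept-free logistic regression on
  within-pair differences.
* The pseudo-sibling rule is verified by exhaustive enumeration over all 27
  hard-call trios (15 consistent, 12 Mendelian-impossible) and PRS
  linearity to machine precision.
* Parameter recovery runs 800 replicates of 1,000 families (a reduced scale
  chosen so the Monte-Carlo error of the bias estimate, ≈0.015 on the log
  scale, and of the coverage estimate, ≈0.8 percentage points, are small
  relative to the bands |bias| < 0.05 and coverage ∈ [0.93, 0.97]); type-I
  error of the interaction Wald test uses 1,000 null replicates of 800
  families against the binomial 99% band around 0.05. Replicate seeds are
  fixed offsets so the runs are deterministic.

## Known limitations

* The Wald interaction test is slightly conservative below ~500 families
  per study; no small-sample (e.g. Firth) correction is implemented.
* Profile-likelihood intervals, additive-scale interaction measures and
  random-effects extensions are out of scope, as is genotype imputation
  and panel re-estimation.
* With both parents and a genotyped sister available, the family is
  classified case-sibling-plus (the sibling genotype takes precedence);
  the source material leaves this precedence unstated.
* Years of hormonal birth control are accumulated over use before the
  index age (an interval partially after the index contributes only its
  pre-index part); whether the original analysis censored differently is
  unknown.
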