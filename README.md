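# famgxe

Family-based analysis of interactions between a polygenic risk score (PRS)
and non-genetic risk factors for young-onset breast cancer.

Case–control studies of gene-by-environment interaction are vulnerable to
exposure-related population stratification. Family-based designs largely
avoid this by matching on ancestry: each woman diagnosed before age 50 is
compared within her own family, either with her genotyped unaffected sister
or — when the parents rather than the sister were genotyped — with a
*pseudo-sister*, the hypothetical, equally likely sibling who carries the
parental alleles not transmitted to the case and who is assigned the real
sister's risk factors. `famgxe` implements this analysis for anyone working
with sister/trio family studies: epidemiologists fitting the models on their
own pedigree + genotype + interview data, and methodologists studying the
design's properties via the built-in simulator.

## The model

The PRS is multiplicative over a weight panel (77 SNPs in the motivating
design), computed on the natural-log scale:

```
PRS = Σ_i g_i · ln(OR_i),      g_i ∈ [0, 2]
```

where `g_i` is the (possibly fractional, imputed) risk-allele dosage and
`OR_i` the published per-allele odds ratio. Reported PRS odds ratios are
per unit change of this score. In interaction models the PRS is centered by
subtracting the control sisters' mean.

Each family contributes one stratum to a conditional logistic regression
(CLR). With genotype sources G (case `c`, real or pseudo sister `s`) and
exposure sources E, the four designs and their matching sets are:

| design            | data available                       | ratio | matching set                         |
|-------------------|--------------------------------------|-------|--------------------------------------|
| case-parents-plus | case G/E, both parents G, sister E   | 1:3   | (Gc,Ec), (Gps,Es), (Gc,Es), (Gps,Ec) |
| case-parents      | case G/E, both parents G             | 1:1   | (Gc,Ec), (Gps,Ec)                    |
| case-sibling-plus | case G/E, sister G and E             | 1:3   | (Gc,Ec), (Gs,Es), (Gc,Es), (Gs,Ec)   |
| case-plus         | case G/E, sister E                   | 1:1   | (Gc,Ec), (Gc,Es)                     |

The conditional likelihood `ℓ(β) = Σ_sets [x_case·β − log Σ_j exp(x_j·β)]`
is maximised by Newton–Raphson with exact derivatives. Interaction models
saturate the categorical risk-factor main effect but use a single
linear-trend product column (integer scores 0,1,2,…) for the PRS × factor
term — except smoking, the one unordered factor, which gets one product
column per non-reference level. Every model adjusts for birth order
(control sisters are more often the elder, a consequence of requiring the
control to have aged past the case's diagnosis age). The exponentiated
interaction coefficient is the **ROR**: the PRS odds ratio in the exposed
category divided by that in the unexposed (or one-unit-lower) category, so
the exposed-group PRS OR is `OR_unexposed × ROR`.

All time-dependent risk factors (menopausal status, births, hormonal birth
control use, …) are evaluated for *both* sisters as of the case's age at
diagnosis (the index age), giving the sisters comparable opportunity for
exposure.

## Worked example

`examples/03_simulate_and_fit.py` simulates 2,000 ascertained families under
a PRS log-OR of ln 2.33 and an ever-use-of-hormonal-birth-control
interaction log-ROR of ln 0.56, then fits the interaction model:

```
design counts: {'case_parents_plus': 663, 'case_parents': 65, 'case_sibling_plus': 753, 'case_plus': 519}

PRS OR (never-users):  3.02 (95% CI 1.71, 5.34)   truth 2.33
interaction ROR:       0.48 (95% CI 0.27, 0.86)   truth 0.56
PRS OR (ever-users):   1.46   (= never-user OR x ROR)
interaction Wald p:    0.0136
```

The never-user PRS OR is the PRS effect in the small (~11%) unexposed group,
hence the wide interval; the ROR below 1 says the PRS is less predictive
among ever-users of hormonal birth control. Both intervals cover the
generating truth. The other examples cover scoring/centering
(`01_score_and_center.py`), the pseudo-sibling construction
(`02_pseudo_sibling.py`) and the file-based pipeline with its report and
exclusion accounting (`04_full_pipeline.py`). A thin CLI wraps the same
pipeline: `famgxe simulate|prs|build-sets|fit|run`.

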