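# Methods

## Score construction

Each catalogued SNP carries an *effect allele*, defined as the HDL-raising
allele, so every per-allele effect β (in mmol/L) is positive and a higher
score always means a higher genetic predisposition to HDL. Dosages dᵢ ∈
{0,1,2} count effect alleles; genotype input in other orientations (e.g.
VCF REF/ALT) is harmonized by complementing the raw count (2 − count) when
the non-effect allele is counted. Allele-set mismatches, including apparent
strand flips (A/T↔T/A, C/G↔G/C patterns), are rejected rather than
repaired: silent strand flips are the classic failure mode of risk-score
pipelines and none of the catalogued pairs can be disambiguated without
frequency heuristics.

Unweighted scores sum the dosages. Weighted scores use

  wᵢ = m·βᵢ / Σβ  (m = number of SNPs in the panel),

i.e. each SNP's share of the panel's total effect size, scaled so the
weights average one. The scaling keeps weighted scores on the 0–2m scale of
allele counts; with raw shares βᵢ/Σβ the maximum possible score would be 2,
which is incompatible with weighted cohort means in the teens. The analytic
moments under Hardy-Weinberg and linkage equilibrium,

  E[S] = Σ wᵢ·2pᵢ,  Var[S] = Σ wᵢ²·2pᵢ(1−pᵢ),

reproduce the published cohort summaries of all six scores from the
catalogued frequencies, which is the package's main external validation
(`scripts/acceptance.py`).

The combined panel is the union of both score sets minus the second member
of each of the two r² > 0.90 LD pairs (rs7134594 dropped in favour of
rs2338104, rs2271293 in favour of rs16942887); its weighted variant uses
the union's Σβ = 0.85 over m = 26. The drop choices are shipped as default
`LDPair` data and are overridable. Pruning is idempotent: re-selecting from
an already-pruned list is a no-op, and only a pair whose *kept* member is
absent while the dropped member is present is an error.

Missing dosages are replaced by the SNP's mean observed dosage **in the
analysis cohort itself**, once, before any scoring or tertile assignment —
so an individual with no genotype data at all scores at the cohort's
mean-profile score, and scores exist for every individual. Imputing from
catalog frequencies instead is available for single-sample scoring.
Tertiles are cut at the empirical 1/3 and 2/3 quantiles after imputation;
samples tied exactly at a boundary fall into the lower tertile
(deterministic and order-independent); fewer than three distinct values,
or a tie pattern that empties a group, is an error rather than a silent
degenerate split.

## Genotype QC

The call-rate floor is 95%, applied to SNPs first and then to samples
(with 28 SNPs a sample missing two calls falls below the floor). The
Hardy-Weinberg test is the asymptotic one-degree-of-freedom chi-square
against p², 2pq, q² at the sample allele frequency; expected counts below 5
are flagged, monomorphic SNPs return p = 1 with a flag, and — matching a
sibship design — frequencies and HWE tests use one member per family (the
first listed). HWE violations are *reported, not dropped* by default, with
a strict mode that drops them; the threshold defaults to 0.05 and is
configurable. LD is measured as composite r², the squared correlation of
dosages over complete pairs, since phase is unavailable in array-type data.

## Association models

Continuous outcomes are transformed toward normality before modelling:
natural log for HDL, LDL and triglycerides, log(CAC + 1) for the
zero-inflated, heavily right-skewed calcium score. Friedewald LDL
(TC − HDL − TG/5) is treated as invalid at TG ≥ 796 mg/dL and those
records drop out of LDL models.

Marginal (population-average) models are solved by generalized estimating
equations with an exchangeable working correlation and the sandwich
variance estimator clustered on family; identity link for continuous
outcomes, logit for binary history outcomes (the link for those is a
package choice). For sibships without parents, exchangeable correlation
coincides with the kinship-implied structure, so the same machinery stands
in for variance-components single-SNP models; this is an approximation for
any more general pedigree. With every cluster of size one the estimates
reduce exactly to ordinary least squares with HC0 robust errors (verified
in tests).

Mortality is modelled by Cox proportional hazards on follow-up time with
cluster-robust (sandwich) variance over families and the Efron
approximation for tied event times; the Newton solver is run to a tight
tolerance so point estimates agree with direct numerical maximization of
the partial likelihood to better than 1e-6 on small fixtures. All 95%
intervals are normal-theory Wald intervals on the estimate scale,
exponentiated for hazard ratios.

Tertile analyses either code T1/T2/T3 as 0/1/2 for a single linear-trend
coefficient or contrast T2 and T3 against T1 with indicators. The three
covariate models are package defaults, explicitly recorded in every run
manifest because the adjustment sets are a genuinely open choice: M1
unadjusted, M2 age + sex + BMI, M3 additionally smoking, hypertension,
cholesterol medication and prior CVD; all are overridable. No
multiple-testing correction is applied anywhere (significance is read at
p < 0.05 across a correlated battery, a deliberate mirroring of the
analysis design this package implements).

## Synthetic cohort

The generator emulates a sibling-pair T2D study: 466 families with 1–4
affected siblings (truncated-geometric, ratio 0.72, mean ≈ 2.11 → ≈ 983
individuals). Genotypes come from explicit parental haplotypes drawn under
HWE at the catalogued frequency with Mendelian transmission to each sib;
SNPs are simulated in linkage equilibrium (the fixed LD-pair exclusions are
catalog data, not re-estimated), and sibling dosage correlation is the
full-sib 0.5.

HDL (mg/dL) is additive in every catalogued effect (β·38.67 per allele,
using 38.67 mg/dL per mmol/L), plus a female–male difference of +7, small
age (+0.05/yr) and BMI (−0.30 per kg/m²) terms, a shared sibship effect
(SD 3.8 mg/dL), and residual noise whose variance is the remainder needed
to hit the marginal target SD of 12 — an infeasible decomposition raises
rather than silently rescaling. The intercept is set so the marginal mean
hits 42.2 mg/dL. LDL (normal, 102.8 ± 32.6) and triglycerides (lognormal,
median 175, log-SD 0.594 → mean ≈ 209) are generated independently of
genotype, and total cholesterol is derived so the Friedewald identity holds
exactly for valid records.

CAC is generated as round(exp(L) − 1) truncated at zero, with latent
L = log(479) + b·z + 0.04·(age−62.5) + 0.8·(male−P(male)) + N(0, 1.65²),
where z is the standardized combined unweighted score and b defaults to
−0.20 per score SD (≈ −0.09 per score unit, a realistic subclinical
effect size); covariate terms are centered so the configured median is the
latent median. The lognormal latent scale produces the extreme right skew
(median ≈ 478, mean ≈ 1900, occasional five-figure values) that motivates
the log(CAC+1) analysis transform.

Survival uses exponential event times with per-subject rate
λ₀·exp(0.07·(age−62.5) + 0.4·male + 0.5·priorCVD + 0.3·smoking + optional
score or arbitrary offset terms), censored at a Uniform(6, 13)-year
follow-up horizon (follow-up duration is a modeling choice; the design
implies staggered entry with a fixed administrative close). λ₀ is solved
by 1-D root finding so the *expected* death fraction given the simulated
covariates equals the configured target (23.3% all-cause); deaths are
labelled CVD with probability 0.443 (→ ≈ 10.3% CVD deaths). The score
coefficient defaults to zero — the null that the mortality analyses are
designed to interrogate — and a per-sample extra log-hazard hook supports
step scenarios such as a T3:T1 hazard ratio of 0.57.

Every quantity above is a `SimulationConfig` field, not a constant; each
run reports simulated-vs-target calibration, and the whole stream is
deterministic under the config seed (a seed sequence is split across
genotype, phenotype, survival and missingness streams). Missing calls are
injected at 0.6% *after* phenotype generation, so phenotypes always derive
from the true genotypes and mean imputation is exercised downstream.

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: LD between the catalogued SNPs (beyond the
fixed exclusions), ascertainment of T2D-concordant sibships, parent or
half-sib structures, assay batch effects, non-proportional hazards,
competing-risk dynamics beyond a cause label, and any score↔LDL/TG
pleiotropy (the generator builds the null that scores are lipid-specific).

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen for stable Monte-Carlo
behaviour at desk scale: 50,000 individuals for the HWE score-moment
cross-check (3-SE agreement), 500 replicates of 150 two-sib families for
marginal-model coverage/type-I calibration, 4–6-subject enumerable fixtures
for the Cox oracle (near-monotone likelihoods, |β̂| > 3, are excluded from
point comparison since the optimum is flat), and the full 466-family scale
for the tertile hazard-ratio recovery scenario and determinism checks.
GEE runs to the statsmodels default convergence; Cox Newton iterations stop
at a 1e-14 step-norm. Degenerate inputs (monomorphic SNPs, zero-variance
dosages, no events, empty tertiles, rank-deficient designs) error or flag
explicitly rather than returning numbers.

## Known limitations

Effect-size weights assume the catalogued β's transfer to the target
cohort; the exchangeable-correlation approximation understates dependence
in multi-generation pedigrees; composite r² underestimates haplotype r²
when Hardy-Weinberg fails; mean imputation shrinks score variance slightly
relative to genotype-complete data; and the simulator's calibration
matches marginal summaries, not joint distributions, of the real cohort.
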