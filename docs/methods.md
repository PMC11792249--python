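# Methods

This note records the models, conventions and numerical choices behind
`twinsteroid`, and what the synthetic cohorts do and do not establish
about analyses of real data.

## Responder phenotyping

The responder definition is control-referenced: the cut-off is
`mean − k·sd` of the saline-control 30-min PaCO₂ values, with `k = 2`
by default and the sample SD (n − 1 denominator). Controls of both
sexes are pooled. Classification is strict — a treated lamb is a
responder iff PaCO₂ < cutoff, so a value exactly at the cut-off is a
non-responder (the definition is "more extreme than" the 2-SD bound).
The rule, not any particular printed cut-off value, is normative: the
operation takes raw control values, and different control samples give
different cut-offs. The ventilation efficacy index uses the fixed
protocol constants (PIP 35, PEEP 5 cmH₂O, rate 50 min⁻¹, numerator
3800) and is strictly decreasing in rate, driving pressure and PaCO₂.

Pooled group moments use the exact identity
`s² = [Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m̄)²]/(N−1)`, which reproduces the sample
variance of the concatenated raw data; size-1 groups contribute only a
between-group term. Response rates are carried as exact fractions and
rounded only for display.

## Genotype model and QC

Alleles are abstract A/B chip calls; strand and "Forward" designations
are not modelled. QC applies the two published filters strictly: a SNP
is kept only if GenTrain > 0.7 (dropping all its calls otherwise), and
a surviving call only if GC > 0.15. The filter is idempotent and
retention is monotone in both thresholds.

Zygosity uses unordered genotype identity (AB ≡ BA) over SNPs called in
both twins, after QC, on all chromosomes (X included — the chip carries
X-linked content and the analysis treats its calls as ordinary diploid
genotypes). Monozygosity requires concordance strictly above 0.9.
Genotype-level, post-QC matching is a documented choice; allele-level
matching would shift dizygotic concordance upward but not across the
0.9 boundary at realistic error rates.

## Two-stage association

Stage 1 is a Pearson chi-square (1 df, no continuity correction) on the
2×2 allele-by-phenotype table; each called fetus contributes its two
alleles to its phenotype column. Tables with a zero marginal are
flagged undefined and skipped. Stage 2 fits, per shortlisted SNP, an
additive logistic model on allele-B dosage with a female indicator, by
maximum likelihood; the reported p-value is Wald by default
(likelihood-ratio available via `AnalysisConfig.logistic_test="lr"`).
Under additive coding the two alleles of a SNP are exact mirror images
(β_A = −β_B with identical p), so both allele rows are emitted, one
labelled responder-associated and one non-responder-associated —
matching the published table's two-direction structure. Complete
separation is flagged (`separated=True`, NaN p) rather than raised, and
a separated fit is never counted as significant. No multiple-testing
correction is applied beyond the staged raw thresholds (0.01, 0.05),
by design. SNP×SNP interaction models are out of scope.

## Twin statistics

Pair response concordance is the fraction of treated pairs whose twins
carry equal responder labels; control pairs are excluded. The GEE uses
a logit link, exchangeable within-ewe working correlation and robust
sandwich covariance, pooling the two steroid arms. Covariate coding is
fixed and reported in the term names: treatment CS2 vs CS1, sex female
vs male, twin type MF and FF vs MM, delivery order first vs second.
Constant columns (e.g. no FF pairs in a draw) are dropped rather than
left to produce singular fits; with single-fetus clusters the estimator
coincides with ordinary logistic regression (verified to 1e-6 in the
tests). Non-convergence is flagged in the output, not raised.

Drug levels honour the assay limits of detection — 0.5 ng/mL in plasma,
1 ng/mL in lung tissue; a value exactly at the LOD is detected. Means
and SDs use detected values only; twin absolute differences use pairs
with both values detected and report the exclusion count. Half-LOD
substitution is available behind `half_lod_substitution` but is off by
default, matching the convention of reporting "< LOD" rather than
imputing.

## Synthetic cohort generator

The generator's defaults are the study conditions: 11/10/10 twin pairs
in CS1/CS2/control, all-dizygotic pairs (`mz_fraction = 0`), sexes
i.i.d. Bernoulli(½) per fetus (an optional `sex_pattern` forces pair
types), and a 5,000-SNP panel with minor-allele frequencies uniform on
(0.1, 0.5). The full 50k chip scale is available by config; 5,000 keeps
a default end-to-end run to a few seconds while leaving every statistic
at cohort scale unchanged.

Dizygotic genotypes are full-sib draws: sire and dam genotypes under
Hardy–Weinberg at each SNP, one transmitted allele per parent per sib,
independently per sib; monozygotic pairs are one draw duplicated. SNPs
are independent (no linkage disequilibrium) — a deliberate limitation:
the analysis nowhere exploits LD, and planted-effect recovery, null
calibration and zygosity properties are all LD-free statements. Call
errors are symmetric single-allele flips; missingness deletes calls;
both default to 0 and are set explicitly in noisy scenarios.

Phenotypes: control PaCO₂ is Normal(130.0, 24.6) mmHg — the n-weighted
pooling of the published sex-stratified control moments. Treated lambs
draw a latent responder status from
`logit p = β₀ + β_sex·I(female) + β_order·I(second) + Σ βₖ·dosageₖ`
with defaults β_sex = ln 7.786 and β_order = ln(1/0.258) (the study's
published marginal odds ratios) and β₀ = −1.4, which centres the
treated response rate near the observed ≈57%; PaCO₂ then comes from
Normal(60, 15) for responders and Normal(125, 25) for non-responders,
floored at 10 mmHg. These overlapping laws intentionally leave a few
percent of misclassification against the control-derived cut-off, as
real physiology would.

Drug levels are hierarchical log-normals moment-matched to the
published delivery concentrations: maternal plasma per ewe (CS1
14.8 ± 11.4, CS2 7.8 ± 2.2 ng/mL), a fetal/maternal ratio (mean 0.19)
and a lung/plasma ratio (mean 14.5), each with a pair-shared component
(CV 0.40 / 0.35) and a small per-fetus jitter (CV 0.08 / 0.15) so that
within-pair differences stay an order of magnitude below between-pair
spread, reproducing the small published twin absolute differences.
Controls carry zero drug and therefore report below-LOD everywhere.
Because products of log-normals are log-normal, the marginal
fetal-plasma law is available in closed form
(`PkParams.fetal_plasma_lognorm`) and the censoring rate is testable
against an analytic CDF.

One master seed feeds fixed-order named streams (design, genotypes,
scores, phenotypes, pk) via `SeedSequence.spawn`, so a subsystem can be
re-run in isolation and reruns are bit-identical.

### What the generator does not emulate

No linkage disequilibrium or population structure; no X-hemizygosity
(male X calls are diploid, as delivered by the chip format); no
pharmacokinetic time-courses (terminal concentrations only); no
RNA-seq, qPCR or protein layers. Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
stated design, not robustness to LD, relatedness structure or assay
artefacts absent from the model.

## Power and recovery scenarios

Two scenario builders document deliberately low-noise conditions used
for parameter-recovery studies: `planted_recovery_config` (13 planted
per-allele effects of ±ln 6, alternating sign, on a 600-SNP panel at
500 treated pairs, intercept offset so the cohort stays balanced) and
`gee_recovery_config` (the sex and delivery-order effects alone). Both
use well-separated responder/non-responder PaCO₂ laws (55 ± 10 vs
130 ± 20) and clean genotyping scores so that recovery measures the
association and GEE machinery itself rather than attenuation from
responder misclassification or QC attrition; the default noisy laws
remain the generator's standard conditions everywhere else. Problem
sizes throughout the test and acceptance suites (e.g. 2,000-SNP null
screens, 20-replicate recovery sweeps, 200-replicate GEE size checks at
100 pairs) were chosen as the smallest designs whose Monte-Carlo error
bands are decisive for the property being checked.

## Numerical conventions and edge cases

Strictness of every threshold follows its published wording: QC scores
and the shortlist alpha are strict ("above", "< 0.01"), monozygosity is
strict ("greater than 0.9"), the responder rule is strict ("lower
than"), while a concentration exactly at the LOD is detected ("defined
as"). Chi-square and pooled-moment arithmetic are closed-form; logistic
fits use Newton MLE with separation guards (|β| > 30 or SE > 10³ flags
a separated fit); GEE confidence intervals are Wald on the log-odds
scale. Degenerate inputs raise typed errors: too few controls,
zero co-called SNPs, one-class phenotypes, zero dosage variance, empty
group lists. File parsers validate headers, allele alphabets, score
ranges and duplicate SNP ids, reporting 1-based line numbers.

## Known limitations

The chi-square stage treats fetuses as independent, but co-twins'
genotypes are correlated; at the study's scale this leaves the null
shortlist rate statistically indistinguishable from its nominal 0.01
(checked empirically), yet it is not exact. Small cohorts (the default
31-pair design) routinely produce separated GEE terms with enormous
odds ratios and near-degenerate CIs — faithful to the design's
information content, and the reason recovery claims are made at 500
pairs. The published cut-off constant cannot be re-derived exactly from
printed summary moments (pooling them gives ≈ 81 mmHg, not 84.3); the
package treats the rule, not the constant, as normative.
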