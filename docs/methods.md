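# Methods

## Study design and data model

The package analyses unmatched case–control data with a three-level
phenotype — eczema only, eczema with asthma (the combined phenotype),
healthy control — one biallelic SNP at a time, and one binary
early-life exposure (parent-reported ETS in the first two years).
Phenotype contrasts are explicit pairs of disjoint level sets, so the
"expanded control" comparison (combined phenotype vs everyone else) is
just another contrast, not a special code path. Genotype calls are
unordered allele pairs; risk-allele orientation comes only from the
`SnpSpec`, never from data, and every reported ratio names the allele
it refers to. Missing genotype/exposure values are excluded listwise
per analysis (complete-case), matching how the published tables were
evidently built; nothing is imputed.

## Contingency statistics

- Pearson χ² is computed **without** Yates continuity correction; the
  corrected variant exists behind a flag but is never the default. The
  uncorrected statistic is what reproduces the published exposure
  associations (8.434 and 1.347) exactly.
- Odds ratios are cross-products with Woolf log-scale intervals; risk
  ratios are cumulative-incidence ratios with Katz intervals. A zero
  cell triggers the Haldane–Anscombe +0.5 on *every* cell and a
  `continuity_corrected` flag. Because the correction is applied before
  anything else, a structurally infinite estimate cannot occur; the
  flag is the audit trail.
- "Fisher as appropriate": the p-value for a 2×2 association switches
  from χ² to Fisher's exact test when any expected cell is below 5
  (threshold configurable). The source study never states its rule;
  this is the conventional choice.
- The HWE test estimates the allele frequency from the sample and
  compares observed genotype counts with (np², 2npq, nq²) on 1 df. A
  monomorphic sample returns p = 1 with a warning rather than an error.

## Genetic models

"Additive" association here is the allele-count 2×2 comparison (each
child contributes two alleles), which is what reproduces the published
allele denominators (376 and 170) and ORs; it is not a trend test. A
Cochran–Armitage trend statistic (N·r² form) is provided as a clearly
separate extra. Treating the two alleles of a child as independent
observations slightly understates the variance when genotypes deviate
from HWE; this standard caveat applies to all allele-level outputs.

## Logistic regression

Model fitting is maximum likelihood via Newton/IRLS (statsmodels
`Logit`), coefficient tolerance 1e-8, at most 50 iterations — enough to
make the saturated 2×2 slope equal the closed-form cross-product OR to
well beyond 6 significant figures, which the tests assert. Complete
separation is detected (perfect-prediction warnings, or |β| > 20 on the
log-odds scale) and flagged rather than silently reported. Wald
intervals are used throughout; no profile likelihood. The default
design for interaction testing is the allele-level expansion (two rows
per child with an effect-allele indicator), because every reproducible
published interaction number is allele-based; carrier coding is one
flag away. Confounding is assessed by the 10% change-in-estimate rule
(a package decision; the source describes the comparison only
qualitatively), with an exactly-10% change treated as borderline, not
flagged.

## Interaction measures

Category estimates in the 2×4 joint classification are computed against
the doubly-unexposed reference on one of two scales. The canonical
scale is the cumulative-incidence ratio on the case/control composition
of each category — the scale on which the published panel is
reproducible — even though, under case–control sampling, it estimates a
population risk ratio only via the rare-disease assumption; the module
logs a standing caveat whenever this scale is used. Odds-ratio-scale
variants reproduce stratified-table conventions.

RERI, AP, S and the ratio of RRs are always computed from **unrounded**
category estimates. A concordance mode (`input_decimals=2`) recomputes
them from 2-decimal inputs, solely to show how report-rounded values
(e.g. RERI 2.84 instead of 2.83) arise. S is reported undefined with a
diagnostic whenever RR₁₀ + RR₀₁ − 2 ≤ 0; emitting a number there would
be meaningless (and for the *TNS1* panel the denominator is negative,
so the module deliberately refuses to print an S for it). Delta-method
CIs for RERI and AP use the gradient in (ln RR₁₀, ln RR₀₁, ln RR₁₁)
with the shared-reference covariance term; they are an extension beyond
the closed-form measures, tagged as such.

One property worth noting: AP ≤ 1 is guaranteed only when
RR₁₀ + RR₀₁ ≥ 1. If both single-factor effects are protective, AP can
exceed 1; the property tests encode the correct conditional form.

## Post hoc power

Implemented exactly as the printed formula: Φ(|β|/SE − z₁₋α/₂),
ignoring the far tail Φ(−|β|/SE − z), which floors at Φ(−z) ≈ 0.025
rather than α as β → 0. The exact two-sided version is behind a flag.
For main effects, β and SE derive from the **crude** allelic OR and its
Woolf CI (this is the variant that reproduces the published 0.59/0.20
figures; adjusted ORs do not). For interaction terms, β is the log
ratio of stratum cross-product ratios and SE the square root of the
summed reciprocals of the eight joint-table cells — numerically the
saturated logistic model's Wald SE. Note the main-effect power for the
stronger SNP computes to 0.595–0.600 depending on whether the CI is
taken at printed precision or at full precision; it is reported as
computed.

## Synthetic data

The generator mirrors the analysis model: HWE genotypes at frequency q,
Bernoulli exposure independent of genotype (a `ge_dependence_or` knob
introduces carrier–exposure dependence for robustness experiments), and
logistic disease risk with genetic, environmental and product terms (G
as allele count by default, carrier indicator optionally). Case–control
samples come from rejection sampling of a simulated population, capped
at 100× the requested sample size, which is simple, exact and cheap at
desk scale. A fast path draws 2×4 allele-level tables directly from the
config-implied multinomial category probabilities for calibration
studies.

Defaults are the observed conditions of the motivating study: q = 0.435
and exposure prevalence 0.27 (the control-group values), 28 cases vs 85
controls, baseline risk 5% (a realistic childhood prevalence for the
combined asthma–eczema phenotype; the case–control design makes slope
estimates insensitive to this choice), and the observed effect pattern
(per-allele OR 0.75 unexposed, exposure OR 1.03 at G = 0, interaction
ratio 4.7).

What the generator does *not* emulate: linkage disequilibrium between
loci, covariate confounding structure, exposure misclassification,
age/sex matching, or onset times. Passing recovery and calibration
tests therefore demonstrates correctness of the estimators under the
assumed model, not robustness to those real-data features.

## The reconstructed cohort

The published evidence consists of group-level margins only. The
`datasets` module rebuilds a synthetic 188-record cohort reproducing
every published margin exactly: genotype counts per group, exposure
counts per group, and the allele-level genotype×exposure joint counts
for combined-phenotype cases and controls. The within-stratum
genotype-by-exposure splits are not identified by those margins; fixed
HWE-plausible splits were chosen once and documented in the module. No
statistic the package validates against the published values depends on
those splits — only on the margins, which are exact.

## Problem sizes and numerical choices

Monte-Carlo checks run at sizes chosen to make their asymptotics clean
while staying desk-scale: parameter recovery on a 20,000-record cohort
(one fit, ±3 SE), additive-null RERI calibration on 400 tables of
10,000 alleles per arm, type-I-error calibration of the interaction
Wald test over 2,000 replicates at the study's own sample size (the
test is well calibrated there: the allele-level cells are large enough
for the normal approximation). All simulations are seeded; hypothesis
property tests run derandomized. Ratio estimates use exact normal
quantiles (`norm.ppf`), so α generalizes beyond 0.05; at α = 0.05 the
difference from the conventional 1.96 is invisible at reported
precision.

## Known limitations

- No matched/conditional logistic analysis (the original controls were
  age/sex matched, but matching identifiers were not published).
- No Firth correction; separation is flagged, not repaired.
- No Mantel–Haenszel pooling across strata; stratified estimates are
  reported per stratum.
- Covariate-adjusted ORs from the source study are not reproducible
  (the individual covariate data are unpublished); the adjustment
  machinery is generic and validated by simulation instead.
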