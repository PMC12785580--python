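# gxepi

Case–control **g**ene-by-**e**nvironment interaction analysis for
**epi**demiology, built around a concrete scientific question: do risk
alleles at *TNS1* rs918949 and *NRXN1* rs10194978 interact with
early-life environmental tobacco smoke (ETS) exposure to raise the risk
of the combined asthma–eczema phenotype in children?

The package is a general, reusable toolkit for studies of this design:
a three-level phenotype (disease A only, disease A + B, healthy
control), one biallelic SNP at a time with an explicit risk-allele
orientation, and a binary early-life exposure. It is aimed at genetic
epidemiologists who want auditable, closed-form statistics on small
candidate-gene cohorts rather than genome-wide machinery.

## What it computes

**Association under inheritance models.** Genotype counts
(ref-hom, het, effect-hom) are collapsed into allelic (per-chromosome),
dominant, recessive and codominant 2×2 contrasts; each yields a crude
cross-product odds ratio `OR = ad/(bc)` with a Woolf log-scale interval
`exp(ln OR ± z₁₋α/₂·√(1/a+1/b+1/c+1/d))`, with Fisher's exact test
replacing the Pearson χ² when any expected cell is small. Hardy–Weinberg
equilibrium in controls is checked by the 1-df χ² goodness of fit.

**Joint-classification (2×4) interaction.** Alleles are
cross-classified as G±/E± against the doubly-unexposed reference, and
the additive-scale measures of Rothman, reported as recommended by Knol
& VanderWeele, are computed from the unrounded category estimates:

- RERI = RR₁₁ − RR₁₀ − RR₀₁ + 1
- AP = RERI / RR₁₁
- S = (RR₁₁ − 1) / (RR₁₀ + RR₀₁ − 2), reported *undefined* when the
  denominator is ≤ 0
- ratio of RRs = RR₁₁ / (RR₁₀ · RR₀₁), with its Wald test
  (SE = √Σ 1/cell over the eight cells — identical to the product-term
  test of the saturated logistic model, which is also available via
  `interaction_wald_test`).

**Post hoc power.** The Wald approximation
`power = Φ(|β|/SE − z₁₋α/₂)` with `β = ln OR` and SE either from a
reported confidence interval or from the eight reciprocal cells of the
joint table, plus a Monte-Carlo cross-check (`empirical_power`).

**Synthetic cohorts.** `simulate_cohort` draws HWE genotypes, Bernoulli
exposure and a logistic disease model
`logit P(D) = β₀ + β_g·G + β_e·E + β_ge·G·E`, then samples cases and
controls by rejection — so every estimator can be validated by
parameter recovery without any external data.

## Worked example

The built-in `gxepi.datasets` module carries the published summary
counts of the motivating 188-child study and a synthetic
individual-level reconstruction that reproduces every published margin:

```python
from gxepi import (TNS1, ASTHMA_ECZEMA_VS_CONTROL, joint_classification,
                   interaction_measures, stratified_effects)
from gxepi.datasets import reconstruct_cohort

records = reconstruct_cohort()
strat = stratified_effects(records, TNS1, ASTHMA_ECZEMA_VS_CONTROL)
print(f"exposed OR {strat['exposed'].point:.2f}, "
      f"unexposed OR {strat['unexposed'].point:.2f}")

jt = joint_classification(records, TNS1, ASTHMA_ECZEMA_VS_CONTROL)
res = interaction_measures(jt, measure="risk_ratio")
print(f"RERI {res.reri:.2f}  AP {res.ap:.2f}  "
      f"ratio of RRs {res.ratio_of_rr:.2f}  p_int {res.interaction_p:.5f}")
```

prints

```
exposed OR 8.50, unexposed OR 0.71
RERI 2.83  AP 0.78  ratio of RRs 4.64  p_int 0.00037
```

Reading: among ETS-exposed children the *TNS1* T allele carries an
8.5-fold odds of the combined phenotype, with no effect in unexposed
children (OR 0.71). RERI ≫ 0 and AP = 0.78 indicate that about 78% of
the risk in exposed T-allele carriers is attributable to the synergy of
the two factors, and the ratio of RRs of 4.6 (Wald p < 0.001) shows the
joint effect exceeds even the multiplicative prediction.

The same pipeline is scriptable from the shell:

```
gxepi assoc --table "[[16,12],[23,62]]"        # χ² 8.434, OR 3.59 (1.48–8.74)
gxepi power --or 2.00 --ci 1.08 3.71           # achieved power ≈ 0.60
gxepi simulate --seed 42 --out cohort.tsv      # synthetic cohort
gxepi report --cohort cohort.tsv --config cfg.yaml
```

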