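"""Inheritance-model encodings of genotype counts and association scans.

A genotype count triple (ref-hom, het, effect-hom) per group is collapsed
into a 2x2 table under one of five contrasts:

* ``allelic`` — chromosome-level: each individual contributes two
  alleles, effect vs reference.  In this package "additive" association
  on the allele scale is this comparison (the per-allele cross-product
  OR), not a trend test; a Cochran-Armitage trend statistic is offered
  separately as a labelled extra.
* ``dominant`` — carriers of the effect allele vs reference homozygotes.
* ``recessive`` — effect homozygotes vs all others.
* ``codominant_het`` / ``codominant_hom`` — heterozygotes (resp. effect
  homozygotes) vs reference homozygotes, discarding the third class.

The allelic encoding treats the two alleles of one child as independent
observations; with within-person allele correlation the nominal CI is
anti-conservative, a standard caveat of allele-level analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .cohort import (CohortRecord, GenotypeCountTable, PhenotypeContrast,
                     SnpSpec, tabulate_genotypes)
from .contingency import (Chi2Result, EffectEstimate, TwoByTwoTable,
                          association_p, odds_ratio, pearson_chi2)


class GeneticModel(str, enum.Enum):
    ALLELIC = "allelic"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    CODOMINANT_HET = "codominant_het"
    CODOMINANT_HOM = "codominant_hom"


DEFAULT_MODELS: tuple[GeneticModel, ...] = (
    GeneticModel.ALLELIC, GeneticModel.DOMINANT, GeneticModel.RECESSIVE,
    GeneticModel.CODOMINANT_HET, GeneticModel.CODOMINANT_HOM)


@dataclass(frozen=True)
class ModelContrast:
    """A 2x2 encoding of genotype counts under an inheritance model.

    Column 1 of the table is the risk category (effect allele / carrier /
    effect homozygote), column 0 the reference category; rows are
    cases / controls.
    """

    model: GeneticModel
    table: TwoByTwoTable
    degenerate: bool = False


def encode_model(counts: GenotypeCountTable,
                 model: GeneticModel | str) -> ModelContrast:
    """Collapse genotype counts into the 2x2 table of an inheritance model."""
    model = GeneticModel(model)
    (r0, h0, e0) = counts.cases
    (r1, h1, e1) = counts.controls
    if model is GeneticModel.ALLELIC:
        eff_ca, ref_ca = counts.allele_counts(counts.cases)
        eff_co, ref_co = counts.allele_counts(counts.controls)
        cells = (eff_ca, ref_ca, eff_co, ref_co)
    elif model is GeneticModel.DOMINANT:
        cells = (h0 + e0, r0, h1 + e1, r1)
    elif model is GeneticModel.RECESSIVE:
        cells = (e0, r0 + h0, e1, r1 + h1)
    elif model is GeneticModel.CODOMINANT_HET:
        cells = (h0, r0, h1, r1)
    else:  # CODOMINANT_HOM
        cells = (e0, r0, e1, r1)
    table = TwoByTwoTable(*cells)
    degenerate = (cells[0] + cells[2] == 0) or (cells[1] + cells[3] == 0)
    return ModelContrast(model=model, table=table, degenerate=degenerate)


@dataclass(frozen=True)
class AssociationRow:
    """One line of a per-model association grid."""

    snp: SnpSpec
    contrast_label: str
    model: GeneticModel
    estimate: EffectEstimate | None
    n_cases: int
    n_controls: int
    degenerate: bool = False


@dataclass(frozen=True)
class AssociationScan:
    """Association results for one SNP across contrasts and models."""

    snp: SnpSpec
    rows: tuple[AssociationRow, ...]
    genotype_chi2: dict  # contrast label -> Chi2Result on the 2x3 table

    def row(self, contrast_label: str, model: GeneticModel | str) -> AssociationRow:
        model = GeneticModel(model)
        for r in self.rows:
            if r.contrast_label == contrast_label and r.model == model:
                return r
        raise KeyError((contrast_label, model))


def association_scan(records: Iterable[CohortRecord], snp: SnpSpec,
                     contrasts: Sequence[PhenotypeContrast],
                     models: Sequence[GeneticModel | str] = DEFAULT_MODELS,
                     alpha: float = 0.05,
                     fisher_threshold: float = 5.0) -> AssociationScan:
    """Crude per-model association estimates for each phenotype contrast.

    For every contrast the genotype-distribution chi-square (2x3, 2 df)
    is also reported.  Estimates are crude cross-product odds ratios with
    Woolf intervals; p-values switch to Fisher's exact test when any
    expected cell of the encoded 2x2 falls below ``fisher_threshold``.
    """
    if not contrasts or not models:
        raise ValueError("need at least one contrast and one model")
    records = list(records)
    rows: list[AssociationRow] = []
    genotype_chi2: dict[str, Chi2Result] = {}
    for contrast in contrasts:
        counts = tabulate_genotypes(records, contrast, snp)
        genotype_chi2[contrast.label] = pearson_chi2(
            [list(counts.cases), list(counts.controls)])
        for m in models:
            enc = encode_model(counts, m)
            if enc.degenerate:
                rows.append(AssociationRow(
                    snp=snp, contrast_label=contrast.label, model=enc.model,
                    estimate=None, n_cases=counts.n_cases,
                    n_controls=counts.n_controls, degenerate=True))
                continue
            p, _ = association_p(enc.table, fisher_threshold)
            est = odds_ratio(enc.table, alpha=alpha, p_value=p)
            rows.append(AssociationRow(
                snp=snp, contrast_label=contrast.label, model=enc.model,
                estimate=est, n_cases=counts.n_cases,
                n_controls=counts.n_controls))
    return AssociationScan(snp=snp, rows=tuple(rows),
                           genotype_chi2=genotype_chi2)


def cochran_armitage_trend(counts: GenotypeCountTable) -> Chi2Result:
    """Cochran-Armitage trend test with scores (0, 1, 2) on genotype classes.

    Offered as an extra alongside the allele-count comparison; the two are
    related but not identical statistics.
    """
    import numpy as np

    # chi2 = N * r^2, with r the correlation between the genotype score
    # and case status over the expanded sample
    cases = np.array(counts.cases, dtype=float)
    controls = np.array(counts.controls, dtype=float)
    scores = np.array([0.0, 1.0, 2.0])
    col = cases + controls
    n = col.sum()
    mean_s = (scores * col).sum() / n
    mean_y = cases.sum() / n
    cov_sy = ((scores - mean_s) * cases).sum() / n
    var_s = ((scores - mean_s) ** 2 * col).sum() / n
    var_y = mean_y * (1 - mean_y)
    if var_s == 0 or var_y == 0:
        return Chi2Result(statistic=0.0, df=1, p_value=1.0)
    chi2 = float(n * cov_sy ** 2 / (var_s * var_y))
    return Chi2Result(statistic=chi2, df=1,
                      p_value=float(stats.chi2.sf(chi2, 1)))
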