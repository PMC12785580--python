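"""Joint-classification (2x4) gene-environment interaction analysis.

Following the reporting recommendations of Knol and VanderWeele for
interaction between two binary factors, cases and controls are
cross-classified into four categories — reference allele/unexposed
(G-E-), effect allele/unexposed (G+E-), reference allele/exposed
(G-E+), effect allele/exposed (G+E+) — at the allele level (two
chromosomes per child) by default.  Against the common G-E- reference,
the module reports per-category effect estimates and the standard
interaction measures:

* additive scale: RERI = RR11 - RR10 - RR01 + 1 (relative excess risk
  due to interaction), AP = RERI / RR11 (attributable proportion), and
  the synergy index S = (RR11 - 1) / (RR10 + RR01 - 2), undefined when
  its denominator is <= 0;
* multiplicative scale: the ratio of relative risks RR11/(RR10*RR01),
  with its Wald test from the eight reciprocal cell counts (numerically
  the product-term test of the saturated log-linear model).

The canonical effect scale is the cumulative-incidence ratio computed
on the case/control composition of each category; under case-control
sampling this estimates a true risk ratio only through the rare-disease
assumption, and a standing caveat is logged whenever that scale is
used.  Odds-ratio-scale variants are available via ``measure``.
Delta-method confidence intervals for RERI and AP (Hosmer-Lemeshow
style, with the shared-reference covariance) are provided as an
extension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .cohort import CohortRecord, PhenotypeContrast, SnpSpec
from .contingency import (EffectEstimate, TwoByTwoTable, association_p,
                          odds_ratio, risk_ratio)

logger = logging.getLogger(__name__)

CATEGORY_LABELS = ("ref/unexposed", "effect/unexposed",
                   "ref/exposed", "effect/exposed")


@dataclass(frozen=True)
class JointClassificationTable:
    """Allele-level case/control counts for the four G x E categories.

    Order: (G-E-, G+E-, G-E+, G+E+); the first category is the
    reference.  At the allele level the case total is twice the number
    of case children.
    """

    snp: SnpSpec
    cases: tuple[int, int, int, int]
    controls: tuple[int, int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cases + self.controls):
            raise ValueError("joint-classification counts must be non-negative")

    @property
    def cells(self) -> tuple[int, ...]:
        return self.cases + self.controls

    def stratum_table(self, exposed: bool) -> TwoByTwoTable:
        """Within-stratum 2x2: rows case/control, cols effect/ref allele."""
        i_ref, i_eff = (2, 3) if exposed else (0, 1)
        return TwoByTwoTable(a=self.cases[i_eff], b=self.cases[i_ref],
                             c=self.controls[i_eff], d=self.controls[i_ref])

    def category_table(self, i: int) -> TwoByTwoTable:
        """Category i vs the reference: rows category/reference, cols case/control."""
        return TwoByTwoTable(a=self.cases[i], b=self.controls[i],
                             c=self.cases[0], d=self.controls[0])


def joint_classification(records: Iterable[CohortRecord], snp: SnpSpec,
                         contrast: PhenotypeContrast) -> JointClassificationTable:
    """Tabulate allele-level counts for the four genotype x exposure
    categories; each child contributes two alleles."""
    cases = [0, 0, 0, 0]
    controls = [0, 0, 0, 0]
    for r in records:
        is_case = contrast.classify(r.phenotype)
        if is_case is None or r.exposure is None:
            continue
        k = r.effect_allele_count(snp)
        if k is None:
            continue
        base = 2 if r.exposure else 0
        grp = cases if is_case else controls
        grp[base + 1] += k        # effect alleles
        grp[base] += 2 - k        # reference alleles
    if cases[2] + cases[3] + controls[2] + controls[3] == 0:
        raise ValueError(f"{contrast.label}: no exposed participants")
    if cases[0] == 0 or controls[0] == 0:
        raise ValueError(
            f"{contrast.label}: reference category (reference allele, "
            "unexposed) is empty in "
            + ("cases" if cases[0] == 0 else "controls"))
    return JointClassificationTable(
        snp=snp, cases=tuple(cases), controls=tuple(controls),  # type: ignore[arg-type]
        label=contrast.label)


def stratified_effects(records: Iterable[CohortRecord], snp: SnpSpec,
                       contrast: PhenotypeContrast, alpha: float = 0.05,
                       fisher_threshold: float = 5.0,
                       ) -> dict[str, EffectEstimate]:
    """Allele-level effect of the risk allele within each exposure stratum.

    Within each stratum the estimate is the cross-product odds ratio of
    case status for effect vs reference allele, with a Woolf CI and a
    Fisher/chi-square p-value.
    """
    jt = joint_classification(records, snp, contrast)
    out: dict[str, EffectEstimate] = {}
    for name, exposed in (("exposed", True), ("unexposed", False)):
        table = jt.stratum_table(exposed)
        if table.a + table.b == 0 or table.c + table.d == 0:
            raise ValueError(f"{name} stratum is empty for {snp.snp_id}")
        p, _ = association_p(table, fisher_threshold)
        out[name] = odds_ratio(table, alpha=alpha, p_value=p)
    return out


@dataclass(frozen=True)
class InteractionResult:
    """Per-category estimates plus additive/multiplicative interaction measures."""

    table: JointClassificationTable
    measure: str
    #: estimates for categories 1..3 vs the reference (index 0 is None)
    category_estimates: tuple[EffectEstimate | None, ...]
    reri: float
    reri_ci: tuple[float, float]
    ap: float
    ap_ci: tuple[float, float]
    synergy_index: float | None
    synergy_note: str | None
    ratio_of_rr: float
    interaction_beta: float
    interaction_se: float
    interaction_p: float


def interaction_wald_from_cells(cells: tuple[int, ...],
                                ) -> tuple[float, float, float]:
    """(beta, se, p) of the multiplicative product term from 8 cell counts.

    beta is the log ratio of within-stratum cross-product ratios; its SE
    is sqrt of the summed reciprocal counts — the Wald statistic of the
    saturated model's interaction term.  A zero cell triggers the
    +0.5-everywhere continuity policy.
    """
    c = [float(x) for x in cells]
    if 0.0 in c:
        c = [x + 0.5 for x in c]
        logger.warning("zero cell in joint table: continuity correction applied")
    ca0, ca1, ca2, ca3 = c[0:4]
    co0, co1, co2, co3 = c[4:8]
    ratio_exposed = (ca3 * co2) / (ca2 * co3)
    ratio_unexposed = (ca1 * co0) / (ca0 * co1)
    beta = math.log(ratio_exposed / ratio_unexposed)
    se = math.sqrt(sum(1.0 / x for x in c))
    p = 2 * stats.norm.sf(abs(beta) / se)
    return beta, se, float(p)


def _category_point(k: int, m: int, k0: int, m0: int, measure: str) -> float:
    if measure == "risk_ratio":
        return (k / (k + m)) / (k0 / (k0 + m0))
    return (k * m0) / (m * k0)


def _log_cov(jt: JointClassificationTable, measure: str) -> np.ndarray:
    """Covariance of (ln EST10, ln EST01, ln EST11); the reference cells
    are shared, inducing a common covariance term."""
    k0, m0 = jt.cases[0], jt.controls[0]
    if measure == "risk_ratio":
        shared = 1 / k0 - 1 / (k0 + m0)
        own = [1 / jt.cases[i] - 1 / (jt.cases[i] + jt.controls[i])
               for i in (1, 2, 3)]
    else:
        shared = 1 / k0 + 1 / m0
        own = [1 / jt.cases[i] + 1 / jt.controls[i] for i in (1, 2, 3)]
    cov = np.full((3, 3), shared)
    for i in range(3):
        cov[i, i] += own[i]
    return cov


def interaction_measures(jt: JointClassificationTable,
                         measure: str = "risk_ratio",
                         alpha: float = 0.05,
                         fisher_threshold: float = 5.0,
                         input_decimals: int | None = None,
                         ) -> InteractionResult:
    """Compute RERI, AP, S and the ratio of relative risks from a 2x4 table.

    All measures derive from the unrounded category estimates;
    ``input_decimals`` recomputes them from estimates rounded to that
    many decimals, solely for concordance with reports quoting rounded
    inputs.  ``measure`` selects the category effect scale:
    ``"risk_ratio"`` (cumulative-incidence ratio, canonical) or
    ``"odds_ratio"``.
    """
    if measure not in ("risk_ratio", "odds_ratio"):
        raise ValueError(f"unknown measure {measure!r}")
    if measure == "risk_ratio":
        logger.warning(
            "risk-ratio scale on case-control counts estimates a true risk "
            "ratio only under the rare-disease assumption")
    k0, m0 = jt.cases[0], jt.controls[0]
    if k0 == 0 or m0 == 0:
        raise ValueError("reference category is empty; reference risk undefined")
    ests: list[EffectEstimate | None] = [None]
    for i in (1, 2, 3):
        tab = jt.category_table(i)
        p, _ = association_p(tab, fisher_threshold)
        if measure == "risk_ratio":
            ests.append(risk_ratio(tab, alpha=alpha, p_value=p))
        else:
            ests.append(odds_ratio(tab, alpha=alpha, p_value=p))
    # category order in ests: 1 = G+E-, 2 = G-E+, 3 = G+E+
    r10, r01, r11 = (e.point for e in ests[1:])  # type: ignore[union-attr]
    if input_decimals is not None:
        r10, r01, r11 = (round(v, input_decimals) for v in (r10, r01, r11))
    reri = r11 - r10 - r01 + 1
    ap = reri / r11
    s_den = r10 + r01 - 2
    if s_den <= 0:
        synergy, note = None, (
            f"synergy index undefined: RR10 + RR01 - 2 = {s_den:.4g} <= 0 "
            "(single-factor effects do not exceed the null on average)")
    else:
        synergy, note = (r11 - 1) / s_den, None
    ratio = r11 / (r10 * r01)
    beta, se, p_int = interaction_wald_from_cells(jt.cells)
    # delta-method intervals for RERI and AP on the log-estimate scale
    cov = _log_cov(jt, measure)
    z = stats.norm.ppf(1 - alpha / 2)
    g_reri = np.array([-r10, -r01, r11])
    var_reri = float(g_reri @ cov @ g_reri)
    reri_ci = (reri - z * math.sqrt(var_reri), reri + z * math.sqrt(var_reri))
    g_ap = np.array([-r10 / r11, -r01 / r11, (r10 + r01 - 1) / r11])
    var_ap = float(g_ap @ cov @ g_ap)
    ap_ci = (ap - z * math.sqrt(var_ap), ap + z * math.sqrt(var_ap))
    return InteractionResult(
        table=jt, measure=measure, category_estimates=tuple(ests),
        reri=reri, reri_ci=reri_ci, ap=ap, ap_ci=ap_ci,
        synergy_index=synergy, synergy_note=note, ratio_of_rr=ratio,
        interaction_beta=beta, interaction_se=se, interaction_p=p_int)
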