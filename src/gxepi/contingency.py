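"""Exact and asymptotic statistics on count tables.

Implements the contingency-table toolkit of a classical case-control
analysis: Pearson chi-square (no continuity correction by default),
Fisher's exact test, cross-product odds ratios with Woolf (log-scale)
confidence intervals, cumulative-incidence risk ratios with Katz
intervals, and the 1-df chi-square goodness-of-fit test for
Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts [[a, b], [c, d]]: rows case/control, columns level1/level0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def transpose(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.a, self.c, self.b, self.d)

    def expected(self) -> np.ndarray:
        t = self.as_array()
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()

    def min_expected(self) -> float:
        return float(self.expected().min())


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio effect measure with its log-scale Wald confidence interval."""

    measure: str  # "odds_ratio" | "risk_ratio"
    point: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    p_value: float | None = None
    method: str = ""
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if math.isfinite(self.point) and math.isfinite(self.ci_low) \
                and math.isfinite(self.ci_high):
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError(
                    f"CI ({self.ci_low}, {self.ci_high}) does not bracket "
                    f"point {self.point}")

    @property
    def log_se(self) -> float:
        """Back-derived SE of the log estimate implied by the CI."""
        z = stats.norm.ppf(1 - self.alpha / 2)
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * z)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


class DegenerateTableError(ValueError):
    """A margin needed by the test is entirely zero."""


def pearson_chi2(table, correction: bool = False) -> Chi2Result:
    """Pearson chi-square test of independence on an r x c count table.

    No Yates continuity correction by default (``correction=True``
    enables it for 2x2 tables).
    """
    arr = table.as_array() if isinstance(table, TwoByTwoTable) \
        else np.asarray(table, dtype=float)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    if min(arr.shape) < 2:
        raise DegenerateTableError("need at least two rows and two columns")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=correction)
    return Chi2Result(statistic=float(stat), df=int(df), p_value=float(p))


def fisher_exact(table: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables (with the observed margins) no more probable than the observed."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def association_p(table: TwoByTwoTable, fisher_threshold: float = 5.0) -> tuple[float, str]:
    """p-value for a 2x2 association: Fisher when any expected cell is
    below ``fisher_threshold``, else Pearson chi-square (1 df)."""
    if table.min_expected() < fisher_threshold:
        return fisher_exact(table), "fisher_exact"
    return pearson_chi2(table).p_value, "pearson_chi2"


def _haldane(table: TwoByTwoTable) -> tuple[tuple[float, float, float, float], bool]:
    """Apply the Haldane-Anscombe +0.5 to every cell iff any cell is zero."""
    if 0 in table.cells:
        return tuple(c + 0.5 for c in table.cells), True  # type: ignore[return-value]
    return tuple(float(c) for c in table.cells), False  # type: ignore[return-value]


def odds_ratio(table: TwoByTwoTable, alpha: float = 0.05,
               p_value: float | None = None) -> EffectEstimate:
    """Cross-product odds ratio ad/(bc) with the Woolf log-scale interval,
    SE = sqrt(1/a + 1/b + 1/c + 1/d).

    On a zero cell, 0.5 is added to every cell (Haldane-Anscombe) and the
    estimate is flagged ``continuity_corrected``.
    """
    (a, b, c, d), corrected = _haldane(table)
    flags = ("continuity_corrected",) if corrected else ()
    method = "cross_product+woolf_ci" + ("+haldane" if corrected else "")
    if b * c == 0:
        return EffectEstimate(measure="odds_ratio", point=math.inf,
                              ci_low=math.inf, ci_high=math.inf, alpha=alpha,
                              p_value=p_value, method=method,
                              flags=flags + ("infinite",))
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = math.exp(math.log(point) - z * se), math.exp(math.log(point) + z * se)
    return EffectEstimate(measure="odds_ratio", point=point, ci_low=lo,
                          ci_high=hi, alpha=alpha, p_value=p_value,
                          method=method, flags=flags)


def risk_ratio(table: TwoByTwoTable, alpha: float = 0.05,
               p_value: float | None = None) -> EffectEstimate:
    """Cumulative-incidence ratio [a/(a+b)] / [c/(c+d)] with the Katz
    log-scale interval, SE = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).

    Here rows index the compared groups and columns diseased/non-diseased.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise DegenerateTableError("both row totals must be positive")
    (a, b, c, d), corrected = _haldane(table)
    flags = ("continuity_corrected",) if corrected else ()
    method = "cumulative_incidence_ratio+katz_ci" + ("+haldane" if corrected else "")
    if c == 0:
        return EffectEstimate(measure="risk_ratio", point=math.inf,
                              ci_low=math.inf, ci_high=math.inf, alpha=alpha,
                              p_value=p_value, method=method,
                              flags=flags + ("infinite",))
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = math.exp(math.log(point) - z * se), math.exp(math.log(point) + z * se)
    return EffectEstimate(measure="risk_ratio", point=point, ci_low=lo,
                          ci_high=hi, alpha=alpha, p_value=p_value,
                          method=method, flags=flags)


def hwe_test(genotype_counts: tuple[int, int, int]) -> Chi2Result:
    """Hardy-Weinberg chi-square goodness of fit on (ref-hom, het, eff-hom).

    The allele frequency is estimated from the counts; expected genotype
    counts are (n p^2, 2npq, n q^2); the statistic has 1 df (3 classes,
    1 estimated frequency).  A monomorphic sample yields p = 1 with a
    warning (no departure is testable).
    """
    ref_hom, het, eff_hom = genotype_counts
    if min(genotype_counts) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = ref_hom + het + eff_hom
    if n == 0:
        raise ValueError("genotype count total must be positive")
    q = (2 * eff_hom + het) / (2 * n)  # effect-allele frequency
    p = 1 - q
    if q == 0 or q == 1:
        logger.warning("monomorphic sample: HWE test degenerate, p = 1")
        return Chi2Result(statistic=0.0, df=1, p_value=1.0)
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array(genotype_counts, dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return Chi2Result(statistic=stat, df=1, p_value=float(stats.chi2.sf(stat, 1)))
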