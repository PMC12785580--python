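"""Logistic regression for adjustment, confounding checks, and the
genotype-by-exposure interaction-term Wald test.

Model fitting is maximum likelihood (Newton/IRLS via statsmodels, with a
coefficient-change tolerance of 1e-8 and at most 50 iterations); Wald
confidence intervals throughout.  The default design for interaction
analysis expands each child into two allele-level rows (one per
chromosome), with an effect-allele indicator; carrier coding at the
child level is available via ``coding="carrier"``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .cohort import CohortRecord, PhenotypeContrast, SnpSpec
from .contingency import EffectEstimate, TwoByTwoTable

#: |beta| beyond which an otherwise-converged logit fit is treated as
#: separated (log-odds of ~20 is far outside any epidemiological scale).
SEPARATION_BETA = 20.0


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient (constant or collinear terms)."""


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model with per-term Wald statistics."""

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    n_obs: int
    separation: bool = False

    def __getitem__(self, term: str) -> tuple[float, float, float]:
        """(beta, se, p) for a named term."""
        i = self.terms.index(term)
        return float(self.beta[i]), float(self.se[i]), float(self.p[i])

    def odds_ratio(self, term: str, alpha: float = 0.05) -> EffectEstimate:
        b, se, p = self[term]
        zc = stats.norm.ppf(1 - alpha / 2)
        flags = ("separation",) if self.separation else ()
        return EffectEstimate(
            measure="odds_ratio", point=math.exp(b),
            ci_low=math.exp(b - zc * se), ci_high=math.exp(b + zc * se),
            alpha=alpha, p_value=p, method="logistic_wald", flags=flags)


def fit_logistic(y, X, terms: Sequence[str],
                 tol: float = 1e-8, maxiter: int = 50) -> LogisticFit:
    """Fit logit(P(y=1)) = X beta by maximum likelihood.

    ``X`` must already contain an intercept column if one is wanted.
    Complete separation is flagged (estimates kept but marked
    unreliable); a rank-deficient design is fatal with the term names.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(terms) != X.shape[1]:
        raise ValueError("X must be 2-D with one column per term")
    if y.min() == y.max():
        raise ValueError("outcome has no variation")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"design with terms {list(terms)} is rank-deficient "
            f"(rank {rank} < {X.shape[1]})")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton",
                                     tol=tol, maxiter=maxiter)
        except PerfectSeparationWarning:
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
    if np.abs(res.params).max() > SEPARATION_BETA:
        separation = True
    return LogisticFit(
        terms=tuple(terms),
        beta=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        z=np.asarray(res.tvalues, dtype=float),
        p=np.asarray(res.pvalues, dtype=float),
        log_likelihood=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", 0)),
        n_obs=int(len(y)),
        separation=separation)


def design_from_table(table: TwoByTwoTable):
    """Expand a 2x2 table into (y, X) rows for a single binary predictor.

    Rows are cases (y=1) and controls (y=0); the predictor is column
    membership (1 for column 1).  The fitted slope then equals
    ln(ad/(bc)) exactly (saturated model).
    """
    a, b, c, d = table.cells
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    X = np.column_stack([np.ones_like(x), x])
    return y, X


def interaction_design(records: Iterable[CohortRecord], snp: SnpSpec,
                       contrast: PhenotypeContrast, coding: str = "allele"):
    """Build (y, X, terms) for the genotype x exposure product-term model.

    ``coding="allele"``: each child contributes two rows, one per allele;
    the genetic term is the effect-allele indicator for that chromosome.
    ``coding="carrier"``: one row per child with a carrier indicator.
    Records with missing genotype or exposure, or outside the contrast,
    are excluded.
    """
    if coding not in ("allele", "carrier"):
        raise ValueError(f"unknown coding {coding!r}")
    ys: list[float] = []
    gs: list[float] = []
    es: list[float] = []
    for r in records:
        is_case = contrast.classify(r.phenotype)
        if is_case is None or r.exposure is None:
            continue
        k = r.effect_allele_count(snp)
        if k is None:
            continue
        e = 1.0 if r.exposure else 0.0
        if coding == "allele":
            for allele_is_effect in ([1.0] * k + [0.0] * (2 - k)):
                ys.append(1.0 if is_case else 0.0)
                gs.append(allele_is_effect)
                es.append(e)
        else:
            ys.append(1.0 if is_case else 0.0)
            gs.append(1.0 if k >= 1 else 0.0)
            es.append(e)
    y = np.array(ys)
    g = np.array(gs)
    e = np.array(es)
    X = np.column_stack([np.ones_like(y), g, e, g * e])
    terms = ("intercept", "G", "E", "GxE")
    return y, X, terms


def dose_design(records: Iterable[CohortRecord], snp: SnpSpec,
                contrast: PhenotypeContrast):
    """Child-level (y, X, terms) with the allele-count dose G in {0, 1, 2}.

    This is the parameterization of the synthetic-data risk model with
    allele coding; under case-control sampling the slope terms (but not
    the intercept) remain consistently estimated.
    """
    ys: list[float] = []
    gs: list[float] = []
    es: list[float] = []
    for r in records:
        is_case = contrast.classify(r.phenotype)
        if is_case is None or r.exposure is None:
            continue
        k = r.effect_allele_count(snp)
        if k is None:
            continue
        ys.append(1.0 if is_case else 0.0)
        gs.append(float(k))
        es.append(1.0 if r.exposure else 0.0)
    y = np.array(ys)
    g = np.array(gs)
    e = np.array(es)
    X = np.column_stack([np.ones_like(y), g, e, g * e])
    return y, X, ("intercept", "G", "E", "GxE")


def interaction_wald_test(records: Iterable[CohortRecord], snp: SnpSpec,
                          contrast: PhenotypeContrast,
                          coding: str = "allele") -> tuple[float, float, float]:
    """(beta, se, p) for the genotype x exposure product term."""
    y, X, terms = interaction_design(records, snp, contrast, coding=coding)
    fit = fit_logistic(y, X, terms)
    return fit["GxE"]


class ConfoundingVerdict(enum.Enum):
    NONE = "no_confounding"
    POSITIVE = "positive_confounding"   # adjusted > crude
    NEGATIVE = "negative_confounding"   # adjusted < crude


@dataclass(frozen=True)
class ConfoundingCheck:
    relative_change: float
    flagged: bool
    verdict: ConfoundingVerdict


def confounding_check(crude: EffectEstimate, adjusted: EffectEstimate,
                      threshold: float = 0.10) -> ConfoundingCheck:
    """Change-in-estimate confounding assessment.

    Flags confounding when |adjusted - crude| / crude exceeds
    ``threshold`` (default 10%), reporting the direction of the shift.
    Both estimates must be on the same measure scale.
    """
    if crude.measure != adjusted.measure:
        raise ValueError(
            f"measure mismatch: {crude.measure} vs {adjusted.measure}")
    change = (adjusted.point - crude.point) / crude.point
    # epsilon keeps an exactly-threshold change (borderline) unflagged
    flagged = abs(change) > threshold + 1e-12
    if not flagged:
        verdict = ConfoundingVerdict.NONE
    elif change > 0:
        verdict = ConfoundingVerdict.POSITIVE
    else:
        verdict = ConfoundingVerdict.NEGATIVE
    return ConfoundingCheck(relative_change=change, flagged=flagged,
                            verdict=verdict)
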