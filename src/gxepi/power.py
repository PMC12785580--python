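"""Wald-based post hoc power for main and interaction effects.

The achieved power of a two-sided Wald test at level alpha is
approximated as Phi(|beta|/SE - z_{1-alpha/2}), where beta is the log
odds ratio and Phi the standard normal CDF.  The far-tail term
Phi(-|beta|/SE - z) is omitted by default — the exact two-sided version
is available via ``exact_two_sided=True``; the difference is negligible
except at tiny effects, where the one-sided form floors at
Phi(-z) ~ 0.025 rather than alpha.

Inputs may be a (beta, se) pair or a reported OR with its confidence
interval, from which SE = (ln CI_high - ln CI_low) / (2 z).  For an
interaction term, beta is the log ratio of within-stratum cross-product
ratios of a 2x4 joint-classification table and SE the square root of
the summed reciprocals of its eight cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .interaction import JointClassificationTable, interaction_wald_from_cells


@dataclass(frozen=True)
class PowerResult:
    achieved_power: float
    z_effect: float  # |beta| / SE
    beta: float
    se: float
    flags: tuple[str, ...] = ()


def se_from_ci(ci_low: float, ci_high: float, alpha: float = 0.05) -> float:
    """Log-scale SE implied by a ratio estimate's Wald interval."""
    if not (0 < ci_low <= ci_high):
        raise ValueError("need 0 < ci_low <= ci_high")
    z = stats.norm.ppf(1 - alpha / 2)
    return (math.log(ci_high) - math.log(ci_low)) / (2 * z)


def wald_power(beta: float | None = None, se: float | None = None,
               or_point: float | None = None,
               ci: tuple[float, float] | None = None,
               ci_alpha: float = 0.05, test_alpha: float = 0.05,
               exact_two_sided: bool = False) -> PowerResult:
    """Post hoc power of a two-sided Wald test for the observed effect.

    Give either ``beta`` and ``se`` directly, or ``or_point`` with its
    ``ci`` (the interval's own level via ``ci_alpha``).
    """
    if beta is None:
        if or_point is None or ci is None:
            raise ValueError("need (beta, se) or (or_point, ci)")
        beta = math.log(or_point)
        se = se_from_ci(*ci, alpha=ci_alpha)
    if se is None or se <= 0:
        raise ValueError("se must be positive")
    z_crit = stats.norm.ppf(1 - test_alpha / 2)
    z_eff = abs(beta) / se
    power = float(stats.norm.cdf(z_eff - z_crit))
    if exact_two_sided:
        power += float(stats.norm.cdf(-z_eff - z_crit))
    return PowerResult(achieved_power=power, z_effect=z_eff,
                       beta=beta, se=se)


def interaction_power_from_table(jt: JointClassificationTable,
                                 test_alpha: float = 0.05,
                                 exact_two_sided: bool = False) -> PowerResult:
    """Post hoc power for the product term of a 2x4 joint table.

    beta = log ratio of the exposed to unexposed stratum cross-product
    ratios; SE = sqrt(sum of 1/cell over all eight cells).  Zero cells
    invoke the +0.5 continuity policy and are flagged.
    """
    flags: tuple[str, ...] = ()
    if 0 in jt.cells:
        flags = ("continuity_corrected",)
    beta, se, _ = interaction_wald_from_cells(jt.cells)
    res = wald_power(beta=beta, se=se, test_alpha=test_alpha,
                     exact_two_sided=exact_two_sided)
    return PowerResult(achieved_power=res.achieved_power,
                       z_effect=res.z_effect, beta=beta, se=se, flags=flags)


def empirical_power(config, n_reps: int, seed: int,
                    alpha: float = 0.05, probs=None) -> float:
    """Monte-Carlo rejection rate of the interaction Wald test.

    Simulates ``n_reps`` 2x4 joint-classification tables under
    ``config`` (a :class:`~gxepi.simulate.SimConfig`) and applies the
    saturated-model Wald test at level ``alpha``.  ``probs`` optionally
    fixes the (case, control) category proportions, e.g. to an observed
    table's composition.  Reproducible under a fixed seed.
    """
    from .simulate import simulate_joint_table

    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    n_reject = 0
    for jt in simulate_joint_table(config, n_reps=n_reps, seed=seed,
                                   probs=probs):
        _, _, p = interaction_wald_from_cells(jt.cells)
        if p < alpha:
            n_reject += 1
    return n_reject / n_reps
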