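"""Schema-validated analysis configuration and full report generation.

``run_full_report`` reproduces the structure of a complete
case-control gene-environment analysis: a characteristics panel
(genotype and exposure counts per group with HWE in controls), an
association grid (per contrast x inheritance model), an
exposure-stratified grid, a joint-classification interaction panel with
RERI/AP/S and the multiplicative ratio, and a post hoc power addendum.

Text rendering rounds percentages to 1 decimal, effect estimates to 2
and chi-square statistics to 3; the JSON bundle keeps full precision.
"""

from __future__ import annotations

import json
import math
from typing import Any, Iterable, Sequence

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cohort import (STANDARD_CONTRASTS, ASTHMA_ECZEMA_VS_CONTROL,
                     CohortRecord, PhenotypeContrast, SnpSpec,
                     exposure_table, tabulate_genotypes)
from .contingency import EffectEstimate, hwe_test, odds_ratio, pearson_chi2
from .genetic import DEFAULT_MODELS, GeneticModel, association_scan
from .interaction import (interaction_measures, joint_classification,
                          stratified_effects)
from .power import interaction_power_from_table, wald_power


class SnpConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    snp_id: str
    effect_allele: str
    reference_allele: str

    def spec(self) -> SnpSpec:
        return SnpSpec(self.snp_id, self.effect_allele, self.reference_allele)


class AnalysisConfig(BaseModel):
    """Validated analysis settings; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    snps: list[SnpConfig]
    models: list[str] = Field(
        default_factory=lambda: [m.value for m in DEFAULT_MODELS])
    measure: str = "risk_ratio"
    alpha: float = 0.05
    fisher_threshold: float = 5.0
    confounding_threshold: float = 0.10
    seed: int = 0

    @field_validator("models")
    @classmethod
    def _known_models(cls, v: list[str]) -> list[str]:
        for m in v:
            GeneticModel(m)  # raises ValueError on unknown names
        return v

    @field_validator("measure")
    @classmethod
    def _known_measure(cls, v: str) -> str:
        if v not in ("risk_ratio", "odds_ratio"):
            raise ValueError(f"unknown measure {v!r}")
        return v

    @field_validator("alpha")
    @classmethod
    def _alpha_range(cls, v: float) -> float:
        if not (0 < v < 1):
            raise ValueError("alpha must lie in (0, 1)")
        return v


def _estimate_dict(e: EffectEstimate | None) -> dict[str, Any] | None:
    if e is None:
        return None
    return {"measure": e.measure, "point": e.point, "ci_low": e.ci_low,
            "ci_high": e.ci_high, "alpha": e.alpha, "p_value": e.p_value,
            "method": e.method, "flags": list(e.flags)}


def run_full_report(records: Iterable[CohortRecord],
                    config: AnalysisConfig,
                    contrasts: Sequence[PhenotypeContrast] = STANDARD_CONTRASTS,
                    ) -> dict[str, Any]:
    """Run the whole pipeline and return a JSON-serializable bundle."""
    records = list(records)
    snps = [s.spec() for s in config.snps]
    models = [GeneticModel(m) for m in config.models]
    bundle: dict[str, Any] = {
        "config": config.model_dump(), "n_records": len(records),
        "characteristics": {}, "association": {}, "stratified": {},
        "interaction": {}, "power": {},
    }
    primary = ASTHMA_ECZEMA_VS_CONTROL
    for snp in snps:
        key = snp.snp_id
        counts = tabulate_genotypes(records, contrasts[0], snp)
        hwe = hwe_test(counts.controls)
        bundle["characteristics"][key] = {
            "cases": list(counts.cases), "controls": list(counts.controls),
            "hwe_controls": {"statistic": hwe.statistic, "p": hwe.p_value},
        }
        scan = association_scan(records, snp, contrasts, models,
                                alpha=config.alpha,
                                fisher_threshold=config.fisher_threshold)
        bundle["association"][key] = {
            "rows": [{
                "contrast": r.contrast_label, "model": r.model.value,
                "n_cases": r.n_cases, "n_controls": r.n_controls,
                "degenerate": r.degenerate,
                "estimate": _estimate_dict(r.estimate),
            } for r in scan.rows],
            "genotype_chi2": {
                lab: {"statistic": c.statistic, "df": c.df, "p": c.p_value}
                for lab, c in scan.genotype_chi2.items()},
        }
        strat = stratified_effects(records, snp, primary, alpha=config.alpha,
                                   fisher_threshold=config.fisher_threshold)
        bundle["stratified"][key] = {
            name: _estimate_dict(est) for name, est in strat.items()}
        jt = joint_classification(records, snp, primary)
        res = interaction_measures(jt, measure=config.measure,
                                   alpha=config.alpha,
                                   fisher_threshold=config.fisher_threshold)
        bundle["interaction"][key] = {
            "cases": list(jt.cases), "controls": list(jt.controls),
            "measure": res.measure,
            "category_estimates": [_estimate_dict(e)
                                   for e in res.category_estimates],
            "reri": res.reri, "reri_ci": list(res.reri_ci),
            "ap": res.ap, "ap_ci": list(res.ap_ci),
            "synergy_index": res.synergy_index,
            "synergy_note": res.synergy_note,
            "ratio_of_rr": res.ratio_of_rr,
            "interaction_p": res.interaction_p,
        }
        scan_row = scan.row(primary.label, GeneticModel.ALLELIC)
        power_main = None
        if scan_row.estimate is not None and \
                math.isfinite(scan_row.estimate.ci_low):
            pm = wald_power(or_point=scan_row.estimate.point,
                            ci=(scan_row.estimate.ci_low,
                                scan_row.estimate.ci_high),
                            ci_alpha=config.alpha)
            power_main = pm.achieved_power
        pi = interaction_power_from_table(jt)
        bundle["power"][key] = {
            "main_allelic": power_main,
            "interaction": pi.achieved_power,
            "interaction_flags": list(pi.flags),
        }
    # exposure-phenotype association (no genotype involved)
    bundle["exposure"] = {}
    for contrast in contrasts:
        try:
            t = exposure_table(records, contrast)
        except ValueError:
            continue
        chi = pearson_chi2(t)
        bundle["exposure"][contrast.label] = {
            "table": [[t.a, t.b], [t.c, t.d]],
            "chi2": chi.statistic, "p": chi.p_value,
            "odds_ratio": _estimate_dict(
                odds_ratio(t, alpha=config.alpha, p_value=chi.p_value)),
        }
    return bundle


def render_text(bundle: dict[str, Any]) -> str:
    """Human-readable summary with the package's rounding conventions."""
    lines: list[str] = []

    def est_str(e: dict[str, Any] | None) -> str:
        if e is None:
            return "-- (degenerate)"
        p = f", p = {e['p_value']:.3f}" if e.get("p_value") is not None else ""
        return (f"{e['point']:.2f} ({e['ci_low']:.2f} - {e['ci_high']:.2f})"
                f"{p}")

    for snp_id, ch in bundle["characteristics"].items():
        lines.append(f"== {snp_id} ==")
        lines.append(f"genotype counts cases {ch['cases']} "
                     f"controls {ch['controls']}; HWE(controls) chi2 = "
                     f"{ch['hwe_controls']['statistic']:.3f}, "
                     f"p = {ch['hwe_controls']['p']:.3f}")
        for row in bundle["association"][snp_id]["rows"]:
            lines.append(f"  [{row['contrast']}] {row['model']}: "
                         f"OR {est_str(row['estimate'])}")
        strat = bundle["stratified"][snp_id]
        lines.append(f"  stratified OR exposed {est_str(strat['exposed'])}; "
                     f"unexposed {est_str(strat['unexposed'])}")
        inter = bundle["interaction"][snp_id]
        s = ("undefined" if inter["synergy_index"] is None
             else f"{inter['synergy_index']:.2f}")
        lines.append(
            f"  interaction ({inter['measure']}): RERI = {inter['reri']:.2f}, "
            f"AP = {inter['ap']:.2f}, S = {s}, "
            f"ratio of RRs = {inter['ratio_of_rr']:.2f}, "
            f"p_interaction = {inter['interaction_p']:.4f}")
        pw = bundle["power"][snp_id]
        main = ("n/a" if pw["main_allelic"] is None
                else f"{pw['main_allelic']:.2f}")
        lines.append(f"  post hoc power: main {main}, "
                     f"interaction {pw['interaction']:.2f}")
    for label, ex in bundle.get("exposure", {}).items():
        lines.append(f"[exposure] {label}: chi2 = {ex['chi2']:.3f}, "
                     f"p = {ex['p']:.3f}, OR {est_str(ex['odds_ratio'])}")
    return "\n".join(lines)


def to_json(bundle: dict[str, Any], indent: int = 2) -> str:
    return json.dumps(bundle, indent=indent)
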