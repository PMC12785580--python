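"""Participant-level data model and cohort file I/O.

A cohort is a flat table of children: an opaque sample id, one biallelic
SNP genotype call per typed variant (an unordered allele pair such as
``"CT"``), a binary early-life exposure (environmental tobacco smoke,
parent-reported), and a three-level phenotype — eczema only, eczema with
asthma (the combined phenotype of interest), or healthy control.
Optional covariates (age in months, sex, family atopy) ride along as
named values.

Files are delimited text (default tab), UTF-8, with a required header:
``sample_id``, one ``genotype_<snp_id>`` column per SNP, ``ets``
(yes/no), ``phenotype``, and any covariate columns.  Unparseable
genotype/exposure/phenotype values become missing with a counted
warning; missing data are handled by listwise exclusion per analysis,
never imputation.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

MISSING_CODES = {"", "na", "nn", "nan", ".", "missing", "none", "?"}


class Phenotype(str, enum.Enum):
    """Three-level outcome classification at the 6-year follow-up."""

    ECZEMA_ONLY = "eczema_only"
    ECZEMA_ASTHMA = "eczema_asthma"
    CONTROL = "control"


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic SNP with an explicit effect (risk) allele orientation.

    Every odds ratio the package reports refers to the effect allele of
    the spec it was computed under; orientation is never inferred from
    data.
    """

    snp_id: str
    effect_allele: str
    reference_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele == self.reference_allele:
            raise ValueError(
                f"{self.snp_id}: effect and reference allele must differ"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset({self.effect_allele, self.reference_allele})


#: The two variants of the motivating replication study.
TNS1 = SnpSpec("rs918949", effect_allele="T", reference_allele="C")
NRXN1 = SnpSpec("rs10194978", effect_allele="A", reference_allele="G")


@dataclass(frozen=True)
class PhenotypeContrast:
    """A case/control definition as two disjoint sets of phenotype levels."""

    case_set: frozenset[Phenotype]
    control_set: frozenset[Phenotype]
    label: str

    def __post_init__(self) -> None:
        if not self.case_set or not self.control_set:
            raise ValueError(f"{self.label}: case and control sets must be non-empty")
        if self.case_set & self.control_set:
            raise ValueError(f"{self.label}: case and control sets overlap")

    def classify(self, phenotype: Phenotype | None) -> bool | None:
        """True for case, False for control, None if outside the contrast."""
        if phenotype in self.case_set:
            return True
        if phenotype in self.control_set:
            return False
        return None


def contrast(cases: Iterable[Phenotype], controls: Iterable[Phenotype],
             label: str) -> PhenotypeContrast:
    return PhenotypeContrast(frozenset(cases), frozenset(controls), label)


ECZEMA_VS_CONTROL = contrast(
    [Phenotype.ECZEMA_ONLY, Phenotype.ECZEMA_ASTHMA], [Phenotype.CONTROL],
    "eczema vs control")
ASTHMA_ECZEMA_VS_CONTROL = contrast(
    [Phenotype.ECZEMA_ASTHMA], [Phenotype.CONTROL],
    "asthma plus eczema vs control")
# The expanded control group: everyone outside the combined phenotype.
ASTHMA_ECZEMA_VS_EXPANDED_CONTROL = contrast(
    [Phenotype.ECZEMA_ASTHMA], [Phenotype.ECZEMA_ONLY, Phenotype.CONTROL],
    "asthma plus eczema vs expanded control")
ASTHMA_ECZEMA_VS_ECZEMA_ONLY = contrast(
    [Phenotype.ECZEMA_ASTHMA], [Phenotype.ECZEMA_ONLY],
    "asthma plus eczema vs eczema only")
ECZEMA_ONLY_VS_CONTROL = contrast(
    [Phenotype.ECZEMA_ONLY], [Phenotype.CONTROL],
    "eczema without asthma vs control")

STANDARD_CONTRASTS: tuple[PhenotypeContrast, ...] = (
    ECZEMA_VS_CONTROL,
    ASTHMA_ECZEMA_VS_CONTROL,
    ASTHMA_ECZEMA_VS_EXPANDED_CONTROL,
    ASTHMA_ECZEMA_VS_ECZEMA_ONLY,
    ECZEMA_ONLY_VS_CONTROL,
)


@dataclass(frozen=True)
class CohortRecord:
    """One participant.

    Genotypes are stored per SNP id as a canonical (sorted) allele pair;
    calls carry no phase, so ``("C", "T")`` and ``("T", "C")`` are the
    same genotype.  ``None`` marks missing genotype or exposure.
    """

    sample_id: str
    genotypes: Mapping[str, tuple[str, str] | None]
    exposure: bool | None
    phenotype: Phenotype
    covariates: Mapping[str, float | str] = field(default_factory=dict)

    def genotype(self, snp: SnpSpec) -> tuple[str, str] | None:
        return self.genotypes.get(snp.snp_id)

    def effect_allele_count(self, snp: SnpSpec) -> int | None:
        """Number of effect-allele copies (0, 1, 2), or None if missing."""
        gt = self.genotype(snp)
        if gt is None:
            return None
        bad = set(gt) - snp.alleles
        if bad:
            raise ValueError(
                f"{self.sample_id}: alleles {sorted(bad)} not in declared "
                f"allele set of {snp.snp_id}")
        return sum(a == snp.effect_allele for a in gt)


def canonical_genotype(call: str, snp: SnpSpec) -> tuple[str, str] | None:
    """Parse a genotype string into a sorted allele pair, or None.

    Accepts two-character calls ("CT") and separator forms ("C/T", "C|T").
    A call using alleles outside the SNP's declared set is unparseable.
    """
    s = call.strip()
    if s.lower() in MISSING_CODES:
        return None
    for sep in ("/", "|"):
        s = s.replace(sep, "")
    if len(s) != 2:
        return None
    a, b = s[0].upper(), s[1].upper()
    if a not in snp.alleles or b not in snp.alleles:
        return None
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def _parse_exposure(raw: str) -> bool | None:
    s = raw.strip().lower()
    if s in {"yes", "y", "1", "true", "exposed"}:
        return True
    if s in {"no", "n", "0", "false", "unexposed"}:
        return False
    return None


@dataclass
class Cohort:
    """A parsed cohort plus parse diagnostics."""

    records: list[CohortRecord]
    n_parse_warnings: int = 0

    def __iter__(self) -> Iterator[CohortRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


class CohortFormatError(ValueError):
    """Fatal structural problem in a cohort file (missing column, duplicate id)."""


def read_cohort(path: str | Path, snps: Sequence[SnpSpec],
                sep: str = "\t") -> Cohort:
    """Read a delimited cohort file into records.

    Unparseable genotype, exposure or phenotype values are mapped to
    missing and counted; a missing mandatory column or a duplicate
    sample id is fatal.
    """
    path = Path(path)
    geno_cols = {snp.snp_id: f"genotype_{snp.snp_id}" for snp in snps}
    mandatory = ["sample_id", "ets", "phenotype", *geno_cols.values()]
    records: list[CohortRecord] = []
    n_warn = 0
    seen: set[str] = set()
    valid_phenotypes = {p.value for p in Phenotype}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        header = reader.fieldnames or []
        missing_cols = [c for c in mandatory if c not in header]
        if missing_cols:
            raise CohortFormatError(
                f"{path}: missing mandatory column(s) {missing_cols}")
        covariate_cols = [c for c in header if c not in mandatory]
        for row in reader:
            sid = (row["sample_id"] or "").strip()
            if sid in seen:
                raise CohortFormatError(f"{path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            genotypes: dict[str, tuple[str, str] | None] = {}
            for snp in snps:
                raw = row[geno_cols[snp.snp_id]] or ""
                gt = canonical_genotype(raw, snp)
                if gt is None and raw.strip().lower() not in MISSING_CODES:
                    n_warn += 1
                    logger.warning("%s: unparseable genotype %r for %s (sample %s)",
                                   path, raw, snp.snp_id, sid)
                genotypes[snp.snp_id] = gt
            raw_ets = row["ets"] or ""
            exposure = _parse_exposure(raw_ets)
            if exposure is None and raw_ets.strip().lower() not in MISSING_CODES:
                n_warn += 1
                logger.warning("%s: unparseable exposure %r (sample %s)",
                               path, raw_ets, sid)
            raw_ph = (row["phenotype"] or "").strip().lower()
            if raw_ph not in valid_phenotypes:
                raise CohortFormatError(
                    f"{path}: sample {sid!r} has phenotype {raw_ph!r}, "
                    f"expected one of {sorted(valid_phenotypes)}")
            covariates: dict[str, float | str] = {}
            for c in covariate_cols:
                v = (row.get(c) or "").strip()
                if v.lower() in MISSING_CODES:
                    continue
                try:
                    covariates[c] = float(v)
                except ValueError:
                    covariates[c] = v
            records.append(CohortRecord(
                sample_id=sid, genotypes=genotypes, exposure=exposure,
                phenotype=Phenotype(raw_ph), covariates=covariates))
    return Cohort(records=records, n_parse_warnings=n_warn)


def write_cohort(records: Iterable[CohortRecord], path: str | Path,
                 snps: Sequence[SnpSpec], sep: str = "\t") -> None:
    """Write records to a delimited file readable by :func:`read_cohort`."""
    path = Path(path)
    records = list(records)
    cov_cols: list[str] = []
    for r in records:
        for c in r.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    header = (["sample_id"]
              + [f"genotype_{snp.snp_id}" for snp in snps]
              + ["ets", "phenotype"] + cov_cols)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(header)
        for r in records:
            row: list[str] = [r.sample_id]
            for snp in snps:
                gt = r.genotype(snp)
                row.append("".join(gt) if gt is not None else "NN")
            row.append({True: "yes", False: "no", None: "NA"}[r.exposure])
            row.append(r.phenotype.value)
            for c in cov_cols:
                v = r.covariates.get(c, "")
                row.append(format(v, "g") if isinstance(v, float) else str(v))
            writer.writerow(row)


@dataclass(frozen=True)
class GenotypeCountTable:
    """Genotype class counts (ref-hom, het, effect-hom) for cases and controls."""

    snp: SnpSpec
    cases: tuple[int, int, int]
    controls: tuple[int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        for grp in (self.cases, self.controls):
            if any(c < 0 for c in grp):
                raise ValueError("genotype counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)

    def allele_counts(self, group: tuple[int, int, int]) -> tuple[int, int]:
        """(effect, reference) allele counts for a genotype-count triple."""
        ref_hom, het, eff_hom = group
        return 2 * eff_hom + het, 2 * ref_hom + het


class EmptyStratumError(ValueError):
    """A case or control stratum required by an analysis is empty."""


def tabulate_genotypes(records: Iterable[CohortRecord],
                       contrast: PhenotypeContrast,
                       snp: SnpSpec) -> GenotypeCountTable:
    """Count genotype classes by case/control membership under a contrast.

    Records with missing genotype, or with a phenotype outside the
    contrast, are excluded (complete-case analysis).
    """
    cases = [0, 0, 0]
    controls = [0, 0, 0]
    for r in records:
        is_case = contrast.classify(r.phenotype)
        if is_case is None:
            continue
        k = r.effect_allele_count(snp)
        if k is None:
            continue
        (cases if is_case else controls)[k] += 1
    if sum(cases) == 0:
        raise EmptyStratumError(
            f"{contrast.label}: no genotyped cases for {snp.snp_id}")
    if sum(controls) == 0:
        raise EmptyStratumError(
            f"{contrast.label}: no genotyped controls for {snp.snp_id}")
    return GenotypeCountTable(snp=snp, cases=(cases[0], cases[1], cases[2]),
                              controls=(controls[0], controls[1], controls[2]),
                              label=contrast.label)


def exposure_table(records: Iterable[CohortRecord],
                   contrast: PhenotypeContrast):
    """2×2 exposure table: rows case/control, columns exposed/unexposed."""
    from .contingency import TwoByTwoTable

    counts = [[0, 0], [0, 0]]
    for r in records:
        is_case = contrast.classify(r.phenotype)
        if is_case is None or r.exposure is None:
            continue
        counts[0 if is_case else 1][0 if r.exposure else 1] += 1
    if sum(counts[0]) == 0:
        raise EmptyStratumError(f"{contrast.label}: no cases with known exposure")
    if sum(counts[1]) == 0:
        raise EmptyStratumError(f"{contrast.label}: no controls with known exposure")
    return TwoByTwoTable(a=counts[0][0], b=counts[0][1],
                         c=counts[1][0], d=counts[1][1])
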