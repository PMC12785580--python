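"""Published summary counts of the motivating replication study, and a
synthetic individual-level reconstruction consistent with them.

The study: 188 Polish children followed to age 6 — 103 with atopic
eczema (28 of whom developed eczema-associated asthma, the combined
phenotype) and 85 healthy controls — genotyped for TNS1 rs918949
(risk allele T) and NRXN1 rs10194978 (risk allele A), with
parent-reported environmental tobacco smoke (ETS) exposure in the
first two years of life.

Only group-level margins were published: genotype counts per phenotype
group, exposure counts per group, and the allele-level genotype-by-
exposure joint counts for the combined-phenotype cases and controls.
:func:`reconstruct_cohort` builds a synthetic 188-record cohort that
reproduces every published margin exactly.  The within-stratum
genotype-by-exposure splits are not identified by those margins; the
fixed splits below were chosen once to be plausible under
Hardy-Weinberg-like composition within stratum, and no published
statistic depends on them.
"""

from __future__ import annotations

from .cohort import NRXN1, TNS1, CohortRecord, Phenotype, SnpSpec
from .interaction import JointClassificationTable

#: Genotype counts (ref-hom, het, effect-hom) by phenotype group.
GENOTYPE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    TNS1.snp_id: {
        "eczema_all": (33, 42, 28),     # the 103 children with eczema
        "control": (24, 48, 13),
        "eczema_asthma": (6, 10, 12),   # from allele-level joint counts / 2
        "eczema_only": (27, 32, 16),
    },
    NRXN1.snp_id: {
        "eczema_all": (21, 45, 37),
        "control": (20, 35, 30),
        "eczema_asthma": (5, 10, 13),
        "eczema_only": (16, 35, 24),
    },
}

#: ETS exposure (exposed, unexposed) by phenotype group.
EXPOSURE_COUNTS: dict[str, tuple[int, int]] = {
    "eczema_all": (36, 67),
    "control": (23, 62),
    "eczema_asthma": (16, 12),
    "eczema_only": (20, 55),
}

#: Allele-level joint genotype x exposure counts, category order
#: (ref/unexposed, effect/unexposed, ref/exposed, effect/exposed),
#: for combined-phenotype cases and controls.
JOINT_ALLELE_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    TNS1.snp_id: {"cases": (14, 10, 8, 24), "controls": (62, 62, 34, 12)},
    NRXN1.snp_id: {"cases": (8, 16, 12, 20), "controls": (42, 82, 33, 13)},
}


def joint_table(snp: SnpSpec) -> JointClassificationTable:
    """The published allele-level 2x4 table for one SNP (combined
    phenotype vs control)."""
    counts = JOINT_ALLELE_COUNTS[snp.snp_id]
    return JointClassificationTable(
        snp=snp, cases=counts["cases"], controls=counts["controls"],
        label="asthma plus eczema vs control")


# Within-stratum genotype splits (ref-hom, het, effect-hom) per
# (group, exposure) cell.  Each split's allele sums equal the published
# joint allele counts, and splits sum across exposure to the published
# genotype margins; within those constraints the splits are synthetic.
_STRATUM_GENOTYPES: dict[str, dict[tuple[str, bool], tuple[int, int, int]]] = {
    TNS1.snp_id: {
        ("eczema_asthma", True): (2, 4, 10),
        ("eczema_asthma", False): (4, 6, 2),
        ("control", True): (13, 8, 2),
        ("control", False): (11, 40, 11),
        ("eczema_only", True): (7, 9, 4),
        ("eczema_only", False): (20, 23, 12),
    },
    NRXN1.snp_id: {
        ("eczema_asthma", True): (3, 6, 7),
        ("eczema_asthma", False): (2, 4, 6),
        ("control", True): (11, 11, 1),
        ("control", False): (9, 24, 29),
        ("eczema_only", True): (4, 10, 6),
        ("eczema_only", False): (12, 25, 18),
    },
}

_PHENOTYPE = {
    "eczema_asthma": Phenotype.ECZEMA_ASTHMA,
    "eczema_only": Phenotype.ECZEMA_ONLY,
    "control": Phenotype.CONTROL,
}

#: Sex counts (male, female): 63/40 among the 103 eczema children,
#: 44/41 among controls.
_SEX = {"eczema_asthma": (17, 11), "eczema_only": (46, 29),
        "control": (44, 41)}


def _genotype_list(split: tuple[int, int, int], snp: SnpSpec) -> list[tuple[str, str]]:
    r, h, e = split
    ref, eff = snp.reference_allele, snp.effect_allele
    pairs = ([tuple(sorted((ref, ref)))] * r
             + [tuple(sorted((ref, eff)))] * h
             + [tuple(sorted((eff, eff)))] * e)
    return pairs  # type: ignore[return-value]


def reconstruct_cohort() -> list[CohortRecord]:
    """A synthetic 188-child cohort reproducing all published margins.

    Within each (phenotype, exposure) stratum the two SNPs' genotype
    lists are paired in a fixed arbitrary order (no joint two-locus
    constraint was published).  Sex is assigned to match the published
    male/female totals per group; it does not enter any computation.
    """
    records: list[CohortRecord] = []
    i = 0
    for group in ("eczema_asthma", "eczema_only", "control"):
        sex_m, sex_f = _SEX[group]
        sexes = ["m"] * sex_m + ["f"] * sex_f
        j = 0
        for exposed in (True, False):
            tns1 = _genotype_list(_STRATUM_GENOTYPES[TNS1.snp_id][(group, exposed)], TNS1)
            nrxn1 = _genotype_list(_STRATUM_GENOTYPES[NRXN1.snp_id][(group, exposed)], NRXN1)
            assert len(tns1) == len(nrxn1)
            for gt_t, gt_n in zip(tns1, nrxn1):
                records.append(CohortRecord(
                    sample_id=f"P{i:03d}",
                    genotypes={TNS1.snp_id: gt_t, NRXN1.snp_id: gt_n},
                    exposure=exposed,
                    phenotype=_PHENOTYPE[group],
                    covariates={"sex": sexes[j]}))
                i += 1
                j += 1
    return records
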