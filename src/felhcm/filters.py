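"""Cohort inclusion/exclusion rules for the case-control association phase.

Three families of criteria are applied before any odds ratio is computed:
phenotypic (ambiguous/restrictive phenotypes out, young or age-unknown
healthy animals out), breed (the caller subsets to the breed of interest),
and genotypic (animals carrying any of the other catalogued variants are
dropped so each variant is assessed on an otherwise wild-type background).
Every exclusion is recorded with a reason code in a :class:`FilterTrace` so
the audit trail can be serialized alongside the report.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .datatypes import MISSING, AnalysisConfig, CatRecord, CohortTable, GenotypeCounts, Phenotype

__all__ = [
    "ExclusionReason",
    "FilterTrace",
    "label_phenotype",
    "apply_phenotype_filters",
    "apply_genotype_exclusion",
    "to_case_control",
]


class ExclusionReason(str, enum.Enum):
    EQUIVOCAL = "EQUIVOCAL"
    RCM = "RCM"
    UNKNOWN_PHENO = "UNKNOWN_PHENO"
    CONTROL_UNDER_AGE = "CONTROL_UNDER_AGE"
    NON_WT_OTHER_VARIANT = "NON_WT_OTHER_VARIANT"
    MISSING_DOSAGE = "MISSING_DOSAGE"


@dataclass
class FilterTrace:
    """Audit trail of one filter pass: counts along the chain and the
    excluded animal ids with their reasons."""

    n_input: int = 0
    n_after_phenotype: int = 0
    n_after_age: int = 0
    n_after_genotype: int = 0
    excluded: list[tuple[str, ExclusionReason]] = field(default_factory=list)

    def exclude(self, record: CatRecord, reason: ExclusionReason) -> None:
        self.excluded.append((record.animal_id, reason))

    def reason_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.excluded:
            out[reason.value] = out.get(reason.value, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_phenotype": self.n_after_phenotype,
            "n_after_age": self.n_after_age,
            "n_after_genotype": self.n_after_genotype,
            "excluded": [
                {"animal_id": aid, "reason": reason.value} for aid, reason in self.excluded
            ],
        }


def label_phenotype(
    lv_wall_mm: float, lower: float = 5.0, upper: float = 6.0
) -> Phenotype:
    """Label from end-diastolic left-ventricular wall thickness: at or below
    ``lower`` (mm) is within normal range, at or above ``upper`` suggests
    concentric hypertrophy, strictly between is equivocal.

    The generic cutoffs hold for average-sized, euthyroid, normotensive cats
    (roughly 3.5-5 kg); outside that weight range body-weight-specific
    prediction intervals should inform the label supplied upstream.
    """
    if not lv_wall_mm > 0:
        raise ValueError(f"wall thickness must be positive, got {lv_wall_mm}")
    if lower >= upper:
        raise ValueError("lower cutoff must be below upper cutoff")
    if lv_wall_mm <= lower:
        return Phenotype.NORMAL
    if lv_wall_mm >= upper:
        return Phenotype.HCM
    return Phenotype.EQUIVOCAL


def apply_phenotype_filters(
    cohort: CohortTable, cfg: AnalysisConfig
) -> tuple[CohortTable, FilterTrace]:
    """Drop equivocal, restrictive-cardiomyopathy and phenotype-unknown
    animals, then drop healthy controls younger than the age cutoff (strictly
    under; an animal exactly at the cutoff stays) or with unknown age.
    Affected animals are kept regardless of age: disease can present from a
    few months on, while a young normal may simply not have converted yet."""
    trace = FilterTrace(n_input=len(cohort))
    after_pheno: list[CatRecord] = []
    for r in cohort:
        if r.phenotype is Phenotype.EQUIVOCAL:
            trace.exclude(r, ExclusionReason.EQUIVOCAL)
        elif r.phenotype is Phenotype.RCM:
            trace.exclude(r, ExclusionReason.RCM)
        elif r.phenotype is Phenotype.UNKNOWN:
            trace.exclude(r, ExclusionReason.UNKNOWN_PHENO)
        else:
            after_pheno.append(r)
    trace.n_after_phenotype = len(after_pheno)

    kept: list[CatRecord] = []
    for r in after_pheno:
        if r.phenotype is Phenotype.NORMAL and (
            r.age_years is None or r.age_years < cfg.control_min_age_years
        ):
            trace.exclude(r, ExclusionReason.CONTROL_UNDER_AGE)
        else:
            kept.append(r)
    trace.n_after_age = len(kept)
    trace.n_after_genotype = len(kept)  # genotype filter not run in this pass
    return CohortTable(kept), trace


def apply_genotype_exclusion(
    cohort: CohortTable, target: str, others: list[str]
) -> tuple[CohortTable, FilterTrace]:
    """Keep only animals homozygous wild type at every variant in ``others``
    and genotyped (non-missing dosage) at ``target``, so the assessed variant
    is evaluated free of the influence of the co-segregating ones."""
    if target in others:
        raise ValueError("others must not contain the target variant")
    known = cohort.variant_ids
    for vid in [target, *others]:
        if known and vid not in known:
            raise ValueError(f"unknown variant_id {vid!r}")
    trace = FilterTrace(n_input=len(cohort))
    trace.n_after_phenotype = len(cohort)
    trace.n_after_age = len(cohort)
    kept: list[CatRecord] = []
    for r in cohort:
        if any(r.dosage(vid) != 0 for vid in others):
            trace.exclude(r, ExclusionReason.NON_WT_OTHER_VARIANT)
        elif r.dosage(target) == MISSING:
            trace.exclude(r, ExclusionReason.MISSING_DOSAGE)
        else:
            kept.append(r)
    trace.n_after_genotype = len(kept)
    return CohortTable(kept), trace


def to_case_control(
    cohort: CohortTable, target: str
) -> tuple[GenotypeCounts, GenotypeCounts]:
    """Collapse a fully filtered cohort into case (affected) and control
    (healthy) genotype-count triples at the target variant."""
    tallies = {Phenotype.HCM: [0, 0, 0], Phenotype.NORMAL: [0, 0, 0]}
    for r in cohort:
        if r.phenotype not in tallies:
            raise ValueError(
                f"phenotype {r.phenotype.value} present; run the phenotype "
                "filters before collapsing to case/control"
            )
        d = r.dosage(target)
        if d == MISSING:
            raise ValueError(
                f"missing dosage at {target!r} for {r.animal_id!r}; run the "
                "genotype exclusion first"
            )
        tallies[r.phenotype][d] += 1
    case = GenotypeCounts(*tallies[Phenotype.HCM])
    control = GenotypeCounts(*tallies[Phenotype.NORMAL])
    return case, control
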