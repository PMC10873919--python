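"""Core domain types for breed-stratified variant evaluation.

The vocabulary mirrors how feline cardiomyopathy cohorts are actually
tabulated: a variant catalogue, per-animal records with alt-allele dosages,
and per-(breed, variant) genotype-count triples (Wt/Wt, Wt/Vt, Vt/Vt) that
drive every downstream statistic.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pydantic import BaseModel, Field, field_validator

MISSING = -1  # sentinel dosage: animal not genotyped for that variant


class Phenotype(str, enum.Enum):
    """Closed phenotype vocabulary for the cardiomyopathy cohort."""

    HCM = "HCM"
    NORMAL = "NORMAL"
    EQUIVOCAL = "EQUIVOCAL"
    RCM = "RCM"
    UNKNOWN = "UNKNOWN"


def normalize_breed(breed: str) -> str:
    """Canonical breed key: trimmed, case-insensitive (owner-reported names)."""
    return " ".join(breed.strip().split()).lower()


@dataclass(frozen=True)
class VariantDef:
    """One catalogued variant: id, gene, HGVS-like labels, breed of origin."""

    variant_id: str
    gene: str
    cdna_label: str = ""
    protein_label: str = ""
    origin_breed: str = ""

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be nonempty")
        if not self.gene:
            raise ValueError("gene must be nonempty")


@dataclass(frozen=True)
class GenotypeCounts:
    """Animal counts per genotype class: homozygous wild type, heterozygous,
    homozygous variant."""

    n_wtwt: int
    n_wtvt: int
    n_vtvt: int

    def __post_init__(self) -> None:
        for name in ("n_wtwt", "n_wtvt", "n_vtvt"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.n_wtwt + self.n_wtvt + self.n_vtvt

    @property
    def n_variant_alleles(self) -> int:
        return self.n_wtvt + 2 * self.n_vtvt

    @property
    def n_wild_alleles(self) -> int:
        return 2 * self.n_wtwt + self.n_wtvt

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_wtwt + other.n_wtwt,
            self.n_wtvt + other.n_wtvt,
            self.n_vtvt + other.n_vtvt,
        )

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_wtwt, self.n_wtvt, self.n_vtvt)


@dataclass
class CatRecord:
    """One animal: breed, age, phenotype label and per-variant alt-allele
    dosage (0/1/2, or MISSING when not genotyped)."""

    animal_id: str
    breed: str
    age_years: float | None
    phenotype: Phenotype
    dosages: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise ValueError("animal_id must be nonempty")
        self.phenotype = Phenotype(self.phenotype)
        if self.age_years is not None:
            if math.isnan(self.age_years):
                self.age_years = None
            elif self.age_years < 0:
                raise ValueError(f"age_years must be non-negative: {self.age_years}")
        for vid, d in self.dosages.items():
            if d not in (0, 1, 2, MISSING):
                raise ValueError(
                    f"dosage for {vid!r} must be 0, 1, 2 or MISSING; got {d!r}"
                )

    def dosage(self, variant_id: str) -> int:
        return self.dosages.get(variant_id, MISSING)


@dataclass
class CohortTable:
    """Ordered collection of :class:`CatRecord` with unique animal ids."""

    records: list[CatRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.animal_id in seen:
                raise ValueError(f"duplicate animal_id {r.animal_id!r}")
            seen.add(r.animal_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def breeds(self) -> set[str]:
        return {normalize_breed(r.breed) for r in self.records}

    @property
    def variant_ids(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out.update(r.dosages)
        return out

    def subset_breed(self, breed: str) -> "CohortTable":
        key = normalize_breed(breed)
        return CohortTable([r for r in self.records if normalize_breed(r.breed) == key])


@dataclass
class CountsTable:
    """Map (breed, variant_id) -> GenotypeCounts; breed keys are normalized."""

    entries: dict[tuple[str, str], GenotypeCounts] = field(default_factory=dict)

    def add(self, breed: str, variant_id: str, counts: GenotypeCounts) -> None:
        """Insert counts; an existing (breed, variant) entry is summed
        (pooling of multiple genotyping batches)."""
        key = (normalize_breed(breed), variant_id)
        if key in self.entries:
            self.entries[key] = self.entries[key] + counts
        else:
            self.entries[key] = counts

    def get(self, breed: str, variant_id: str) -> GenotypeCounts | None:
        return self.entries.get((normalize_breed(breed), variant_id))

    def __len__(self) -> int:
        return len(self.entries)

    def items(self) -> Iterable[tuple[tuple[str, str], GenotypeCounts]]:
        return self.entries.items()


class AnalysisConfig(BaseModel):
    """Tunable analysis parameters.

    control_min_age_years
        Healthy animals younger than this are excluded from the control arm
        (late-onset disease; young normals may yet convert). Default 6.0.
    ps4_or_threshold
        A significant odds ratio above this fulfils the case-control ACMG
        criterion (PS4). Default 5.0.
    acmg_ba1_cutoff
        The fixed allele-frequency cutoff separating stand-alone benign (BA1,
        above) from moderate pathogenic support (PM2, below). Default 0.05.
    ci_level
        Two-sided confidence level for Wald intervals. Default 0.95.
    tv_by_variant
        Per-variant alternative allele-frequency thresholds (proportions).
    haldane_policy
        'auto' adds 0.5 to all four 2x2 cells when any cell is zero;
        'always' / 'never' force or suppress the correction.
    """

    control_min_age_years: float = 6.0
    ps4_or_threshold: float = 5.0
    acmg_ba1_cutoff: float = Field(default=0.05, ge=0.0, le=1.0)
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)
    tv_by_variant: dict[str, float] = Field(default_factory=dict)
    rounding: int = 2
    haldane_policy: str = "auto"
    bonferroni: bool = False  # extension, off by default
    seed: int = 0

    @field_validator("haldane_policy")
    @classmethod
    def _policy(cls, v: str) -> str:
        if v not in ("auto", "always", "never"):
            raise ValueError("haldane_policy must be auto, always or never")
        return v

    @field_validator("tv_by_variant")
    @classmethod
    def _tv(cls, v: Mapping[str, float]) -> dict[str, float]:
        for vid, tv in v.items():
            if not (0.0 < tv <= 1.0):
                raise ValueError(f"Tv for {vid!r} must lie in (0, 1], got {tv}")
        return dict(v)
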