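"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from felhcm.acmg import Category, Criterion, EvidenceSet, combine
from felhcm.datatypes import (
    MISSING,
    AnalysisConfig,
    CatRecord,
    CohortTable,
    GenotypeCounts,
    Phenotype,
)


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


def make_record(
    animal_id: str,
    phenotype: Phenotype | str = Phenotype.NORMAL,
    age: float | None = 8.0,
    breed: str = "Test Breed",
    **dosages: int,
) -> CatRecord:
    return CatRecord(animal_id, breed, age, Phenotype(phenotype), dict(dosages))


def cohort_from_triples(
    breed: str,
    target: str,
    case: GenotypeCounts,
    control: GenotypeCounts,
    other_variants: tuple[str, ...] = (),
    case_age: float = 4.0,
    control_age: float = 8.0,
    prefix: str = "",
) -> CohortTable:
    """Reconstruct a per-animal cohort whose filtered case/control collapse
    reproduces the given genotype triples: affected animals at ``case_age``,
    healthy ones at ``control_age``, homozygous wild type at all other
    variants."""
    records = []
    i = 0
    for pheno, triple, age in (
        (Phenotype.HCM, case, case_age),
        (Phenotype.NORMAL, control, control_age),
    ):
        for dosage, count in zip((0, 1, 2), triple.as_tuple()):
            for _ in range(count):
                dosages = {target: dosage, **{v: 0 for v in other_variants}}
                records.append(
                    CatRecord(f"{prefix}{breed}-{i:04d}", breed, age, pheno, dosages)
                )
                i += 1
    return CohortTable(records)


def random_cohort(
    rng: np.random.Generator,
    n: int = 100,
    variant_ids: tuple[str, ...] = ("VAR_A", "VAR_B", "VAR_C"),
    missing_rate: float = 0.1,
    breed: str = "Rand Breed",
) -> CohortTable:
    """Arbitrary cohort with all phenotype labels, missing ages and missing
    dosages, for round-trip and filter-oracle tests."""
    phenos = list(Phenotype)
    records = []
    for i in range(n):
        age = None if rng.random() < 0.1 else float(np.round(rng.uniform(0.2, 20.0), 2))
        dosages = {}
        for vid in variant_ids:
            if rng.random() < missing_rate:
                dosages[vid] = MISSING
            else:
                dosages[vid] = int(rng.integers(0, 3))
        records.append(
            CatRecord(
                f"cat-{i:04d}",
                breed,
                age,
                phenos[int(rng.integers(0, len(phenos)))],
                dosages,
            )
        )
    return CohortTable(records)


# ---------------------------------------------------------------------------
# independent evidence-combination oracle: every combining rule checked
# one by one from the raw strength counts, written without reference to the
# engine's control flow
# ---------------------------------------------------------------------------

def combine_oracle(pvs: int, ps: int, pm: int, pp: int, ba: int, bs: int, bp: int) -> Category:
    pathogenic_rules = [
        pvs >= 1 and ps >= 1,
        pvs >= 1 and pm >= 2,
        pvs >= 1 and pm == 1 and pp >= 1,
        pvs >= 1 and pp >= 2,
        ps >= 2,
        ps == 1 and pm >= 3,
        ps == 1 and pm == 2 and pp >= 2,
        ps == 1 and pm == 1 and pp >= 4,
    ]
    lp_rules = [
        pvs >= 1 and pm == 1,
        ps == 1 and pm in (1, 2),
        ps == 1 and pp >= 2,
        pm >= 3,
        pm == 2 and pp >= 2,
        pm == 1 and pp >= 4,
    ]
    benign_rules = [bs >= 2]
    lb_rules = [bs == 1 and bp >= 1, bp >= 2]

    if ba >= 1:
        return Category.BENIGN
    path_fires = any(pathogenic_rules) or any(lp_rules)
    benign_fires = any(benign_rules) or any(lb_rules)
    if path_fires and benign_fires:
        return Category.VUS
    if any(pathogenic_rules):
        return Category.PATHOGENIC
    if any(lp_rules):
        return Category.LIKELY_PATHOGENIC
    if any(benign_rules):
        return Category.BENIGN
    if any(lb_rules):
        return Category.LIKELY_BENIGN
    return Category.VUS


def evidence_from_counts(pvs: int, ps: int, pm: int, pp: int, ba: int, bs: int, bp: int) -> EvidenceSet:
    codes = (
        ["PVS1"][:pvs]
        + ["PS1", "PS2", "PS3", "PS4"][:ps]
        + ["PM1", "PM3", "PM4", "PM5", "PM6"][:pm]  # PM2 reserved for frequency
        + ["PP1", "PP2", "PP3", "PP4", "PP5"][:pp]
        + ["BA1"][:ba]
        + ["BS2", "BS3", "BS4"][:bs]  # BS1 reserved for frequency
        + ["BP1", "BP2", "BP4", "BP5"][:bp]
    )
    return EvidenceSet("x", [Criterion(c) for c in codes])


def enumerate_bounded_counts():
    """All evidence-count vectors with <=1 PVS, <=2 PS, <=3 PM, <=4 PP,
    <=1 BA, <=2 BS, <=2 BP."""
    return itertools.product(
        range(2), range(3), range(4), range(5), range(2), range(3), range(3)
    )


def assert_combine_matches_oracle() -> int:
    n = 0
    for counts in enumerate_bounded_counts():
        got = combine(evidence_from_counts(*counts)).category
        want = combine_oracle(*counts)
        assert got is want, f"counts {counts}: engine {got}, oracle {want}"
        n += 1
    return n
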