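"""Built-in catalogue of the six feline HCM-associated variants.

Ships, as in-memory fixtures, the published breed-stratified genotype
counts, the post-filter case/control genotype triples, the curated
non-frequency classification evidence, and the per-variant alternative
allele-frequency thresholds (Tv) reported for these variants in the
veterinary literature. These are the canonical worked inputs for the
pipeline; they also let every report table be regenerated end to end.
"""

from __future__ import annotations

from .acmg import Criterion, EvidenceSet, TvSpec
from .datatypes import AnalysisConfig, CountsTable, GenotypeCounts, VariantDef

__all__ = [
    "variant_catalogue",
    "breed_genotype_counts",
    "case_control_counts",
    "evidence_sets",
    "tv_thresholds",
    "classification_breed",
    "default_config",
    "reference_inputs",
]

A31P = "MYBPC3_A31P"
A74T = "MYBPC3_A74T"
R818W = "MYBPC3_R818W"
TNNT2 = "TNNT2_c95-108"
ALMS1 = "ALMS1_G2462R"
E1883K = "MYH7_E1883K"

VARIANT_IDS = (A31P, A74T, R818W, TNNT2, ALMS1, E1883K)


def variant_catalogue() -> list[VariantDef]:
    return [
        VariantDef(A31P, "MYBPC3", "c.91G>C", "A31P", "Maine Coon"),
        VariantDef(A74T, "MYBPC3", "c.220G>A", "A74T", "Maine Coon"),
        VariantDef(R818W, "MYBPC3", "c.2453C>T", "R818W", "Ragdoll"),
        VariantDef(TNNT2, "TNNT2", "c.95-108G>A", "", "Maine Coon"),
        VariantDef(ALMS1, "ALMS1", "c.7384G>C", "G2462R", "Sphynx"),
        VariantDef(E1883K, "MYH7", "c.5647G>A", "E1883K", "Domestic Shorthair"),
    ]


# (breed, variant) -> (n Wt/Wt, n Wt/Vt, n Vt/Vt)
_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("British Short- and Longhair", A31P): (878, 0, 0),
    ("British Short- and Longhair", A74T): (14, 20, 11),
    ("British Short- and Longhair", R818W): (878, 0, 0),
    ("British Short- and Longhair", TNNT2): (42, 3, 0),
    ("British Short- and Longhair", ALMS1): (44, 1, 0),
    ("British Short- and Longhair", E1883K): (44, 0, 0),
    ("Ragdoll", A31P): (2978, 1, 0),
    ("Ragdoll", A74T): (13, 6, 1),
    ("Ragdoll", R818W): (4533, 212, 9),
    ("Ragdoll", TNNT2): (14, 6, 0),
    ("Ragdoll", ALMS1): (19, 1, 0),
    ("Ragdoll", E1883K): (20, 0, 0),
    ("Sphynx", A31P): (1159, 0, 0),
    ("Sphynx", A74T): (9, 72, 25),
    ("Sphynx", R818W): (1159, 0, 0),
    ("Sphynx", TNNT2): (99, 8, 0),
    ("Sphynx", ALMS1): (24, 55, 28),
    ("Sphynx", E1883K): (104, 0, 0),
    ("Maine Coon", A31P): (12508, 1444, 75),
    ("Maine Coon", A74T): (59, 29, 7),
    ("Maine Coon", R818W): (5181, 0, 0),
    ("Maine Coon", TNNT2): (51, 39, 7),
    ("Maine Coon", ALMS1): (96, 0, 1),
    ("Maine Coon", E1883K): (77, 0, 0),
    ("Devon Rex", A31P): (956, 0, 0),
    ("Devon Rex", A74T): (7, 22, 3),
    ("Devon Rex", R818W): (956, 0, 0),
    ("Devon Rex", TNNT2): (30, 3, 0),
    ("Devon Rex", ALMS1): (15, 14, 4),
    ("Devon Rex", E1883K): (33, 0, 0),
}


def breed_genotype_counts() -> CountsTable:
    """All-sample genotype counts per breed and variant (phase-one data)."""
    table = CountsTable()
    for (breed, vid), triple in _COUNTS.items():
        table.add(breed, vid, GenotypeCounts(*triple))
    return table


# variant -> (breed, case triple, control triple), post-filter
_CASE_CONTROL: dict[str, tuple[str, tuple[int, int, int], tuple[int, int, int]]] = {
    A31P: ("Maine Coon", (8, 3, 9), (10, 6, 1)),
    A74T: ("Maine Coon", (8, 5, 1), (10, 3, 0)),
    TNNT2: ("Maine Coon", (8, 4, 2), (10, 3, 1)),
    R818W: ("Ragdoll", (4, 0, 5), (7, 0, 0)),
    ALMS1: ("Sphynx", (12, 25, 16), (6, 17, 8)),
}


def case_control_counts() -> dict[str, tuple[str, GenotypeCounts, GenotypeCounts]]:
    """Filtered case/control genotype triples for the five variants that
    segregate in their breed of origin (the sixth was never observed, so no
    association could be computed)."""
    return {
        vid: (breed, GenotypeCounts(*case), GenotypeCounts(*control))
        for vid, (breed, case, control) in _CASE_CONTROL.items()
    }


def evidence_sets() -> dict[str, EvidenceSet]:
    """Curated non-frequency evidence (fulfilled criteria only): functional
    studies, computational consensus, cross-species precedent, gene-level
    missense burden, and the case-control criterion where a significant OR
    above the threshold was found."""
    fulfilled = {
        A31P: ["PS4", "PS3", "PP2"],
        A74T: ["PP2"],
        R818W: ["PS4", "PP3", "PS1", "PM5", "PP2"],
        TNNT2: [],
        ALMS1: ["PP3"],
        E1883K: ["PP3", "PS3", "PP2"],
    }
    return {
        vid: EvidenceSet(vid, [Criterion(code) for code in codes])
        for vid, codes in fulfilled.items()
    }


def tv_thresholds() -> dict[str, float]:
    """Alternative (prevalence-aware) allele-frequency thresholds, as
    proportions."""
    return {
        A31P: 0.17,
        A74T: 0.40,
        R818W: 0.11,
        TNNT2: 0.27,
        ALMS1: 0.15,
        E1883K: 0.02,
    }


def classification_breed() -> dict[str, str | None]:
    """Breed whose allele frequency enters the frequency criteria for each
    variant (None: absent from every breed studied, frequency taken as 0)."""
    return {
        A31P: "Maine Coon",
        A74T: "Maine Coon",
        R818W: "Ragdoll",
        TNNT2: "Maine Coon",
        ALMS1: "Sphynx",
        E1883K: None,
    }


def default_config() -> AnalysisConfig:
    return AnalysisConfig(tv_by_variant=tv_thresholds())


def reference_inputs() -> tuple[CountsTable, dict[str, EvidenceSet], AnalysisConfig]:
    """The packaged worked-example inputs: genotype counts, evidence sheets,
    and a config carrying the per-variant Tv thresholds."""
    return breed_genotype_counts(), evidence_sets(), default_config()
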