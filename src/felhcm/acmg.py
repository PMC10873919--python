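"""ACMG-style evidence combination and allele-frequency criteria.

Implements the standard combining rules over the coded evidence vocabulary
(PVS/PS/PM/PP pathogenic, BA/BS/BP benign), the fixed 5% allele-frequency
criteria (BA1/PM2), and the alternative prevalence-aware threshold Tv with
its starred counterparts (PM2*/BS1*/BA1*). Classification runs in two
stages: first from the non-frequency evidence alone, then with either
frequency-criterion family added, so the impact of the frequency rules can
be isolated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

from .datatypes import AnalysisConfig

__all__ = [
    "Strength",
    "Direction",
    "Category",
    "Stage",
    "Criterion",
    "EvidenceSet",
    "Classification",
    "TvSpec",
    "VALID_CODES",
    "FREQUENCY_CODES",
    "combine",
    "af_criterion_acmg",
    "af_criterion_tv",
    "tv_from_parameters",
    "classify_two_stage",
]


class Strength(str, enum.Enum):
    STAND_ALONE = "STAND_ALONE"
    VERY_STRONG = "VERY_STRONG"
    STRONG = "STRONG"
    MODERATE = "MODERATE"
    SUPPORTING = "SUPPORTING"


class Direction(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    BENIGN = "BENIGN"


class Category(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    VUS = "VUS"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN = "BENIGN"


class Stage(str, enum.Enum):
    INITIAL = "INITIAL"
    ACMG_AF = "ACMG_AF"
    TV_AF = "TV_AF"


_PREFIX_DEFAULTS: dict[str, tuple[Direction, Strength]] = {
    "PVS": (Direction.PATHOGENIC, Strength.VERY_STRONG),
    "PS": (Direction.PATHOGENIC, Strength.STRONG),
    "PM": (Direction.PATHOGENIC, Strength.MODERATE),
    "PP": (Direction.PATHOGENIC, Strength.SUPPORTING),
    "BA": (Direction.BENIGN, Strength.STAND_ALONE),
    "BS": (Direction.BENIGN, Strength.STRONG),
    "BP": (Direction.BENIGN, Strength.SUPPORTING),
}

VALID_CODES: frozenset[str] = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
    + ["PM2*", "BS1*", "BA1*"]  # starred = Tv-based frequency criteria
)

#: Frequency-family codes, unstarred (fixed-cutoff) vs starred (Tv-based).
FREQUENCY_CODES: dict[str, frozenset[str]] = {
    "acmg": frozenset({"PM2", "BA1", "BS1"}),
    "tv": frozenset({"PM2*", "BA1*", "BS1*"}),
}


def _defaults_for(code: str) -> tuple[Direction, Strength]:
    base = code.rstrip("*")
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if base.startswith(prefix):
            return _PREFIX_DEFAULTS[prefix]
    raise ValueError(f"unknown criterion code {code!r}; valid: {sorted(VALID_CODES)}")


@dataclass(frozen=True)
class Criterion:
    """One evidence item. Strength defaults from the code prefix but may be
    overridden per instance (e.g. a case-count criterion downgraded to
    supporting weight); starred codes carry the same weight as their
    unstarred counterparts."""

    code: str
    direction: Direction = None  # type: ignore[assignment]
    strength: Strength = None  # type: ignore[assignment]
    note: str = ""

    def __post_init__(self) -> None:
        if self.code not in VALID_CODES:
            raise ValueError(
                f"unknown criterion code {self.code!r}; valid codes: "
                f"{', '.join(sorted(VALID_CODES))}"
            )
        d, s = _defaults_for(self.code)
        if self.direction is None:
            object.__setattr__(self, "direction", d)
        else:
            object.__setattr__(self, "direction", Direction(self.direction))
        if self.strength is None:
            object.__setattr__(self, "strength", s)
        else:
            object.__setattr__(self, "strength", Strength(self.strength))

    def with_strength(self, strength: Strength) -> "Criterion":
        return replace(self, strength=Strength(strength))


@dataclass
class EvidenceSet:
    """The fulfilled criteria for one variant.

    At most one frequency-family criterion may be active, and the fixed-cutoff
    and Tv-based families are mutually exclusive (they are alternative
    operationalizations of the same evidence)."""

    variant_id: str
    fulfilled: list[Criterion] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [c.code for c in self.fulfilled]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate criterion codes in evidence: {codes}")
        acmg_freq = set(codes) & FREQUENCY_CODES["acmg"]
        tv_freq = set(codes) & FREQUENCY_CODES["tv"]
        if acmg_freq and tv_freq:
            raise ValueError(
                "fixed-cutoff and Tv-based frequency criteria are mutually "
                f"exclusive; got {sorted(acmg_freq)} and {sorted(tv_freq)}"
            )
        if len(acmg_freq) > 1 or len(tv_freq) > 1:
            raise ValueError("at most one frequency criterion may be active")

    @property
    def codes(self) -> set[str]:
        return {c.code for c in self.fulfilled}

    def adding(self, criterion: Criterion | None) -> "EvidenceSet":
        extra = [] if criterion is None else [criterion]
        return EvidenceSet(self.variant_id, list(self.fulfilled) + extra)

    def has_frequency_criterion(self) -> bool:
        return bool(
            self.codes & (FREQUENCY_CODES["acmg"] | FREQUENCY_CODES["tv"])
        )


@dataclass(frozen=True)
class Classification:
    category: Category
    fired_rule: str
    stage: Stage


def _strength_counts(crits: Iterable[Criterion], direction: Direction) -> dict[Strength, int]:
    out = {s: 0 for s in Strength}
    for c in crits:
        if c.direction is direction:
            out[c.strength] += 1
    return out


def combine(e: EvidenceSet, stage: Stage = Stage.INITIAL) -> Classification:
    """Apply the standard combining rules to a validated evidence set.

    Pathogenic:
        (very strong AND (>=1 strong, or >=2 moderate, or 1 moderate + 1
        supporting, or >=2 supporting)) OR (>=2 strong) OR (1 strong AND
        (>=3 moderate, or 2 moderate + >=2 supporting, or 1 moderate + >=4
        supporting)).
    Likely pathogenic:
        (very strong + 1 moderate) OR (1 strong + 1-2 moderate) OR (1 strong
        + >=2 supporting) OR (>=3 moderate) OR (2 moderate + >=2 supporting)
        OR (1 moderate + >=4 supporting).
    Benign:
        stand-alone (BA1 family) OR >=2 benign strong.
    Likely benign:
        (1 benign strong + 1 benign supporting) OR >=2 benign supporting.

    A stand-alone benign criterion is literal: it classifies benign even in
    the face of pathogenic evidence (this is exactly how the fixed >5%
    frequency rule behaves when applied mechanically). Any other simultaneous
    pathogenic-side and benign-side rule firing is a conflict and yields a
    variant of unknown significance.
    """
    p = _strength_counts(e.fulfilled, Direction.PATHOGENIC)
    b = _strength_counts(e.fulfilled, Direction.BENIGN)

    pvs = p[Strength.VERY_STRONG]
    ps, pm, pp = p[Strength.STRONG], p[Strength.MODERATE], p[Strength.SUPPORTING]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )

    ba = b[Strength.STAND_ALONE]
    bs, bp = b[Strength.STRONG], b[Strength.SUPPORTING]
    benign_strong_pair = bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    if ba >= 1:
        return Classification(Category.BENIGN, "stand-alone benign", stage)

    path_side = pathogenic or likely_pathogenic
    benign_side = benign_strong_pair or likely_benign
    if path_side and benign_side:
        return Classification(Category.VUS, "conflicting evidence", stage)
    if pathogenic:
        return Classification(Category.PATHOGENIC, "pathogenic rule", stage)
    if likely_pathogenic:
        return Classification(Category.LIKELY_PATHOGENIC, "likely pathogenic rule", stage)
    if benign_strong_pair:
        return Classification(Category.BENIGN, ">=2 benign strong", stage)
    if likely_benign:
        return Classification(Category.LIKELY_BENIGN, "likely benign rule", stage)
    return Classification(Category.VUS, "insufficient evidence", stage)


def af_criterion_acmg(af: float, cfg: AnalysisConfig) -> Criterion | None:
    """Fixed-cutoff frequency criterion: above the cutoff (default 5%) the
    allele is too common for a rare pathogenic variant (BA1, stand-alone
    benign); below it, rarity supports pathogenicity (PM2). Exactly at the
    cutoff neither strict inequality holds and no criterion fires."""
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allele frequency must lie in [0, 1], got {af}")
    if af > cfg.acmg_ba1_cutoff:
        return Criterion("BA1")
    if af < cfg.acmg_ba1_cutoff:
        return Criterion("PM2")
    return None


@dataclass(frozen=True)
class TvSpec:
    """Alternative allele-frequency threshold: either a literal proportion or
    the parameters of the maximum-credible-allele-frequency calculation
    (disease prevalence, the largest share of disease attributable to one
    allele, and penetrance, under a dominant or recessive architecture)."""

    tv: float | None = None
    prevalence: float | None = None
    max_allelic_contribution: float | None = None
    penetrance: float | None = None
    inheritance: str | None = None  # DOMINANT or RECESSIVE

    def __post_init__(self) -> None:
        if self.tv is not None and not (0.0 < self.tv <= 1.0):
            raise ValueError(f"tv must lie in (0, 1], got {self.tv}")

    def resolve(self) -> float:
        if self.tv is not None:
            return self.tv
        return tv_from_parameters(self)


def tv_from_parameters(p: TvSpec) -> float:
    """Maximum credible population allele frequency.

    Under Hardy-Weinberg, a fully penetrant recessive allele at frequency q
    explains a disease of prevalence q^2; allowing for partial penetrance f
    and for the allele accounting for at most a share c of all disease,
    q_max = sqrt(prevalence * c / f). For a dominant architecture carriers
    (frequency ~2q) are at risk, giving q_max = prevalence * c / (2 f).
    Clipped to 1."""
    for name in ("prevalence", "max_allelic_contribution", "penetrance"):
        v = getattr(p, name)
        if v is None or not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    if p.inheritance not in ("DOMINANT", "RECESSIVE"):
        raise ValueError("inheritance must be DOMINANT or RECESSIVE")
    if p.inheritance == "DOMINANT":
        tv = p.prevalence * p.max_allelic_contribution / (2.0 * p.penetrance)
    else:
        tv = math.sqrt(p.prevalence * p.max_allelic_contribution / p.penetrance)
    return min(tv, 1.0)


def af_criterion_tv(af: float, tv: TvSpec | float) -> Criterion:
    """Tv-based frequency criterion: at or below the threshold the observed
    frequency is consistent with the disease characteristics (PM2*, moderate
    pathogenic); above it, inconsistent (BS1*, strong benign). BA1* exists in
    the vocabulary for manual curation but is never auto-assigned."""
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allele frequency must lie in [0, 1], got {af}")
    threshold = tv.resolve() if isinstance(tv, TvSpec) else float(tv)
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"Tv must lie in (0, 1], got {threshold}")
    return Criterion("PM2*") if af <= threshold else Criterion("BS1*")


def classify_two_stage(
    base: EvidenceSet,
    af: float,
    tv: TvSpec | float,
    cfg: AnalysisConfig,
) -> dict[Stage, Classification]:
    """Classify three ways: from the non-frequency evidence alone, with the
    fixed-cutoff criterion added, and with the Tv criterion added."""
    if base.has_frequency_criterion():
        raise ValueError(
            "base evidence must not contain frequency criteria; they are "
            "added per stage"
        )
    return {
        Stage.INITIAL: combine(base, Stage.INITIAL),
        Stage.ACMG_AF: combine(base.adding(af_criterion_acmg(af, cfg)), Stage.ACMG_AF),
        Stage.TV_AF: combine(base.adding(af_criterion_tv(af, tv)), Stage.TV_AF),
    }
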