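"""Case-control association statistics for a biallelic variant.

Allele frequencies, collapse of genotype triples to 2x2 tables under three
codings (allelic: variant alleles vs wild alleles; dominant: carriers vs
non-carriers; recessive: homozygous variant vs the rest), unconditional
maximum-likelihood odds ratios with Wald confidence intervals on the log
scale, and the Haldane-Anscombe continuity correction (add 0.5 to every cell
of a table containing a zero so the OR and its log-scale standard error stay
finite).

The module also exposes a small model/results pair in the statsmodels
idiom: build :class:`CaseControlAssociation` from count triples (or from a
filtered cohort), call :meth:`~CaseControlAssociation.fit`, and read the
estimates off the returned :class:`AssociationResults`, including a
``summary()`` table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .datatypes import AnalysisConfig, CohortTable, GenotypeCounts

__all__ = [
    "InheritanceModel",
    "TwoByTwo",
    "OREstimate",
    "allele_frequency",
    "collapse",
    "odds_ratio",
    "evaluate_association",
    "stern_style_or",
    "ps4_check",
    "CaseControlAssociation",
    "AssociationResults",
    "format_or",
    "format_ci",
]


class InheritanceModel(str, enum.Enum):
    ALLELIC = "ALLELIC"
    DOMINANT = "DOMINANT"
    RECESSIVE = "RECESSIVE"


@dataclass(frozen=True)
class TwoByTwo:
    """Collapsed 2x2 table: a = case exposed, b = case unexposed,
    c = control exposed, d = control unexposed."""

    a: float
    b: float
    c: float
    d: float
    model: InheritanceModel
    corrected: bool = False

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class OREstimate:
    """Odds-ratio point estimate with Wald CI.

    ``significant`` is CI-based: true iff 1.0 lies outside
    [ci_low, ci_high]. ``corrected`` records whether the continuity
    correction was applied to the underlying table."""

    or_point: float
    ci_low: float
    ci_high: float
    model: InheritanceModel
    significant: bool
    corrected: bool
    log_se: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def allele_frequency(g: GenotypeCounts) -> float:
    """Variant allele frequency q = (het + 2*hom) / (2*total)."""
    if g.total == 0:
        raise ValueError("cannot compute an allele frequency from zero animals")
    return g.n_variant_alleles / (2.0 * g.total)


def collapse(
    case: GenotypeCounts, control: GenotypeCounts, model: InheritanceModel
) -> TwoByTwo:
    """Collapse case/control genotype triples to a 2x2 under the given
    inheritance coding. The allelic coding counts alleles (two per animal);
    the genotypic codings count animals."""
    model = InheritanceModel(model)
    if model is InheritanceModel.ALLELIC:
        a, b = case.n_variant_alleles, case.n_wild_alleles
        c, d = control.n_variant_alleles, control.n_wild_alleles
    elif model is InheritanceModel.DOMINANT:
        a, b = case.n_wtvt + case.n_vtvt, case.n_wtwt
        c, d = control.n_wtvt + control.n_vtvt, control.n_wtwt
    else:  # RECESSIVE
        a, b = case.n_vtvt, case.n_wtwt + case.n_wtvt
        c, d = control.n_vtvt, control.n_wtwt + control.n_wtvt
    return TwoByTwo(float(a), float(b), float(c), float(d), model)


def _apply_haldane(t: TwoByTwo, policy: str) -> TwoByTwo:
    cells = t.cells()
    if policy == "always" or (policy == "auto" and any(x == 0 for x in cells)):
        return TwoByTwo(*(x + 0.5 for x in cells), model=t.model, corrected=True)
    return t


def odds_ratio(t: TwoByTwo, cfg: AnalysisConfig | None = None) -> OREstimate:
    """Sample (unconditional ML) odds ratio with a Wald CI on the log scale.

    Under the 'auto' policy the Haldane-Anscombe correction (+0.5 to all four
    cells) is applied iff any cell is zero. After any correction every cell
    must be positive: a table with an entire zero margin under policy
    'never' is rejected rather than reported as 0 or infinity.
    """
    cfg = cfg or AnalysisConfig()
    t = _apply_haldane(t, cfg.haldane_policy)
    a, b, c, d = t.cells()
    if min(a, b, c, d) <= 0:
        raise ValueError(
            f"zero cell in 2x2 table {t.cells()} with haldane_policy="
            f"{cfg.haldane_policy!r}; OR undefined"
        )
    point = (a * d) / (b * c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    # the conventional two-sided critical value at the 95% level; exact
    # normal quantile for any other level
    z = 1.96 if abs(cfg.ci_level - 0.95) < 1e-12 else norm.ppf(0.5 + cfg.ci_level / 2.0)
    log_or = math.log(point)
    ci_low = math.exp(log_or - z * log_se)
    ci_high = math.exp(log_or + z * log_se)
    significant = not (ci_low <= 1.0 <= ci_high)
    return OREstimate(point, ci_low, ci_high, t.model, significant, t.corrected, log_se)


#: Deterministic reporting order: allelic, recessive, dominant.
MODEL_ORDER = (
    InheritanceModel.ALLELIC,
    InheritanceModel.RECESSIVE,
    InheritanceModel.DOMINANT,
)


def evaluate_association(
    case: GenotypeCounts, control: GenotypeCounts, cfg: AnalysisConfig | None = None
) -> list[OREstimate]:
    """One OR estimate per inheritance coding, in (allelic, recessive,
    dominant) order."""
    cfg = cfg or AnalysisConfig()
    return [odds_ratio(collapse(case, control, m), cfg) for m in MODEL_ORDER]


def stern_style_or(
    case: GenotypeCounts, control: GenotypeCounts, cfg: AnalysisConfig | None = None
) -> OREstimate:
    """Homozygote-contrast OR: homozygous variant vs homozygous wild type,
    heterozygotes dropped from both arms (the contrast used by some earlier
    cardiomyopathy association studies)."""
    t = TwoByTwo(
        float(case.n_vtvt),
        float(case.n_wtwt),
        float(control.n_vtvt),
        float(control.n_wtwt),
        InheritanceModel.RECESSIVE,
    )
    return odds_ratio(t, cfg)


def ps4_check(
    estimates: list[OREstimate], cfg: AnalysisConfig | None = None
) -> tuple[bool, InheritanceModel | None]:
    """Case-control criterion: fulfilled iff any coding shows a significant
    OR above the configured threshold; the witness is the first qualifying
    coding in reporting order."""
    if not estimates:
        raise ValueError("need at least one OR estimate")
    cfg = cfg or AnalysisConfig()
    for est in estimates:
        if est.significant and est.or_point > cfg.ps4_or_threshold:
            return True, est.model
    return False, None


def format_or(value: float, decimals: int = 2) -> str:
    """Render an OR or CI bound: configured decimals, trailing zeros trimmed
    to at most the printed precision; very large bounds (>= 500) rendered as
    integers."""
    if value >= 500:
        return str(int(round(value)))
    s = round(value, decimals)
    # trim a trailing zero only when the value is exact at fewer decimals
    text = f"{s:.{decimals}f}"
    if text.endswith("0") and float(text[:-1]) == s:
        stripped = text.rstrip("0").rstrip(".")
        return stripped
    return text


def format_ci(ci_low: float, ci_high: float, decimals: int = 2) -> str:
    return f"[{format_or(ci_low, decimals)}–{format_or(ci_high, decimals)}]"


class CaseControlAssociation:
    """Model object for a single-variant case-control association.

    Parameters
    ----------
    case, control
        Genotype-count triples for affected and healthy animals.
    cfg
        Analysis configuration (CI level, continuity-correction policy,
        OR threshold for the case-control criterion).

    Use :meth:`from_cohort` to build the model from a filtered per-animal
    cohort instead of pre-tabulated counts.
    """

    def __init__(
        self,
        case: GenotypeCounts,
        control: GenotypeCounts,
        cfg: AnalysisConfig | None = None,
    ) -> None:
        self.case = case
        self.control = control
        self.cfg = cfg or AnalysisConfig()

    @classmethod
    def from_cohort(
        cls, cohort: CohortTable, target: str, cfg: AnalysisConfig | None = None
    ) -> "CaseControlAssociation":
        from .filters import to_case_control

        case, control = to_case_control(cohort, target)
        return cls(case, control, cfg)

    def fit(self) -> "AssociationResults":
        estimates = evaluate_association(self.case, self.control, self.cfg)
        hom = None
        try:
            hom = stern_style_or(self.case, self.control, self.cfg)
        except ValueError:
            pass  # undefined homozygote contrast under policy 'never'
        fulfilled, witness = ps4_check(estimates, self.cfg)
        return AssociationResults(self, estimates, hom, fulfilled, witness)


class AssociationResults:
    """Fitted association results: one OR per inheritance coding plus the
    homozygote contrast, with CI-based significance flags."""

    def __init__(
        self,
        model: CaseControlAssociation,
        estimates: list[OREstimate],
        homozygote_contrast: OREstimate | None,
        ps4_fulfilled: bool,
        ps4_witness: InheritanceModel | None,
    ) -> None:
        self.model = model
        self.estimates = estimates
        self.homozygote_contrast = homozygote_contrast
        self.ps4_fulfilled = ps4_fulfilled
        self.ps4_witness = ps4_witness

    @property
    def n(self) -> int:
        return self.model.case.total + self.model.control.total

    def by_model(self, model: InheritanceModel) -> OREstimate:
        model = InheritanceModel(model)
        for est in self.estimates:
            if est.model is model:
                return est
        raise KeyError(model)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates:
            rows.append(
                {
                    "model": est.model.value,
                    "or": est.or_point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "log_se": est.log_se,
                    "corrected": est.corrected,
                    "significant": est.significant,
                }
            )
        return pd.DataFrame(rows)

    def summary(self, decimals: int | None = None) -> str:
        decimals = self.model.cfg.rounding if decimals is None else decimals
        case, control = self.model.case, self.model.control
        lines = [
            "Case-control association (single variant)",
            f"  n = {self.n} animals "
            f"(case {case.total}: {case.as_tuple()}, "
            f"control {control.total}: {control.as_tuple()})",
            f"  CI level = {self.model.cfg.ci_level:g}, "
            f"continuity correction = {self.model.cfg.haldane_policy}",
            "",
            f"  {'model':<10} {'OR':>8}  {'CI':<18} {'corrected':>9} {'significant':>11}",
        ]
        for est in self.estimates:
            lines.append(
                f"  {est.model.value:<10} {format_or(est.or_point, decimals):>8}  "
                f"{format_ci(est.ci_low, est.ci_high, decimals):<18} "
                f"{str(est.corrected):>9} {str(est.significant):>11}"
            )
        if self.homozygote_contrast is not None:
            hc = self.homozygote_contrast
            lines.append(
                f"  {'VtVt/WtWt':<10} {format_or(hc.or_point, decimals):>8}  "
                f"{format_ci(hc.ci_low, hc.ci_high, decimals):<18} "
                f"{str(hc.corrected):>9} {str(hc.significant):>11}"
            )
        witness = self.ps4_witness.value if self.ps4_witness else "-"
        lines.append("")
        lines.append(
            f"  case-control criterion (significant OR > "
            f"{self.model.cfg.ps4_or_threshold:g}): "
            f"{'fulfilled via ' + witness if self.ps4_fulfilled else 'not fulfilled'}"
        )
        return "\n".join(lines)
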