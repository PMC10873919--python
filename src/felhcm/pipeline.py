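"""End-to-end orchestration: allele frequencies -> associations -> two-stage
classification, with rendered report tables.

Phase one pools genotype counts (cohort-derived counts are merged with any
pre-tabulated count tables by breed and variant, summing duplicates). Phase
two runs the filter chain per (breed, variant) on the phenotyped cohort and
estimates odds ratios under the three inheritance codings. The in-silico
phase arrives as curated evidence flags. The final phase classifies each
variant three ways: from the non-frequency evidence, with the fixed-cutoff
frequency criterion added, and with the alternative Tv criterion added.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .acmg import (
    EvidenceSet,
    Stage,
    TvSpec,
    af_criterion_acmg,
    af_criterion_tv,
    classify_two_stage,
)
from .association import CaseControlAssociation, allele_frequency, format_or
from .datatypes import (
    AnalysisConfig,
    CohortTable,
    CountsTable,
    GenotypeCounts,
    VariantDef,
    normalize_breed,
)
from .filters import apply_genotype_exclusion, apply_phenotype_filters

logger = logging.getLogger("felhcm")

__all__ = ["PipelineResult", "run_pipeline", "render", "cohort_to_counts"]


def cohort_to_counts(cohort: CohortTable) -> CountsTable:
    """Tabulate per-(breed, variant) genotype counts from a cohort; animals
    with a missing dosage at a variant are omitted for that variant only."""
    table = CountsTable()
    tallies: dict[tuple[str, str], list[int]] = {}
    for r in cohort:
        for vid, d in r.dosages.items():
            if d not in (0, 1, 2):
                continue
            key = (normalize_breed(r.breed), vid)
            tallies.setdefault(key, [0, 0, 0])[d] += 1
    for (breed, vid), t in tallies.items():
        table.add(breed, vid, GenotypeCounts(*t))
    return table


@dataclass
class PipelineResult:
    """Full pipeline output: the three report tables plus audit trail."""

    af_table: pd.DataFrame
    assoc_table: pd.DataFrame
    classification_table: pd.DataFrame
    filter_traces: dict[str, dict] = field(default_factory=dict)
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    version: str = __version__


def _association_phase(
    cohort: CohortTable | None,
    variants: list[VariantDef],
    cfg: AnalysisConfig,
) -> tuple[pd.DataFrame, dict[str, dict], dict[str, bool]]:
    rows: list[dict] = []
    traces: dict[str, dict] = {}
    computed_ps4: dict[str, bool] = {}
    if cohort is None:
        return pd.DataFrame(rows), traces, computed_ps4
    by_breed = {v.variant_id: v.origin_breed for v in variants}
    all_ids = [v.variant_id for v in variants]
    for v in variants:
        breed = by_breed[v.variant_id]
        sub = cohort.subset_breed(breed) if breed else cohort
        if not len(sub):
            logger.debug("no animals of breed %r; skipping %s", breed, v.variant_id)
            continue
        others = [
            vid
            for vid in all_ids
            if vid != v.variant_id and vid in sub.variant_ids
        ]
        filtered, trace_p = apply_phenotype_filters(sub, cfg)
        filtered, trace_g = apply_genotype_exclusion(filtered, v.variant_id, others)
        trace = {
            "n_input": trace_p.n_input,
            "n_after_phenotype": trace_p.n_after_phenotype,
            "n_after_age": trace_p.n_after_age,
            "n_after_genotype": trace_g.n_after_genotype,
            "excluded": trace_p.to_dict()["excluded"] + trace_g.to_dict()["excluded"],
        }
        traces[v.variant_id] = trace
        model = CaseControlAssociation.from_cohort(filtered, v.variant_id, cfg)
        if model.case.total == 0 or model.control.total == 0:
            logger.debug("empty arm for %s after filtering; skipping", v.variant_id)
            continue
        if model.case.n_variant_alleles + model.control.n_variant_alleles == 0:
            logger.debug("variant %s absent after filtering; no OR", v.variant_id)
            continue
        res = model.fit()
        computed_ps4[v.variant_id] = res.ps4_fulfilled
        for est in res.estimates:
            rows.append(
                {
                    "breed": breed,
                    "variant_id": v.variant_id,
                    "n": res.n,
                    "case_wtwt": model.case.n_wtwt,
                    "case_wtvt": model.case.n_wtvt,
                    "case_vtvt": model.case.n_vtvt,
                    "control_wtwt": model.control.n_wtwt,
                    "control_wtvt": model.control.n_wtvt,
                    "control_vtvt": model.control.n_vtvt,
                    "model": est.model.value,
                    "or": est.or_point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "corrected": est.corrected,
                    "significant": est.significant,
                }
            )
    return pd.DataFrame(rows), traces, computed_ps4


def run_pipeline(
    cohort: CohortTable | None = None,
    counts: CountsTable | None = None,
    variants: list[VariantDef] | None = None,
    evidence: dict[str, EvidenceSet] | None = None,
    cfg: AnalysisConfig | None = None,
    classification_af: dict[str, float] | None = None,
) -> PipelineResult:
    """Run the full pipeline.

    At least one of ``cohort`` / ``counts`` must be given. ``variants``
    defaults to ids discovered in the inputs. ``classification_af`` maps a
    variant to the allele frequency used by the frequency criteria; by
    default the highest per-breed frequency among breeds where the variant
    was observed (0 if never observed) is used.
    """
    if cohort is None and counts is None:
        raise ValueError("need a cohort and/or a counts table")
    cfg = cfg or AnalysisConfig()
    evidence = evidence or {}

    pooled = CountsTable()
    if counts is not None:
        for (breed, vid), g in counts.items():
            pooled.add(breed, vid, g)
    if cohort is not None:
        for (breed, vid), g in cohort_to_counts(cohort).items():
            pooled.add(breed, vid, g)

    if variants is None:
        ids = sorted({vid for (_, vid) in pooled.entries})
        variants = [VariantDef(vid, gene=vid.split("_")[0]) for vid in ids]

    # phase one: breed-stratified allele frequencies
    af_rows = []
    for (breed, vid), g in sorted(pooled.items()):
        af_rows.append(
            {
                "breed": breed,
                "variant_id": vid,
                "total": g.total,
                "n_wtwt": g.n_wtwt,
                "n_wtvt": g.n_wtvt,
                "n_vtvt": g.n_vtvt,
                "q": allele_frequency(g) if g.total else float("nan"),
            }
        )
    af_table = pd.DataFrame(af_rows)

    # phase two: associations on the phenotyped cohort
    assoc_table, traces, computed_ps4 = _association_phase(cohort, variants, cfg)

    # phase four: two-stage classification
    cls_rows = []
    for v in variants:
        vid = v.variant_id
        if vid not in evidence:
            logger.info("no evidence sheet for %s; classification skipped", vid)
            continue
        base = evidence[vid]
        if vid in computed_ps4:
            sheet_ps4 = "PS4" in base.codes
            if sheet_ps4 != computed_ps4[vid]:
                logger.warning(
                    "evidence sheet PS4=%s conflicts with computed PS4=%s for "
                    "%s; evidence sheet wins (curator override)",
                    sheet_ps4,
                    computed_ps4[vid],
                    vid,
                )
        if classification_af and vid in classification_af:
            af = classification_af[vid]
        else:
            # frequency in the breed of origin when tabulated there; else the
            # highest frequency among breeds where the variant was observed
            origin = pooled.get(v.origin_breed, vid) if v.origin_breed else None
            if origin is not None and origin.total > 0:
                af = allele_frequency(origin)
            else:
                per_breed = [
                    allele_frequency(g)
                    for (_, v2), g in pooled.items()
                    if v2 == vid and g.total > 0 and g.n_variant_alleles > 0
                ]
                af = max(per_breed, default=0.0)
        tv = cfg.tv_by_variant.get(vid)
        if tv is None:
            logger.info("no Tv for %s; Tv stage skipped", vid)
            stages = {
                Stage.INITIAL: classify_two_stage(base, af, TvSpec(tv=1.0), cfg)[
                    Stage.INITIAL
                ]
            }
        else:
            stages = classify_two_stage(base, af, TvSpec(tv=tv), cfg)
        acmg_crit = af_criterion_acmg(af, cfg)
        tv_crit = af_criterion_tv(af, TvSpec(tv=tv)) if tv is not None else None
        row = {
            "variant_id": vid,
            "base_criteria": "+".join(sorted(base.codes)),
            "af": af,
            "acmg_af_criterion": acmg_crit.code if acmg_crit else "",
            "tv": tv if tv is not None else float("nan"),
            "tv_criterion": tv_crit.code if tv_crit else "",
            "initial": stages[Stage.INITIAL].category.value,
            "initial_rule": stages[Stage.INITIAL].fired_rule,
        }
        if Stage.ACMG_AF in stages:
            row["acmg_af"] = stages[Stage.ACMG_AF].category.value
            row["acmg_af_rule"] = stages[Stage.ACMG_AF].fired_rule
            row["tv_af"] = stages[Stage.TV_AF].category.value
            row["tv_af_rule"] = stages[Stage.TV_AF].fired_rule
        cls_rows.append(row)
    classification_table = pd.DataFrame(cls_rows)

    return PipelineResult(af_table, assoc_table, classification_table, traces, cfg)


def render(result: PipelineResult, out_dir: str | Path, fmt: str = "tsv") -> list[Path]:
    """Write the three report tables plus filter traces. TSV applies the
    configured rounding (allele frequencies as percent, two decimals by
    default; CI bounds >= 500 as integers); JSON keeps full precision."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dec = result.config.rounding
    written: list[Path] = []

    def _emit(df: pd.DataFrame, name: str) -> None:
        if fmt in ("tsv", "markdown"):
            path = out_dir / f"{name}.{ 'md' if fmt == 'markdown' else 'tsv'}"
            if fmt == "tsv":
                df.to_csv(path, sep="\t", index=False)
            else:
                path.write_text(df.to_markdown(index=False) if len(df) else "")
        else:
            path = out_dir / f"{name}.json"
            path.write_text(df.to_json(orient="records", indent=2))
        written.append(path)

    af = result.af_table.copy()
    if len(af) and fmt != "json":
        af["q_pct"] = af.pop("q").map(lambda q: f"{100 * q:.{dec}f}")
    _emit(af, "af_table")

    assoc = result.assoc_table.copy()
    if len(assoc) and fmt != "json":
        assoc["or"] = assoc["or"].map(lambda x: format_or(x, dec))
        assoc["ci"] = [
            f"{format_or(lo, dec)}–{format_or(hi, dec)}"
            for lo, hi in zip(assoc.pop("ci_low"), assoc.pop("ci_high"))
        ]
    _emit(assoc, "assoc_table")

    cls = result.classification_table.copy()
    if len(cls) and fmt != "json":
        cls["af"] = cls["af"].map(lambda q: f"{100 * q:.{dec}f}")
    _emit(cls, "classification_table")

    traces_path = out_dir / "filter_traces.json"
    traces_path.write_text(json.dumps(result.filter_traces, indent=2) + "\n")
    written.append(traces_path)
    config_path = out_dir / "config_echo.json"
    config_path.write_text(
        json.dumps({"version": result.version, **result.config.model_dump()}, indent=2)
        + "\n"
    )
    written.append(config_path)
    return written
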