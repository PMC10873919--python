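"""Readers and writers for the plain-text exchange formats.

Canonical dialect is TSV with a fixed header:

* ``cohort.tsv``   — animal_id, breed, age_years, phenotype, then one column
  per variant holding the alt-allele dosage (0/1/2, empty or NA = missing).
* ``counts.tsv``   — breed, variant_id, n_wtwt, n_wtvt, n_vtvt.
* ``variants.tsv`` — variant_id, gene, cdna_label, protein_label, origin_breed.
* ``evidence.yaml``/``.json`` — per variant, a list of {code, note, fulfilled}.
* ``config.yaml``  — AnalysisConfig fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .acmg import VALID_CODES, Criterion, EvidenceSet
from .datatypes import (
    MISSING,
    AnalysisConfig,
    CatRecord,
    CohortTable,
    CountsTable,
    GenotypeCounts,
    Phenotype,
    VariantDef,
)

COHORT_FIXED_COLUMNS = ["animal_id", "breed", "age_years", "phenotype"]
_MISSING_TOKENS = {"", "na", "nan", "none", "missing", "."}


class ParseError(ValueError):
    """Raised for malformed input files; message carries the line number."""


def _is_missing(tok: str) -> bool:
    return tok.strip().lower() in _MISSING_TOKENS


def read_cohort(path: str | Path, fmt: str = "tsv") -> CohortTable:
    """Read a per-animal cohort table. Line numbers in error messages refer
    to the file (header = line 1)."""
    if fmt != "tsv":
        raise ValueError(f"unsupported cohort format {fmt!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_FIXED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")
    variant_cols = [c for c in df.columns if c not in COHORT_FIXED_COLUMNS]

    records: list[CatRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        try:
            pheno_tok = rowd["phenotype"].strip()
            try:
                pheno = Phenotype(pheno_tok)
            except ValueError:
                raise ParseError(
                    f"unknown phenotype {pheno_tok!r}; valid: "
                    f"{[p.value for p in Phenotype]}"
                )
            age_tok = rowd["age_years"]
            age = None if _is_missing(age_tok) else float(age_tok)
            dosages: dict[str, int] = {}
            for vc in variant_cols:
                tok = rowd[vc]
                if _is_missing(tok):
                    dosages[vc] = MISSING
                else:
                    try:
                        d = int(tok)
                    except ValueError:
                        raise ParseError(f"dosage {tok!r} for {vc!r} is not an integer")
                    if d not in (0, 1, 2):
                        raise ParseError(f"dosage {d} for {vc!r} not in {{0,1,2,NA}}")
                    dosages[vc] = d
            records.append(
                CatRecord(rowd["animal_id"].strip(), rowd["breed"].strip(), age, pheno, dosages)
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}:{idx}: {exc}") from exc
    try:
        return CohortTable(records)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    variant_ids = sorted(cohort.variant_ids)
    rows = []
    for r in cohort:
        row: dict[str, Any] = {
            "animal_id": r.animal_id,
            "breed": r.breed,
            "age_years": "" if r.age_years is None else repr(r.age_years),
            "phenotype": r.phenotype.value,
        }
        for vid in variant_ids:
            d = r.dosage(vid)
            row[vid] = "NA" if d == MISSING else str(d)
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_FIXED_COLUMNS + variant_ids).to_csv(
        path, sep="\t", index=False
    )


def read_counts(path: str | Path) -> CountsTable:
    """Read a per-(breed, variant) genotype-count table; duplicate keys are
    pooled by summation."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["breed", "variant_id", "n_wtwt", "n_wtvt", "n_vtvt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    table = CountsTable()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        try:
            counts = GenotypeCounts(
                int(rowd["n_wtwt"]), int(rowd["n_wtvt"]), int(rowd["n_vtvt"])
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{idx}: {exc}") from exc
        table.add(rowd["breed"], rowd["variant_id"], counts)
    return table


def write_counts(table: CountsTable, path: str | Path) -> None:
    rows = [
        {
            "breed": breed,
            "variant_id": vid,
            "n_wtwt": g.n_wtwt,
            "n_wtvt": g.n_wtvt,
            "n_vtvt": g.n_vtvt,
        }
        for (breed, vid), g in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["breed", "variant_id", "n_wtwt", "n_wtvt", "n_vtvt"]).to_csv(
        path, sep="\t", index=False
    )


def read_variants(path: str | Path) -> list[VariantDef]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["variant_id", "gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    out: list[VariantDef] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        vid = rowd["variant_id"].strip()
        if vid in seen:
            raise ParseError(f"{path}:{idx}: duplicate variant_id {vid!r}")
        seen.add(vid)
        out.append(
            VariantDef(
                vid,
                rowd["gene"].strip(),
                rowd.get("cdna_label", "").strip(),
                rowd.get("protein_label", "").strip(),
                rowd.get("origin_breed", "").strip(),
            )
        )
    return out


def write_variants(variants: list[VariantDef], path: str | Path) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "cdna_label": v.cdna_label,
            "protein_label": v.protein_label,
            "origin_breed": v.origin_breed,
        }
        for v in variants
    ]
    pd.DataFrame(
        rows, columns=["variant_id", "gene", "cdna_label", "protein_label", "origin_breed"]
    ).to_csv(path, sep="\t", index=False)


def read_evidence(path: str | Path) -> dict[str, EvidenceSet]:
    """Read a curated evidence sheet (YAML or JSON): per variant, a list of
    ``{code, note, fulfilled}`` items; only fulfilled criteria enter the
    evidence set. Unknown codes are rejected with the valid vocabulary."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping variant_id -> criterion list")
    out: dict[str, EvidenceSet] = {}
    for vid, items in data.items():
        crits: list[Criterion] = []
        for item in items or []:
            code = item.get("code")
            if code not in VALID_CODES:
                raise ParseError(
                    f"{path}: unknown criterion code {code!r} for {vid!r}; "
                    f"valid codes: {', '.join(sorted(VALID_CODES))}"
                )
            if item.get("fulfilled", True):
                kwargs: dict[str, Any] = {"note": item.get("note", "")}
                if "strength" in item:
                    kwargs["strength"] = item["strength"]
                crits.append(Criterion(code, **kwargs))
        try:
            out[vid] = EvidenceSet(vid, crits)
        except ValueError as exc:
            raise ParseError(f"{path}: {vid!r}: {exc}") from exc
    return out


def write_evidence(evidence: dict[str, EvidenceSet], path: str | Path) -> None:
    data = {
        vid: [
            {"code": c.code, "note": c.note, "fulfilled": True}
            for c in es.fulfilled
        ]
        for vid, es in evidence.items()
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def read_config(path: str | Path) -> AnalysisConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisConfig(**data)


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def write_report(report: pd.DataFrame | dict, path: str | Path, fmt: str = "tsv") -> None:
    """Write a report table (TSV) or mapping (JSON)."""
    path = Path(path)
    if fmt == "tsv":
        df = report if isinstance(report, pd.DataFrame) else pd.DataFrame(report)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        if isinstance(report, pd.DataFrame):
            path.write_text(report.to_json(orient="records", indent=2))
        else:
            path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    else:
        raise ValueError(f"unsupported report format {fmt!r}")
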