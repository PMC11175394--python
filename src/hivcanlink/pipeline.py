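"""End-to-end orchestration: simulate → standardize → link → cohort → tables.

Each stage reads its inputs from and writes its outputs to a run directory,
so any stage can be re-run standalone from the previous stage's files. A
run manifest accumulates per-stage record counts (which must chain), the
attrition log, linkage-quality metrics when ground truth is available, and
the config hash + seed that make the run reproducible.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import linkage, standardize, synthgen, tables
from .config import (
    GeneratorConfig, load_demographics_fixture, load_od_fixture,
)
from .provinces import PROVINCES


def _read_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str), encoding="utf-8")


# --------------------------------------------------------------------------
# stages

def stage_simulate(config: GeneratorConfig, outdir: Path) -> dict:
    data = synthgen.generate(config)
    return synthgen.write_outputs(data, outdir, config)


def stage_standardize(outdir: Path) -> dict:
    outdir = Path(outdir)
    hiv = _read_csv(outdir / "hiv_records.csv")
    cancer = _read_csv(outdir / "cancer_records.csv")
    hc = standardize.clean_records(hiv, "test_date")
    cc = standardize.clean_records(cancer, "diagnosis_date")
    hc.to_csv(outdir / "hiv_clean.csv", index=False, lineterminator="\n")
    cc.to_csv(outdir / "cancer_clean.csv", index=False, lineterminator="\n")
    return {"stage": "standardize", "timestamp": _now(),
            "counts": {"hiv_records": len(hc), "cancer_records": len(cc)}}


def stage_link(outdir: Path, seed: int, n_training_pairs: int = 5000,
               threshold: float = 0.0) -> dict:
    """Train (from the truth table when present, else reuse model.json),
    classify blocked pairs, deduplicate, and link cancer records."""
    outdir = Path(outdir)
    hc = _read_csv(outdir / "hiv_clean.csv")
    cc = _read_csv(outdir / "cancer_clean.csv")
    for df in (hc, cc):
        df["birth_year"] = pd.to_numeric(
            df["birth_year"], errors="coerce").astype("Int64")
        df["year_from_age"] = df["year_from_age"] == "True"
    pairs = standardize.candidate_pairs(hc)

    truth_path = outdir / "truth.csv"
    if truth_path.exists():
        truth = _read_csv(truth_path)
        rng = np.random.default_rng(seed)
        X, y = linkage.make_training_pairs(hc, pairs, truth,
                                           n_training_pairs, rng)
        model = linkage.train_classifier(X, y, threshold=threshold)
        model.to_json(outdir / "model.json")
    else:
        model = linkage.MatchModel.from_json(outdir / "model.json")

    scored = linkage.classify_pairs(hc, pairs, model)
    clusters = linkage.deduplicate(hc["record_id"], scored[scored["match"]])
    links = linkage.link_hiv_cancer(hc, clusters, cc, model)
    clusters.to_csv(outdir / "clusters.csv", index=False, lineterminator="\n")
    links.to_csv(outdir / "links.csv", index=False, lineterminator="\n",
                 float_format="%.6f")
    return {"stage": "link", "timestamp": _now(),
            "counts": {"candidate_pairs": len(pairs),
                       "matched_pairs": int(scored["match"].sum()),
                       "clusters": int(clusters["cluster_id"].nunique()),
                       "links": len(links)}}


def stage_cohort(outdir: Path) -> dict:
    outdir = Path(outdir)
    clusters = _read_csv(outdir / "clusters.csv")
    links = _read_csv(outdir / "links.csv")
    hiv = _read_csv(outdir / "hiv_records.csv")
    cancer = _read_csv(outdir / "cancer_records.csv")
    cases, attrition = cohort_mod.build_cases(clusters, links, hiv, cancer)
    cases.to_csv(outdir / "cases.csv", index=False, lineterminator="\n")
    _write_json(outdir / "attrition.json", attrition)
    return {"stage": "cohort", "timestamp": _now(),
            "counts": {"input_clusters": attrition["input_clusters"],
                       "cases": attrition["final_cases"]},
            "attrition": attrition}


def stage_tables(outdir: Path, cases_path: Path | None = None) -> dict:
    outdir = Path(outdir)
    cases = _read_csv(cases_path or outdir / "cases.csv")
    cases["out_of_province"] = cases["out_of_province"] == "True"
    cases["age_at_diagnosis"] = pd.to_numeric(
        cases["age_at_diagnosis"], errors="coerce")

    demo = tables.demographics_table(cases)
    demo.to_csv(outdir / "table1.csv", index=False, lineterminator="\n")
    od = tables.od_matrix(cases)
    t2 = od.counts.copy().astype(object)
    pct = od.column_percentages()
    for r in PROVINCES:
        for c in PROVINCES:
            t2.loc[r, c] = f"{od.counts.loc[r, c]} ({pct.loc[r, c]}%)"
    t2.to_csv(outdir / "table2.csv", lineterminator="\n")

    notes = {}
    try:
        t3 = tables.logistic_fit(cases)
        notes["table3_references"] = t3.attrs["references"]
    except ValueError as exc:
        # thin strata (rare cancer types) can separate; fall back to the
        # demographic covariates alone and record that we did
        t3 = tables.logistic_fit(cases, covariates=("age", "gender", "race"))
        notes["table3_references"] = t3.attrs["references"]
        notes["table3_note"] = f"cancer_type omitted: {exc}"
    t3.to_csv(outdir / "table3.csv", index=False, lineterminator="\n",
              float_format="%.6f")

    flows = tables.export_flows(od)
    _write_json(outdir / "flows.geojson", flows)
    return {"stage": "tables", "timestamp": _now(),
            "counts": {"cases": len(cases),
                       "out_of_province": int(cases["out_of_province"].sum())},
            **notes}


def stage_tables_fixtures(outdir: Path) -> dict:
    """Reproduce the printed demographic and OD tables from the packaged
    cell-count fixtures (percentages re-derived from counts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    demo = tables.demographics_from_counts(load_demographics_fixture())
    demo.to_csv(outdir / "table1_printed.csv", index=False,
                lineterminator="\n")
    od = tables.OriginDestinationMatrix.from_counts(load_od_fixture())
    pct = od.column_percentages()
    t2 = od.counts.astype(object).copy()
    for r in PROVINCES:
        for c in PROVINCES:
            t2.loc[r, c] = f"{od.counts.loc[r, c]} ({pct.loc[r, c]}%)"
    t2["row_total"] = od.row_totals()
    t2.to_csv(outdir / "table2_printed.csv", lineterminator="\n")
    flows = tables.export_flows(od)
    _write_json(outdir / "flows_printed.geojson", flows)
    return {"stage": "tables-fixtures", "timestamp": _now(),
            "counts": {"od_total": od.total(),
                       "out_of_province": od.off_diagonal_total()}}


def stage_evaluate(outdir: Path) -> dict:
    outdir = Path(outdir)
    truth = _read_csv(outdir / "truth.csv")
    clusters = _read_csv(outdir / "clusters.csv")
    links = _read_csv(outdir / "links.csv")
    metrics = linkage.evaluate_clusters(clusters, truth)
    metrics.update(linkage.evaluate_links(links, clusters, truth))
    _write_json(outdir / "evaluation.json", metrics)
    return {"stage": "evaluate", "timestamp": _now(), "metrics": metrics}


def run_pipeline(config: GeneratorConfig, outdir: str | Path,
                 n_training_pairs: int = 5000,
                 evaluate: bool = True) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [stage_simulate(config, outdir),
              stage_standardize(outdir),
              stage_link(outdir, seed=config.seed,
                         n_training_pairs=n_training_pairs),
              stage_cohort(outdir),
              stage_tables(outdir)]
    if evaluate and (outdir / "truth.csv").exists():
        stages.append(stage_evaluate(outdir))
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "timestamp": _now(),
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


# --------------------------------------------------------------------------
# schema validation

_SCHEMAS = {
    "hiv_records": {
        "columns": ["record_id", "first_name", "surname", "dob", "age",
                    "episode_number", "folder_number", "test_type",
                    "result_label", "facility_id", "province", "test_date"],
        "province_cols": ["province"],
        "date_cols": ["test_date"],
    },
    "cancer_records": {
        "columns": ["record_id", "first_name", "surname", "dob", "age",
                    "episode_number", "folder_number", "diagnosis_date",
                    "cancer_type", "basis", "diagnosis_province",
                    "facility_id"],
        "province_cols": [],           # diagnosis_province may be missing
        "date_cols": ["diagnosis_date"],
        "optional_province_cols": ["diagnosis_province"],
    },
    "truth": {"columns": ["record_id", "entity_id"],
              "province_cols": [], "date_cols": []},
    "cases": {
        "columns": list(cohort_mod.CASE_COLUMNS),
        "province_cols": ["home_province", "diagnosis_province"],
        "date_cols": ["hiv_first_date", "cancer_diagnosis_date"],
    },
}


def validate_schema(path: str | Path, schema: str) -> list[str]:
    """Check a CSV against a named schema; returns itemised violations
    (empty list = ok)."""
    if schema not in _SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; "
                       f"known: {sorted(_SCHEMAS)}")
    spec = _SCHEMAS[schema]
    df = _read_csv(Path(path))
    violations = []
    for col in spec["columns"]:
        if col not in df.columns:
            violations.append(f"missing column: {col}")
            return violations  # further checks need the columns
    for col in spec["province_cols"]:
        bad = df.index[~df[col].isin(PROVINCES)]
        for i in bad[:20]:
            violations.append(
                f"row {i}: invalid province {df[col].iat[i]!r} in {col}")
    for col in spec.get("optional_province_cols", []):
        mask = (df[col] != "") & ~df[col].isin(PROVINCES)
        for i in df.index[mask][:20]:
            violations.append(
                f"row {i}: invalid province {df[col].iat[i]!r} in {col}")
    for col in spec["date_cols"]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        for i in df.index[parsed.isna() & (df[col] != "")][:20]:
            violations.append(
                f"row {i}: unparseable date {df[col].iat[i]!r} in {col}")
    return violations
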