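"""End-to-end driver: simulate/load -> identify -> episodes -> eligibility ->
recurrence -> incidence -> trends, with a conserved stage-count ledger.

Outputs are buffered and written only after every stage succeeds, so a
failed run leaves no partial files. Identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import DEFAULT_BANDS, band_labels
from .cases import identify_aom_visits, load_exclusion_list
from .config import RunConfig, config_echo
from .episodes import apply_eligibility, assign_attributes, build_episodes
from .incidence import person_time_table, rounded_report, stratum_counts, tabulate
from .recurrence import label_episodes, split_counts
from .simulate import generate_cohort
from .trends import trend_report

logger = logging.getLogger(__name__)

CHILD_COLUMNS = ["child_id", "birth_date", "sex", "registration_date", "end_date"]
VISIT_COLUMNS = ["child_id", "visit_date"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def read_children(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"child_id": str})
    for col in ("birth_date", "registration_date", "end_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    return df


def read_visits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"child_id": str}, keep_default_na=False)
    for col in ("icd9", "free_text"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def validate_inputs(children: pd.DataFrame, visits: pd.DataFrame) -> dict:
    """Schema, date, referential-integrity and chronology checks.

    Returns {check: {"passed": bool, "n_bad": int, "samples": [...]}}.
    """
    report = {}

    def add(name, bad_mask, frame, key="child_id"):
        n = int(np.asarray(bad_mask).sum())
        samples = (
            frame.loc[np.asarray(bad_mask)][key].astype(str).head(5).tolist() if n else []
        )
        report[name] = {"passed": n == 0, "n_bad": n, "samples": samples}

    missing_child_cols = [c for c in CHILD_COLUMNS if c not in children.columns]
    missing_visit_cols = [c for c in VISIT_COLUMNS if c not in visits.columns]
    report["schema"] = {
        "passed": not (missing_child_cols or missing_visit_cols),
        "n_bad": len(missing_child_cols) + len(missing_visit_cols),
        "samples": missing_child_cols + missing_visit_cols,
    }
    if not report["schema"]["passed"]:
        return report

    birth = pd.to_datetime(children["birth_date"], errors="coerce")
    reg = pd.to_datetime(children["registration_date"], errors="coerce")
    end = pd.to_datetime(children["end_date"], errors="coerce")
    vdate = pd.to_datetime(visits["visit_date"], errors="coerce")
    add("child_dates_parse", reg.isna() | end.isna(), children)
    add("visit_dates_parse", vdate.isna(), visits)
    add(
        "referential_integrity",
        ~visits["child_id"].isin(set(children["child_id"])),
        visits,
    )
    add("registration_order", (reg > end).fillna(False), children)
    birth_by_id = children.set_index("child_id")["birth_date"]
    vbirth = visits["child_id"].map(pd.to_datetime(birth_by_id, errors="coerce"))
    add("visit_chronology", (vdate < vbirth).fillna(False), visits)
    report["passed"] = all(v["passed"] for v in report.values() if isinstance(v, dict))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write interface files and return the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    ledger: dict = {}
    outputs: dict[str, object] = {}

    stage = "configure"
    try:
        case_def = config.case
        if not case_def.exclusion_list:
            path = config.inputs.exclusion_list if config.inputs else None
            case_def = dataclasses.replace(
                case_def, exclusion_list=load_exclusion_list(path)
            )

        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            params = dataclasses.replace(config.simulate, seed=config.seed)
            children, visits = generate_cohort(params)
            outputs["children.csv"] = children
            outputs["visits.csv"] = visits
        else:
            children = read_children(config.inputs.children)
            visits = read_visits(config.inputs.visits)
            stage = "validate"
            validation = validate_inputs(children, visits)
            ledger["validation"] = validation
            if not validation.get("passed"):
                failing = [k for k, v in validation.items() if isinstance(v, dict) and not v["passed"]]
                raise ValueError(f"input validation failed: {failing}")
        ledger["children_in"] = len(children)
        ledger["visits_in"] = len(visits)

        stage = "identify"
        aom = identify_aom_visits(visits, case_def)
        ledger["identify"] = {
            "rows_in": len(visits),
            "rows_out": len(aom),
            "rows_excluded": len(visits) - len(aom),
            "rejected_dates": aom.attrs.get("n_rejected_dates", 0),
        }
        outputs["aom_visits.csv"] = aom

        stage = "episodes"
        episodes = build_episodes(aom, config.episode)
        episodes = assign_attributes(episodes, children, DEFAULT_BANDS)
        ledger["episodes"] = {
            "aom_visits": int(len(aom)),
            "episodes_built": int(len(episodes)),
            "visits_in_episodes": int(episodes["n_visits"].sum()) if len(episodes) else 0,
        }

        stage = "eligibility"
        retained, exclusions = apply_eligibility(
            children, visits, episodes, config.episode, study_end=config.study_end
        )
        ledger["eligibility"] = {
            "rows_in": int(len(episodes)),
            "rows_out": int(len(retained)),
            "rows_excluded": int(len(episodes) - len(retained)),
            "children_excluded": exclusions["reason"].value_counts().to_dict(),
        }
        outputs["exclusions.csv"] = exclusions

        stage = "classify"
        labeled = label_episodes(retained, config.recurrence)
        sex_by_id = children.set_index("child_id")["sex"]
        labeled["sex"] = labeled["child_id"].map(sex_by_id)
        simple, recurrent = split_counts(labeled)
        ledger["classify"] = {
            "rows_in": int(len(retained)),
            "simple": int(len(simple)),
            "recurrent": int(len(recurrent)),
        }
        outputs["episodes.csv"] = labeled

        stage = "person_time"
        denom_children = children
        if config.denominator == "eligible":
            denom_children = children.loc[
                ~children["child_id"].isin(set(exclusions["child_id"]))
            ]
        pt = person_time_table(
            denom_children, config.study_start, config.study_end, DEFAULT_BANDS
        )
        ledger["person_time"] = {
            "children": int(pt["child_id"].nunique()) if len(pt) else 0,
            "person_years": float(pt["person_years"].sum()) if len(pt) else 0.0,
        }

        stage = "incidence"
        groupings = {
            "overall": [],
            "age_band": ["age_band"],
            "sex": ["sex"],
            "label": ["label"],
        }
        incidence_tables = {}
        for name, by in groupings.items():
            if len(pt) == 0:
                continue
            tabs = tabulate(labeled, pt, by)
            incidence_tables[name] = tabs
            outputs[f"incidence_annual_{name}.csv"] = rounded_report(tabs["annual"])
            outputs[f"incidence_mean_{name}.csv"] = rounded_report(tabs["mean"])

        stage = "trends"
        trends_csv = pd.DataFrame()
        notes: list[str] = []
        if len(pt) and len(labeled):
            annual_tables = {"overall": incidence_tables["overall"]["annual"]}
            counts_tables = {"overall": stratum_counts(labeled, pt, ["age_band", "sex"])}
            band_annual = incidence_tables["age_band"]["annual"]
            for band in band_labels(DEFAULT_BANDS):
                annual_tables[band] = band_annual.loc[band_annual["age_band"] == band]
                counts_tables[band] = stratum_counts(
                    labeled.loc[labeled["age_band"] == band],
                    pt.loc[pt["age_band"] == band],
                    ["sex"],
                )
            label_annual = incidence_tables["label"]["annual"]
            for lab in ("simple", "recurrent"):
                annual_tables[lab] = label_annual.loc[label_annual["label"] == lab]
                counts_tables[lab] = stratum_counts(
                    labeled.loc[labeled["label"] == lab], pt, ["age_band", "sex"]
                )
            out_dir.mkdir(parents=True, exist_ok=True)
            trends_csv, fits, notes = trend_report(
                annual_tables,
                counts_tables,
                config.its,
                figure_path=out_dir / "its_panels.png",
                panel_names=("overall", *band_labels(DEFAULT_BANDS)),
            )
        else:
            notes = ["no episodes or person-time; trend analysis skipped"]
        outputs["trend_results.csv"] = trends_csv
        ledger["trends"] = {"series": int(trends_csv["series"].nunique()) if len(trends_csv) else 0,
                            "notes": notes}
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        raise StageError(stage, exc) from exc

    report = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "stages": ledger,
        "config": config_echo(config),
    }

    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in outputs.items():
        df = obj.copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        df.to_csv(out_dir / name, index=False)
    with open(out_dir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
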