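"""Person-time accrual and incidence-rate estimation.

Person-time is accrued at day resolution: each child's observation interval
runs from the latest of registration, birth and study start to the earliest
of deregistration, study end and the day before ageing out of the oldest
band, and is split at every 1 January and at the band-edge birthdays, so
each calendar day belongs to exactly one (year, age band) cell. Days are
converted to person-years with 365.25 days per year.

Rates are episodes per 1000 person-years with Poisson normal-approximation
confidence intervals::

    IR = 1000 * events / PY
    IR +/- z * sqrt(events) / PY * 1000

Reported tables round rates half-up to integers; internal values keep full
precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, band_of, birthday, max_age_years

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class IncidenceEstimate:
    ir: float
    ci_low: float
    ci_high: float
    events: int
    person_years: float


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def accrue_person_time(
    birth_date,
    registration_date,
    end_date,
    study_start,
    study_end,
    bands=DEFAULT_BANDS,
) -> list[tuple[int, str, int]]:
    """Split one child's observation interval into (year, age_band, days) cells.

    The interval is closed on both ends in calendar days; a split happens at
    each 1 January and at each band-edge birthday, the boundary day counting
    in the later fragment. An inverted interval contributes nothing (logged).
    """
    birth = pd.Timestamp(birth_date)
    start = max(pd.Timestamp(registration_date), pd.Timestamp(study_start), birth)
    stop = min(
        pd.Timestamp(end_date),
        pd.Timestamp(study_end),
        birthday(birth, max_age_years(bands)) - pd.Timedelta(days=1),
    )
    if stop < start:
        # silent when emptiness is plain study-window/age clipping
        if pd.Timestamp(end_date) < pd.Timestamp(registration_date) <= pd.Timestamp(
            study_end
        ):
            logger.warning(
                "inverted observation interval (%s > %s)", start.date(), stop.date()
            )
        return []
    end_excl = stop + pd.Timedelta(days=1)

    cuts = {start, end_excl}
    for y in range(start.year + 1, end_excl.year + 1):
        c = pd.Timestamp(year=y, month=1, day=1)
        if start < c < end_excl:
            cuts.add(c)
    for _, lo, hi in bands:
        for edge in (lo, hi):
            c = birthday(birth, edge)
            if start < c < end_excl:
                cuts.add(c)
    points = sorted(cuts)
    out = []
    for a, b in zip(points[:-1], points[1:]):
        band = band_of(birth, a, bands)
        if band is not None:
            out.append((a.year, band, (b - a).days))
    return out


def person_time_table(
    children: pd.DataFrame,
    study_start,
    study_end,
    bands=DEFAULT_BANDS,
) -> pd.DataFrame:
    """Accrue person-time for every child.

    Returns one row per (child, year, age_band) with day counts,
    person-years and the child's stratification attributes (sex and any
    risk-factor flags present in the child table).
    """
    extra = [c for c in ("sex", "preterm", "comorbidity") if c in children.columns]
    rows = []
    for rec in children.itertuples(index=False):
        d = rec._asdict()
        if pd.isna(pd.Timestamp(d["birth_date"]) if d["birth_date"] is not None else pd.NaT):
            continue
        for year, band, days in accrue_person_time(
            d["birth_date"], d["registration_date"], d["end_date"], study_start, study_end, bands
        ):
            row = {"child_id": d["child_id"], "year": year, "age_band": band, "days": days}
            for c in extra:
                row[c] = d[c]
            rows.append(row)
    pt = pd.DataFrame(rows, columns=["child_id", "year", "age_band", "days", *extra])
    pt["person_years"] = pt["days"] / DAYS_PER_YEAR
    return pt


def compute_ir(events: int, person_years: float) -> float:
    """Episodes per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("undefined rate: person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    return 1000.0 * events / person_years


def compute_ci(events: int, person_years: float, z: float = 1.96) -> tuple[float, float]:
    """Poisson normal-approximation CI, clipped at zero below."""
    ir = compute_ir(events, person_years)
    hw = z * math.sqrt(events) / person_years * 1000.0
    return max(0.0, ir - hw), ir + hw


def estimate(events: int, person_years: float, z: float = 1.96) -> IncidenceEstimate:
    lo, hi = compute_ci(events, person_years, z)
    return IncidenceEstimate(compute_ir(events, person_years), lo, hi, events, person_years)


def _summarize(grouped: pd.DataFrame) -> pd.DataFrame:
    out = grouped.loc[grouped["person_years"] > 0].copy()
    out["ir"] = 1000.0 * out["events"] / out["person_years"]
    ci = [compute_ci(e, p) for e, p in zip(out["events"], out["person_years"])]
    out["ci_low"] = [c[0] for c in ci]
    out["ci_high"] = [c[1] for c in ci]
    return out


def tabulate(
    labeled_episodes: pd.DataFrame,
    person_time: pd.DataFrame,
    by: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Annual and mean-annual incidence tables for one grouping.

    ``by`` may contain episode/person-time columns such as ``age_band``,
    ``sex`` or ``label`` (episode label; person-time is not label-specific,
    so labelled rates share the full denominator of their stratum). Returns
    ``{"annual": ..., "mean": ...}``; strata with zero person-years are
    omitted rather than reported as zero rates.
    """
    by = list(by or [])
    pt_keys = [c for c in by if c != "label"]

    py_annual = person_time.groupby(["year", *pt_keys], as_index=False)["person_years"].sum()
    ev = labeled_episodes.rename(columns={"calendar_year": "year"})
    ev_annual = ev.groupby(["year", *by], as_index=False).size().rename(columns={"size": "events"})
    if "label" in by:
        labels = sorted(ev["label"].unique()) if len(ev) else []
        py_annual = py_annual.merge(pd.DataFrame({"label": labels}), how="cross") if labels else py_annual.assign(label=pd.NA)
    annual = py_annual.merge(ev_annual, on=["year", *by], how="left").fillna({"events": 0})
    annual["events"] = annual["events"].astype(int)
    annual = _summarize(annual).sort_values(["year", *by]).reset_index(drop=True)

    if by:
        py_mean = person_time.groupby(pt_keys, as_index=False)["person_years"].sum() if pt_keys else pd.DataFrame({"person_years": [person_time["person_years"].sum()]})
        ev_mean = ev.groupby(by, as_index=False).size().rename(columns={"size": "events"})
        if "label" in by and pt_keys:
            py_mean = py_mean.merge(ev_mean[["label"]].drop_duplicates(), how="cross")
        elif "label" in by:
            py_mean = py_mean.merge(ev_mean[["label"]].drop_duplicates(), how="cross")
        mean = py_mean.merge(ev_mean, on=by, how="left").fillna({"events": 0})
    else:
        mean = pd.DataFrame(
            {
                "events": [len(ev)],
                "person_years": [person_time["person_years"].sum()],
            }
        )
    mean["events"] = mean["events"].astype(int)
    mean = _summarize(mean).reset_index(drop=True)
    return {"annual": annual, "mean": mean}


def stratum_counts(
    labeled_episodes: pd.DataFrame,
    person_time: pd.DataFrame,
    factors: list[str] = ("age_band", "sex"),
) -> pd.DataFrame:
    """Aggregate to (year x factors) cells with events and person-years.

    The full person-time grid is kept (cells with observation time but no
    episodes get zero events); this is the input to the interrupted time
    series fit.
    """
    factors = [f for f in factors if f in person_time.columns]
    py = person_time.groupby(["year", *factors], as_index=False)["person_years"].sum()
    ev = (
        labeled_episodes.rename(columns={"calendar_year": "year"})
        .groupby(["year", *factors], as_index=False)
        .size()
        .rename(columns={"size": "events"})
    )
    out = py.merge(ev, on=["year", *factors], how="left").fillna({"events": 0})
    out["events"] = out["events"].astype(int)
    return out.loc[out["person_years"] > 0].reset_index(drop=True)


def rounded_report(table: pd.DataFrame) -> pd.DataFrame:
    """Reporting view: integer-rounded IR and CI columns."""
    out = table.copy()
    for col in ("ir", "ci_low", "ci_high"):
        out[col] = out[col].map(round_half_up)
    return out
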