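"""Synthetic pediatric primary-care cohort generator.

Emulates an Italian family-paediatrician database: children enrolled at or
shortly after birth, followed until deregistration, ageing out at 15, or
study close (2010-2017 by default). Each child's AOM episode onsets follow
a non-homogeneous Poisson process whose intensity is piecewise constant in
the child's age band and calendar year — base rates of roughly 180, 200 and
48 episodes per 1000 person-years for ages <2, 2-4 and 5-14, scaled by a
multiplicative annual trend (separate multipliers for the early and late
vaccine periods) and a per-child log-normal frailty inducing
recurrence-prone children. Episodes emit an index visit plus, with some
probability, one or two follow-up visits within 14 days. A background
stream of non-AOM visits (routine checks, unrelated diagnoses) is also
generated, a configurable share of which carries free text that matches the
otitis search patterns but belongs to the exclusion vocabulary
(e.g. "vomito"), exercising the false-positive path.

The generator documents what it does *not* emulate: seasonality, daycare or
sibling effects, hospital contacts, and self-exciting episode clustering
(frailty is a stationary simplification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, band_labels, birthday, max_age_years
from .incidence import DAYS_PER_YEAR
from .recurrence import RecurrenceConfig, classify_onsets

TRUE_POSITIVE_TEXTS = (
    "otite media acuta",
    "otite",
    "oma bilaterale",
    "otalgia con otite",
    "otite media purulenta",
)
FALSE_POSITIVE_TEXTS = (
    "vomito",
    "vomito e diarrea",
    "dolore addominale",
    "gomito dolorante",
    "sindrome influenzale",
    "stomatite",
    "addome acuto",
)
NEUTRAL_TEXTS = ("febbre", "visita di controllo", "tosse", "faringite", "dermatite")
NEUTRAL_CODES = ("460", "466.0", "558.9", "")
AOM_ICD9 = ("382.00", "382.01", "382.9", "382.4")


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic cohort.

    Rates are per 1000 person-years; hazards are per year. The defaults
    describe the emulated setting: 2010-2017 follow-up of children under 15
    with age-band AOM rates 180/200/48, a 6%-per-year declining trend in
    both periods, enrolment within about a month of birth, and 2%/year
    dropout.
    """

    n_children: int = 5000
    study_start: str = "2010-01-01"
    study_end: str = "2017-12-31"
    base_rates: dict = field(
        default_factory=lambda: {"<2": 180.0, "2-4": 200.0, "5-14": 48.0}
    )
    annual_rate_multiplier: dict = field(
        default_factory=lambda: {"early": 0.94, "late": 0.94}
    )
    breakpoint_year: int = 2014
    followup_visit_prob: float = 0.5
    recurrence_frailty_sd: float = 1.0
    false_positive_text_rate: float = 0.2
    background_visit_rate: float = 3.0
    enrollment_hazard: float = 12.0
    dropout_hazard: float = 0.02
    sex_ratio: float = 0.512
    preterm_prob: float = 0.07
    comorbidity_prob: float = 0.05
    icd9_code_prob: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_children < 0:
            raise ValueError("n_children must be non-negative")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ValueError("study_start must precede study_end")
        if set(self.base_rates) != set(band_labels(DEFAULT_BANDS)):
            raise ValueError("base_rates keys must exactly cover the age bands")
        for k, v in self.base_rates.items():
            if v < 0:
                raise ValueError(f"base_rates[{k!r}] must be >= 0")
        for k, v in self.annual_rate_multiplier.items():
            if k not in ("early", "late"):
                raise ValueError("annual_rate_multiplier keys must be 'early'/'late'")
            if v <= 0:
                raise ValueError(f"annual_rate_multiplier[{k!r}] must be positive")
        for name in (
            "followup_visit_prob",
            "sex_ratio",
            "preterm_prob",
            "comorbidity_prob",
            "icd9_code_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "recurrence_frailty_sd",
            "false_positive_text_rate",
            "background_visit_rate",
            "enrollment_hazard",
            "dropout_hazard",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def trend_factor(params: SimulationParams, year: int) -> float:
    """Cumulative multiplicative trend relative to the first study year."""
    first = pd.Timestamp(params.study_start).year
    bp = params.breakpoint_year
    m_early = params.annual_rate_multiplier.get("early", 1.0)
    m_late = params.annual_rate_multiplier.get("late", 1.0)
    return m_early ** min(year - first, bp - first) * m_late ** max(0, year - bp)


def configured_rate(params: SimulationParams, year: int, band: str) -> float:
    """True episode intensity (per 1000 PY) in a (year, band) cell, frailty aside."""
    return params.base_rates[band] * trend_factor(params, year)


def _observation_window(params, birth, registration, end_date):
    start = max(registration, pd.Timestamp(params.study_start), birth)
    stop = min(
        end_date,
        pd.Timestamp(params.study_end),
        birthday(birth, max_age_years()) - pd.Timedelta(days=1),
    )
    return start, stop


def _segments(params, birth, start, stop):
    """Piecewise-constant intensity segments [(seg_start, seg_end_excl, year, band)]."""
    if stop < start:
        return []
    end_excl = stop + pd.Timedelta(days=1)
    cuts = {start, end_excl}
    for y in range(start.year + 1, end_excl.year + 1):
        c = pd.Timestamp(year=y, month=1, day=1)
        if start < c < end_excl:
            cuts.add(c)
    for _, lo, hi in DEFAULT_BANDS:
        for edge in (lo, hi):
            c = birthday(birth, edge)
            if start < c < end_excl:
                cuts.add(c)
    points = sorted(cuts)
    segs = []
    for a, b in zip(points[:-1], points[1:]):
        band = None
        for label, lo, hi in DEFAULT_BANDS:
            if birthday(birth, lo) <= a < birthday(birth, hi):
                band = label
                break
        if band is not None:
            segs.append((a, b, a.year, band))
    return segs


def _simulate(params: SimulationParams):
    rng = np.random.default_rng(params.seed)
    study_start = pd.Timestamp(params.study_start)
    study_end = pd.Timestamp(params.study_end)
    horizon_days = 15 * 365  # birth window so that age < 15 overlaps the study
    child_rows, visit_rows, truth_rows = [], [], []
    rec_cfg = RecurrenceConfig()

    for i in range(params.n_children):
        child_id = f"C{i + 1:06d}"
        birth = study_start + pd.Timedelta(
            days=int(rng.integers(-horizon_days + 1, (study_end - study_start).days + 1))
        )
        delay_days = (
            rng.exponential(DAYS_PER_YEAR / params.enrollment_hazard)
            if params.enrollment_hazard > 0
            else 0.0
        )
        registration = birth + pd.Timedelta(days=int(round(delay_days)))
        if params.dropout_hazard > 0:
            dropout_days = int(round(rng.exponential(DAYS_PER_YEAR / params.dropout_hazard)))
        else:
            dropout_days = None
        horizon = (study_end - registration).days
        if dropout_days is not None and dropout_days <= horizon:
            end_date = registration + pd.Timedelta(days=dropout_days)
        else:
            end_date = study_end
        sex = "M" if rng.random() < params.sex_ratio else "F"
        preterm = int(rng.random() < params.preterm_prob)
        comorbidity = int(rng.random() < params.comorbidity_prob)
        frailty = (
            float(
                np.exp(
                    params.recurrence_frailty_sd * rng.standard_normal()
                    - 0.5 * params.recurrence_frailty_sd**2
                )
            )
            if params.recurrence_frailty_sd > 0
            else 1.0
        )
        child_rows.append(
            {
                "child_id": child_id,
                "birth_date": birth,
                "sex": sex,
                "registration_date": registration,
                "end_date": end_date,
                "preterm": preterm,
                "comorbidity": comorbidity,
            }
        )

        start, stop = _observation_window(params, birth, registration, end_date)
        if stop < start:
            continue
        obs_days = (stop - start).days + 1

        # --- episode onsets: thinned piecewise-constant Poisson process
        onsets: list[pd.Timestamp] = []
        for a, b, year, band in _segments(params, birth, start, stop):
            lam_day = (
                configured_rate(params, year, band) / 1000.0 / DAYS_PER_YEAR * frailty
            )
            n_days = (b - a).days
            k = rng.poisson(lam_day * n_days)
            if k:
                offsets = np.sort(rng.integers(0, n_days, size=k))
                onsets.extend(a + pd.Timedelta(days=int(o)) for o in offsets)
        onsets = sorted(set(onsets))

        labels = classify_onsets(onsets, rec_cfg) if onsets else []
        for onset, label in zip(onsets, labels):
            truth_rows.append(
                {"child_id": child_id, "onset_date": onset, "true_label": label}
            )
            dates = [onset]
            if params.followup_visit_prob > 0 and rng.random() < params.followup_visit_prob:
                n_extra = int(rng.integers(1, 3))
                extra = rng.choice(np.arange(1, 15), size=n_extra, replace=False)
                dates.extend(onset + pd.Timedelta(days=int(d)) for d in np.sort(extra))
            for d in dates:
                if d > stop:
                    continue
                if rng.random() < params.icd9_code_prob:
                    icd9 = str(rng.choice(AOM_ICD9))
                    text = ""
                else:
                    icd9 = ""
                    text = str(rng.choice(TRUE_POSITIVE_TEXTS))
                visit_rows.append(
                    {"child_id": child_id, "visit_date": d, "icd9": icd9, "free_text": text}
                )

        # --- background non-AOM visits and false-positive free text
        for rate, texts, codes in (
            (params.background_visit_rate, NEUTRAL_TEXTS, NEUTRAL_CODES),
            (params.false_positive_text_rate, FALSE_POSITIVE_TEXTS, ("",)),
        ):
            if rate <= 0:
                continue
            k = rng.poisson(rate / DAYS_PER_YEAR * obs_days)
            for o in np.sort(rng.integers(0, obs_days, size=k)):
                d = start + pd.Timedelta(days=int(o))
                visit_rows.append(
                    {
                        "child_id": child_id,
                        "visit_date": d,
                        "icd9": str(rng.choice(codes)),
                        "free_text": str(rng.choice(texts)),
                    }
                )

    children = pd.DataFrame(
        child_rows,
        columns=[
            "child_id",
            "birth_date",
            "sex",
            "registration_date",
            "end_date",
            "preterm",
            "comorbidity",
        ],
    )
    visits = pd.DataFrame(
        visit_rows, columns=["child_id", "visit_date", "icd9", "free_text"]
    )
    if len(visits):
        visits = visits.sort_values(
            ["child_id", "visit_date"], kind="stable"
        ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["child_id", "onset_date", "true_label"])
    return children, visits, truth


def generate_cohort(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (child table, visit table); deterministic in params.seed."""
    children, visits, _ = _simulate(params)
    return children, visits


def ground_truth(
    params: SimulationParams, children: pd.DataFrame, visits: pd.DataFrame
) -> pd.DataFrame:
    """True episode onsets and simple/recurrent labels for a generated cohort.

    Re-simulates from ``params`` and verifies the supplied tables match,
    guarding against a params/cohort provenance mismatch.
    """
    ref_children, ref_visits, truth = _simulate(params)
    try:
        pd.testing.assert_frame_equal(
            ref_children.reset_index(drop=True), children.reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            ref_visits.reset_index(drop=True), visits.reset_index(drop=True)
        )
    except AssertionError as exc:
        raise ValueError(
            "cohort does not match these parameters and seed"
        ) from exc
    return truth


def simulate_stratum_counts(
    years,
    py_per_cell: float,
    base_rates: dict | None = None,
    trend_rr: float = 0.94,
    level_change_rr: float = 1.0,
    trend_change_rr: float = 1.0,
    breakpoint_year: int = 2014,
    dispersion: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate an aggregate (year x age band x sex) stratum-count table.

    Counts are Poisson (or gamma-Poisson when ``dispersion`` > 0, the NB2
    variance model) around mu = PY * rate with a segmented log-linear rate:
    annual ratio ``trend_rr`` before the break, an immediate ``level_change_rr``
    step and an extra ``trend_change_rr`` per-year factor after it. Used for
    recovery and power studies of the ITS fit.
    """
    rng = rng or np.random.default_rng(0)
    base_rates = base_rates or {"<2": 180.0, "2-4": 200.0, "5-14": 48.0}
    years = list(years)
    first = min(years)
    rows = []
    for year in years:
        t = year - first
        post = year >= breakpoint_year
        rate_factor = trend_rr**t
        if post:
            rate_factor *= level_change_rr * trend_change_rr ** (year - breakpoint_year)
        for band, base in base_rates.items():
            for sex, sex_mult in (("M", 1.05), ("F", 0.95)):
                mu = py_per_cell * base / 1000.0 * rate_factor * sex_mult
                if dispersion > 0:
                    lam = rng.gamma(1.0 / dispersion, dispersion * mu)
                else:
                    lam = mu
                rows.append(
                    {
                        "year": year,
                        "age_band": band,
                        "sex": sex,
                        "events": int(rng.poisson(lam)),
                        "person_years": py_per_cell,
                    }
                )
    return pd.DataFrame(rows)
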