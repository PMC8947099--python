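"""Person-time accrual, rate and CI arithmetic, and stratified tabulation."""

import numpy as np
import pandas as pd
import pytest

from aomburden import (
    accrue_person_time,
    compute_ci,
    compute_ir,
    person_time_table,
    stratum_counts,
    tabulate,
)
from aomburden.bands import birthday
from aomburden.incidence import round_half_up


def test_accrual_single_cell_full_year():
    cells = accrue_person_time(
        "2002-06-15", "2002-07-01", "2017-12-31", "2010-01-01", "2010-12-31"
    )
    assert cells == [(2010, "5-14", 365)]


def test_accrual_birthday_split_conserves_days():
    # child turns 2 on 2010-07-01; observed all of 2010
    cells = accrue_person_time(
        "2008-07-01", "2008-07-01", "2010-12-31", "2010-01-01", "2010-12-31"
    )
    assert cells == [(2010, "<2", 181), (2010, "2-4", 184)]
    assert sum(d for _, _, d in cells) == 365


def test_accrual_clipping_to_registration_interval():
    cells = accrue_person_time(
        "2010-05-01", "2016-11-01", "2017-03-01", "2010-01-01", "2017-12-31"
    )
    years = {y for y, _, _ in cells}
    assert years == {2016, 2017}
    assert sum(d for _, _, d in cells) == (pd.Timestamp("2017-03-01") - pd.Timestamp("2016-11-01")).days + 1


def test_accrual_ageing_out_at_15th_birthday():
    cells = accrue_person_time(
        "2000-06-15", "2000-07-01", "2017-12-31", "2010-01-01", "2017-12-31"
    )
    last_day = max(
        pd.Timestamp(year=y, month=1, day=1) + pd.Timedelta(days=d - 1)
        for y, _, d in cells
        if y == 2015
    )
    assert all(b == "5-14" for _, b, _ in cells)
    # observation ends the day before the 15th birthday
    total = sum(d for _, _, d in cells)
    expected = (birthday(pd.Timestamp("2000-06-15"), 15) - pd.Timestamp("2010-01-01")).days
    assert total == expected


def test_accrual_inverted_interval_contributes_nothing():
    assert (
        accrue_person_time("2012-01-01", "2014-01-01", "2013-01-01", "2010-01-01", "2017-12-31")
        == []
    )


def test_fragment_additivity_random_children():
    """Day-resolution additivity across year and band splits, birthdays included."""
    rng = np.random.default_rng(21)
    study_start, study_end = pd.Timestamp("2010-01-01"), pd.Timestamp("2017-12-31")
    for _ in range(300):
        birth = study_start + pd.Timedelta(days=int(rng.integers(-15 * 365, 2900)))
        reg = birth + pd.Timedelta(days=int(rng.integers(0, 400)))
        end = reg + pd.Timedelta(days=int(rng.integers(0, 4000)))
        cells = accrue_person_time(birth, reg, end, study_start, study_end)
        start = max(reg, study_start, birth)
        stop = min(end, study_end, birthday(birth, 15) - pd.Timedelta(days=1))
        expected = max(0, (stop - start).days + 1)
        assert sum(d for _, _, d in cells) == expected
        # each (year, band) appears at most once
        keys = [(y, b) for y, b, _ in cells]
        assert len(keys) == len(set(keys))


@pytest.mark.parametrize(
    "events,py,ir_int",
    [
        (5510, 43692.02, 126),
        (4077, 51348.38, 79),
        (41683, 402868.0, 103),
        (22245, 208832.96, 107),
        (10040, 55875.52, 180),
        (0, 1000.0, 0),
    ],
)
def test_rate_arithmetic(events, py, ir_int):
    assert round_half_up(compute_ir(events, py)) == ir_int


@pytest.mark.parametrize(
    "events,py,lo,hi",
    [
        (5510, 43692.02, 123, 129),
        (1504, 8396.77, 170, 188),
        (4077, 51348.38, 77, 82),
    ],
)
def test_ci_arithmetic(events, py, lo, hi):
    ci = compute_ci(events, py)
    assert (round_half_up(ci[0]), round_half_up(ci[1])) == (lo, hi)


def test_zero_events_ci_degenerate():
    assert compute_ci(0, 1000.0) == (0.0, 0.0)


def test_undefined_rate_errors():
    with pytest.raises(ValueError, match="person_years"):
        compute_ir(5, 0.0)
    with pytest.raises(ValueError):
        compute_ci(5, 0.0)


def _toy_cohort():
    children = pd.DataFrame(
        {
            "child_id": ["A", "B"],
            "birth_date": ["2009-03-01", "2001-01-01"],
            "sex": ["M", "F"],
            "registration_date": ["2009-03-10", "2009-01-01"],
            "end_date": ["2017-12-31", "2014-06-30"],
            "preterm": [0, 0],
            "comorbidity": [0, 0],
        }
    )
    episodes = pd.DataFrame(
        {
            "child_id": ["A", "A", "B"],
            "onset_date": pd.to_datetime(["2010-02-01", "2011-03-01", "2012-05-01"]),
            "calendar_year": [2010, 2011, 2012],
            "age_band": ["<2", "2-4", "5-14"],
            "sex": ["M", "M", "F"],
            "label": ["simple", "simple", "recurrent"],
        }
    )
    pt = person_time_table(children, "2010-01-01", "2017-12-31")
    return children, episodes, pt


def test_tabulate_totals_and_partition():
    _, episodes, pt = _toy_cohort()
    overall = tabulate(episodes, pt)
    assert overall["mean"]["events"].iloc[0] == 3
    assert overall["mean"]["person_years"].iloc[0] == pytest.approx(
        pt["person_years"].sum()
    )
    by_label = tabulate(episodes, pt, by=["label"])
    assert by_label["mean"]["events"].sum() == 3
    by_band = tabulate(episodes, pt, by=["age_band"])
    # numerator additivity across strata
    assert by_band["mean"]["events"].sum() == 3
    # person-time additivity across bands
    assert by_band["mean"]["person_years"].sum() == pytest.approx(
        pt["person_years"].sum()
    )


def test_pooled_rate_is_weighted_mean_of_stratum_rates():
    _, episodes, pt = _toy_cohort()
    by_band = tabulate(episodes, pt, by=["age_band"])["mean"]
    pooled = tabulate(episodes, pt)["mean"]["ir"].iloc[0]
    assert by_band["ir"].min() <= pooled <= by_band["ir"].max()


def test_zero_person_year_cells_omitted():
    children = pd.DataFrame(
        {
            "child_id": ["A"],
            "birth_date": ["2009-03-01"],
            "sex": ["M"],
            "registration_date": ["2009-03-10"],
            "end_date": ["2010-12-31"],
            "preterm": [0],
            "comorbidity": [0],
        }
    )
    pt = person_time_table(children, "2010-01-01", "2017-12-31")
    episodes = pd.DataFrame(
        {
            "child_id": ["A"],
            "onset_date": pd.to_datetime(["2010-02-01"]),
            "calendar_year": [2010],
            "age_band": ["<2"],
            "sex": ["M"],
            "label": ["simple"],
        }
    )
    annual = tabulate(episodes, pt)["annual"]
    assert set(annual["year"]) == {2010}  # no empty later years reported as 0


def test_stratum_counts_keeps_zero_event_cells():
    _, episodes, pt = _toy_cohort()
    counts = stratum_counts(episodes, pt, ["age_band", "sex"])
    assert (counts["events"] == 0).any()
    assert counts["events"].sum() == len(episodes)
    assert counts["person_years"].sum() == pytest.approx(pt["person_years"].sum())
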