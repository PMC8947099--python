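"""Episode grouping (14-day rule), attributes, and eligibility filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aomburden import (
    EpisodeConfig,
    apply_eligibility,
    assign_attributes,
    build_episodes,
    group_visit_dates,
)
from conftest import day


def oracle_rolling_partition(days, gap):
    """Brute force: try every contiguous partition, keep the unique one whose
    within-run gaps are all <= gap and whose between-run boundary gaps are > gap."""
    days = sorted(set(days))
    n = len(days)
    if n == 0:
        return []
    valid = []
    for cuts in itertools.product([0, 1], repeat=n - 1):
        runs, cur = [], [days[0]]
        for i, cut in enumerate(cuts):
            if cut:
                runs.append(cur)
                cur = [days[i + 1]]
            else:
                cur.append(days[i + 1])
        runs.append(cur)
        ok = all(
            (b - a) <= gap for run in runs for a, b in zip(run, run[1:])
        ) and all(
            (runs[k + 1][0] - runs[k][-1]) > gap for k in range(len(runs) - 1)
        )
        if ok:
            valid.append(runs)
    assert len(valid) == 1, "maximal-run partition must be unique"
    return valid[0]


def to_dates(days):
    return [day(int(d)) for d in days]


@pytest.mark.parametrize(
    "days,mode,expected_sizes",
    [
        ([0, 10, 20], "rolling", [3]),
        ([0, 15], "rolling", [1, 1]),
        ([0, 10, 20], "anchor_to_first", [2, 1]),
        ([0, 14], "rolling", [2]),  # gap of exactly 14 stays in the episode
        ([], "rolling", []),
        ([0, 0, 5], "rolling", [2]),  # same-day duplicate merged
    ],
)
def test_gap_rule_examples(days, mode, expected_sizes):
    runs = group_visit_dates(to_dates(days), EpisodeConfig(gap_mode=mode))
    assert [len(r) for r in runs] == expected_sizes


def test_rolling_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(1, 13))
        days = sorted(set(rng.integers(0, 80, size=n).tolist()))
        got = [[(d - day(0)).days for d in run] for run in group_visit_dates(to_dates(days))]
        assert got == oracle_rolling_partition(days, 14)


def test_gap_monotonicity_and_visit_conservation():
    rng = np.random.default_rng(11)
    for _ in range(100):
        days = sorted(set(rng.integers(0, 200, size=int(rng.integers(1, 15))).tolist()))
        sizes = []
        for gap in (7, 14, 30):
            runs = group_visit_dates(to_dates(days), EpisodeConfig(gap_days=gap))
            assert sum(len(r) for r in runs) == len(days)
            sizes.append(len(runs))
        assert sizes[0] >= sizes[1] >= sizes[2]


def _children(**overrides):
    base = {
        "child_id": "K1",
        "birth_date": "2009-01-01",
        "sex": "M",
        "registration_date": "2009-01-15",
        "end_date": "2017-12-31",
        "preterm": 0,
        "comorbidity": 0,
    }
    base.update(overrides)
    return pd.DataFrame([base])


def test_assign_attributes_year_and_bands():
    children = _children(birth_date="2010-12-30")
    eps = pd.DataFrame(
        {
            "child_id": ["K1"],
            "onset_date": ["2012-12-30"],
            "last_visit_date": ["2013-01-05"],
            "n_visits": [2],
        }
    )
    out = assign_attributes(eps, children)
    assert out["calendar_year"].iloc[0] == 2012  # year of onset, not last visit
    assert out["age_band"].iloc[0] == "2-4"  # onset on the 2nd birthday


def test_assign_attributes_upper_age_boundary():
    children = _children(birth_date="2000-06-15")
    eps = pd.DataFrame(
        {
            "child_id": ["K1", "K1"],
            "onset_date": ["2015-06-14", "2015-06-15"],  # day before / on 15th birthday
            "last_visit_date": ["2015-06-14", "2015-06-15"],
            "n_visits": [1, 1],
        }
    )
    out = assign_attributes(eps, children)
    assert len(out) == 1 and out["age_band"].iloc[0] == "5-14"


def test_assign_attributes_onset_before_birth_raises():
    children = _children(birth_date="2012-01-01")
    eps = pd.DataFrame(
        {
            "child_id": ["K1"],
            "onset_date": ["2011-06-01"],
            "last_visit_date": ["2011-06-01"],
            "n_visits": [1],
        }
    )
    with pytest.raises(ValueError, match="before birth"):
        assign_attributes(eps, children)


def _episode_row(onset, child="K1"):
    return {
        "child_id": child,
        "onset_date": onset,
        "last_visit_date": onset,
        "n_visits": 1,
        "calendar_year": pd.Timestamp(onset).year,
        "age_band": "2-4",
    }


def _visits(child, dates):
    return pd.DataFrame({"child_id": child, "visit_date": dates})


@pytest.mark.parametrize(
    "birth,reason",
    [
        ("2009-01-01", "pre_index"),  # age 3 at index, registered ~4 months before
        ("2011-09-01", None),  # age ~0.5 at index: pre-index requirement waived
    ],
)
def test_pre_index_rule_and_infant_waiver(birth, reason):
    children = _children(birth_date=birth, registration_date="2011-11-01")
    eps = pd.DataFrame([_episode_row("2012-03-01")])
    visits = _visits("K1", ["2012-03-01", "2012-06-01"])
    retained, log = apply_eligibility(children, visits, eps, study_end="2017-12-31")
    if reason:
        assert len(retained) == 0 and list(log["reason"]) == [reason]
    else:
        assert len(retained) == 1 and len(log) == 0


def test_post_index_rule_and_study_end_waiver():
    children = _children(end_date="2012-09-01", registration_date="2010-01-01")
    eps = pd.DataFrame([_episode_row("2012-03-01")])
    visits = _visits("K1", ["2012-03-01", "2012-06-01"])
    retained, log = apply_eligibility(children, visits, eps, study_end="2017-12-31")
    assert list(log["reason"]) == ["post_index"]

    # index in the last study year with registration ongoing at study close
    children = _children(end_date="2017-12-31", registration_date="2010-01-01")
    eps = pd.DataFrame([_episode_row("2017-09-01")])
    visits = _visits("K1", ["2017-09-01", "2017-10-01"])
    retained, log = apply_eligibility(children, visits, eps, study_end="2017-12-31")
    assert len(retained) == 1 and len(log) == 0


def test_min_distinct_visits_and_missing_birth():
    children = _children()
    eps = pd.DataFrame([_episode_row("2012-03-01")])
    retained, log = apply_eligibility(
        children, _visits("K1", ["2012-03-01"]), eps, study_end="2017-12-31"
    )
    assert list(log["reason"]) == ["min_visits"]

    children = _children(birth_date=None)
    retained, log = apply_eligibility(
        children, _visits("K1", ["2012-03-01", "2012-06-01"]), eps, study_end="2017-12-31"
    )
    assert list(log["reason"]) == ["missing_age"]


def test_eligibility_drops_all_episodes_of_a_child():
    children = _children(end_date="2012-09-01", registration_date="2010-01-01")
    eps = pd.DataFrame([_episode_row("2012-03-01"), _episode_row("2012-08-01")])
    retained, log = apply_eligibility(
        children, _visits("K1", ["2012-03-01", "2012-08-01"]), eps, study_end="2017-12-31"
    )
    assert len(retained) == 0 and len(log) == 1


def test_build_episodes_table_multi_child(visit_table, case_def):
    from aomburden import identify_aom_visits

    rows = [
        ("A", 0, "382.9", ""),
        ("A", 10, "382.9", ""),
        ("A", 40, "382.9", ""),
        ("B", 5, "", "otite"),
    ]
    eps = build_episodes(identify_aom_visits(visit_table(rows), case_def))
    assert len(eps) == 3
    assert eps.groupby("child_id").size().to_dict() == {"A": 2, "B": 1}
    assert eps["n_visits"].sum() == 4


def test_config_validation():
    with pytest.raises(ValueError):
        EpisodeConfig(gap_days=0)
    with pytest.raises(ValueError):
        EpisodeConfig(gap_mode="sliding")
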