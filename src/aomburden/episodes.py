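"""Grouping AOM visits into episodes and applying cohort eligibility filters.

An episode is a maximal cluster of AOM-related visits: visits within 14 days
are follow-ups of the same episode, while a gap of more than 14 days opens a
new one. The default ``rolling`` mode measures the gap from the previous
visit; ``anchor_to_first`` measures it from the episode's first visit (the
two readings differ for chains of three or more visits).

Eligibility mirrors a claims-database cohort definition: a child's episodes
count only if the child was registered at least six months before the index
(first) episode — waived under one year of age — remained registered at
least twelve months after it, has a known birth date, and has at least two
distinct visit dates overall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .bands import DEFAULT_BANDS, age_years, band_of, birthday, max_age_years

logger = logging.getLogger(__name__)

#: mean Gregorian month length; 6 months -> 183 days, 12 months -> 365 days.
_DAYS_PER_MONTH = 30.4375


def months_to_days(months: int) -> int:
    return int(round(months * _DAYS_PER_MONTH))


@dataclass(frozen=True)
class EpisodeConfig:
    gap_days: int = 14
    gap_mode: str = "rolling"  # or "anchor_to_first"
    pre_index_months: int = 6
    post_index_months: int = 12
    pre_index_waiver_age_years: float = 1.0
    min_distinct_visits: int = 2
    #: whether min_distinct_visits counts visits of any kind or AOM visits only
    min_visits_scope: str = "all"  # or "aom"
    #: waive the post-index requirement when registration is ongoing at study end
    waive_post_index_at_study_end: bool = True

    def __post_init__(self):
        if self.gap_days < 1:
            raise ValueError("gap_days must be >= 1")
        if self.gap_mode not in ("rolling", "anchor_to_first"):
            raise ValueError(f"unknown gap_mode: {self.gap_mode!r}")
        if self.pre_index_months < 0 or self.post_index_months < 0:
            raise ValueError("eligibility windows must be non-negative")
        if self.min_visits_scope not in ("all", "aom"):
            raise ValueError(f"unknown min_visits_scope: {self.min_visits_scope!r}")

    @property
    def pre_index_days(self) -> int:
        return months_to_days(self.pre_index_months)

    @property
    def post_index_days(self) -> int:
        return months_to_days(self.post_index_months)


def group_visit_dates(dates, config: EpisodeConfig = EpisodeConfig()) -> list[list[pd.Timestamp]]:
    """Partition one child's visit dates into maximal episode runs.

    Same-day duplicates are merged into a single visit occurrence first.
    Returns a list of date lists, one per episode, in chronological order.
    """
    uniq = sorted({pd.Timestamp(d) for d in dates})
    if not uniq:
        return []
    episodes: list[list[pd.Timestamp]] = [[uniq[0]]]
    for d in uniq[1:]:
        anchor = episodes[-1][-1] if config.gap_mode == "rolling" else episodes[-1][0]
        if (d - anchor).days > config.gap_days:
            episodes.append([d])
        else:
            episodes[-1].append(d)
    return episodes


def build_episodes(
    aom_visits: pd.DataFrame, config: EpisodeConfig = EpisodeConfig()
) -> pd.DataFrame:
    """Group an AOM-visit table (all children) into an episode table.

    Output columns: child_id, onset_date, last_visit_date, n_visits.
    """
    records = []
    if len(aom_visits):
        visits = aom_visits.assign(visit_date=pd.to_datetime(aom_visits["visit_date"]))
        for child_id, grp in visits.groupby("child_id", sort=True):
            for run in group_visit_dates(grp["visit_date"], config):
                records.append(
                    {
                        "child_id": child_id,
                        "onset_date": run[0],
                        "last_visit_date": run[-1],
                        "n_visits": len(run),
                    }
                )
    return pd.DataFrame(
        records, columns=["child_id", "onset_date", "last_visit_date", "n_visits"]
    )


def assign_attributes(
    episodes: pd.DataFrame, children: pd.DataFrame, bands=DEFAULT_BANDS
) -> pd.DataFrame:
    """Attach calendar year, exact age at onset and age band to each episode.

    The calendar year is the onset year even when follow-up visits cross 1
    January. Band membership uses completed birthdays (an onset on the 2nd
    birthday is in the 2-4 band). Episodes at or beyond the oldest band's
    upper birthday fall outside the study population and are dropped; an
    onset before birth is corrupt data and raises.
    """
    if not len(episodes):
        return episodes.assign(calendar_year=[], age_at_onset=[], age_band=[])
    birth = children.set_index("child_id")["birth_date"].map(pd.Timestamp)
    ep = episodes.copy()
    ep["onset_date"] = pd.to_datetime(ep["onset_date"])
    b = ep["child_id"].map(birth)
    if (ep["onset_date"] < b).any():
        bad = ep.loc[ep["onset_date"] < b, "child_id"].iloc[0]
        raise ValueError(f"episode onset before birth for child {bad}")
    ep["calendar_year"] = ep["onset_date"].dt.year
    ep["age_at_onset"] = [age_years(bi, on) for bi, on in zip(b, ep["onset_date"])]
    ep["age_band"] = [band_of(bi, on, bands) for bi, on in zip(b, ep["onset_date"])]
    n_over = ep["age_band"].isna().sum()
    if n_over:
        logger.info("dropped %d episodes outside the age bands", n_over)
    return ep.loc[ep["age_band"].notna()].reset_index(drop=True)


def apply_eligibility(
    children: pd.DataFrame,
    visits: pd.DataFrame,
    episodes: pd.DataFrame,
    config: EpisodeConfig = EpisodeConfig(),
    study_end=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the child-level eligibility filters to an episode table.

    All episodes of a child stand or fall together; the exclusion log holds
    one reason per dropped child, the first failing check in the order
    missing_age, pre_index, post_index, min_visits.

    ``study_end`` enables the waiver of the 12-month post-index requirement
    for children whose registration is still open at study close.
    """
    if not len(episodes):
        return episodes.copy(), pd.DataFrame(columns=["child_id", "reason"])

    ch = children.set_index("child_id")
    birth = pd.to_datetime(ch["birth_date"], errors="coerce")
    reg = pd.to_datetime(ch["registration_date"], errors="coerce")
    end = pd.to_datetime(ch["end_date"], errors="coerce")
    study_end = pd.Timestamp(study_end) if study_end is not None else None

    ep = episodes.copy()
    ep["onset_date"] = pd.to_datetime(ep["onset_date"])
    index_onset = ep.groupby("child_id")["onset_date"].min()

    if config.min_visits_scope == "all":
        vis_pool = visits
    else:
        vis_pool = visits.loc[visits["child_id"].isin(ep["child_id"])]
    n_distinct = (
        vis_pool.assign(visit_date=pd.to_datetime(vis_pool["visit_date"]))
        .groupby("child_id")["visit_date"]
        .nunique()
    )

    dropped: list[tuple[str, str]] = []
    for child_id, idx in index_onset.items():
        b = birth.get(child_id, pd.NaT)
        if pd.isna(b):
            dropped.append((child_id, "missing_age"))
            continue
        r = reg.get(child_id, pd.NaT)
        age_at_index = age_years(b, idx)
        if (
            (pd.isna(r) or (idx - r).days < config.pre_index_days)
            and age_at_index >= config.pre_index_waiver_age_years
        ):
            dropped.append((child_id, "pre_index"))
            continue
        e = end.get(child_id, pd.NaT)
        ongoing = (
            config.waive_post_index_at_study_end
            and study_end is not None
            and not pd.isna(e)
            and e >= study_end
        )
        if not ongoing and (pd.isna(e) or (e - idx).days < config.post_index_days):
            dropped.append((child_id, "post_index"))
            continue
        if int(n_distinct.get(child_id, 0)) < config.min_distinct_visits:
            dropped.append((child_id, "min_visits"))
            continue

    log = pd.DataFrame(dropped, columns=["child_id", "reason"])
    retained = ep.loc[~ep["child_id"].isin(log["child_id"])].reset_index(drop=True)
    return retained, log
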