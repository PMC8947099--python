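"""Age-band arithmetic on exact birthdays.

Bands are defined by integer birthday edges: a child enters a band on the
morning of the lower-edge birthday and leaves on the morning of the
upper-edge birthday. The default bands are <2, 2-4 and 5-14 years, i.e.
edges at the 2nd, 5th and 15th birthdays.
"""

from __future__ import annotations

import pandas as pd

#: (label, lower birthday, upper birthday); intervals are [lower, upper).
DEFAULT_BANDS: tuple[tuple[str, int, int], ...] = (
    ("<2", 0, 2),
    ("2-4", 2, 5),
    ("5-14", 5, 15),
)


def band_labels(bands=DEFAULT_BANDS) -> list[str]:
    return [b[0] for b in bands]


def max_age_years(bands=DEFAULT_BANDS) -> int:
    """Upper birthday edge of the oldest band (15 for the defaults)."""
    return max(b[2] for b in bands)


def birthday(birth: pd.Timestamp, years: int) -> pd.Timestamp:
    """The ``years``-th birthday (29 Feb rolls back to 28 Feb off leap years)."""
    return pd.Timestamp(birth) + pd.DateOffset(years=years)


def age_years(birth: pd.Timestamp, on: pd.Timestamp) -> float:
    """Exact age in years (days / 365.25) on a given date."""
    return (pd.Timestamp(on) - pd.Timestamp(birth)).days / 365.25


def band_of(birth: pd.Timestamp, on: pd.Timestamp, bands=DEFAULT_BANDS) -> str | None:
    """Band label on date ``on`` for a child born ``birth``; None if out of range.

    Membership is decided by completed birthdays, not fractional age, so the
    boundary day itself belongs to the higher band.
    """
    birth = pd.Timestamp(birth)
    on = pd.Timestamp(on)
    for label, lo, hi in bands:
        if birthday(birth, lo) <= on < birthday(birth, hi):
            return label
    return None
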