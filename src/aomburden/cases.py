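"""Identification of AOM-related visits from diagnosis codes and free text.

A visit counts as AOM-related if any of its ICD-9-CM codes falls under the
otitis-media rubric 382.x, or if its free-text diagnosis matches one of the
otitis search patterns (``oti*``, ``*oti*``, ``om*``, ``*om*``) and is not on
an exclusion list of known false-positive strings. The exclusion list is a
reproducible stand-in for the manual expert review used when such databases
are curated by hand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

_CODE_DELIMS = re.compile(r"[;,|\s]+")

#: (mode, pattern) where mode is "prefix" (anchored at token start) or
#: "substring" (anywhere in a token).
DEFAULT_TEXT_PATTERNS: tuple[tuple[str, str], ...] = (
    ("prefix", "oti"),
    ("substring", "oti"),
    ("prefix", "om"),
    ("substring", "om"),
)


def load_exclusion_list(path=None) -> frozenset[str]:
    """Read an exclusion list: one string per line, ``#`` comments allowed.

    With no path, the small Italian-vocabulary fixture shipped with the
    package is used.
    """
    if path is None:
        text = (
            resources.files("aomburden").joinpath("data/exclusions_it.txt").read_text("utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    entries = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            entries.append(line)
    return frozenset(entries)


@dataclass(frozen=True)
class CaseDefinition:
    """Rules defining an AOM-related visit."""

    icd9_prefixes: tuple[str, ...] = ("382",)
    text_patterns: tuple[tuple[str, str], ...] = DEFAULT_TEXT_PATTERNS
    exclusion_list: frozenset[str] = field(default_factory=frozenset)
    case_sensitive: bool = False

    def __post_init__(self):
        if not self.icd9_prefixes:
            raise ValueError("icd9_prefixes must be non-empty")
        if not self.text_patterns:
            raise ValueError("text_patterns must be non-empty")
        for mode, pat in self.text_patterns:
            if mode not in ("prefix", "substring"):
                raise ValueError(f"unknown text pattern mode: {mode!r}")
            if not pat:
                raise ValueError("empty text pattern")
        # normalize exclusion entries consistently with case handling
        object.__setattr__(
            self,
            "exclusion_list",
            frozenset(self._normalize(e) for e in self.exclusion_list),
        )

    def _normalize(self, text: str) -> str:
        text = " ".join(str(text).split())
        return text if self.case_sensitive else text.casefold()


def match_icd9(code, definition: CaseDefinition = CaseDefinition()) -> bool:
    """True iff ``code`` falls under one of the configured rubric prefixes.

    Dots are ignored so "382", "382.0" and "38200" all match prefix "382";
    the prefix must anchor at the start of the code field, so "038.2" and
    "1382" do not.
    """
    if code is None or (isinstance(code, float) and pd.isna(code)):
        return False
    stripped = str(code).strip().replace(".", "")
    if not stripped:
        return False
    return any(stripped.startswith(p.replace(".", "")) for p in definition.icd9_prefixes)


def match_freetext(text, definition: CaseDefinition = CaseDefinition()) -> bool:
    """True iff any pattern matches a token of the normalized text and the
    full normalized text is not excluded."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return False
    norm = definition._normalize(text)
    if not norm:
        return False
    if norm in definition.exclusion_list:
        return False
    tokens = norm.split()
    for mode, pat in definition.text_patterns:
        pat_n = pat if definition.case_sensitive else pat.casefold()
        if mode == "prefix":
            if any(tok.startswith(pat_n) for tok in tokens):
                return True
        else:
            if any(pat_n in tok for tok in tokens):
                return True
    return False


def _any_code_matches(raw, definition: CaseDefinition) -> bool:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return False
    return any(
        match_icd9(c, definition) for c in _CODE_DELIMS.split(str(raw).strip()) if c
    )


def identify_aom_visits(
    visits: pd.DataFrame, definition: CaseDefinition = CaseDefinition()
) -> pd.DataFrame:
    """Filter a visit table down to AOM-related visits.

    The ``icd9`` field may hold several delimiter-separated codes (primary
    and secondary positions); all are checked. Output rows keep the input
    order and gain a ``match_rule`` column (``icd9``, ``text`` or ``both``).
    Rows whose ``visit_date`` cannot be parsed are rejected with a warning;
    the reject count is stored in ``result.attrs["n_rejected_dates"]``.
    """
    out = visits.copy()
    dates = pd.to_datetime(out["visit_date"], errors="coerce", format="ISO8601")
    n_bad = int(dates.isna().sum())
    if n_bad:
        logger.warning("rejected %d visit rows with unparseable dates", n_bad)
        out = out.loc[dates.notna()]
        dates = dates.loc[dates.notna()]
    out = out.assign(visit_date=dates)

    icd = out["icd9"].map(lambda c: _any_code_matches(c, definition)) if "icd9" in out else False
    txt = (
        out["free_text"].map(lambda t: match_freetext(t, definition))
        if "free_text" in out
        else False
    )
    icd = pd.Series(icd, index=out.index)
    txt = pd.Series(txt, index=out.index)
    keep = icd | txt
    result = out.loc[keep].copy()
    rule = pd.Series("icd9", index=result.index, dtype=object)
    rule[txt.loc[result.index] & ~icd.loc[result.index]] = "text"
    rule[txt.loc[result.index] & icd.loc[result.index]] = "both"
    result["match_rule"] = rule
    result.attrs["n_rejected_dates"] = n_bad
    return result
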