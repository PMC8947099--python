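import pandas as pd
import pytest

from aomburden import CaseDefinition, load_exclusion_list


@pytest.fixture(scope="session")
def case_def() -> CaseDefinition:
    """Default case definition with the packaged exclusion vocabulary."""
    return CaseDefinition(exclusion_list=load_exclusion_list())


def day(n: int, start: str = "2012-01-01") -> pd.Timestamp:
    """Day offset helper for constructing visit streams."""
    return pd.Timestamp(start) + pd.Timedelta(days=n)


@pytest.fixture
def visit_table():
    """Builder for small visit tables from (child, day, icd9, text) tuples."""

    def build(rows):
        return pd.DataFrame(
            [
                {
                    "child_id": r[0],
                    "visit_date": day(r[1]).strftime("%Y-%m-%d"),
                    "icd9": r[2],
                    "free_text": r[3],
                }
                for r in rows
            ]
        )

    return build
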