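import datetime as dt

import numpy as np
import pytest

from plateaurecord import CohortTable

BASE_DATE = dt.date(1900, 1, 1)


def cohort_from_lifespans(spans, group="g") -> CohortTable:
    """Build an extinct cohort whose exact lifespans approximate `spans`.

    Lifespans are realised as whole day counts, so the table's computed
    lifespans differ from the requested ones by at most half a day.
    """
    records = []
    for i, s in enumerate(spans):
        days = max(1, int(round(float(s) * 365.25)))
        records.append((f"r{i:04d}", BASE_DATE, BASE_DATE + dt.timedelta(days=days), group))
    return CohortTable.from_records(records)


@pytest.fixture
def small_cohort() -> CohortTable:
    """Three deaths at (approximately) ages 31, 40 and 50."""
    return cohort_from_lifespans([31.0, 40.0, 50.0])


def dkw_epsilon(n: int, alpha: float = 0.01) -> float:
    """Dvoretzky-Kiefer-Wolfowitz band half-width at confidence 1 - alpha."""
    return float(np.sqrt(np.log(2.0 / alpha) / (2.0 * n)))
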