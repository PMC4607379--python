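import numpy as np
import pandas as pd
import pytest

from ema_phq9 import CohortConfig, DEFAULT_DESIGN, generate_cohort


def make_records(rows):
    """Build a canonical response table from (sid, day, slot, item, value) tuples."""
    columns = [
        "subject_id",
        "study_day",
        "slot",
        "item_id",
        "polarity",
        "raw_value",
        "timestamp_iso8601",
        "canonical_value",
    ]
    data = [
        (sid, day, slot, item, "standard", value, "", value)
        for sid, day, slot, item, value in rows
    ]
    return pd.DataFrame(data, columns=columns)


def roster_of(config: CohortConfig) -> dict[str, int]:
    return {
        f"S{i + 1:02d}": d for i, d in enumerate(config.days_per_subject)
    }


@pytest.fixture
def design():
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150324)
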