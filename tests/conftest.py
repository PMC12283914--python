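import numpy as np
import pandas as pd
import pytest

from conformalbp import synth
from conformalbp.schema import COLUMNS, DAYTIME, FEATURES, NIGHTTIME


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 40-subject cohort with default (heteroscedastic) settings."""
    return synth.generate_cohort(synth.CohortConfig(n_subjects=40, seed=3))


@pytest.fixture(scope="session")
def homo_config() -> synth.CohortConfig:
    return synth.CohortConfig.homoscedastic(n_subjects=150, seed=5)


@pytest.fixture(scope="session")
def homo_cohort(homo_config) -> pd.DataFrame:
    return synth.generate_cohort(homo_config)


def make_records(rows) -> pd.DataFrame:
    """Build a toy feature table from (subject, iso_timestamp, phase, valid[, sbp]) tuples."""
    data = []
    for i, row in enumerate(rows):
        subject, ts, phase, valid = row[:4]
        sbp = row[4] if len(row) > 4 else 120.0 + i
        rec = {
            "subject_id": subject,
            "timestamp": pd.Timestamp(ts),
            "phase": phase,
            "sbp_ref": sbp,
            "dbp_ref": sbp - 45.0,
            "valid": valid,
        }
        for j, f in enumerate(FEATURES):
            rec[f] = float(10 * j + i)
        data.append(rec)
    return pd.DataFrame(data)[list(COLUMNS)]
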