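import numpy as np
import pandas as pd
import pytest

from riskstrat import CohortTable, generate_cohort, sepsis_default_config


@pytest.fixture(scope="session")
def sepsis_cohort_100():
    """Default synthetic sepsis cohort, n=100, fixed seed."""
    return generate_cohort(sepsis_default_config(n=100), seed=42)


@pytest.fixture(scope="session")
def sepsis_cohort_large():
    """Large cohort for Monte-Carlo calibration checks."""
    return generate_cohort(sepsis_default_config(n=200_000), seed=7)


@pytest.fixture()
def tiny_cohort():
    """Three-subject hand-built cohort."""
    df = pd.DataFrame(
        {
            "subject_id": ["p1", "p2", "p3"],
            "outcome": [1, 0, 0],
            "time": [3.0, 28.0, 28.0],
            "event": [1, 0, 0],
            "eNAPRT": [20.5, 4.2, np.nan],
            "CRP": [210.0, 95.0, 140.0],
        }
    )
    return CohortTable(data=df, biomarkers=["eNAPRT", "CRP"])


def make_cohort(values, outcomes, name="eNAPRT"):
    """Cohort from parallel biomarker/outcome sequences."""
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(values))],
            "outcome": list(outcomes),
            name: list(values),
        }
    )
    return CohortTable(data=df, biomarkers=[name])
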