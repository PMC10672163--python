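import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from neuromirnet.types import CountMatrix, SampleSheet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def small_matrix() -> CountMatrix:
    """3 features x 4 samples with hand-checkable counts."""
    counts = np.array(
        [
            [10, 20, 12, 24],
            [0, 0, 5, 5],
            [100, 200, 100, 200],
        ]
    )
    return CountMatrix(["fA", "fB", "fC"], ["s1", "s2", "s3", "s4"], counts)


@pytest.fixture
def small_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "cohort_id": "cohort1",
                "condition": ["control", "control", "case", "case"],
                "assigned_reads": [2_000_000, 3_000_000, 2_500_000, 4_000_000],
            }
        )
    )


def de_table(rows: list[tuple[str, float, float]]) -> pd.DataFrame:
    """Minimal DE result table from (feature_id, lfc, fdr) triples."""
    df = pd.DataFrame(rows, columns=["feature_id", "lfc", "fdr"])
    df["base_mean"] = 100.0
    df["se"] = 0.1
    df["wald"] = df["lfc"] / df["se"]
    df["pvalue"] = df["fdr"] / 2.0
    return df[["feature_id", "base_mean", "lfc", "se", "wald", "pvalue", "fdr"]]
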