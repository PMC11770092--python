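import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_transcript(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def single_cohort_matrix():
    """10 tumor / 10 non-tumor samples, 4 proteins with hand-set missingness."""
    from lepscan.screen import AbundanceMatrix

    samples = [f"T{i}" for i in range(10)] + [f"N{i}" for i in range(10)]
    meta = pd.DataFrame(
        {
            "cohort": ["kidney"] * 20,
            "group": ["tumor"] * 10 + ["nontumor"] * 10,
            "pair_id": [None] * 20,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        np.exp2(rng.normal(25, 0.5, size=(4, 20))),
        index=["P1", "P2", "P3", "P4"],
        columns=samples,
    )
    # P2: present in exactly 4/10 tumor, 0/10 nontumor
    values.loc["P2", [f"T{i}" for i in range(4, 10)]] = np.nan
    values.loc["P2", [f"N{i}" for i in range(10)]] = np.nan
    # P3: present in exactly 3/10 of each group (30% is not > 30%)
    values.loc["P3", [f"T{i}" for i in range(3, 10)]] = np.nan
    values.loc["P3", [f"N{i}" for i in range(3, 10)]] = np.nan
    # P4: present in 4/10 tumor (40% fails the 50% DE rule), all nontumor
    values.loc["P4", [f"T{i}" for i in range(4, 10)]] = np.nan
    return AbundanceMatrix(values, meta)
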