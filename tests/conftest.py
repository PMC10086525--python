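import numpy as np
import pandas as pd
import pytest

from agesig import simdata


@pytest.fixture(scope="session")
def small_config():
    """A small two-tissue study used across integration-style tests."""
    return simdata.SimConfig(
        seed=7,
        tissues=("PBL", "spleen"),
        n_genes=600,
        replicates_per_age=4,
        chrom_length=1_000_000,
        n_peaks=200,
        footprints_per_group=800,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simdata.generate_study(small_config)


@pytest.fixture()
def toy_counts():
    """5 genes x 3 samples with one composition-shifted gene (gene d)."""
    data = {
        "a": [100, 200, 300, 400, 500],
        "b": [150, 210, 280, 800, 520],
        "c": [90, 220, 350, 390, 510],
    }
    return pd.DataFrame(data, index=list("vwxyz"))


def two_group_samples(n_per_group=6, ages=(3.0, 18.0)):
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "strain": "B6",
            "tissue": "PBL",
            "age_months": np.repeat(ages, n_per_group),
            "sex": np.tile(["F", "M"], n)[:n],
        },
        index=[f"s{i}" for i in range(n)],
    )
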