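import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metaboflux.table import ConcentrationTable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_table(values: dict[str, np.ndarray], groups: list[str],
               tissue: str = "maternal_heart",
               group_order: tuple[str, str] = ("sham", "rupp")) -> ConcentrationTable:
    """Assemble a ConcentrationTable from per-metabolite value arrays."""
    n = len(groups)
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "tissue": tissue,
        "group": groups,
        "wet_weight_g": 0.1,
        **values,
    })
    return ConcentrationTable(df, group_order=list(group_order))


@pytest.fixture
def two_group_table():
    rng = np.random.default_rng(42)
    groups = ["sham"] * 5 + ["rupp"] * 5
    return make_table(
        {
            "glucose": rng.lognormal(0.7, 0.15, 10),
            "lactate": rng.lognormal(1.6, 0.15, 10),
            "ATP": rng.lognormal(1.4, 0.15, 10),
        },
        groups,
    )


@pytest.fixture(scope="session")
def reduced_network():
    from metaboflux.flux import reduced_cardiomyocyte_network

    return reduced_cardiomyocyte_network()
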