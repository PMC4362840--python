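import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diffpath as dp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_group_design():
    """Balanced one-factor design: 3 WT + 3 MKR samples."""
    return dp.SampleDesign(
        sample_ids=("WT_1", "WT_2", "WT_3", "MKR_1", "MKR_2", "MKR_3"),
        factor_a=("WT",) * 3 + ("MKR",) * 3,
    )


@pytest.fixture
def crossed_design():
    """Balanced 2x2 crossed design with 2 replicates per cell."""
    return dp.SampleDesign(
        sample_ids=tuple(f"s{i}" for i in range(8)),
        factor_a=("A1",) * 4 + ("A2",) * 4,
        factor_b=("B1", "B1", "B2", "B2") * 2,
    )


@pytest.fixture
def fat_table():
    return dp.datasets.load_gene_table("fat")


@pytest.fixture
def treated_fat_table():
    return dp.datasets.load_gene_table("treated_fat")


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)
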