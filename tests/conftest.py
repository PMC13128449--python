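import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chronosere import (
    AbundanceTable,
    Category,
    GeneratorConfig,
    PlotRecord,
    generate_community_chronosequence,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_plots() -> list[PlotRecord]:
    """2 active cacao, 3 secondary cacao, 3 old-growth."""
    return [
        PlotRecord("A1", Category.ACTIVE_CACAO, 0),
        PlotRecord("A2", Category.ACTIVE_CACAO, 0),
        PlotRecord("S1", Category.SECONDARY_CACAO, 5),
        PlotRecord("S2", Category.SECONDARY_CACAO, 15),
        PlotRecord("S3", Category.SECONDARY_CACAO, 30),
        PlotRecord("O1", Category.OLD_GROWTH, None),
        PlotRecord("O2", Category.OLD_GROWTH, None),
        PlotRecord("O3", Category.OLD_GROWTH, None),
    ]


@pytest.fixture
def toy_table(toy_plots) -> AbundanceTable:
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.integers(0, 30, size=(6, len(toy_plots))).astype(float),
        index=[f"sp{i}" for i in range(6)],
        columns=[rec.plot_id for rec in toy_plots],
    )
    return AbundanceTable("toy", data)


@pytest.fixture(scope="session")
def community_dataset():
    """One default-condition synthetic chronosequence (cacao legacy)."""
    plots, table, truth = generate_community_chronosequence(
        GeneratorConfig(seed=11), "cacao"
    )
    return plots, table, truth


def random_abundance_matrix(rng: np.random.Generator, n_species=None, sparse=0.4):
    """Small random paired abundance vectors with overlapping support."""
    s = n_species or rng.integers(3, 12)
    a = rng.gamma(1.0, 5.0, s) * (rng.random(s) > sparse)
    b = rng.gamma(1.0, 5.0, s) * (rng.random(s) > sparse)
    if a.sum() == 0:
        a[rng.integers(s)] = 1.0
    if b.sum() == 0:
        b[rng.integers(s)] = 1.0
    return a, b
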