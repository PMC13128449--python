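"""Hill numbers, pairwise similarities and reference-series construction.

The Hill-partition overlap transforms are validated against
independently coded classical indices (Sorensen, Horn, Morisita-Horn),
which pin down the two-assemblage alpha convention.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import chronosere as cs
from chronosere.errors import UndefinedInputError, ValidationError

from conftest import random_abundance_matrix


# --- independent classical-index oracles ----------------------------------


def sorensen(a, b):
    pa, pb = np.asarray(a) > 0, np.asarray(b) > 0
    shared = np.logical_and(pa, pb).sum()
    return 2 * shared / (pa.sum() + pb.sum())


def horn(a, b):
    p = np.asarray(a, float) / np.sum(a)
    q = np.asarray(b, float) / np.sum(b)
    s = p + q
    term = lambda x: np.sum(x[x > 0] * np.log(x[x > 0]))
    return (term(s) - term(p) - term(q)) / (2 * math.log(2))


def morisita_horn(a, b):
    p = np.asarray(a, float) / np.sum(a)
    q = np.asarray(b, float) / np.sum(b)
    return 2 * np.sum(p * q) / (np.sum(p**2) + np.sum(q**2))


# --- per-plot metrics ------------------------------------------------------


def test_total_abundance_sums_counts():
    assert cs.total_abundance([3, 0, 7]) == 10
    assert cs.total_abundance([0, 0]) == 0
    assert cs.total_abundance([1.5, 2.5]) == 4.0


@pytest.mark.parametrize(
    "column, q, expected",
    [
        ([5, 5, 5, 5], 0, 4.0),
        ([5, 5, 5, 5], 1, 4.0),
        ([5, 5, 5, 5], 2, 4.0),
        ([75, 25], 0, 2.0),
        ([75, 25], 1, 1.7548),
        ([75, 25], 2, 1.6),
        ([9], 0, 1.0),
        ([9], 1, 1.0),
        ([9], 2, 1.0),
    ],
)
def test_hill_alpha_known_values(column, q, expected):
    assert cs.hill_alpha(column, q) == pytest.approx(expected, abs=1e-4)


def test_hill_alpha_rejects_all_zero():
    with pytest.raises(UndefinedInputError):
        cs.hill_alpha([0, 0, 0], 1)


@given(
    arrays(
        float,
        st.integers(2, 15),
        elements=st.floats(0, 100, allow_nan=False),
    ).filter(lambda x: x.sum() > 0)
)
def test_hill_numbers_decrease_with_order(column):
    """Effective species numbers are non-increasing in q."""
    h0, h1, h2 = (cs.hill_alpha(column, q) for q in (0, 1, 2))
    assert h0 + 1e-9 >= h1 >= h2 - 1e-9
    assert h2 >= 1.0


# --- pairwise similarities -------------------------------------------------


@pytest.mark.parametrize("q", [0, 1, 2])
def test_hill_beta_similarity_identical_and_disjoint(q):
    assert cs.hill_beta_similarity([3, 1, 2], [3, 1, 2], q) == pytest.approx(1.0)
    if q == 0:
        assert cs.hill_beta_similarity([5, 5, 0, 0], [0, 0, 5, 5], 0) == pytest.approx(0.0)


def test_hill_beta_similarity_sorensen_example():
    # one shared, one unique species each: 2a/(2a+b+c) = 2/4
    assert cs.hill_beta_similarity([10, 10, 0], [0, 10, 10], 0) == pytest.approx(0.5)


def test_hill_beta_matches_classical_indices_on_random_pairs():
    """Sorensen (q=0), Horn (q=1) and Morisita-Horn (q=2) to 1e-10."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        a, b = random_abundance_matrix(rng)
        assert cs.hill_beta_similarity(a, b, 0) == pytest.approx(sorensen(a, b), abs=1e-10)
        assert cs.hill_beta_similarity(a, b, 1) == pytest.approx(horn(a, b), abs=1e-10)
        assert cs.hill_beta_similarity(a, b, 2) == pytest.approx(
            morisita_horn(a, b), abs=1e-10
        )


def test_bray_curtis_similarity_values():
    assert cs.bray_curtis_similarity([2, 4], [1, 2]) == pytest.approx(1.0)
    assert cs.bray_curtis_similarity([5, 0], [0, 3]) == pytest.approx(0.0)
    assert cs.bray_curtis_similarity([0.75, 0.25, 0], [0, 0.25, 0.75]) == pytest.approx(0.25)


def test_jaccard_similarity_values():
    assert cs.jaccard_similarity([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(0.5)
    assert cs.jaccard_similarity([1, 1], [1, 1]) == pytest.approx(1.0)
    assert cs.jaccard_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    with pytest.raises(UndefinedInputError):
        cs.jaccard_similarity([0, 0], [0, 0])


def test_zero_total_vector_rejected():
    for fn in (
        lambda: cs.bray_curtis_similarity([0, 0], [1, 2]),
        lambda: cs.hill_beta_similarity([0, 0], [1, 2], 1),
    ):
        with pytest.raises(UndefinedInputError):
            fn()


@given(
    st.integers(0, 2**31 - 1),
    st.floats(0.1, 50, allow_nan=False),
)
def test_similarities_symmetric_and_scale_invariant(seed, scale):
    """All pair metrics are symmetric; rescaling one plot's counts by a
    positive constant changes nothing (relative abundances)."""
    rng = np.random.default_rng(seed)
    a, b = random_abundance_matrix(rng)
    for metric in cs.Metric.BRAY_CURTIS_SIM, cs.Metric.HILL_BETA_SIM_Q1, cs.Metric.JACCARD_SIM:
        try:
            ab = cs.pairwise_similarity(a, b, metric)
        except UndefinedInputError:
            continue
        assert ab == pytest.approx(cs.pairwise_similarity(b, a, metric), abs=1e-12)
        assert ab == pytest.approx(cs.pairwise_similarity(a * scale, b, metric), abs=1e-9)
        assert 0.0 <= ab <= 1.0


# --- series construction ---------------------------------------------------


def _table(columns: dict[str, list[float]], taxon="t") -> cs.AbundanceTable:
    return cs.AbundanceTable(taxon, pd.DataFrame(columns, dtype=float))


def test_reference_series_hand_example():
    """3 old-growth plots with pairwise Bray-Curtis 0.8/0.6/0.4 give
    per-plot means (0.7, 0.6, 0.5) and psiRef = their median 0.6."""
    plots = [
        cs.PlotRecord("A1", cs.Category.ACTIVE_CACAO, 0),
        cs.PlotRecord("A2", cs.Category.ACTIVE_CACAO, 0),
        cs.PlotRecord("S1", cs.Category.SECONDARY_CACAO, 10),
        cs.PlotRecord("O1", cs.Category.OLD_GROWTH, None),
        cs.PlotRecord("O2", cs.Category.OLD_GROWTH, None),
        cs.PlotRecord("O3", cs.Category.OLD_GROWTH, None),
    ]
    # two-species compositions: BC(x, y) = 1 - |x1 - y1|
    table = _table(
        {
            "A1": [1, 9],
            "A2": [2, 8],
            "S1": [3, 7],
            "O1": [4, 6],
            "O2": [2, 8],
            "O3": [8, 2],
        }
    )
    series = cs.similarity_to_reference_series(table, plots, cs.Metric.BRAY_CURTIS_SIM)[
        cs.Legacy.CACAO
    ]
    assert series.psi_ref == pytest.approx(0.6)
    assert dict((p, v) for p, v in series.og_values) == pytest.approx(
        {"O1": 0.7, "O2": 0.6, "O3": 0.5}
    )
    assert series.center_rule == "median"


def test_reference_series_identical_plots_all_one():
    plots = [
        cs.PlotRecord("A1", cs.Category.ACTIVE_CACAO, 0),
        cs.PlotRecord("S1", cs.Category.SECONDARY_CACAO, 3),
        cs.PlotRecord("O1", cs.Category.OLD_GROWTH, None),
        cs.PlotRecord("O2", cs.Category.OLD_GROWTH, None),
    ]
    table = _table({p.plot_id: [5, 5, 10] for p in plots})
    series = cs.similarity_to_reference_series(table, plots)[cs.Legacy.CACAO]
    assert series.psi_ref == pytest.approx(1.0)
    assert np.allclose(series.values, 1.0)


def test_reference_series_needs_two_old_growth(toy_table, toy_plots):
    keep = [r for r in toy_plots if r.plot_id != "O1" and r.plot_id != "O2"]
    table = toy_table.subset_plots([r.plot_id for r in keep])
    with pytest.raises(ValidationError):
        cs.similarity_to_reference_series(table, keep)


def test_center_rule_switches_to_mean_when_og_median_zero():
    """Old-growth abundances (0, 0, 5): median 0 -> mean rule, psiRef = 5/3."""
    plots = [
        cs.PlotRecord("A1", cs.Category.ACTIVE_CACAO, 0),
        cs.PlotRecord("A2", cs.Category.ACTIVE_CACAO, 0),
        cs.PlotRecord("S1", cs.Category.SECONDARY_CACAO, 4),
        cs.PlotRecord("O1", cs.Category.OLD_GROWTH, None),
        cs.PlotRecord("O2", cs.Category.OLD_GROWTH, None),
        cs.PlotRecord("O3", cs.Category.OLD_GROWTH, None),
    ]
    table = _table(
        {"A1": [1, 2], "A2": [3, 0], "S1": [2, 2], "O1": [0, 0], "O2": [0, 0], "O3": [5, 0]}
    )
    series = cs.metric_series_for(table, plots, cs.Metric.ABUNDANCE)[cs.Legacy.CACAO]
    assert series.center_rule == "mean"
    assert series.psi_ref == pytest.approx(5 / 3)
    assert series.psi0 == pytest.approx(3.0)  # mean rule applies to psi0 too


def test_metric_series_median_center_by_default():
    plots = [
        cs.PlotRecord("A1", cs.Category.ACTIVE_CACAO, 0),
        cs.PlotRecord("S1", cs.Category.SECONDARY_CACAO, 4),
        cs.PlotRecord("O1", cs.Category.OLD_GROWTH, None),
        cs.PlotRecord("O2", cs.Category.OLD_GROWTH, None),
        cs.PlotRecord("O3", cs.Category.OLD_GROWTH, None),
    ]
    table = _table(
        {"A1": [1, 1], "S1": [2, 2], "O1": [2, 0], "O2": [4, 0], "O3": [6, 0]}
    )
    series = cs.metric_series_for(table, plots, cs.Metric.ABUNDANCE)[cs.Legacy.CACAO]
    assert series.center_rule == "median"
    assert series.psi_ref == pytest.approx(4.0)


def test_series_requires_active_plots():
    plots = [
        cs.PlotRecord("S1", cs.Category.SECONDARY_CACAO, 4),
        cs.PlotRecord("S2", cs.Category.SECONDARY_CACAO, 9),
        cs.PlotRecord("O1", cs.Category.OLD_GROWTH, None),
        cs.PlotRecord("O2", cs.Category.OLD_GROWTH, None),
    ]
    table = _table({p.plot_id: [1, 2] for p in plots})
    with pytest.raises(ValidationError, match="psi0"):
        cs.metric_series(table, plots, cs.Metric.ABUNDANCE)


def test_pairwise_similarity_table_long_format(toy_table):
    out = cs.pairwise_similarity_table(toy_table, [cs.Metric.BRAY_CURTIS_SIM])
    n = len(toy_table.plot_ids)
    assert len(out) == n * (n - 1) // 2
    assert set(out.columns) == {"plot_a", "plot_b", "metric", "value"}
    assert out["value"].between(0, 1).all()
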