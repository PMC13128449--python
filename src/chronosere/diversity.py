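"""Per-plot diversity metrics and compositional similarity to reference.

Alpha diversity is expressed as Hill numbers (effective numbers of
species) of orders q = 0 (richness), q = 1 (exponential Shannon
entropy) and q = 2 (inverse Simpson concentration). Compositional
similarity between two plots is computed either as Bray-Curtis
similarity on relative abundances, as presence/absence Jaccard, or via
the multiplicative diversity partition for a pair of equally weighted
assemblages,

    qD_beta = qD_gamma / qD_alpha  in [1, 2],

transformed to a community overlap in [0, 1]:

    overlap_q = ((1/qD_beta)^(q-1) - (1/2)^(q-1)) / (1 - (1/2)^(q-1))

for q != 1, and overlap_1 = (ln 2 - H_beta,Shannon)/ln 2 in the q -> 1
limit. These overlaps coincide with the classical Sorensen (q = 0),
Horn (q = 1) and Morisita-Horn (q = 2) indices, which is how the
implementation is cross-checked.

The similarity of a disturbed or recovering plot to the old-growth
state is its mean pairwise similarity to every old-growth plot; the
reference value psiRef is the median, over old-growth plots, of each
plot's mean similarity to the remaining old-growth plots.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from scipy.special import xlogy

from .errors import UndefinedInputError, ValidationError
from .io import (
    SIMILARITY_METRICS,
    AbundanceTable,
    Legacy,
    Metric,
    MetricSeries,
    PlotRecord,
)

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


def _as_vector(x, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0 or not np.all(np.isfinite(v)) or (v < 0).any():
        raise UndefinedInputError(f"{name}: finite non-negative vector required")
    return v


def total_abundance(column) -> float:
    """Total number of individuals recorded in one plot."""
    return float(_as_vector(column, "abundance column").sum())


def hill_alpha(column, q: float) -> float:
    """Hill number of order q for one plot (effective number of species).

    q = 0 counts species with positive abundance; q = 1 is the
    exponential of the Shannon entropy of relative abundances; q = 2 is
    the inverse Simpson concentration. Always >= 1 on valid input.
    """
    v = _as_vector(column, "abundance column")
    total = v.sum()
    if total == 0:
        raise UndefinedInputError("hill_alpha undefined on an all-zero column")
    p = v[v > 0] / total
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(xlogy(p, p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _relative(v: np.ndarray, name: str) -> np.ndarray:
    total = v.sum()
    if total == 0:
        raise UndefinedInputError(f"{name}: zero-total abundance vector")
    return v / total


def hill_beta(col_a, col_b, q: float) -> float:
    """Beta diversity qD_beta = qD_gamma / qD_alpha for one plot pair.

    Both assemblages are weighted equally: alpha pools the within-plot
    relative abundances halved across the joint assemblage, gamma is
    the Hill number of the mean relative-abundance profile. Lies in
    [1, 2]; 1 for identical compositions, 2 for disjoint ones.
    """
    pa = _relative(_as_vector(col_a, "col_a"), "col_a")
    pb = _relative(_as_vector(col_b, "col_b"), "col_b")
    if pa.size != pb.size:
        raise ValidationError("paired columns must have equal length")
    joint = np.concatenate([pa, pb]) / 2.0
    joint = joint[joint > 0]
    pooled = (pa + pb) / 2.0
    pooled = pooled[pooled > 0]
    if q == 1:
        alpha = np.exp(-np.sum(xlogy(joint, joint))) / 2.0
        gamma = np.exp(-np.sum(xlogy(pooled, pooled)))
    elif q == 0:
        alpha = joint.size / 2.0
        gamma = float(pooled.size)
    else:
        alpha = np.sum(joint**q) ** (1.0 / (1.0 - q)) / 2.0
        gamma = np.sum(pooled**q) ** (1.0 / (1.0 - q))
    return float(min(max(gamma / alpha, 1.0), 2.0))


def hill_beta_similarity(col_a, col_b, q: float) -> float:
    """Community overlap of order q for one plot pair, in [0, 1]."""
    d_beta = hill_beta(col_a, col_b, q)
    if q == 1:
        overlap = (LN2 - math.log(d_beta)) / LN2
    else:
        half = 0.5 ** (q - 1.0)
        overlap = ((1.0 / d_beta) ** (q - 1.0) - half) / (1.0 - half)
    return float(min(max(overlap, 0.0), 1.0))


def bray_curtis_similarity(col_a, col_b) -> float:
    """1 - Bray-Curtis dissimilarity on relative abundances."""
    pa = _relative(_as_vector(col_a, "col_a"), "col_a")
    pb = _relative(_as_vector(col_b, "col_b"), "col_b")
    if pa.size != pb.size:
        raise ValidationError("paired columns must have equal length")
    return float(min(max(1.0 - braycurtis(pa, pb), 0.0), 1.0))


def jaccard_similarity(col_a, col_b) -> float:
    """|intersection| / |union| on presence/absence."""
    a = _as_vector(col_a, "col_a") > 0
    b = _as_vector(col_b, "col_b") > 0
    if a.size != b.size:
        raise ValidationError("paired columns must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedInputError("jaccard undefined on an empty union")
    return float(np.logical_and(a, b).sum() / union)


def pairwise_similarity(col_a, col_b, metric: Metric) -> float:
    metric = Metric(metric)
    if metric is Metric.BRAY_CURTIS_SIM:
        return bray_curtis_similarity(col_a, col_b)
    if metric is Metric.JACCARD_SIM:
        return jaccard_similarity(col_a, col_b)
    if metric is Metric.HILL_BETA_SIM_Q0:
        return hill_beta_similarity(col_a, col_b, 0)
    if metric is Metric.HILL_BETA_SIM_Q1:
        return hill_beta_similarity(col_a, col_b, 1)
    if metric is Metric.HILL_BETA_SIM_Q2:
        return hill_beta_similarity(col_a, col_b, 2)
    raise ValidationError(f"{metric} is not a pairwise similarity metric")


def pairwise_similarity_table(
    table: AbundanceTable, metrics: Sequence[Metric] | None = None
) -> pd.DataFrame:
    """All unordered plot pairs in long format (plot_a, plot_b, metric, value)."""
    metrics = [Metric(m) for m in (metrics or [Metric.BRAY_CURTIS_SIM])]
    table = table.drop_zero_species()
    rows = []
    ids = table.plot_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            for metric in metrics:
                try:
                    value = pairwise_similarity(table.column(a), table.column(b), metric)
                except UndefinedInputError:
                    continue
                rows.append({"plot_a": a, "plot_b": b, "metric": metric.value, "value": value})
    return pd.DataFrame(rows, columns=["plot_a", "plot_b", "metric", "value"])


# ---------------------------------------------------------------------------
# series construction
# ---------------------------------------------------------------------------


def _center(values: np.ndarray, rule: str) -> float:
    return float(np.mean(values)) if rule == "mean" else float(np.median(values))


def _center_rule(og_values: np.ndarray) -> str:
    """Median by default; mean when the old-growth median is 0 (recovery
    toward a reference of 0 is not biologically meaningful)."""
    return "mean" if float(np.median(og_values)) == 0.0 else "median"


def _split_plots(
    table: AbundanceTable, plots: Sequence[PlotRecord]
) -> tuple[list[PlotRecord], dict[Legacy, list[PlotRecord]]]:
    by_id = {rec.plot_id: rec for rec in plots}
    unknown = [p for p in table.plot_ids if p not in by_id]
    if unknown:
        raise ValidationError(f"abundance columns without plot records: {unknown}")
    sampled = [by_id[p] for p in table.plot_ids]
    og = [rec for rec in sampled if rec.is_old_growth]
    per_legacy: dict[Legacy, list[PlotRecord]] = {}
    for rec in sampled:
        if not rec.is_old_growth:
            per_legacy.setdefault(rec.legacy, []).append(rec)
    return og, per_legacy


def _build_series(
    metric: Metric,
    legacy: Legacy,
    recs: list[PlotRecord],
    values: dict[str, float],
    og_values: list[tuple[str, float]],
) -> MetricSeries:
    og_arr = np.array([v for _, v in og_values], dtype=float)
    rule = _center_rule(og_arr)
    psi_ref = _center(og_arr, rule)
    points = [
        (rec.plot_id, float(rec.age_years), values[rec.plot_id])
        for rec in recs
        if rec.plot_id in values
    ]
    active = np.array([v for _, t, v in points if t == 0], dtype=float)
    if active.size == 0:
        raise ValidationError(
            f"{metric.value}/{legacy.value}: no active plots, psi0 undefined"
        )
    psi0 = _center(active, rule)
    return MetricSeries(
        metric=metric,
        legacy=legacy,
        points=points,
        psi0=psi0,
        psi_ref=psi_ref,
        center_rule=rule,
        og_values=og_values,
    )


def similarity_to_reference_series(
    table: AbundanceTable,
    plots: Sequence[PlotRecord],
    metric: Metric = Metric.BRAY_CURTIS_SIM,
) -> dict[Legacy, MetricSeries]:
    """Similarity-to-old-growth series per legacy.

    Each active or secondary plot's value is its mean pairwise
    similarity to every old-growth plot; each old-growth plot's value is
    its mean similarity to the other old-growth plots, and psiRef is the
    center (median by default) of those values.
    """
    metric = Metric(metric)
    if metric not in SIMILARITY_METRICS:
        raise ValidationError(f"{metric.value} is not a similarity metric")
    table = table.drop_zero_species()
    og, per_legacy = _split_plots(table, plots)
    if len(og) < 2:
        raise ValidationError(
            f"need >= 2 old-growth plots to build a reference, got {len(og)}"
        )

    def mean_sim_to(plot_id: str, references: list[PlotRecord]) -> float:
        col = table.column(plot_id)
        sims = [
            pairwise_similarity(col, table.column(ref.plot_id), metric)
            for ref in references
            if ref.plot_id != plot_id
        ]
        return float(np.mean(sims))

    og_values = []
    for rec in og:
        try:
            og_values.append((rec.plot_id, mean_sim_to(rec.plot_id, og)))
        except UndefinedInputError as exc:
            logger.warning("old-growth plot %s dropped: %s", rec.plot_id, exc)
    if len(og_values) < 2:
        raise ValidationError("fewer than 2 usable old-growth plots")

    out: dict[Legacy, MetricSeries] = {}
    for legacy, recs in per_legacy.items():
        values: dict[str, float] = {}
        for rec in recs:
            try:
                values[rec.plot_id] = mean_sim_to(rec.plot_id, og)
            except UndefinedInputError as exc:
                logger.warning(
                    "plot %s dropped from %s/%s series: %s",
                    rec.plot_id,
                    metric.value,
                    legacy.value,
                    exc,
                )
        out[legacy] = _build_series(metric, legacy, recs, values, og_values)
    return out


def metric_series_for(
    table: AbundanceTable,
    plots: Sequence[PlotRecord],
    metric: Metric,
) -> dict[Legacy, MetricSeries]:
    """Per-plot scalar series (abundance or alpha Hill number) per legacy."""
    metric = Metric(metric)
    fns = {
        Metric.ABUNDANCE: total_abundance,
        Metric.HILL_Q0: lambda c: hill_alpha(c, 0),
        Metric.HILL_Q1: lambda c: hill_alpha(c, 1),
        Metric.HILL_Q2: lambda c: hill_alpha(c, 2),
    }
    if metric not in fns:
        raise ValidationError(f"{metric.value} is not a per-plot scalar metric")
    fn = fns[metric]
    table = table.drop_zero_species()
    og, per_legacy = _split_plots(table, plots)
    if not og:
        raise ValidationError("no old-growth plots, psiRef undefined")

    def value_of(plot_id: str) -> float | None:
        try:
            return fn(table.column(plot_id))
        except UndefinedInputError as exc:
            logger.warning("plot %s dropped from %s series: %s", plot_id, metric.value, exc)
            return None

    og_values = [
        (rec.plot_id, v) for rec in og if (v := value_of(rec.plot_id)) is not None
    ]
    if not og_values:
        raise ValidationError("no usable old-growth plots")
    out: dict[Legacy, MetricSeries] = {}
    for legacy, recs in per_legacy.items():
        values = {
            rec.plot_id: v for rec in recs if (v := value_of(rec.plot_id)) is not None
        }
        out[legacy] = _build_series(metric, legacy, recs, values, og_values)
    return out


def metric_series(
    table: AbundanceTable,
    plots: Sequence[PlotRecord],
    metric: Metric,
) -> dict[Legacy, MetricSeries]:
    """Dispatch to the scalar or similarity-to-reference series builder."""
    metric = Metric(metric)
    if metric in SIMILARITY_METRICS:
        return similarity_to_reference_series(table, plots, metric)
    return metric_series_for(table, plots, metric)
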