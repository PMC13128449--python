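"""Leave-one-plot-out jackknife confidence bands.

Each replicate deletes one plot — any plot of the focal legacy or any
old-growth plot (the reference is shared by both legacies) — and reruns
the entire pipeline from the abundance matrix, so similarity-to-
reference values and psiRef are recomputed when a reference plot is
removed. 95% intervals are percentile intervals (linear interpolation
between order statistics) over the replicate statistics; for curves, a
pointwise percentile envelope over the replicate trajectories. The
jackknife is preferred over the bootstrap here because with this few
plots a bootstrap replicate omits too much of the data to support the
nonlinear fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ChronosereError, ValidationError
from .io import AbundanceTable, Legacy, Metric, PlotRecord
from .resilience import (
    DEFAULT_ALPHA,
    DEFAULT_CAP_YEARS,
    DEFAULT_T_EVAL,
    Classification,
    RecoveryFit,
    ResilienceSummary,
    analyze_taxon,
)

logger = logging.getLogger(__name__)

DEFAULT_LEVEL = 0.95


@dataclass
class JackknifeEnsemble:
    """n leave-one-out replicates of the resilience decomposition."""

    taxon: str
    metric: Metric
    legacy: Legacy
    replicates: list[ResilienceSummary]
    deleted_plots: list[str]
    excluded: dict[str, str] = field(default_factory=dict)
    cap_years: float = DEFAULT_CAP_YEARS

    @property
    def n(self) -> int:
        return len(self.replicates) + len(self.excluded)

    @property
    def curves(self) -> list[RecoveryFit]:
        return [rep.fit for rep in self.replicates if rep.fit is not None]


def jackknife(
    table: AbundanceTable,
    plots: list[PlotRecord],
    metric: Metric,
    legacy: Legacy,
    cap_years: float = DEFAULT_CAP_YEARS,
    t_eval: float = DEFAULT_T_EVAL,
    alpha: float = DEFAULT_ALPHA,
    fit_mode: str = "fixed",
) -> JackknifeEnsemble:
    """One replicate per eligible plot, each a full rerun on n-1 plots.

    Eligible plots are the sampled plots of the focal legacy plus all
    sampled old-growth plots. Replicates rendered degenerate by the
    deletion (for example no active plot left) are excluded and logged.
    """
    legacy = Legacy(legacy)
    metric = Metric(metric)
    sampled = {p for p in table.plot_ids}
    eligible = [
        rec.plot_id
        for rec in plots
        if rec.plot_id in sampled and (rec.legacy is legacy or rec.is_old_growth)
    ]
    if not eligible:
        raise ValidationError(f"no eligible plots for legacy {legacy.value}")
    replicates: list[ResilienceSummary] = []
    deleted: list[str] = []
    excluded: dict[str, str] = {}
    for plot_id in eligible:
        reduced_plots = [rec for rec in plots if rec.plot_id != plot_id]
        reduced_table = table.subset_plots([p for p in table.plot_ids if p != plot_id])
        try:
            rep = analyze_taxon(
                reduced_table,
                reduced_plots,
                metric,
                legacy,
                cap_years=cap_years,
                t_eval=t_eval,
                alpha=alpha,
                fit_mode=fit_mode,
            )
        except ChronosereError as exc:
            logger.warning(
                "jackknife %s/%s/%s: replicate without %s excluded: %s",
                table.taxon_name, metric.value, legacy.value, plot_id, exc,
            )
            excluded[plot_id] = str(exc)
            continue
        replicates.append(rep)
        deleted.append(plot_id)
    return JackknifeEnsemble(
        taxon=table.taxon_name,
        metric=metric,
        legacy=legacy,
        replicates=replicates,
        deleted_plots=deleted,
        excluded=excluded,
        cap_years=cap_years,
    )


def percentile_interval(values, level: float = DEFAULT_LEVEL) -> tuple[float, float]:
    """(2.5th, 97.5th) percentile pair by linear interpolation (level 0.95)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need >= 2 replicate values for a CI")
    tail = 100.0 * (1.0 - level) / 2.0
    finite = v[np.isfinite(v)]
    if finite.size == v.size:
        lo, hi = np.percentile(v, [tail, 100.0 - tail], method="linear")
        return float(lo), float(hi)
    # infinite entries (arrested replicates) sort above every finite value;
    # interpolation touching them yields inf, rendered downstream as ">cap"
    order = np.sort(v)
    lo = _percentile_sorted(order, tail)
    hi = _percentile_sorted(order, 100.0 - tail)
    return float(lo), float(hi)


def _percentile_sorted(order: np.ndarray, q: float) -> float:
    pos = (q / 100.0) * (order.size - 1)
    lo_idx = int(math.floor(pos))
    hi_idx = int(math.ceil(pos))
    if order[lo_idx] == order[hi_idx]:
        return float(order[lo_idx])
    frac = pos - lo_idx
    if math.isinf(order[hi_idx]):
        return float(order[hi_idx]) if frac > 0 else float(order[lo_idx])
    return float(order[lo_idx] + frac * (order[hi_idx] - order[lo_idx]))


def ci_from_ensemble(
    ensemble: JackknifeEnsemble, level: float = DEFAULT_LEVEL
) -> dict[str, tuple[float, float]]:
    """Percentile CIs per statistic over the replicate summaries.

    Return-rate CIs are computed over the replicates where a rate is
    defined (the instant-recovery rule yields none); the defined count
    is reported under ``n_return_rate``. Recovery-time intervals may
    have an infinite upper bound (arrested replicates), rendered as
    ``>cap`` in the summary table.
    """
    reps = ensemble.replicates
    if len(reps) < 2:
        raise ValidationError("need >= 2 valid replicates for CIs")
    out: dict[str, tuple[float, float]] = {}
    out["resistance_pct"] = percentile_interval([r.resistance_pct for r in reps], level)
    out["relative_recovery_30_pct"] = percentile_interval(
        [r.relative_recovery_30_pct for r in reps], level
    )
    out["recovery_time_years"] = percentile_interval(
        [r.recovery_time_years for r in reps], level
    )
    rates = [r.return_rate for r in reps if r.return_rate is not None]
    if len(rates) >= 2:
        out["return_rate"] = percentile_interval(rates, level)
        out["n_return_rate"] = (float(len(rates)), float(len(rates)))
    return out


def jackknife_se(replicate_values) -> float:
    """Classical leave-one-out jackknife standard error,

        SE = sqrt((n - 1)/n * sum_i (theta_(i) - theta_bar)^2).

    Leave-one-out replicates scatter tightly around the full estimate,
    so the percentile band of :func:`ci_from_ensemble` describes the
    spread of the replicate curves (the reporting convention used in
    the summary tables) but understates sampling uncertainty; this
    inflation-corrected SE is the classical estimator of the latter.
    """
    v = np.asarray(replicate_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValidationError("need >= 2 finite replicate values")
    n = v.size
    return float(np.sqrt((n - 1) / n * np.sum((v - v.mean()) ** 2)))


def jackknife_se_interval(
    ensemble: JackknifeEnsemble,
    point_estimate: float,
    statistic: str = "return_rate",
    level: float = DEFAULT_LEVEL,
) -> tuple[float, float]:
    """Normal-theory interval point_estimate +- z * jackknife SE."""
    from scipy.stats import norm

    values = [
        getattr(rep, statistic)
        for rep in ensemble.replicates
        if getattr(rep, statistic) is not None
    ]
    se = jackknife_se(values)
    z = float(norm.ppf(0.5 + level / 2.0))
    return point_estimate - z * se, point_estimate + z * se


def curve_envelope(
    ensemble: JackknifeEnsemble,
    t_grid,
    level: float = DEFAULT_LEVEL,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise percentile envelope of the replicate trajectories."""
    curves = ensemble.curves
    if len(curves) < 2:
        raise ValidationError("need >= 2 fitted replicate curves for an envelope")
    t_grid = np.asarray(t_grid, dtype=float)
    values = np.stack([fit.predict(t_grid) for fit in curves])
    tail = 100.0 * (1.0 - level) / 2.0
    lo = np.percentile(values, tail, axis=0, method="linear")
    hi = np.percentile(values, 100.0 - tail, axis=0, method="linear")
    return lo, hi


def attach_cis(
    summary: ResilienceSummary, ensemble: JackknifeEnsemble, level: float = DEFAULT_LEVEL
) -> ResilienceSummary:
    """Return the summary with jackknife CIs filled in (in place)."""
    ci = ci_from_ensemble(ensemble, level)
    ci.pop("n_return_rate", None)
    summary.ci = ci
    return summary
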