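"""Cross-taxon comparative analyses.

Given per-taxon resilience decompositions, this module asks which
component — resistance or return rate — drives variation in recovery
time (random-forest impurity importance), whether the two components
are correlated across taxa (Spearman), whether paired recovery times
differ between attributes (Wilcoxon signed-rank, V = sum of positive
ranks as in the R convention), and whether life-history rank, dispersal
mode or trophic level group recovery statistics (Kruskal-Wallis with
Benjamini-Hochberg FDR across the declared test family). It also hosts
the literature mode, which pushes presence/absence studies through the
same resilience pipeline restricted to richness (Hill q = 0) and
Jaccard similarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .errors import ChronosereError, ValidationError
from .io import AbundanceTable, Legacy, Metric, PlotRecord
from .resilience import INSTANT_THRESHOLD_PCT, ResilienceSummary, analyze_taxon

logger = logging.getLogger(__name__)

RF_N_ESTIMATORS = 500
EXACT_N_MAX = 10


@dataclass
class ImportanceResult:
    predictor: str  # "resistance" | "return_rate"
    importance: float
    n_taxa: int
    excluded_instant: int


@dataclass
class GroupTestResult:
    grouping: str
    statistic: float
    p_value: float
    p_adjusted: float
    n_groups: int


@dataclass
class PairedTestResult:
    v_statistic: float | None
    p_value: float | None
    n_pairs: int
    defined: bool
    note: str = ""


def importance_rf(
    rows: pd.DataFrame,
    seed: int,
    n_estimators: int = RF_N_ESTIMATORS,
    min_rows: int = 5,
) -> tuple[ImportanceResult, ImportanceResult] | None:
    """Impurity importances of resistance and return rate for recovery time.

    ``rows`` needs columns resistance_pct, return_rate, recovery_time_years
    (one row per taxon x metric x legacy). Rows where the instant-recovery
    rule fired (resistance > 90%, no rate defined) are omitted, as are rows
    with non-finite values. Returns None (analysis skipped) below
    ``min_rows`` usable rows.
    """
    needed = {"resistance_pct", "return_rate", "recovery_time_years"}
    missing = needed - set(rows.columns)
    if missing:
        raise ValidationError(f"importance_rf: missing columns {sorted(missing)}")
    instant = (rows["resistance_pct"] > INSTANT_THRESHOLD_PCT) | rows["return_rate"].isna()
    usable = rows.loc[~instant, sorted(needed)].astype(float)
    usable = usable[np.isfinite(usable).all(axis=1)]
    n_excluded = len(rows) - len(usable)
    if len(usable) < min_rows:
        logger.warning(
            "importance_rf skipped: %d usable rows < %d", len(usable), min_rows
        )
        return None
    x = usable[["resistance_pct", "return_rate"]].to_numpy()
    y = usable["recovery_time_years"].to_numpy()
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    forest.fit(x, y)
    imp_res, imp_rate = forest.feature_importances_
    return (
        ImportanceResult("resistance", float(imp_res), len(usable), n_excluded),
        ImportanceResult("return_rate", float(imp_rate), len(usable), n_excluded),
    )


def importance_ratio(results: tuple[ImportanceResult, ImportanceResult]) -> float:
    """return-rate importance relative to resistance importance."""
    res, rate = results
    if res.importance == 0:
        return math.inf if rate.importance > 0 else math.nan
    return rate.importance / res.importance


def spearman_resistance_vs_return(
    rows: pd.DataFrame,
) -> tuple[float, float, int]:
    """Spearman rho (midranks, two-sided p) between the two components.

    Rows with an undefined return rate are excluded with a logged count.
    """
    usable = rows[["resistance_pct", "return_rate"]].dropna().astype(float)
    dropped = len(rows) - len(usable)
    if dropped:
        logger.info("spearman: %d rows with undefined return rate excluded", dropped)
    if len(usable) < 3:
        raise ValidationError(f"need >= 3 paired values, got {len(usable)}")
    rho, p = sps.spearmanr(usable["resistance_pct"], usable["return_rate"])
    return float(rho), float(p), len(usable)


def wilcoxon_paired(times_a, times_b) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired recovery statistics.

    The reported statistic is V, the sum of the midranks of positive
    differences (a - b), with zero differences dropped. Exact p for
    n <= 10 without ties, else normal approximation with continuity
    correction.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        return PairedTestResult(None, None, 0, False, "all differences zero")
    ranks = sps.rankdata(np.abs(diff))
    v = float(ranks[diff > 0].sum())
    ties = np.unique(np.abs(diff)).size < n
    method = "exact" if (n <= EXACT_N_MAX and not ties) else "approx"
    _, p = sps.wilcoxon(diff, zero_method="wilcox", correction=True, method=method)
    return PairedTestResult(v, float(p), n, True)


def kruskal_fdr(
    family: Mapping[str, Mapping[str, Sequence[float]]],
    min_groups: int = 2,
) -> tuple[list[GroupTestResult], dict[str, str]]:
    """Kruskal-Wallis per test, BH-FDR adjusted across the whole family.

    ``family`` maps test name -> {group label -> values}. Tests with an
    empty group or fewer than ``min_groups`` non-empty groups are
    skipped with the reason recorded; adjustment spans the tests that
    actually ran (the declared family of one invocation).
    """
    results: list[tuple[str, float, float, int]] = []
    skipped: dict[str, str] = {}
    for name, groups in family.items():
        arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
        if any(arr.size == 0 for arr in arrays.values()):
            skipped[name] = "empty group"
            continue
        if len(arrays) < min_groups:
            skipped[name] = f"fewer than {min_groups} groups"
            continue
        values = list(arrays.values())
        if all(np.all(v == values[0][0]) for v in values):
            # all observations identical: H = 0 by definition, p = 1
            results.append((name, 0.0, 1.0, len(arrays)))
            continue
        h, p = sps.kruskal(*values)
        results.append((name, float(h), float(p), len(arrays)))
    if not results:
        return [], skipped
    _, p_adj, _, _ = multipletests([r[2] for r in results], method="fdr_bh")
    out = [
        GroupTestResult(name, h, p, float(pa), k)
        for (name, h, p, k), pa in zip(results, p_adj)
    ]
    return out, skipped


# ---------------------------------------------------------------------------
# literature mode
# ---------------------------------------------------------------------------

LITERATURE_METRICS = (Metric.HILL_Q0, Metric.JACCARD_SIM)


@dataclass
class LiteratureStudy:
    """One published chronosequence: presence/absence matrix + stages."""

    name: str
    plots: list[PlotRecord]
    table: AbundanceTable


def literature_mode(
    studies: Sequence[LiteratureStudy],
    metrics: Sequence[Metric] = LITERATURE_METRICS,
    on_missing: str = "skip",
    **analysis_kwargs,
) -> tuple[list[ResilienceSummary], dict[str, str]]:
    """Run the resilience pipeline on presence/absence literature data.

    Metrics are restricted to species richness (Hill q = 0) and Jaccard
    similarity, which are well defined without abundances. A study must
    provide >= 2 reference samples, >= 1 disturbed (t = 0) sample and
    >= 1 aged secondary sample per legacy; studies failing a
    precondition are skipped with the reason recorded (or raise with
    ``on_missing="error"``).
    """
    if on_missing not in ("skip", "error"):
        raise ValidationError(f"on_missing must be 'skip' or 'error', got {on_missing!r}")
    metrics = [Metric(m) for m in metrics]
    bad = [m for m in metrics if m not in LITERATURE_METRICS]
    if bad:
        raise ValidationError(
            f"literature mode supports {[m.value for m in LITERATURE_METRICS]}, "
            f"got {[m.value for m in bad]}"
        )
    summaries: list[ResilienceSummary] = []
    skipped: dict[str, str] = {}

    def skip(study: LiteratureStudy, reason: str) -> None:
        if on_missing == "error":
            raise ValidationError(f"study {study.name!r}: {reason}")
        logger.warning("study %s skipped: %s", study.name, reason)
        skipped[study.name] = reason

    for study in studies:
        sampled = set(study.table.plot_ids)
        recs = [r for r in study.plots if r.plot_id in sampled]
        og = [r for r in recs if r.is_old_growth]
        if len(og) < 2:
            skip(study, f"needs >= 2 reference samples, got {len(og)}")
            continue
        legacies = sorted({r.legacy for r in recs if not r.is_old_growth})
        ran = False
        for legacy in legacies:
            active = [r for r in recs if r.legacy is legacy and r.is_active]
            secondary = [r for r in recs if r.legacy is legacy and not r.is_active and not r.is_old_growth]
            if not active or not secondary:
                skip(study, f"{legacy.value}: missing disturbed or secondary stage")
                continue
            presence = AbundanceTable(
                f"{study.name}", (study.table.data > 0).astype(float)
            )
            for metric in metrics:
                try:
                    summary = analyze_taxon(presence, study.plots, metric, legacy, **analysis_kwargs)
                except ChronosereError as exc:
                    skip(study, f"{legacy.value}/{metric.value}: {exc}")
                    continue
                summaries.append(summary)
                ran = True
        if not ran and study.name not in skipped:
            skip(study, "no runnable legacy")
    return summaries, skipped


def summaries_frame(summaries: Sequence[ResilienceSummary]) -> pd.DataFrame:
    """Flatten summaries for the cross-taxon analyses."""
    return pd.DataFrame(
        [
            {
            "taxon": s.taxon,
            "metric": s.metric.value,
            "legacy": s.legacy.value,
            "resistance_pct": s.resistance_pct,
            "return_rate": s.return_rate if s.return_rate is not None else np.nan,
            "recovery_time_years": s.recovery_time_years,
            "relative_recovery_30_pct": s.relative_recovery_30_pct,
            "classification": s.classification.value,
            }
            for s in summaries
        ]
    )
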