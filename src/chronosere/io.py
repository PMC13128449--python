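"""Canonical data model and delimited-text I/O.

The data model mirrors a space-for-time chronosequence study design:
plots are either under active agricultural use (cacao plantation or
pasture, time since abandonment t = 0), secondary forest regenerating
from one of those two land-use legacies (t > 0 years), or undisturbed
old-growth forest serving as the recovery reference (no age).

Files are plain delimited text (TSV by default, comma auto-detected
from the header line), one plot-metadata table per study and one
species x plot abundance matrix per taxon.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .resilience import ResilienceSummary

logger = logging.getLogger(__name__)


class Category(str, Enum):
    """Successional stage x land use of a plot."""

    ACTIVE_CACAO = "active_cacao"
    ACTIVE_PASTURE = "active_pasture"
    SECONDARY_CACAO = "secondary_cacao"
    SECONDARY_PASTURE = "secondary_pasture"
    OLD_GROWTH = "old_growth"


class Legacy(str, Enum):
    """Previous land use of a recovering plot; old-growth has none."""

    CACAO = "cacao"
    PASTURE = "pasture"
    NONE = "none"


class Metric(str, Enum):
    """Per-plot ecological attributes the pipeline can track."""

    ABUNDANCE = "abundance"
    HILL_Q0 = "hill_q0"
    HILL_Q1 = "hill_q1"
    HILL_Q2 = "hill_q2"
    BRAY_CURTIS_SIM = "bray_curtis_sim"
    HILL_BETA_SIM_Q0 = "hill_beta_sim_q0"
    HILL_BETA_SIM_Q1 = "hill_beta_sim_q1"
    HILL_BETA_SIM_Q2 = "hill_beta_sim_q2"
    JACCARD_SIM = "jaccard_sim"


#: metrics whose per-plot value is a similarity to the old-growth reference
SIMILARITY_METRICS = frozenset(
    {
        Metric.BRAY_CURTIS_SIM,
        Metric.HILL_BETA_SIM_Q0,
        Metric.HILL_BETA_SIM_Q1,
        Metric.HILL_BETA_SIM_Q2,
        Metric.JACCARD_SIM,
    }
)

_CATEGORY_LEGACY = {
    Category.ACTIVE_CACAO: Legacy.CACAO,
    Category.ACTIVE_PASTURE: Legacy.PASTURE,
    Category.SECONDARY_CACAO: Legacy.CACAO,
    Category.SECONDARY_PASTURE: Legacy.PASTURE,
    Category.OLD_GROWTH: Legacy.NONE,
}


def legacy_of(category: Category) -> Legacy:
    return _CATEGORY_LEGACY[Category(category)]


@dataclass(frozen=True)
class PlotRecord:
    """One plot of the chronosequence.

    ``age_years`` is the time t since abandonment: 0 for plots still under
    active use, positive for secondary forest, and None for old-growth
    reference plots (which have no recovery age).
    """

    plot_id: str
    category: Category
    age_years: float | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        if self.category is Category.OLD_GROWTH:
            if self.age_years is not None and not (
                isinstance(self.age_years, float) and math.isnan(self.age_years)
            ):
                raise ValidationError(
                    f"plot {self.plot_id!r}: old-growth plots must not carry an age"
                )
            object.__setattr__(self, "age_years", None)
            return
        if self.age_years is None or (
            isinstance(self.age_years, float) and math.isnan(self.age_years)
        ):
            raise ValidationError(
                f"plot {self.plot_id!r}: {self.category.value} requires age_years"
            )
        age = float(self.age_years)
        if not math.isfinite(age) or age < 0:
            raise ValidationError(
                f"plot {self.plot_id!r}: age_years must be finite and >= 0"
            )
        active = self.category in (Category.ACTIVE_CACAO, Category.ACTIVE_PASTURE)
        if active and age != 0:
            raise ValidationError(
                f"plot {self.plot_id!r}: active plots must have age_years = 0"
            )
        if not active and age <= 0:
            raise ValidationError(
                f"plot {self.plot_id!r}: secondary plots must have age_years > 0"
            )
        object.__setattr__(self, "age_years", age)

    @property
    def legacy(self) -> Legacy:
        return legacy_of(self.category)

    @property
    def is_old_growth(self) -> bool:
        return self.category is Category.OLD_GROWTH

    @property
    def is_active(self) -> bool:
        return self.category in (Category.ACTIVE_CACAO, Category.ACTIVE_PASTURE)


@dataclass
class AbundanceTable:
    """Species x plot abundance matrix for one taxon.

    ``data`` holds non-negative counts with species ids on the index and
    plot ids on the columns. Species identity is by id string throughout;
    row/column order carries no meaning.
    """

    taxon_name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate species ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate plot ids: {dup}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"{self.taxon_name}: non-finite abundance values")
        if (values < 0).any():
            raise ValidationError(f"{self.taxon_name}: negative abundance values")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def column(self, plot_id: str) -> np.ndarray:
        return self.data[plot_id].to_numpy(dtype=float)

    def zero_species(self) -> list[str]:
        """Species present in the table but never recorded in any plot."""
        sums = self.data.sum(axis=1)
        return list(sums.index[sums == 0])

    def drop_zero_species(self) -> "AbundanceTable":
        """Copy without all-zero species rows (no metric is affected)."""
        zero = self.zero_species()
        if zero:
            logger.info(
                "%s: dropping %d all-zero species rows before metric "
                "computation: %s",
                self.taxon_name,
                len(zero),
                ", ".join(zero[:10]) + ("..." if len(zero) > 10 else ""),
            )
        return AbundanceTable(self.taxon_name, self.data.drop(index=zero))

    def subset_plots(self, plot_ids: Iterable[str]) -> "AbundanceTable":
        keep = [p for p in self.plot_ids if p in set(plot_ids)]
        return AbundanceTable(self.taxon_name, self.data[keep])


@dataclass
class MetricSeries:
    """Per-plot values of one ecological attribute for one legacy.

    ``points`` holds (plot_id, age_years, value) for the active (t = 0)
    and secondary plots of the legacy; ``og_values`` the per-plot values
    of the old-growth reference plots (for similarity metrics these are
    each reference plot's mean similarity to the other reference plots).
    psi0 is the center of the active plots, psiRef the center of the
    old-growth plots; the center is the median unless the old-growth
    median is 0, in which case the mean is used for both.
    """

    metric: Metric
    legacy: Legacy
    points: list[tuple[str, float, float]]
    psi0: float
    psi_ref: float
    center_rule: str  # "median" | "mean"
    og_values: list[tuple[str, float]] = field(default_factory=list)

    @property
    def ages(self) -> np.ndarray:
        return np.array([t for _, t, _ in self.points], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.points], dtype=float)

    @property
    def active_values(self) -> np.ndarray:
        return np.array([v for _, t, v in self.points if t == 0], dtype=float)

    @property
    def og_value_array(self) -> np.ndarray:
        return np.array([v for _, v in self.og_values], dtype=float)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PLOT_COLUMNS = ("plot_id", "category", "age_years")


def _detect_sep(path: Path, override: str | None = None) -> str:
    if override:
        return override
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_plot_table(path: str | Path, sep: str | None = None) -> list[PlotRecord]:
    """Parse a plot-metadata table into validated :class:`PlotRecord` s.

    Expects header columns ``plot_id``, ``category``, ``age_years``; the
    age cell may be empty only for old-growth plots.
    """
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype={"plot_id": str})
    missing = [c for c in _PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["plot_id"].duplicated().any():
        dup = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValidationError(f"{path}: duplicate plot ids {dup}")
    records: list[PlotRecord] = []
    for row in df.itertuples(index=False):
        try:
            cat = Category(row.category)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: unknown category {row.category!r} for plot "
                f"{row.plot_id!r}"
            ) from exc
        age = row.age_years
        age = None if (age is None or (isinstance(age, float) and math.isnan(age))) else float(age)
        records.append(PlotRecord(str(row.plot_id), cat, age))
    return records


def write_plot_table(records: Sequence[PlotRecord], path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(_PLOT_COLUMNS)
        for rec in records:
            age = "" if rec.age_years is None else format(rec.age_years, "g")
            writer.writerow([rec.plot_id, rec.category.value, age])


def read_abundance_matrix(
    path: str | Path,
    plots: Sequence[PlotRecord],
    taxon_name: str | None = None,
    sep: str | None = None,
    strict: bool = True,
) -> AbundanceTable:
    """Parse a species x plot abundance matrix and align it to known plots.

    The first column holds species ids; every remaining column must match
    a :class:`PlotRecord` (strict mode) or is dropped with a warning
    (lenient mode). All-zero species rows are kept on input; use
    :meth:`AbundanceTable.drop_zero_species` before metric computation.
    """
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    known = {rec.plot_id for rec in plots}
    stray = [c for c in df.columns if c not in known]
    if stray:
        if strict:
            raise ValidationError(
                f"{path}: plot columns with no plot record: {stray}"
            )
        logger.warning("%s: dropping unknown plot columns %s", path, stray)
        df = df.drop(columns=stray)
    table = AbundanceTable(taxon_name or path.stem, df)
    zero = table.zero_species()
    if zero:
        logger.info("%s: %d all-zero species rows flagged droppable", path, len(zero))
    return table


def write_abundance_matrix(table: AbundanceTable, path: str | Path, sep: str = "\t") -> None:
    table.data.to_csv(Path(path), sep=sep, index_label="species_id")


# ---------------------------------------------------------------------------
# summary table (shaped like the per-taxon resilience report)
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = (
    "taxon",
    "metric",
    "legacy",
    "resistance_pct",
    "return_rate_e3_per_year",
    "relative_recovery_30_pct",
    "recovery_time_years",
    "classification",
    "n_points",
    "lambda_significant",
)

EN_DASH = "–"
NA = "NA"


def _fmt_value(value: float | None, digits: int = 1) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return NA
    if math.isinf(value):
        return "inf"
    return format(round(float(value), digits), f".{digits}f")


def _fmt_time(value: float | None, cap: float, digits: int = 1) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return NA
    if math.isinf(value) or value > cap:
        return f">{format(cap, 'g')}"
    return format(round(float(value), digits), f".{digits}f")


def _fmt_cell(
    value: float | None,
    ci: tuple[float, float] | None,
    cap: float | None = None,
    digits: int = 1,
) -> str:
    fmt = (lambda v: _fmt_time(v, cap, digits)) if cap is not None else (
        lambda v: _fmt_value(v, digits)
    )
    body = fmt(value)
    if ci is None:
        return body
    return f"{body} ({fmt(ci[0])}{EN_DASH}{fmt(ci[1])})"


def write_summary_table(
    summaries: "Sequence[ResilienceSummary]",
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write one row per taxon x legacy with resistance (%), return rate
    (x 10^-3 / year), relative recovery after 30 years (%) and recovery
    time (years; ``>cap`` for arrested recovery), each with a jackknife
    CI rendered as ``(lo–hi)`` when available."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(SUMMARY_COLUMNS)
        for s in summaries:
            ci = s.ci or {}
            rr = None if s.return_rate is None else s.return_rate * 1e3
            rr_ci = ci.get("return_rate")
            rr_ci = None if rr_ci is None else (rr_ci[0] * 1e3, rr_ci[1] * 1e3)
            writer.writerow(
                [
                    s.taxon,
                    s.metric.value,
                    s.legacy.value,
                    _fmt_cell(s.resistance_pct, ci.get("resistance_pct")),
                    _fmt_cell(rr, rr_ci),
                    _fmt_cell(
                        s.relative_recovery_30_pct, ci.get("relative_recovery_30_pct")
                    ),
                    _fmt_cell(
                        s.recovery_time_years,
                        ci.get("recovery_time_years"),
                        cap=s.cap_years,
                    ),
                    s.classification.value,
                    s.n_points,
                    "" if s.lambda_significant is None else str(s.lambda_significant),
                ]
            )
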