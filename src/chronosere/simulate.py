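"""Synthetic chronosequence generator with known ground truth.

Emulates the study design the pipeline is built for: per legacy, 6
active plots at t = 0, ~16-17 secondary-forest plots with integer ages
between 1 and 38 years, and 17 shared old-growth reference plots.

Community model: an old-growth composition p_OG is drawn from a
rank-abundance model over a species pool; each land-use legacy gets a
disturbed composition p_D, a mixture of the surviving old-growth
community and a disjoint pool of disturbance specialists, with the
mixture weight calibrated so that the *pipeline-measured* Bray-Curtis
resistance targets ``resistance_true`` (sampling noise lowers both the
active-to-reference and the within-reference similarity; a seeded
internal Monte Carlo inverts that attenuation once per dataset). A plot
of age t samples its counts multinomially from a Dirichlet-perturbed
mixture

    (1 - w(t)) * p_D + w(t) * p_OG,   w(t) = 1 - exp(-lambda_true * t),

so the expected similarity to the reference follows the negative-
exponential recovery trajectory with rate lambda_true exactly.
All randomness flows from ``GeneratorConfig.seed``; the same seed
yields byte-identical emitted files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io import (
    AbundanceTable,
    Category,
    Legacy,
    Metric,
    MetricSeries,
    PlotRecord,
    write_abundance_matrix,
    write_plot_table,
)
from .diversity import bray_curtis_similarity

logger = logging.getLogger(__name__)

#: fraction of the species pool reserved for disturbance specialists
SPECIALIST_FRACTION = 0.25
#: Monte Carlo pairs per evaluation during resistance calibration
_CALIBRATION_PAIRS = 48

STUDY_DESIGN = {
    Category.ACTIVE_CACAO: 6,
    Category.ACTIVE_PASTURE: 6,
    Category.SECONDARY_CACAO: 17,
    Category.SECONDARY_PASTURE: 16,
    Category.OLD_GROWTH: 17,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic taxon and legacy.

    Defaults mirror the study design: 6 active plots, 16 secondary
    plots aged 1-38 y, 17 old-growth plots, 500 individuals per plot,
    Dirichlet concentration 200 (mild plot-level heterogeneity so that
    sampling noise is visible but does not dominate).
    """

    n_active: int = 6
    n_secondary: int = 16
    n_old_growth: int = 17
    age_range: tuple[int, int] = (1, 38)
    lambda_true: float = 0.05
    resistance_true: float = 0.4
    s_species: int = 100
    abundance_model: str = "lognormal_rank"
    n_individuals: int = 500
    noise_sd: float = 0.05
    dirichlet_concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_secondary, self.n_old_growth) <= 0:
            raise ConfigError("plot counts must be positive")
        lo, hi = self.age_range
        if not (0 < lo <= hi <= 60):
            raise ConfigError("age_range must lie within (0, 60]")
        if not 0.0 <= self.resistance_true <= 1.0:
            raise ConfigError("resistance_true must be a fraction in [0, 1]")
        if self.lambda_true < 0:
            raise ConfigError("lambda_true must be >= 0")
        if self.s_species < 4:
            raise ConfigError("s_species must be >= 4")
        if self.n_individuals <= 0 or self.dirichlet_concentration <= 0:
            raise ConfigError("n_individuals and dirichlet_concentration must be > 0")
        if self.abundance_model not in ("lognormal_rank", "uniform"):
            raise ConfigError(f"unknown abundance_model {self.abundance_model!r}")


def _rank_abundance(rng: np.random.Generator, s: int, model: str) -> np.ndarray:
    if model == "uniform":
        comp = np.ones(s)
    else:  # lognormal species-abundance distribution
        comp = np.sort(rng.lognormal(mean=0.0, sigma=1.0, size=s))[::-1]
    return comp / comp.sum()


def _sample_counts(
    rng: np.random.Generator,
    comp: np.ndarray,
    n_individuals: int,
    concentration: float,
) -> np.ndarray:
    """Dirichlet-perturbed multinomial draw from a composition."""
    counts = np.zeros(comp.size, dtype=float)
    support = comp > 0
    theta = rng.dirichlet(concentration * comp[support])
    counts[support] = rng.multinomial(n_individuals, theta)
    return counts


class _CommunityModel:
    """Species pool, compositions and the measured-similarity calibration.

    Every plot composition lies on the one-parameter family

        p(v) = v * p_OG + (1 - v) * p_spec,   v in [0, 1],

    mixing the old-growth composition with the legacy's disturbance-
    specialist pool. Sampling noise attenuates the Bray-Curtis
    similarity of a sampled plot to sampled reference plots, and the
    attenuation depends on v, so the generator calibrates the response
    curve G(v) = E[sim(p(v), p_OG)] / E[sim(p_OG, p_OG')] once per
    dataset by seeded Monte Carlo (common random numbers keep it
    monotone) and inverts it. The active composition uses
    v0 = G^-1(resistance_true) and a plot of age t uses
    v(t) = G^-1(r(t)) with r(t) = R + (1 - R)(1 - e^(-lambda t)), so the
    expected *measured* similarity follows the negative-exponential
    recovery trajectory with rate lambda_true.
    """

    _V_GRID = np.linspace(0.0, 1.0, 13)

    def __init__(self, config: GeneratorConfig, legacies: tuple[Legacy, ...], seed: int):
        self.config = config
        self.legacies = legacies
        s = config.s_species
        n_spec = max(1, round(SPECIALIST_FRACTION * s)) if config.resistance_true < 1 else 0
        if s - n_spec * len(legacies) < 2:
            raise ConfigError(
                f"species pool of {s} too small for {len(legacies)} specialist "
                f"pools of {n_spec} at resistance_true={config.resistance_true}"
            )
        rng = np.random.default_rng(seed)
        s_og = s - n_spec * len(legacies)
        p_og = np.zeros(s)
        p_og[:s_og] = _rank_abundance(rng, s_og, config.abundance_model)
        self.p_og = p_og
        self.p_spec: dict[Legacy, np.ndarray] = {}
        self._g: dict[Legacy, np.ndarray] = {}
        self.m: dict[Legacy, float] = {}
        for k, legacy in enumerate(legacies):
            if n_spec == 0:
                self.p_spec[legacy] = p_og.copy()
                self.m[legacy] = 1.0
                continue
            spec = np.zeros(s)
            lo = s_og + k * n_spec
            spec[lo : lo + n_spec] = _rank_abundance(rng, n_spec, config.abundance_model)
            self.p_spec[legacy] = spec
            self._g[legacy] = self._response_curve(spec, seed + 7919 * (k + 1))
            self.m[legacy] = self._invert(legacy, config.resistance_true)

    def _measured_ratio(self, comp: np.ndarray, seed: int) -> float:
        """E[sim(sampled comp, sampled p_OG)] / E[sim among sampled p_OG]."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        ref_sims, sims = [], []
        for _ in range(_CALIBRATION_PAIRS):
            og_a = _sample_counts(rng, self.p_og, cfg.n_individuals, cfg.dirichlet_concentration)
            og_b = _sample_counts(rng, self.p_og, cfg.n_individuals, cfg.dirichlet_concentration)
            x = _sample_counts(rng, comp, cfg.n_individuals, cfg.dirichlet_concentration)
            ref_sims.append(bray_curtis_similarity(og_a, og_b))
            sims.append(bray_curtis_similarity(x, og_b))
        return float(np.mean(sims) / np.mean(ref_sims))

    def _response_curve(self, spec: np.ndarray, seed: int) -> np.ndarray:
        g = np.array(
            [
                self._measured_ratio(v * self.p_og + (1.0 - v) * spec, seed)
                for v in self._V_GRID
            ]
        )
        g = np.maximum.accumulate(g)  # monotone despite Monte Carlo jitter
        g[-1] = 1.0  # v = 1 is the reference itself
        return g

    def _invert(self, legacy: Legacy, ratio: float) -> float:
        g = self._g[legacy]
        return float(np.interp(np.clip(ratio, g[0], 1.0), g, self._V_GRID))

    def composition_at(self, legacy: Legacy, t: float) -> np.ndarray:
        if self.m[legacy] == 1.0:
            return self.p_og
        r_true = self.config.resistance_true
        target = r_true + (1.0 - r_true) * (1.0 - np.exp(-self.config.lambda_true * t))
        v = self._invert(legacy, target)
        return v * self.p_og + (1.0 - v) * self.p_spec[legacy]


def generate_metric_series(
    config: GeneratorConfig, legacy: Legacy = Legacy.CACAO
) -> tuple[MetricSeries, dict]:
    """Directly simulate a metric series from the recovery trajectory.

    Values are the negative-exponential curve (psi0 = resistance_true,
    psiRef = 1) evaluated at the sampled ages plus Gaussian noise of
    sd = noise_sd * psiRef; active plots sit at t = 0 and old-growth
    values scatter around psiRef. Ground truth is returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    psi_ref_true = 1.0
    psi0_true = config.resistance_true * psi_ref_true
    ages = np.concatenate(
        [
            np.zeros(config.n_active),
            rng.integers(config.age_range[0], config.age_range[1] + 1, config.n_secondary),
        ]
    ).astype(float)
    curve = psi0_true + (psi_ref_true - psi0_true) * (1.0 - np.exp(-config.lambda_true * ages))
    noise = rng.normal(0.0, config.noise_sd * psi_ref_true, ages.size)
    values = curve + noise
    og_noise = rng.normal(0.0, config.noise_sd * psi_ref_true, config.n_old_growth)
    og_values = [
        (f"OG{i + 1:02d}", float(psi_ref_true + og_noise[i]))
        for i in range(config.n_old_growth)
    ]
    prefix = "C" if legacy is Legacy.CACAO else "P"
    points = []
    for i, (t, v) in enumerate(zip(ages, values)):
        kind = "ACT" if t == 0 else "SEC"
        points.append((f"{kind}-{prefix}{i + 1:02d}", float(t), float(v)))
    og_arr = np.array([v for _, v in og_values])
    rule = "mean" if float(np.median(og_arr)) == 0.0 else "median"
    center = np.mean if rule == "mean" else np.median
    active = np.array([v for _, t, v in points if t == 0])
    series = MetricSeries(
        metric=Metric.BRAY_CURTIS_SIM,
        legacy=legacy,
        points=points,
        psi0=float(center(active)),
        psi_ref=float(center(og_arr)),
        center_rule=rule,
        og_values=og_values,
    )
    truth = {
        "lambda_true": config.lambda_true,
        "psi0_true": psi0_true,
        "psi_ref_true": psi_ref_true,
        "resistance_true_pct": 100.0 * config.resistance_true,
    }
    return series, truth


def _plot_records(
    config: GeneratorConfig, legacy: Legacy, rng: np.random.Generator
) -> list[PlotRecord]:
    prefix = "C" if legacy is Legacy.CACAO else "P"
    active_cat = Category.ACTIVE_CACAO if legacy is Legacy.CACAO else Category.ACTIVE_PASTURE
    sec_cat = (
        Category.SECONDARY_CACAO if legacy is Legacy.CACAO else Category.SECONDARY_PASTURE
    )
    records = [
        PlotRecord(f"ACT-{prefix}{i + 1:02d}", active_cat, 0.0)
        for i in range(config.n_active)
    ]
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, config.n_secondary)
    records += [
        PlotRecord(f"SEC-{prefix}{i + 1:02d}", sec_cat, float(age))
        for i, age in enumerate(ages)
    ]
    return records


def _sample_table(
    taxon: str,
    model: _CommunityModel,
    records: list[PlotRecord],
    rng: np.random.Generator,
) -> AbundanceTable:
    cfg = model.config
    columns = {}
    for rec in records:
        comp = (
            model.p_og
            if rec.is_old_growth
            else model.composition_at(rec.legacy, rec.age_years)
        )
        columns[rec.plot_id] = _sample_counts(
            rng, comp, cfg.n_individuals, cfg.dirichlet_concentration
        )
    species = [f"sp{i + 1:04d}" for i in range(model.p_og.size)]
    return AbundanceTable(taxon, pd.DataFrame(columns, index=species))


def generate_community_chronosequence(
    config: GeneratorConfig,
    legacy: Legacy = Legacy.CACAO,
    taxon: str = "synthetic",
) -> tuple[list[PlotRecord], AbundanceTable, dict]:
    """One-legacy chronosequence: plot table + abundance matrix + truth."""
    legacy = Legacy(legacy)
    rng = np.random.default_rng(config.seed)
    model = _CommunityModel(config, (legacy,), seed=config.seed + 104729)
    records = _plot_records(config, legacy, rng)
    records += [
        PlotRecord(f"OG{i + 1:02d}", Category.OLD_GROWTH, None)
        for i in range(config.n_old_growth)
    ]
    table = _sample_table(taxon, model, records, rng)
    truth = {
        "lambda_true": config.lambda_true,
        "resistance_true_pct": 100.0 * config.resistance_true,
        "mixture_weight": model.m[legacy],
    }
    return records, table, truth


DEFAULT_TAXA: dict[str, tuple[float, float]] = {
    # taxon -> (lambda_true / year, resistance_true fraction)
    "fast": (0.15, 0.4),
    "slow": (0.01, 0.2),
    "resistant": (0.05, 0.95),
}


def generate_study_shaped_dataset(
    seed: int = 0,
    out_dir: str | Path | None = None,
    taxa: dict[str, tuple[float, float]] | None = None,
    config: GeneratorConfig | None = None,
) -> dict:
    """Deterministic 62-plot, two-legacy, multi-taxon fixture bundle.

    Category counts follow the study design (6 + 6 active, 17/16
    secondary per legacy, 17 shared old-growth). Taxa contrast return
    rates and resistances (``fast``, ``slow`` and a near-undisturbed
    ``resistant`` taxon by default). With ``out_dir`` the bundle is
    written as the TSV dialect the readers accept plus a YAML manifest
    of the generating parameters.
    """
    taxa = dict(taxa or DEFAULT_TAXA)
    base = config or GeneratorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    records: list[PlotRecord] = []
    for legacy, n_sec in ((Legacy.CACAO, 17), (Legacy.PASTURE, 16)):
        cfg_l = _replace(base, n_secondary=n_sec, seed=seed)
        records += _plot_records(cfg_l, legacy, rng)
    records += [
        PlotRecord(f"OG{i + 1:02d}", Category.OLD_GROWTH, None) for i in range(17)
    ]
    tables: dict[str, AbundanceTable] = {}
    truth: dict[str, dict] = {}
    for i, (taxon, (lam, res)) in enumerate(sorted(taxa.items())):
        cfg_t = _replace(base, lambda_true=lam, resistance_true=res, seed=seed)
        model = _CommunityModel(cfg_t, (Legacy.CACAO, Legacy.PASTURE), seed=seed + 15485863 * (i + 1))
        tables[taxon] = _sample_table(taxon, model, records, rng)
        truth[taxon] = {
            "lambda_true": lam,
            "resistance_true_pct": 100.0 * res,
            "mixture_weight": {leg.value: model.m[leg] for leg in model.m},
        }
    bundle = {
        "plots": records,
        "tables": tables,
        "truth": truth,
        "manifest": {
            "seed": seed,
            "taxa": {name: {"lambda_true": l, "resistance_true": r} for name, (l, r) in taxa.items()},
            "generator": asdict(base),
        },
    }
    if out_dir is not None:
        write_dataset(bundle, out_dir)
    return bundle


def _replace(config: GeneratorConfig, **kwargs) -> GeneratorConfig:
    params = asdict(config)
    params.update(kwargs)
    params["age_range"] = tuple(params["age_range"])
    return GeneratorConfig(**params)


def write_dataset(bundle: dict, out_dir: str | Path) -> None:
    """Emit plots.tsv, one abundance TSV per taxon, and manifest.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_plot_table(bundle["plots"], out / "plots.tsv")
    for taxon, table in bundle["tables"].items():
        write_abundance_matrix(table, out / f"{taxon}.tsv")
    manifest = dict(bundle["manifest"])
    manifest["truth"] = bundle["truth"]
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
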