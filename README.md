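# chronosere

Resistance, return rate and recovery time of biodiversity along
tropical-forest chronosequences.

`chronosere` is a Python package for ecologists analysing space-for-time
chronosequences: networks of plots under active agricultural use (e.g.
cacao plantation or pasture), secondary forest of known age regenerating
from one of those land-use legacies, and undisturbed old-growth plots
serving as the recovery reference. Given a plot-metadata table and one
species × plot abundance matrix per taxon, it quantifies how much of an
ecological attribute survives disturbance, how fast it returns, and how
long full recovery takes.

## The model

For an attribute ψ — total abundance, an alpha Hill number
(`q = 0, 1, 2`), or compositional similarity to the old-growth reference
(Bray–Curtis, Hill-partition overlap of order q, or Jaccard) — the
package computes, per land-use legacy:

- **Resistance** — the fraction of ψ remaining under active use,

  ```
  Resistance = exp(−|ln(ψ0 / ψRef)|) ∈ [0, 1],
  ```

  where ψ0 and ψRef are the medians of the active-use and old-growth
  plots (the mean is used when the old-growth median is 0). The
  absolute value makes levels *above* the reference count as
  disturbance too: a 30% deficit gives 70%, a 30% excess gives 77%.

- **Return rate λ** — the rate constant of the negative-exponential
  approach to the reference, fitted by bounded nonlinear least squares
  with ψ0 and ψRef held fixed at the data centers:

  ```
  ψ(t) = ψ0 + (ψRef − ψ0)(1 − e^(−λt)).
  ```

- **Recovery time** — years until ψ(t) is within ±10% of ψRef:

  ```
  T_rec = −ln(0.1 ψRef / |ψRef − ψ0|) / λ.
  ```

  Resistance above 90% counts as instant recovery (T = 0, no λ).
  A fit beyond 300 years is zeroed when the active and old-growth
  mean ± SD intervals overlap (a spread artefact) and reported as
  arrested recovery (`>300`) when they do not.

- **Relative recovery after 30 years** — the resistance transform
  applied to the modelled ψ(30).

Uncertainty comes from a leave-one-plot-out jackknife (every metric,
including ψRef, recomputed per replicate), and cross-taxon analyses
compare the components: random-forest impurity importance of resistance
vs return rate for recovery time, Spearman correlation, paired Wilcoxon
tests, and Kruskal–Wallis group tests with Benjamini–Hochberg FDR. A
literature mode pushes presence/absence studies through the same
pipeline with richness and Jaccard similarity. A synthetic
chronosequence generator with known λ and resistance, matching the
62-plot study design the package targets, backs every stage with ground
truth.

## Worked example

```python
import chronosere as cs

cfg = cs.GeneratorConfig(seed=7, lambda_true=0.05, resistance_true=0.4)
plots, table, truth = cs.generate_community_chronosequence(cfg, "cacao")
summary = cs.analyze_taxon(table, plots, "bray_curtis_sim", "cacao")
ensemble = cs.jackknife(table, plots, "bray_curtis_sim", "cacao")
cs.attach_cis(summary, ensemble)
```

prints, via the fields of `summary`:

```
resistance        39.0%  CI (36.8, 41.2)
return rate       50.6 x 1e-3 / year  CI (48.7, 52.5)
recovery time     35.7 years
recovery at 30 y  86.6%
classification    normal
```

The generator was asked for 40% resistance and λ = 0.05 / year; the
pipeline recovers 39.0% and 0.0506 / year from the sampled counts, and
the implied recovery time (time to 90% of the old-growth reference)
is ≈ 36 years. The CI bounds are percentile intervals over the 40
leave-one-plot-out replicates.

The same analysis runs from the shell:

```sh
chronosere simulate --seed 7 --out-dir data/
chronosere all --plot-table data/plots.tsv --matrix data/fast.tsv \
    --matrix data/slow.tsv --out-dir results/
```

writing a per-taxon summary table (resistance, return rate ×10⁻³/y,
relative recovery at 30 y, recovery time with `(lo–hi)` jackknife CIs),
pairwise-similarity long tables, cross-taxon statistics and a run
manifest.

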