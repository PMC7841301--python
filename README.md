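# psycop

Systematic behavioral and cognitive profiling of 2×2
genotype-by-environment (G×E) mouse cohorts.

Two-hit psychiatric disease models cross a genetic manipulation (wildtype
`wt` vs. transgenic `tg`) with an environmental insult (no-stress control
`ns` vs. social defeat `sd`) and phenotype the four groups across a large
behavioral battery. `psycop` takes the raw material of such a study —
automated home-cage event streams (corner visits, nosepokes, licks) plus
per-animal measures from classical tests — and produces a statistically
disciplined neurocognitive profile:

1. **Derived metrics** — trials ("visits with at least one nosepoke"),
   chance-anchored preference scores `(A − wB)/(A + wB)`, a sequential
   probability ratio test (SPRT) learning criterion (`p0 = 25%`,
   `p1 = 35%`, α = β = 5% for four corners; censored at the phase's total
   trial count), serial-reversal learning AUC, activity, and nocturnality.
2. **Factorial statistics** — one multivariate bifactorial linear model
   under sum-to-zero coding with Type-II cross-products: a Wilks'-lambda
   MANOVA per term (Rao's F, exact for 1-df hypotheses), per-variable
   two-way ANOVAs with Benjamini–Hochberg FDR, interaction-triggered
   per-genotype one-way follow-ups, an energy-statistic test of
   multivariate normality (parametric bootstrap), and a split-plot
   repeated-measures ANOVA with Mauchly's test and Huynh–Feldt correction.
3. **Profiles** — NIPALS PCA with missing-value imputation, z-transform,
   canonical discriminant analysis (CDA) overall and per model term, an
   RDoC-blocked heatmap of group-mean z-scores relative to the healthy
   control, CDA dimension plots with 75% coverage ellipses, boxplots, and
   residual diagnostics.

A synthetic-data module generates cohorts (default n = 15/17/15/17, 19
correlated variables across the five RDoC domains) and learnable event
streams with full ground truth, so the entire pipeline is testable without
animal data.

## Worked example

Simulate a default cohort, run the factorial statistics and the dimension
reduction:

```sh
psycop simulate --out demo --seed 42
psycop stats  --table demo/measure_table.csv --out demo/stats --n-boot 200
psycop dimred --table demo/measure_table.csv --out demo/dimred
```

The `stats` step prints the MANOVA summary (53 of 64 animals are
listwise-complete at the default 2% missing-cell rate, so the error df is
49 and Rao's F has df (19, 29)):

```
      wilks_lambda         F   df1   df2             p
term
G         0.173599  7.265892  19.0  29.0  1.356937e-06
E         0.166535  7.638826  19.0  29.0  7.938756e-07
GxE       0.423195  2.080335  19.0  29.0  3.664371e-02
```

Both the genotype and the environment term separate the groups strongly —
the generator's defaults plant an environment signature on valence,
arousal and fear-memory variables and a genotype signature on sensorimotor
gating and reversal learning — while the interaction is weak. The `dimred`
step prints

```
canonical correlation percentages: 68.7%, 24.1%, 7.2%
```

i.e. the first canonical component carries two thirds of the group
separation (it aligns with the environmental factor), the second about a
quarter (genotype). Per-variable results land in
`demo/stats/univariate_tests.tsv` with FDR-adjusted p-values and the
figure-legend star convention (`* < 0.05`, `** < 0.01`, `*** < 0.001`),
e.g.

```
variable            term  F          df1  df2  p       p_adj   stars
y_maze_alternation  G     2.522      1    47   0.119   0.339   n.s.
```

`psycop run config.yaml` drives the full pipeline (derived-measure table,
stats report, heatmap, CDA plots, boxplots, run log) from one YAML file;
`psycop metrics` derives home-cage variables from an event stream, and
`psycop report` renders figures for an existing measure table. Identical
config and seed give byte-identical tables and figures.

## Layout

```
src/psycop/
  datatypes.py   cohort table, factors, RDoC map, event stream, schedules
  io.py          CSV/TSV/YAML readers and writers
  metrics.py     trials, preference scores, SPRT, reversal AUC, circadian
  stats.py       MANOVA, follow-ups, E-test, split-plot RM-ANOVA
  dimred.py      NIPALS imputation, z-transform, CDA, per-term CDA
  viz.py         heatmap, dimension plots, boxplots, diagnostics
  simulate.py    synthetic cohorts, event streams, recovery suite
  pipeline.py    end-to-end driver with staged, atomic outputs
  cli.py         `psycop` command-line interface
docs/methods.md  model and procedure documentation
```

Out of scope: hardware control, live cage connections, video tracking,
and GUIs — the package consumes exported event tables and per-animal
measures only.
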