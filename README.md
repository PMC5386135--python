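# triomr

Simulation and instrumental-variable estimation tools for testing causal
**intrauterine effects** with maternal genetic instruments in
parent-offspring trios.

When a maternal genetic score is used as an instrument for a pregnancy
exposure, any overlap with offspring variants that affect the offspring
outcome violates the exclusion restriction: the maternal and offspring
scores are correlated at 0.5 by Mendelian transmission. `triomr` provides
the machinery to quantify and correct for this:

- **`triomr.simulate`** — a trio cohort simulator parameterized entirely by
  variance proportions (instrument strength `q_x`, offspring/paternal direct
  outcome paths `v_o`/`v_p`, confounding, causal effect `gamma`), with
  haplotype-level transmission labels, optional assortative mating and
  per-variant horizontal pleiotropy, plus the closed-form model-implied
  covariance used to solve residual variances and predict estimator limits.
- **`triomr.transmission`** — resolution of maternal transmitted /
  non-transmitted alleles from unphased trio dosages (deterministic rule;
  mother-offspring double heterozygotes resolve only via a homozygous
  father), and construction of standardized non-transmitted haplotype
  scores for use as instruments.
- **`triomr.estimators`** — two-stage least squares with the four
  estimation strategies compared in the simulation study (unadjusted,
  offspring-adjusted, offspring+paternal-adjusted, non-transmitted
  instrument) plus the transmitted-score comparator, first-stage F
  diagnostics, and instrument-confounder balance checks with and without
  offspring adjustment.
- **`triomr.summary_mr`** — per-variant summary-statistic sensitivity
  estimators: IVW, MR-Egger (intercept = average directional pleiotropy),
  the weighted median, and the minus-0.5 correction for the same-trait
  design.
- **`triomr.runner`** — replicate x scenario grid orchestration with
  bias / empirical SD / power / coverage aggregation, deterministic
  reporting, and shipped scenario presets for the standard bias-evaluation grids.

## CLI

```sh
# one simulated cohort to delimited text
triomr simulate --config scenario.cfg --out cohort.tsv

# TSLS strategies on a cohort table
triomr estimate --cohort cohort.tsv --strategies unadjusted,nontransmitted

# IVW / MR-Egger / weighted-median sensitivity estimates
triomr sensitivity --cohort cohort.tsv --seed 3

# full scenario grid from a config crossing parameter vectors
triomr grid --config grid.cfg --out report/ --seed 1

# re-aggregate saved per-replicate estimates
triomr report --estimates estimates.tsv --gamma 0.1
```

Scenario configs are flat `key = value` text (vectors comma-separated); see
`triomr.simulate.ScenarioConfig`. Grid configs list parameter vectors that
are crossed factorially (`gamma = 0, 0.1` etc.).

## Example

```python
from triomr import ScenarioConfig, run_scenario

cfg = ScenarioConfig(n_trios=10000, q_x=0.02, gamma=0.10, v_o=0.05, seed=1)
summary = run_scenario(cfg, n_replicates=200)
print(summary.table[["method", "mean_beta", "empirical_sd", "power"]])
```

The unadjusted strategy converges to `gamma + 0.5*sqrt(v_o/q_x)` (large
upward bias), the offspring-adjusted strategy to `gamma - sqrt(v_p/q_x)/3`
(collider-induced negative bias), while the offspring+paternal-adjusted and
non-transmitted-allele strategies recover `gamma`.
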