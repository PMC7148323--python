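# twasim

Monte-Carlo simulation study of **selection bias in two-stage
transcriptome-wide association analysis**, with inverse-probability-weighting
(IPW) correction.

Two-stage least squares (regression imputation) is the workhorse of
integrative TWAS: in an eQTL dataset D1 = {(z_i, x_i)} of size n1, expression
x is regressed on genotype z; in an independent GWAS dataset
D2 = {(z_j, y_j)} of size n2, the trait y is regressed on predicted
expression x̂_j = α̂0 + z_j α̂, and the slope γ̂1 estimates the
expression-trait association. Real D1 and D2 are rarely random draws from
the same population — tissue-donor biobanks under-sample obesity, disease
cohorts over-sample it, volunteer studies skew lean. `twasim` generates a
population under the composite model

    x_i = α0 + z_i1 α1 + z_i2 α2 + δ_i ,   δ ~ N(0, σ_δ²)
    y_i = γ0 + γ1 x_i + ε_i ,              ε ~ N(0, σ_ε²)

(y = natural-log BMI, x = log2 expression, two Hardy–Weinberg SNPs), draws
TWAS/GWAS datasets either at random or by **BMI-decile-matched sampling**
that mimics published cohort BMI profiles, and measures the bias, CI length
and coverage of γ̂1 over thousands of replicates — unweighted or with
known/estimated inverse-probability weights in the first stage. It is aimed
at biostatisticians studying transportability and sampling design in
integrative genomics.

## Layout

- `src/twasim/` — the library: `cohorts` (synthetic reference cohorts from
  published BMI category tables), `dgp` (the generative model), `weights`
  (decile-matched sampling + IPW), `twostage` (the estimator and metrics),
  `experiment` (scenario orchestration and Monte-Carlo aggregation).
- `analysis/` — numbered drivers that produce the tables in `results/`.
- `docs/methods.md` — model, parameter and design notes, including the
  weak-instrument analysis of the default constants.

## Worked example

```python
from twasim import DGPParams, ScenarioConfig, run_scenario

cfg = ScenarioConfig(name="RS", replicates=200, base_seed=7,
                     dgp=DGPParams(pop_size=20_000))
results, s = run_scenario(cfg)
print(f"mean gamma1_hat  {s.mean_estimate:.3f}   (true 0.15)")
print(f"mean rel. bias   {s.mean_relative_bias:.1f}%")
print(f"mean CI length   {s.mean_ci_length:.3f}")
print(f"coverage         {s.coverage:.3f}")
print(f"stage-1 rel bias {s.stage1_mean_relative_bias.round(1)}")
```

prints

```
mean gamma1_hat  0.062   (true 0.15)
mean rel. bias   -58.4%
mean CI length   0.427
coverage         0.630
stage-1 rel bias [-0.1  3.7  2.1]
```

Read: under purely *random* sampling the stage-1 eQTL coefficients are
unbiased (last line, Monte-Carlo noise around 0), yet the stage-2 estimate
of γ1 = 0.15 is strongly attenuated and its nominal 95% interval covers only
~63% of the time. That is the weak-instrument signature of the default
constants — the two SNPs explain ≈0.1% of expression variance, so predicted
expression is mostly first-stage noise, which the stage-2 interval ignores.
Biased sampling adds a second, structural effect: run
`analysis/03_run_scenarios.py` and compare the `stage1_bias.tsv` rows —
biobank-mimicking TWAS selection biases α̂0 and both SNP coefficients
*downward* (≈ −5% / −25 to −30%), and first-stage IPW with known weights
pulls them most of the way back (≈ −0.1% / −10%), with estimated weights in
between. See `docs/methods.md` for why the stage-2 scenario contrasts are
not resolvable above Monte-Carlo noise in this regime.

## The analysis drivers

```sh
python analysis/01_build_cohorts.py --seed 1        # cohort fidelity + KS/Wilcoxon tests
python analysis/02_simulate_population.py --seed 1  # population moments, BMI deciles
python analysis/03_run_scenarios.py --seed 1        # 4 scenarios + 2 IPW variants
```

Each writes TSV tables under `results/` (scenario summaries mirror a
results-table row: mean estimate, relative bias, IQR, CI length, coverage).

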