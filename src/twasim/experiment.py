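"""Monte-Carlo scenario orchestration.

Four sampling scenarios are studied, each defined by which side of the
two-stage analysis is sampled through a reference cohort's BMI profile:

====  ==========  =====================  =====================
#     name        TWAS sampling          GWAS sampling
====  ==========  =====================  =====================
1     RS          random                 random
2     GTEx-RS     GTEx-like weighted     random
3     GTEx-CRIC   GTEx-like weighted     CRIC-like weighted
4     GTEx-GENE   GTEx-like weighted     GENE-like weighted
====  ==========  =====================  =====================

Scenario 2 additionally supports inverse-probability weighting of the
stage-1 fit with known or estimated weights.  Each replicate regenerates the
population and the synthetic reference cohorts (at their published sizes) by
default, so small-cohort weight-estimation noise propagates into the
results; fixed-population and fixed-cohort modes are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import CohortSpec, ReferenceBMISample, get_cohort, sample_reference_bmi
from .dgp import DGPParams, PopulationData, simulate_population
from .twostage import (
    StageOneFit,
    StageTwoFit,
    ci_covers,
    predict_expression,
    relative_bias,
    stage_one,
    stage_two,
)
from .weights import (
    SampledDataset,
    SelectionWeights,
    draw_biased_sample,
    fit_bmi_predictor,
    ipw_estimated,
    ipw_known,
    random_sample_split,
)

__all__ = [
    "ScenarioConfig",
    "ReplicateResult",
    "ScenarioSummary",
    "table2_scenarios",
    "run_replicate",
    "run_scenario",
    "summarize_scenario",
    "compare_distributions",
    "stage_one_bias_table",
    "summaries_to_frame",
    "replicates_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    ``ipw`` applies to the stage-1 fit only and requires a TWAS reference
    (weights are undefined for a randomly sampled TWAS dataset).  IPW with
    estimated weights additionally needs a survey reference
    (``nhanes_reference``) on which the BMI ~ age + weight predictor is fit.
    """

    name: str
    twas_reference: CohortSpec | str | None = None
    gwas_reference: CohortSpec | str | None = None
    ipw: str = "none"  # "none" | "known" | "estimated"
    nhanes_reference: CohortSpec | None = None
    n1: int = 750
    n2: int = 1500
    replicates: int = 2000
    base_seed: int = 0
    dgp: DGPParams = field(default_factory=DGPParams)
    regenerate_population_each_replicate: bool = True
    regenerate_cohorts_each_replicate: bool = True
    #: size of the uniform population draw used when a reference is "self"
    self_reference_size: int = 2000

    def __post_init__(self) -> None:
        for ref in (self.twas_reference, self.gwas_reference):
            if isinstance(ref, str) and ref != "self":
                raise ValueError(
                    "string references must be 'self' (uniform draw from the "
                    "population, the self-reference null)"
                )
        if self.ipw not in ("none", "known", "estimated"):
            raise ValueError("ipw must be 'none', 'known' or 'estimated'")
        if self.ipw != "none" and self.twas_reference is None:
            raise ValueError("IPW requires a biased (reference-weighted) TWAS side")
        if self.ipw == "estimated" and self.nhanes_reference is None:
            raise ValueError(
                "estimated IPW requires a survey reference cohort "
                "(nhanes_reference) to fit the BMI predictor"
            )
        if self.gwas_reference is not None and self.twas_reference is None:
            raise ValueError(
                "scenarios with a GWAS reference also use a TWAS reference"
            )


def table2_scenarios(
    replicates: int = 2000,
    base_seed: int = 0,
    dgp: DGPParams | None = None,
    sex: str = "women",
    **kwargs,
) -> dict[str, ScenarioConfig]:
    """The four standard scenarios (plus none for IPW; see ``with_ipw``)
    built from the published cohort table for one sex stratum."""
    dgp = dgp or DGPParams()
    common = dict(replicates=replicates, base_seed=base_seed, dgp=dgp, **kwargs)
    gtex = get_cohort("GTEx", sex)
    return {
        "RS": ScenarioConfig(name="RS", **common),
        "GTEx-RS": ScenarioConfig(name="GTEx-RS", twas_reference=gtex, **common),
        "GTEx-CRIC": ScenarioConfig(
            name="GTEx-CRIC", twas_reference=gtex,
            gwas_reference=get_cohort("CRIC", sex), **common,
        ),
        "GTEx-GENE": ScenarioConfig(
            name="GTEx-GENE", twas_reference=gtex,
            gwas_reference=get_cohort("GENE", sex), **common,
        ),
    }


def with_ipw(config: ScenarioConfig, ipw: str, sex: str = "women") -> ScenarioConfig:
    """Derive an IPW variant of a biased scenario; wires in the survey
    reference cohort when estimated weights are requested."""
    nhanes = config.nhanes_reference
    if ipw == "estimated" and nhanes is None:
        nhanes = get_cohort("NHANES", sex)
    return replace(
        config, name=f"{config.name}+IPW-{ipw}", ipw=ipw, nhanes_reference=nhanes
    )


@dataclass(frozen=True)
class ReplicateResult:
    """Per-replicate fits and metrics."""

    replicate: int
    stage1: StageOneFit
    stage2: StageTwoFit
    relative_bias_gamma1: float
    covered: bool
    relative_bias_alpha: np.ndarray  # (alpha0, alpha1, alpha2), percent


@dataclass(frozen=True)
class ScenarioSummary:
    """Monte-Carlo aggregate of one scenario (the machine-readable analogue
    of a results-table row)."""

    name: str
    ipw: str
    replicates: int
    mean_estimate: float
    mean_relative_bias: float
    median_relative_bias: float
    iqr_relative_bias: tuple[float, float]
    mean_ci_length: float
    coverage: float
    stage1_mean_relative_bias: np.ndarray  # per coefficient, percent
    xhat_mean_log2: float
    xhat_sd_log2: float
    xhat_mean_antilog: float


def _reference_weights(
    reference: CohortSpec | str,
    population: PopulationData,
    rng: np.random.Generator,
    self_reference_size: int,
) -> SelectionWeights:
    """Selection weights for a cohort reference, or for the self-reference
    null ("self": a uniform draw from the population itself, whose decile
    weights are ~0.1 each and whose biased sampling is indistinguishable
    from random sampling)."""
    if isinstance(reference, str):  # "self"
        ref_bmi = rng.choice(population.bmi, size=self_reference_size, replace=False)
        return SelectionWeights.from_reference(population.bmi, ref_bmi, "self")
    ref = sample_reference_bmi(reference, seed=rng)
    return SelectionWeights.from_reference(
        population.bmi, ref.bmi, reference.cohort_name
    )


def run_replicate(
    config: ScenarioConfig,
    seed: int | np.random.Generator | None,
    population: PopulationData | None = None,
    twas_weights: SelectionWeights | None = None,
    gwas_weights: SelectionWeights | None = None,
    nhanes_sample: ReferenceBMISample | None = None,
    replicate: int = 0,
) -> ReplicateResult:
    """Execute one replicate: (re)generate the population and cohorts as
    configured, draw the TWAS and GWAS datasets, fit both stages and compute
    the per-replicate metrics.

    RNG draw order is fixed: population, TWAS reference cohort, GWAS
    reference cohort, survey cohort (estimated IPW only), TWAS sample draw,
    GWAS sample draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    need_cov = config.ipw == "estimated"
    if population is None:
        population = simulate_population(
            config.dgp, rng, include_covariates=need_cov
        )
    if config.twas_reference is not None and twas_weights is None:
        twas_weights = _reference_weights(
            config.twas_reference, population, rng, config.self_reference_size
        )
    if config.gwas_reference is not None and gwas_weights is None:
        gwas_weights = _reference_weights(
            config.gwas_reference, population, rng, config.self_reference_size
        )
    if config.ipw == "estimated" and nhanes_sample is None:
        nhanes_sample = sample_reference_bmi(config.nhanes_reference, seed=rng)

    if config.twas_reference is None:
        d1, d2 = random_sample_split(population.size, config.n1, config.n2, rng)
    else:
        d1 = draw_biased_sample(twas_weights, config.n1, rng, role="TWAS")
        if gwas_weights is not None:
            d2 = draw_biased_sample(gwas_weights, config.n2, rng, role="GWAS")
        else:
            idx = rng.choice(population.size, size=config.n2, replace=False)
            d2 = SampledDataset(indices=idx, role="GWAS", scheme="random")

    obs_weights = None
    if config.ipw == "known":
        obs_weights = ipw_known(d1)
    elif config.ipw == "estimated":
        predictor = fit_bmi_predictor(nhanes_sample)
        obs_weights = ipw_estimated(
            population.age[d1.indices],
            population.weight[d1.indices],
            predictor,
            twas_weights,
        )

    s1 = stage_one(
        population.z[d1.indices], population.x[d1.indices],
        obs_weights, weights_used=config.ipw,
    )
    xhat = predict_expression(s1, population.z[d2.indices])
    s2 = stage_two(xhat, population.y[d2.indices])

    truth = config.dgp.gamma1
    rb = relative_bias(s2.gamma1_hat, truth)
    covered = ci_covers(s2.ci_low, s2.ci_high, truth)
    rb_alpha = 100.0 * (s1.coef - config.dgp.alphas) / config.dgp.alphas
    return ReplicateResult(
        replicate=replicate,
        stage1=s1,
        stage2=s2,
        relative_bias_gamma1=rb,
        covered=covered,
        relative_bias_alpha=rb_alpha,
    )


def run_scenario(
    config: ScenarioConfig,
    progress_every: int = 0,
) -> tuple[list[ReplicateResult], ScenarioSummary]:
    """Run all replicates of a scenario.

    Per-replicate seeds are spawned from ``SeedSequence(base_seed)`` so
    replicates are statistically independent and the whole run is
    reproducible from ``(config, base_seed)`` alone.  Fixed-population /
    fixed-cohort modes draw those objects once from the first spawned stream
    and reuse them across replicates.
    """
    seeds = np.random.SeedSequence(config.base_seed).spawn(config.replicates + 1)
    setup_rng = np.random.default_rng(seeds[0])

    population = None
    twas_w = gwas_w = None
    nhanes_sample = None
    need_cov = config.ipw == "estimated"
    if not config.regenerate_population_each_replicate:
        population = simulate_population(config.dgp, setup_rng, include_covariates=need_cov)
    if not config.regenerate_cohorts_each_replicate:
        if population is None:
            raise ValueError(
                "fixed cohorts require a fixed population (weights depend on "
                "the population's decile cuts)"
            )
        if config.twas_reference is not None:
            twas_w = _reference_weights(
                config.twas_reference, population, setup_rng,
                config.self_reference_size,
            )
        if config.gwas_reference is not None:
            gwas_w = _reference_weights(
                config.gwas_reference, population, setup_rng,
                config.self_reference_size,
            )
        if config.ipw == "estimated":
            nhanes_sample = sample_reference_bmi(config.nhanes_reference, seed=setup_rng)

    results: list[ReplicateResult] = []
    for r in range(config.replicates):
        rng = np.random.default_rng(seeds[r + 1])
        results.append(
            run_replicate(
                config, rng,
                population=population,
                twas_weights=twas_w,
                gwas_weights=gwas_w,
                nhanes_sample=nhanes_sample,
                replicate=r,
            )
        )
        if progress_every and (r + 1) % progress_every == 0:
            logger.info("%s: replicate %d/%d", config.name, r + 1, config.replicates)
    return results, summarize_scenario(results, config.dgp.gamma1, config)


def summarize_scenario(
    results: list[ReplicateResult],
    truth: float,
    config: ScenarioConfig | None = None,
) -> ScenarioSummary:
    """Aggregate replicate results: mean estimate, mean/median/IQR relative
    bias (linear-interpolation percentiles), mean CI length, coverage, and
    stage-1 / predicted-expression summaries."""
    if not results:
        raise ValueError("no replicates to summarize")
    est = np.array([r.stage2.gamma1_hat for r in results])
    rb = np.array([r.relative_bias_gamma1 for r in results])
    cil = np.array([r.stage2.ci_length for r in results])
    cov = np.array([r.covered for r in results])
    rb_a = np.vstack([r.relative_bias_alpha for r in results])
    xm = np.array([r.stage2.xhat_mean for r in results])
    q25, q75 = np.percentile(rb, [25, 75])
    mean_xhat = float(xm.mean())
    return ScenarioSummary(
        name=config.name if config else "",
        ipw=config.ipw if config else "none",
        replicates=len(results),
        mean_estimate=float(est.mean()),
        mean_relative_bias=float(rb.mean()),
        median_relative_bias=float(np.median(rb)),
        iqr_relative_bias=(float(q25), float(q75)),
        mean_ci_length=float(cil.mean()),
        coverage=float(cov.mean()),
        stage1_mean_relative_bias=rb_a.mean(axis=0),
        xhat_mean_log2=mean_xhat,
        xhat_sd_log2=float(xm.std(ddof=1)) if len(results) > 1 else 0.0,
        xhat_mean_antilog=float(2.0**mean_xhat),
    )


def compare_distributions(sample_a: np.ndarray, sample_b: np.ndarray) -> dict[str, float]:
    """Two-sample Kolmogorov-Smirnov and two-sided Wilcoxon rank-sum tests
    comparing two BMI (or any continuous) samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = stats.ks_2samp(a, b)
    rs = stats.ranksums(a, b)
    return {
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "ranksum_stat": float(rs.statistic),
        "ranksum_p": float(rs.pvalue),
    }


def stage_one_bias_table(results: list[ReplicateResult]) -> pd.DataFrame:
    """Mean / median / IQR of the stage-1 relative bias per coefficient."""
    if not results:
        raise ValueError("no replicates to summarize")
    rb = np.vstack([r.relative_bias_alpha for r in results])
    rows = []
    for k, name in enumerate(["alpha0", "alpha1", "alpha2"]):
        q25, q75 = np.percentile(rb[:, k], [25, 75])
        rows.append(
            {
                "coefficient": name,
                "mean_rel_bias": rb[:, k].mean(),
                "median_rel_bias": np.median(rb[:, k]),
                "iqr_lo": q25,
                "iqr_hi": q75,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    """Scenario summaries as a tidy table (one row per scenario)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "scenario": s.name,
                "ipw": s.ipw,
                "replicates": s.replicates,
                "mean_estimate": s.mean_estimate,
                "mean_rel_bias": s.mean_relative_bias,
                "median_rel_bias": s.median_relative_bias,
                "iqr_lo": s.iqr_relative_bias[0],
                "iqr_hi": s.iqr_relative_bias[1],
                "mean_ci_length": s.mean_ci_length,
                "coverage": s.coverage,
                "stage1_rb_alpha0": s.stage1_mean_relative_bias[0],
                "stage1_rb_alpha1": s.stage1_mean_relative_bias[1],
                "stage1_rb_alpha2": s.stage1_mean_relative_bias[2],
                "xhat_mean_log2": s.xhat_mean_log2,
                "xhat_sd_log2": s.xhat_sd_log2,
                "xhat_mean_antilog": s.xhat_mean_antilog,
            }
        )
    return pd.DataFrame(rows)


def replicates_to_frame(name: str, results: list[ReplicateResult]) -> pd.DataFrame:
    """Per-replicate results as a tidy table."""
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": name,
                "replicate": r.replicate,
                "alpha0_hat": r.stage1.alpha0_hat,
                "alpha1_hat": r.stage1.alpha1_hat,
                "alpha2_hat": r.stage1.alpha2_hat,
                "stage1_resid_sd": r.stage1.residual_sd,
                "gamma1_hat": r.stage2.gamma1_hat,
                "se_gamma1": r.stage2.se_gamma1,
                "ci_low": r.stage2.ci_low,
                "ci_high": r.stage2.ci_high,
                "ci_length": r.stage2.ci_length,
                "xhat_mean": r.stage2.xhat_mean,
                "rel_bias_gamma1": r.relative_bias_gamma1,
                "covered": r.covered,
            }
        )
    return pd.DataFrame(rows)
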