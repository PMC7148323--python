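"""Cohort-mimicking sampling and inverse-probability weights.

A study cohort rarely looks like the population it is nominally drawn from.
This module makes the mismatch operational: the population's BMI distribution
is cut into deciles, each decile receives the fraction of a *reference
cohort* that falls inside it, and individuals are then sampled with
probability proportional to their decile's reference fraction.  A tissue-
donor-like reference (few obese donors) thus yields samples depleted of high
BMI; a kidney-disease reference enriches it.

Inverse-probability weights undo the distortion in weighted fits:
``ipw_known`` inverts the true selection probabilities used in sampling;
``ipw_estimated`` inverts probabilities reconstructed from *predicted* BMI,
with BMI predicted from age and body weight via a linear model fitted on a
population-survey reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohorts import ReferenceBMISample

__all__ = [
    "SelectionWeights",
    "SampledDataset",
    "BMIPredictor",
    "population_deciles",
    "decile_weights",
    "selection_probabilities",
    "draw_biased_sample",
    "random_sample_split",
    "ipw_known",
    "fit_bmi_predictor",
    "ipw_estimated",
]


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def population_deciles(bmi_pop: np.ndarray) -> np.ndarray:
    """Nine empirical decile cut points of the population BMI distribution
    (linear-interpolation quantiles at 0.1, ..., 0.9).  Decile bins are
    left-closed / right-open with unbounded bottom and top bins."""
    bmi_pop = np.asarray(bmi_pop, dtype=float)
    if np.unique(bmi_pop).size < 10:
        raise ValueError("need at least 10 distinct BMI values to form deciles")
    return np.quantile(bmi_pop, np.arange(1, 10) / 10.0)


def _decile_of(bmi: np.ndarray, decile_cuts: np.ndarray) -> np.ndarray:
    # bin k holds cuts[k-1] <= bmi < cuts[k]
    return np.digitize(np.asarray(bmi, dtype=float), decile_cuts, right=False)


def decile_weights(reference_bmi: np.ndarray, decile_cuts: np.ndarray) -> np.ndarray:
    """Fraction of the reference cohort in each population BMI decile
    (10-vector summing to 1)."""
    reference_bmi = np.asarray(reference_bmi, dtype=float)
    if reference_bmi.size == 0:
        raise ValueError("reference sample is empty")
    counts = np.bincount(_decile_of(reference_bmi, decile_cuts), minlength=10)
    return counts / reference_bmi.size


def selection_probabilities(
    pop_bmi: np.ndarray, w: np.ndarray, decile_cuts: np.ndarray
) -> np.ndarray:
    """Per-individual selection probabilities: each individual receives its
    decile's reference fraction, normalized to sum to 1 over the population.

    The normalization runs over the whole population being sampled (the
    sampling design's denominator), so individuals in deciles the reference
    cohort never occupies have probability exactly 0.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (10,) or np.any(w < 0):
        raise ValueError("w must be a nonnegative 10-vector")
    p = w[_decile_of(pop_bmi, decile_cuts)]
    total = p.sum()
    if total <= 0:
        raise ValueError("all selection weights are zero: no sampleable individuals")
    return p / total


@dataclass(frozen=True)
class SelectionWeights:
    """Decile cuts, per-decile reference fractions, per-individual selection
    probabilities, and the per-decile probability shared by every individual
    in a decile (``decile_probs[k] = w[k] / S`` with S the population sum of
    per-individual weights)."""

    decile_cuts: np.ndarray
    w: np.ndarray
    p: np.ndarray
    decile_probs: np.ndarray
    reference_name: str = ""

    @classmethod
    def from_reference(
        cls, pop_bmi: np.ndarray, reference_bmi: np.ndarray, name: str = ""
    ) -> "SelectionWeights":
        cuts = population_deciles(pop_bmi)
        w = decile_weights(reference_bmi, cuts)
        pop_dec = _decile_of(pop_bmi, cuts)
        per_indiv_w = w[pop_dec]
        total = per_indiv_w.sum()
        if total <= 0:
            raise ValueError(
                "all selection weights are zero: no sampleable individuals"
            )
        return cls(
            decile_cuts=cuts,
            w=w,
            p=per_indiv_w / total,
            decile_probs=w / total,
            reference_name=name,
        )


@dataclass(frozen=True)
class SampledDataset:
    """Indices into a population forming one analysis dataset; ``p_at_draw``
    records each drawn individual's selection probability (for known IPW)."""

    indices: np.ndarray
    role: str  # "TWAS" | "GWAS"
    scheme: str  # "random" | "weighted"
    p_at_draw: np.ndarray | None = None

    def __len__(self) -> int:
        return self.indices.size


def draw_biased_sample(
    weights: SelectionWeights | np.ndarray,
    size: int,
    seed: int | np.random.Generator | None = None,
    role: str = "TWAS",
) -> SampledDataset:
    """Sample ``size`` individuals independently with replacement, with
    per-individual probabilities ``p``; deterministic given the seed."""
    p = weights.p if isinstance(weights, SelectionWeights) else np.asarray(weights, float)
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = _as_rng(seed)
    indices = rng.choice(p.size, size=size, replace=True, p=p)
    return SampledDataset(
        indices=indices, role=role, scheme="weighted", p_at_draw=p[indices]
    )


def random_sample_split(
    pop_size: int,
    n1: int = 750,
    n2: int = 1500,
    seed: int | np.random.Generator | None = None,
) -> tuple[SampledDataset, SampledDataset]:
    """Draw n1 + n2 distinct individuals uniformly without replacement and
    partition them at random into a TWAS set (n1) and a GWAS set (n2)."""
    if n1 + n2 > pop_size:
        raise ValueError("population smaller than requested n1 + n2")
    rng = _as_rng(seed)
    idx = rng.permutation(rng.choice(pop_size, size=n1 + n2, replace=False))
    d1 = SampledDataset(indices=idx[:n1], role="TWAS", scheme="random")
    d2 = SampledDataset(indices=idx[n1:], role="GWAS", scheme="random")
    return d1, d2


def ipw_known(sample: SampledDataset) -> np.ndarray:
    """True inverse-probability weights 1 / p_i for a weighted sample."""
    if sample.scheme != "weighted" or sample.p_at_draw is None:
        raise ValueError("known IPW requires a weighted sample with recorded p")
    p = sample.p_at_draw
    if np.any(p <= 0):
        raise ValueError("selection probabilities at draw must be positive")
    return 1.0 / p


@dataclass(frozen=True)
class BMIPredictor:
    """OLS coefficients of BMI on (age, weight), fitted on the survey
    reference sample an estimated-weight IPW analysis observes."""

    intercept: float
    age: float
    weight: float

    def predict(self, age: np.ndarray, weight: np.ndarray) -> np.ndarray:
        return self.intercept + self.age * np.asarray(age) + self.weight * np.asarray(weight)


def fit_bmi_predictor(referent: ReferenceBMISample) -> BMIPredictor:
    """Fit BMI ~ age + weight by ordinary least squares on a reference
    cohort sample; deterministic."""
    n = len(referent)
    if n < 3:
        raise ValueError("need at least 3 records to fit the BMI predictor")
    X = np.column_stack([np.ones(n), referent.age, referent.weight])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: age/weight are degenerate")
    coef, *_ = np.linalg.lstsq(X, referent.bmi, rcond=None)
    return BMIPredictor(intercept=float(coef[0]), age=float(coef[1]), weight=float(coef[2]))


def ipw_estimated(
    age: np.ndarray,
    weight: np.ndarray,
    predictor: BMIPredictor,
    selection: SelectionWeights,
) -> np.ndarray:
    """Estimated inverse-probability weights from predicted BMI.

    Each sampled individual's BMI is predicted from (age, weight), mapped to
    its population BMI decile, and assigned that decile's selection
    probability; the weight is the reciprocal.  Prediction error can land an
    individual in a decile the reference cohort never occupies (estimated
    probability 0); such individuals receive the capped fallback weight
    1 / (minimum positive per-decile probability), which preserves the weight
    ordering without producing infinities.  The absolute probability scale is
    immaterial: weighted least squares is invariant to a common rescaling of
    the weights.
    """
    pred_bmi = predictor.predict(age, weight)
    dec = _decile_of(pred_bmi, selection.decile_cuts)
    decile_p = selection.decile_probs
    positive = decile_p[decile_p > 0]
    p_est = np.where(decile_p[dec] > 0, decile_p[dec], positive.min())
    return 1.0 / p_est
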