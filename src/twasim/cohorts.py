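"""Synthetic reference cohorts with realistic BMI category structure.

Real observational cohorts (a population survey, a tissue-donor biobank, a
chronic-kidney-disease cohort, a healthy-volunteer study) differ sharply in
their BMI distributions.  Only the four-category BMI breakdown of each cohort
is published, so this module reconstructs *synthetic* BMI samples whose
category proportions match the published table, and attaches age / body-weight
/ height covariates from which BMI is predictable with realistic error.  These
samples stand in for the cohorts' observed BMI data when building
decile-matched sampling weights (:mod:`twasim.weights`).

BMI categories follow the WHO convention, read left-closed / right-open:
underweight [0, 18.5), normal [18.5, 25), overweight [25, 30), obese [30, inf)
kg/m^2.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "CATEGORY_EDGES",
    "CohortSpec",
    "ReferenceBMISample",
    "builtin_cohort_table",
    "load_cohort_table",
    "sample_reference_bmi",
    "attach_covariates",
    "category_proportions",
]

#: Internal BMI category boundaries (kg/m^2); bins are [lo, hi).
CATEGORY_EDGES = (18.5, 25.0, 30.0)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CohortSpec:
    """A reference cohort's published BMI category breakdown.

    Parameters
    ----------
    cohort_name, sex
        Labels identifying the published table row.
    n
        Published cohort size for that sex stratum.
    proportions
        Fractions in the four BMI categories [<18.5, 18.5-24.9, 25.0-29.9,
        >=30.0]; renormalized to sum to 1 on construction (published rows can
        sum to 0.999/1.001 through rounding).
    underweight_lower
        Lower support of the underweight category (the published table is
        open-ended below 18.5); uniform on [underweight_lower, 18.5).
    obese_tail_mean
        Mean of the exponential tail above 30 kg/m^2 for the obese category.
    """

    cohort_name: str
    sex: str
    n: int
    proportions: tuple[float, float, float, float]
    underweight_lower: float = 15.0
    obese_tail_mean: float = 5.0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (4,):
            raise ValueError("proportions must have exactly 4 categories")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("proportions must lie in [0, 1]")
        total = p.sum()
        if not 0.99 <= total <= 1.01:
            raise ValueError(f"proportions sum to {total:.4f}, expected ~1")
        object.__setattr__(self, "proportions", tuple(p / total))
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        if self.proportions[0] > 0 and not (0 < self.underweight_lower < 18.5):
            raise ValueError(
                "underweight category has positive mass but degenerate support: "
                f"underweight_lower={self.underweight_lower!r}"
            )
        if self.proportions[3] > 0 and self.obese_tail_mean <= 0:
            raise ValueError(
                "obese category has positive mass but degenerate support: "
                f"obese_tail_mean={self.obese_tail_mean!r}"
            )


@dataclass(frozen=True)
class ReferenceBMISample:
    """A synthetic draw of BMI and covariates from a :class:`CohortSpec`.

    Invariants: ``weight == bmi * height**2`` per record; all vectors share
    one length (``spec.n`` unless an override size was requested).
    """

    bmi: np.ndarray
    age: np.ndarray
    weight: np.ndarray
    height: np.ndarray
    spec: CohortSpec
    seed: int | None = None

    def __len__(self) -> int:
        return self.bmi.size


def load_cohort_table(path_or_file) -> dict[tuple[str, str], CohortSpec]:
    """Read cohort specs from a TSV with columns cohort, sex, n, p_under,
    p_normal, p_over, p_obese.  Returns a mapping keyed by (cohort, sex)."""
    if hasattr(path_or_file, "read"):
        rows = list(csv.DictReader(path_or_file, delimiter="\t"))
    else:
        with open(path_or_file, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    table: dict[tuple[str, str], CohortSpec] = {}
    for row in rows:
        spec = CohortSpec(
            cohort_name=row["cohort"],
            sex=row["sex"],
            n=int(row["n"]),
            proportions=(
                float(row["p_under"]),
                float(row["p_normal"]),
                float(row["p_over"]),
                float(row["p_obese"]),
            ),
        )
        table[(spec.cohort_name, spec.sex)] = spec
    return table


def builtin_cohort_table() -> dict[tuple[str, str], CohortSpec]:
    """The eight published cohort x sex rows (NHANES / GTEx / CRIC / GENE,
    women / men) shipped with the package."""
    ref = resources.files("twasim").joinpath("data/table1_cohorts.tsv")
    with ref.open(newline="") as fh:
        return load_cohort_table(fh)


def get_cohort(cohort_name: str, sex: str) -> CohortSpec:
    """Look up one built-in cohort row; raises ``KeyError`` naming the valid
    keys for unknown (cohort, sex) pairs."""
    table = builtin_cohort_table()
    key = (cohort_name, sex)
    if key not in table:
        raise KeyError(
            f"unknown cohort row {key!r}; valid keys: {sorted(table)}"
        )
    return table[key]


def sample_reference_bmi(
    spec: CohortSpec,
    size: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> ReferenceBMISample:
    """Draw a synthetic BMI + covariate sample from a cohort spec.

    Each record's category is multinomial on ``spec.proportions``; BMI within
    categories 1-3 is uniform on the category interval, and the obese
    category is 30 + Exponential(``spec.obese_tail_mean``), capturing the
    right-tail skew of real BMI distributions.  Deterministic given
    ``(spec, size, seed)``.
    """
    rng = _as_rng(seed)
    n = spec.n if size is None else int(size)
    if n < 1:
        raise ValueError("size must be >= 1")
    p = np.asarray(spec.proportions)
    cat = rng.choice(4, size=n, p=p)
    u = rng.random(n)
    edges = (spec.underweight_lower,) + CATEGORY_EDGES
    bmi = np.empty(n)
    for k in range(3):
        mask = cat == k
        bmi[mask] = edges[k] + u[mask] * (edges[k + 1] - edges[k])
    mask = cat == 3
    bmi[mask] = 30.0 + rng.exponential(spec.obese_tail_mean, mask.sum())
    age, weight, height = attach_covariates(bmi, rng)
    return ReferenceBMISample(
        bmi=bmi, age=age, weight=weight, height=height, spec=spec,
        seed=seed if isinstance(seed, int) else None,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lo: float, hi: float, size: int,
) -> np.ndarray:
    # rejection sampling; bounds are ~3 sd out so rejection rate is ~0.1%
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def attach_covariates(
    bmi: np.ndarray,
    seed: int | np.random.Generator | None = None,
    *,
    height_mean: float = 1.65,
    height_sd: float = 0.08,
    height_bounds: tuple[float, float] = (1.40, 2.05),
    age_range: tuple[float, float] = (21.0, 70.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (age, weight, height) consistent with a BMI vector.

    Height is drawn independently of BMI from a truncated normal; body weight
    is then *defined* by the BMI identity ``weight = bmi * height**2`` (kg),
    so a linear model of BMI on (age, weight) is informative but imperfect —
    exactly the situation an estimated-weight IPW procedure faces.  Age is
    uniform on ``age_range`` and carries no BMI information by construction.
    """
    bmi = np.asarray(bmi, dtype=float)
    if bmi.size == 0:
        raise ValueError("bmi vector is empty")
    if np.any(bmi <= 0):
        raise ValueError("all BMI values must be positive")
    rng = _as_rng(seed)
    n = bmi.size
    height = _truncated_normal(
        rng, height_mean, height_sd, height_bounds[0], height_bounds[1], n
    )
    age = rng.uniform(age_range[0], age_range[1], n)
    weight = bmi * height**2
    return age, weight, height


def category_proportions(bmi: np.ndarray) -> np.ndarray:
    """Fractions of records in the four WHO BMI categories (left-closed bins:
    a value of exactly 18.5 counts as normal weight)."""
    bmi = np.asarray(bmi, dtype=float)
    if bmi.size == 0:
        raise ValueError("cannot compute category proportions of an empty vector")
    counts = np.bincount(np.digitize(bmi, CATEGORY_EDGES), minlength=4)
    return counts / bmi.size
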