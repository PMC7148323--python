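#!/usr/bin/env python
"""Simulate one full-size population under the composite model and summarize it.

Reports the sample moments of genotype, expression and trait, the anti-log
expression scale, and the BMI decile cut points used downstream by the
cohort-mimicking sampling. Writes results/population_summary.tsv and (for
inspection) a 1,000-row sample of individual records to
results/population_head.tsv.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from twasim import DGPParams, population_summary, simulate_population
from twasim.weights import population_deciles


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--pop-size", type=int, default=100_000)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    pop = simulate_population(DGPParams(pop_size=args.pop_size), seed=args.seed)
    summ = population_summary(pop)
    cuts = population_deciles(pop.bmi)

    args.outdir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([summ])
    frame.to_csv(args.outdir / "population_summary.tsv", sep="\t", index=False)
    head = pd.DataFrame(
        {
            "id": np.arange(1000),
            "z1": pop.z[:1000, 0],
            "z2": pop.z[:1000, 1],
            "x": pop.x[:1000].round(4),
            "y": pop.y[:1000].round(4),
            "bmi": pop.bmi[:1000].round(2),
            "age": pop.age[:1000].round(1),
            "weight": pop.weight[:1000].round(2),
            "height": pop.height[:1000].round(3),
        }
    )
    head.to_csv(args.outdir / "population_head.tsv", sep="\t", index=False)

    print(f"wrote {args.outdir}/population_summary.tsv and population_head.tsv",
          file=sys.stderr)
    for k, v in summ.items():
        print(f"{k}: {v}")
    print("bmi decile cuts:", np.round(cuts, 2))
    print(
        "\nThe trait is natural-log BMI anchored at the survey mean; the two "
        "SNPs shift expression by 0.06 log2 units per allele against a "
        "residual sd of 1.6, so the genetic signal explains ~0.1% of "
        "expression variance."
    )


if __name__ == "__main__":
    main()
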