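#!/usr/bin/env python
"""Run the four sampling scenarios plus the IPW variants and tabulate results.

Monte-Carlo study of how cohort-mimicking (BMI-decile-matched) sampling of
the TWAS and GWAS datasets distorts the two-stage expression-trait
association estimate, and what inverse probability weighting recovers.
Each replicate regenerates the population and the synthetic reference
cohorts; the per-scenario summary mirrors a results-table row (mean
estimate, relative bias, CI length, coverage) plus the stage-1 coefficient
biases.

Writes results/scenario_summary.tsv and results/stage1_bias.tsv; with
--keep-replicates, per-replicate tables go to scratch/replicates_<name>.tsv.
"""

import argparse
import sys
import time
from pathlib import Path

import pandas as pd

from twasim import DGPParams, run_scenario, summaries_to_frame
from twasim.experiment import replicates_to_frame, stage_one_bias_table, table2_scenarios, with_ipw


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=2000)
    ap.add_argument("--pop-size", type=int, default=20_000,
                    help="population size per replicate (use 100000 for the full-scale run)")
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--keep-replicates", action="store_true")
    args = ap.parse_args()

    dgp = DGPParams(pop_size=args.pop_size)
    scen = table2_scenarios(replicates=args.replicates, base_seed=args.seed, dgp=dgp)
    configs = list(scen.values()) + [
        with_ipw(scen["GTEx-RS"], "known"),
        with_ipw(scen["GTEx-RS"], "estimated"),
    ]

    summaries, bias_tables = [], []
    for cfg in configs:
        t0 = time.time()
        results, summary = run_scenario(cfg)
        summaries.append(summary)
        tab = stage_one_bias_table(results)
        tab.insert(0, "scenario", cfg.name)
        bias_tables.append(tab)
        print(f"{cfg.name}: {len(results)} replicates in {time.time()-t0:.1f}s",
              file=sys.stderr)
        if args.keep_replicates:
            scratch = Path("scratch")
            scratch.mkdir(exist_ok=True)
            replicates_to_frame(cfg.name, results).to_csv(
                scratch / f"replicates_{cfg.name}.tsv", sep="\t", index=False
            )

    args.outdir.mkdir(parents=True, exist_ok=True)
    summary_frame = summaries_to_frame(summaries).round(4)
    summary_frame.to_csv(args.outdir / "scenario_summary.tsv", sep="\t", index=False)
    stage1_frame = pd.concat(bias_tables, ignore_index=True).round(2)
    stage1_frame.to_csv(args.outdir / "stage1_bias.tsv", sep="\t", index=False)

    cols = ["scenario", "ipw", "mean_estimate", "mean_rel_bias",
            "median_rel_bias", "mean_ci_length", "coverage"]
    print(summary_frame[cols].to_string(index=False))
    print("\nstage-1 mean relative bias (%):")
    print(stage1_frame.pivot(index="scenario", columns="coefficient",
                             values="mean_rel_bias").to_string())
    print(
        "\nUnder these generative constants the two SNPs are a very weak "
        "instrument (they explain ~0.1% of expression variance), so the "
        "stage-2 estimate is strongly attenuated and noisy in every "
        "scenario; biased sampling shifts the stage-1 coefficients downward "
        "as expected, but its stage-2 signature and the IPW correction are "
        "swamped by first-stage noise. See docs/methods.md for the "
        "weak-instrument analysis."
    )


if __name__ == "__main__":
    main()
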