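"""Locate the best hybrid weighting alpha per round and scenario.

Reads the summary produced by 01_run_selection_experiment.py (or recomputes
it when absent) and reports, for each sex, scenario and fit round, the grid
alpha whose mean capture cost is smallest. The expected pattern: trait-heavy
weightings win early, contest-heavy weightings win once enough rounds have
accumulated, and the squad pre-cut shifts the optimum toward trait weight.
"""

import argparse
from pathlib import Path

import pandas as pd

from adaptsel.experiment_runner import (
    SCENARIO_ALL,
    SCENARIO_PRECUT,
    SimConfig,
    find_optimal_alpha,
    run_experiment,
    summarize,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    summary_path = args.out_dir / "selection_summary.csv"
    if summary_path.exists():
        summary = pd.read_csv(summary_path, dtype={"alpha": str})
    else:
        config = SimConfig(master_seed=args.seed)
        summary = summarize(run_experiment(config))

    rows = []
    for sex in ("male", "female"):
        for scenario in (SCENARIO_ALL, SCENARIO_PRECUT):
            for rnd in sorted(summary.loc[summary["round"] > 0, "round"].unique()):
                alpha, mean = find_optimal_alpha(summary, sex, scenario, int(rnd))
                rows.append(
                    {
                        "sex": sex,
                        "scenario": scenario,
                        "round": int(rnd),
                        "optimal_alpha": alpha,
                        "mean_min_selected": mean,
                    }
                )
    optima = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    optima.to_csv(args.out_dir / "hybrid_optima.csv", index=False)

    print(f"wrote {len(optima)} optimum cells to {args.out_dir}/hybrid_optima.csv\n")
    for (sex, scenario), grp in optima.groupby(["sex", "scenario"]):
        first, last = grp.iloc[0], grp.iloc[-1]
        print(
            f"{sex:6s} {scenario:15s}: optimal alpha {first['optimal_alpha']:.1f} "
            f"(round {first['round']:.0f}, {first['mean_min_selected']:.1f} needed) "
            f"-> {last['optimal_alpha']:.1f} "
            f"(round {last['round']:.0f}, {last['mean_min_selected']:.1f} needed)"
        )


if __name__ == "__main__":
    main()
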