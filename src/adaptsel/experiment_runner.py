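"""Replicate orchestration: simulate, score strategies, aggregate.

One replicate = one fresh population of N individuals per sex, 20 rounds of
random deterministic contests, Bradley-Terry refits on the cumulative
records every two rounds, and the capture statistic evaluated for trait-only
selection, contest-only selection, and the full alpha grid of hybrid scores.
Two selection scenarios share the same contest stream: one uses every
contest, the other (squad pre-selection) admits only the top 40 individuals
by trait rank and uses only the contests fought among them.
Across replicates the per-cell means and t-based 95% confidence intervals
form the experiment summary.

Randomness: a single master seed spawns an independent, order-independent
stream per (sex, replicate) via numpy's SeedSequence, so any replicate can be
re-run in isolation and reproduce bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bt_rank import fit_bradley_terry
from .contest_engine import simulate_rounds
from .selection_metrics import (
    DEFAULT_ALPHA_GRID,
    alpha_sweep,
    apply_precut,
    min_selected_to_capture,
)
from .synthetic_population import (
    FEMALE_PARAMS,
    MALE_PARAMS,
    SexParams,
    generate_population,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "run_replicate",
    "run_experiment",
    "summarize",
    "find_optimal_alpha",
    "headline_metrics",
]

SCENARIO_ALL = "all_individuals"
SCENARIO_PRECUT = "precut_top40"
TRAIT_ONLY = "trait_only"

SUMMARY_COLUMNS = [
    "sex",
    "scenario",
    "round",
    "alpha",
    "mean_min_selected",
    "ci_low",
    "ci_high",
    "sem",
    "n_effective",
]

_SEX_CODE = {"male": 1, "female": 2}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the replicate experiment (defaults = full design)."""

    n_individuals: int = 100
    n_replicates: int = 20
    n_rounds: int = 20
    fit_rounds: tuple[int, ...] = tuple(range(2, 21, 2))
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    true_top_fraction: float = 0.10
    precut_keep: int = 40
    bt_penalty: float = 0.0  # 0 = capped-IRLS ML fit, the published procedure
    sex_params: dict[str, SexParams] = field(
        default_factory=lambda: {"male": MALE_PARAMS, "female": FEMALE_PARAMS}
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 1 or r > self.n_rounds for r in self.fit_rounds):
            raise ValueError("fit_rounds must lie within 1..n_rounds")
        k = self.true_top_fraction * self.n_individuals
        if round(k) < 1:
            raise ValueError("true_top_fraction * n_individuals must round to >= 1")
        if self.precut_keep > self.n_individuals:
            raise ValueError("precut_keep cannot exceed n_individuals")

    @property
    def true_top_k(self) -> int:
        return int(round(self.true_top_fraction * self.n_individuals))


def _replicate_rng(config: SimConfig, sex: str, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=config.master_seed, spawn_key=(_SEX_CODE[sex], replicate)
    )
    return np.random.default_rng(ss)


def run_replicate(config: SimConfig, sex: str, replicate_index: int) -> pd.DataFrame:
    """Run one replicate for one sex; returns long-format SelectionCurve rows.

    Emits one trait-only row (round 0, alpha label ``trait_only``) plus one
    row per (scenario, fit round, grid alpha). In the pre-cut scenario a
    replicate whose true top k is not fully inside the trait-rank cut has no
    attainable capture cutoff; its cells are recorded as NaN and excluded
    from aggregation (with a log message), since selection is confined to the
    admitted pool.
    """
    params = config.sex_params[sex]
    rng = _replicate_rng(config, sex, replicate_index)
    pop = generate_population(config.n_individuals, params, rng)

    ids = list(pop["id"])
    dominance = dict(zip(pop["id"], pop["true_dominance"]))
    trait_ranks = dict(zip(pop["id"], pop["trait_rank"]))
    k = config.true_top_k
    true_top = set(pop.loc[pop["true_rank"] <= k, "id"])
    # tie-break for equal BT abilities: best trait rank first
    tie_break = list(pop.sort_values("trait_rank")["id"])

    rows = [
        {
            "replicate": replicate_index,
            "sex": sex,
            "scenario": SCENARIO_ALL,
            "round": 0,
            "alpha": TRAIT_ONLY,
            "min_selected": float(min_selected_to_capture(trait_ranks, true_top)),
        }
    ]

    # One contest stream per replicate: all individuals compete. The pre-cut
    # scenario restricts attention to contests among the top trait ranks —
    # the removed individuals' contests simply never inform that analysis —
    # so each admitted individual carries fewer usable contests per round
    # than in the full scenario.
    records_all = simulate_rounds(ids, dominance, config.n_rounds, rng)
    precut_pop = apply_precut(pop, config.precut_keep)
    precut_ids = set(precut_pop["id"])
    records_precut = records_all[
        records_all["winner_id"].isin(precut_ids)
        & records_all["loser_id"].isin(precut_ids)
    ]

    scenarios = {
        SCENARIO_ALL: (pop, records_all),
        SCENARIO_PRECUT: (precut_pop, records_precut),
    }
    for scenario, (subpop, records) in scenarios.items():
        sub_ids = list(subpop["id"])
        sub_trait_ranks = {i: trait_ranks[i] for i in sub_ids}
        sub_tie_break = [i for i in tie_break if i in set(sub_ids)]
        capturable = true_top <= set(sub_ids)
        if not capturable:
            logger.info(
                "replicate %d (%s, %s): %d true-top member(s) removed by the "
                "pre-cut; capture unattainable",
                replicate_index,
                sex,
                scenario,
                len(true_top - set(sub_ids)),
            )
        contest_ranks_by_round = {}
        for rnd in config.fit_rounds:
            cumulative = records[records["round"] <= rnd]
            abilities = fit_bradley_terry(
                cumulative,
                sub_ids,
                penalty=config.bt_penalty,
                round=rnd,
                tie_break=sub_tie_break,
            )
            contest_ranks_by_round[rnd] = dict(
                zip(abilities["id"], abilities["contest_rank"])
            )
        if capturable:
            sweep = alpha_sweep(
                sub_trait_ranks, contest_ranks_by_round, true_top, config.alpha_grid
            )
            for rec in sweep.itertuples(index=False):
                rows.append(
                    {
                        "replicate": replicate_index,
                        "sex": sex,
                        "scenario": scenario,
                        "round": rec.round,
                        "alpha": f"{rec.alpha:.1f}",
                        "min_selected": float(rec.min_selected),
                    }
                )
        else:
            for rnd in config.fit_rounds:
                for alpha in config.alpha_grid:
                    rows.append(
                        {
                            "replicate": replicate_index,
                            "sex": sex,
                            "scenario": scenario,
                            "round": rnd,
                            "alpha": f"{alpha:.1f}",
                            "min_selected": np.nan,
                        }
                    )
    return pd.DataFrame(rows)


def run_experiment(
    config: SimConfig, sexes: tuple[str, ...] = ("male", "female")
) -> pd.DataFrame:
    """All replicates for the requested sexes, concatenated."""
    frames = []
    for sex in sexes:
        for rep in range(config.n_replicates):
            logger.debug("running replicate %d (%s)", rep, sex)
            frames.append(run_replicate(config, sex, rep))
    return pd.concat(frames, ignore_index=True)


def summarize(rows: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Per-cell mean, t-based CI and s.e.m. across replicates.

    NaN cells (pre-cut replicates where capture was unattainable) are dropped
    before aggregation; ``n_effective`` records how many replicates remain.
    A cell with fewer than two contributing replicates has no interval and
    raises.
    """
    out = []
    for (sex, scenario, rnd, alpha), grp in rows.groupby(
        ["sex", "scenario", "round", "alpha"], sort=True
    ):
        vals = grp["min_selected"].dropna().to_numpy()
        n = len(vals)
        if n < 2:
            raise ValueError(
                f"cell (sex={sex}, scenario={scenario}, round={rnd}, alpha={alpha}) "
                f"has {n} usable replicate(s); cannot form a confidence interval"
            )
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(n))
        tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
        out.append(
            {
                "sex": sex,
                "scenario": scenario,
                "round": rnd,
                "alpha": alpha,
                "mean_min_selected": mean,
                "ci_low": mean - tcrit * sem,
                "ci_high": mean + tcrit * sem,
                "sem": sem,
                "n_effective": n,
            }
        )
    return pd.DataFrame(out, columns=SUMMARY_COLUMNS)


def find_optimal_alpha(
    summary: pd.DataFrame, sex: str, scenario: str, round: int
) -> tuple[float, float]:
    """Grid alpha minimizing the mean capture statistic for one cell group.

    Ties go to the larger alpha: trait information is available before any
    contest, so at equal cost the trait-heavier weighting is the cheaper
    strategy to run.
    """
    cells = summary[
        (summary["sex"] == sex)
        & (summary["scenario"] == scenario)
        & (summary["round"] == round)
        & (summary["alpha"] != TRAIT_ONLY)
    ]
    if cells.empty:
        raise ValueError(f"no grid cells for ({sex}, {scenario}, round {round})")
    alphas = cells["alpha"].astype(float).to_numpy()
    means = cells["mean_min_selected"].to_numpy()
    best = min(zip(means, -alphas))  # ties -> larger alpha
    return float(-best[1]), float(best[0])


def headline_metrics(summary: pd.DataFrame) -> dict[str, float]:
    """The experiment's headline quantities, extracted from a summary frame.

    Units are individuals throughout: each value is the mean (across
    replicates) of the minimum number of top-ranked individuals that must be
    selected to capture the true top 10%.
    """

    def cell(sex, scenario, rnd, alpha):
        m = summary[
            (summary["sex"] == sex)
            & (summary["scenario"] == scenario)
            & (summary["round"] == rnd)
            & (summary["alpha"] == alpha)
        ]
        return float(m["mean_min_selected"].iloc[0])

    plateau_cells = [
        cell(sex, SCENARIO_ALL, rnd, "0.0")
        for sex in ("male", "female")
        for rnd in (14, 16, 18, 20)
    ]
    metrics = {
        "trait_only_mean_male": cell("male", SCENARIO_ALL, 0, TRAIT_ONLY),
        "trait_only_mean_female": cell("female", SCENARIO_ALL, 0, TRAIT_ONLY),
        "contest_only_mean_male_round4": cell("male", SCENARIO_ALL, 4, "0.0"),
        "contest_only_mean_male_round10": cell("male", SCENARIO_ALL, 10, "0.0"),
        "contest_only_mean_female_round10": cell("female", SCENARIO_ALL, 10, "0.0"),
        "contest_only_plateau_rounds14_20": float(np.mean(plateau_cells)),
    }
    for sex in ("male", "female"):
        for rnd in (4, 20):
            _, best = find_optimal_alpha(summary, sex, SCENARIO_ALL, rnd)
            metrics[f"best_hybrid_mean_{sex}_round{rnd}_all"] = best
        _, best = find_optimal_alpha(summary, sex, SCENARIO_PRECUT, 20)
        metrics[f"best_hybrid_mean_{sex}_round20_precut"] = best
    return metrics
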