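"""Hybrid rank aggregation and the minimum-selected-to-capture statistic.

A selection strategy produces a candidate ranking; its cost is the smallest
cutoff c such that choosing the top c candidates is guaranteed to include
every member of the true top k. That cutoff equals the worst (largest)
candidate rank held by a true-top member.

The hybrid strategy blends the pre-contest trait ranking with the
contest-based ranking through a convex combination of the two rank vectors,

    h_i = alpha * trait_rank_i + (1 - alpha) * contest_rank_i,

so alpha = 1 is trait-only selection and alpha = 0 is contest-only.
Individuals are re-ranked by ascending h.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "hybrid_rank",
    "min_selected_to_capture",
    "apply_precut",
    "alpha_sweep",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = tuple(round(0.1 * k, 1) for k in range(11))

SELECTION_COLUMNS = ["replicate", "sex", "scenario", "round", "alpha", "min_selected"]


def hybrid_rank(
    trait_ranks: Mapping, contest_ranks: Mapping, alpha: float
) -> dict:
    """Re-rank individuals by the alpha-weighted combination of two rankings.

    Ties in the hybrid score are broken by trait rank then id — deterministic
    and favouring the information available before any contest.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if set(trait_ranks) != set(contest_ranks):
        raise ValueError("trait and contest rankings cover different id sets")
    ids = sorted(trait_ranks)
    h = {i: alpha * trait_ranks[i] + (1.0 - alpha) * contest_ranks[i] for i in ids}
    order = sorted(ids, key=lambda i: (h[i], trait_ranks[i], i))
    return {ident: r for r, ident in enumerate(order, start=1)}


def min_selected_to_capture(candidate_ranks: Mapping, true_top: Iterable) -> int:
    """Smallest cutoff whose top set contains all of ``true_top``.

    Equals the maximum candidate rank over the true-top members.
    """
    true_top = set(true_top)
    if not true_top:
        raise ValueError("true_top must be non-empty")
    missing = true_top - set(candidate_ranks)
    if missing:
        raise KeyError(
            f"true-top members absent from the candidate ranking: {sorted(missing)[:5]}"
        )
    return max(candidate_ranks[i] for i in true_top)


def apply_precut(population: pd.DataFrame, keep_n: int) -> pd.DataFrame:
    """Keep only the ``keep_n`` best individuals by trait rank.

    Models squad pre-selection: the removed individuals never compete, but
    the true top k stays defined on the full population, so capture can
    become impossible when trait noise pushes a true-top member below the
    cut — callers must handle that case (see the experiment runner).
    """
    n = len(population)
    if keep_n > n:
        raise ValueError(f"keep_n ({keep_n}) exceeds population size ({n})")
    kept = population[population["trait_rank"] <= keep_n]
    return kept.reset_index(drop=True)


def alpha_sweep(
    trait_ranks: Mapping,
    contest_ranks_by_round: Mapping[int, Mapping],
    true_top: Iterable,
    alpha_grid: Iterable[float] = DEFAULT_ALPHA_GRID,
) -> pd.DataFrame:
    """Capture statistic for every (round, alpha) cell.

    At alpha = 0 and alpha = 1 the rows reproduce the contest-only and
    trait-only metrics exactly.
    """
    alpha_grid = list(alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid must be non-empty")
    true_top = set(true_top)
    rows = []
    for rnd, cranks in sorted(contest_ranks_by_round.items()):
        for alpha in alpha_grid:
            ranks = hybrid_rank(trait_ranks, cranks, alpha)
            rows.append(
                {
                    "round": rnd,
                    "alpha": alpha,
                    "min_selected": min_selected_to_capture(ranks, true_top),
                }
            )
    return pd.DataFrame(rows)
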