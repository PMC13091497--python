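"""Bradley-Terry fitting and contest ranking from win/loss records.

The Bradley-Terry model places each individual i at a log-ability a_i and
models the probability that i beats j as sigma(a_i - a_j), with sigma the
logistic function. Abilities are identifiable only up to an additive
constant; the returned tables are re-centred to sum to zero.

Deterministic contest data are perfectly consistent with a total order
(quasi-complete separation), under which the maximum-likelihood abilities
have no finite maximizer. The fitter offers two regimes:

``penalty > 0``
    Maximizes the ridge-penalized log-likelihood

        L(a) = sum_contests log sigma(a_winner - a_loser) - penalty * sum a_i^2,

    which is strictly concave, by damped Newton iteration to gradient norm
    < 1e-8. This is the well-posed choice for downstream inference on the
    ability scale.

``penalty = 0`` (default)
    Plain maximum likelihood via iteratively reweighted least squares
    (Newton) from a zero start, capped at 25 iterations — the standard GLM
    fitting procedure and cap. Under separation the abilities grow without
    bound and the cap is what terminates the fit; the returned estimates are
    the conventional capped-iteration solution whose ordering is the usable
    output. Rankings derived this way match what practitioners obtain from
    logistic-regression Bradley-Terry software on separable contest data.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

__all__ = ["fit_bradley_terry", "contest_ranks", "penalized_loglik"]

ABILITY_COLUMNS = ["round", "id", "ability", "contest_rank", "n_contests"]

#: Standard GLM/IRLS iteration cap used for the unpenalized fit.
ML_MAX_ITER = 25


def _aggregate(records: pd.DataFrame, index: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a contest stream to per-ordered-pair win counts.

    Returns (i, j, wins) arrays where ``wins[k]`` is how often ``i[k]`` beat
    ``j[k]``; each unordered pair appears at most twice (once per direction).
    """
    w = records["winner_id"].map(index)
    l = records["loser_id"].map(index)
    if w.isna().any() or l.isna().any():
        bad = set(records.loc[w.isna(), "winner_id"]) | set(records.loc[l.isna(), "loser_id"])
        raise ValueError(f"contest records reference unknown ids: {sorted(bad)[:5]}")
    counts = (
        pd.DataFrame({"i": w.astype(int), "j": l.astype(int)})
        .groupby(["i", "j"])
        .size()
    )
    idx = counts.index.to_frame(index=False)
    return idx["i"].to_numpy(), idx["j"].to_numpy(), counts.to_numpy(dtype=float)


def penalized_loglik(
    abilities: np.ndarray, i: np.ndarray, j: np.ndarray, wins: np.ndarray, penalty: float
) -> float:
    """(Penalized) Bradley-Terry log-likelihood at ``abilities``."""
    d = abilities[i] - abilities[j]
    return float(np.sum(wins * log_expit(d)) - penalty * np.sum(abilities**2))


def _grad_hess(a, i, j, wins, n):
    p = expit(a[i] - a[j])
    g_pair = wins * (1.0 - p)
    grad = np.zeros(n)
    np.add.at(grad, i, g_pair)
    np.add.at(grad, j, -g_pair)
    h_pair = wins * p * (1.0 - p)
    hess = np.zeros((n, n))
    np.add.at(hess, (i, i), h_pair)
    np.add.at(hess, (j, j), h_pair)
    np.add.at(hess, (i, j), -h_pair)
    np.add.at(hess, (j, i), -h_pair)
    return grad, hess


def _fit_ridge(i, j, wins, n, penalty, tol, max_iter):
    a = np.zeros(n)
    for _ in range(max_iter):
        grad, hess = _grad_hess(a, i, j, wins, n)
        grad -= 2.0 * penalty * a
        if np.linalg.norm(grad) < tol:
            return a
        hess += 2.0 * penalty * np.eye(n)
        step = np.linalg.solve(hess, grad)
        # backtracking keeps the strictly concave objective increasing
        ll0 = penalized_loglik(a, i, j, wins, penalty)
        t = 1.0
        while t >= 1e-12:
            a_new = a + t * step
            if penalized_loglik(a_new, i, j, wins, penalty) >= ll0:
                break
            t *= 0.5
        a = a_new
    grad, _ = _grad_hess(a, i, j, wins, n)
    grad -= 2.0 * penalty * a
    if np.linalg.norm(grad) >= tol:
        raise FloatingPointError(
            f"penalized Bradley-Terry fit did not reach |grad| < {tol:g} "
            f"(|grad| = {np.linalg.norm(grad):.3g})"
        )
    return a


def _fit_ml_irls(i, j, wins, n, max_iter):
    """Unpenalized Newton/IRLS from zero, reference player fixed at 0.

    No line search and a hard iteration cap, mirroring standard GLM fitting;
    under separation the iterates diverge steadily and the cap terminates
    the fit. The tiny diagonal stabilizer makes the step well defined when
    the comparison graph is disconnected (aliased abilities in GLM terms).
    """
    a = np.zeros(n)
    for _ in range(max_iter):
        grad, hess = _grad_hess(a, i, j, wins, n)
        hr = hess[1:, 1:] + 1e-10 * np.eye(n - 1)
        step = np.linalg.solve(hr, grad[1:])
        a[1:] += step
        if not np.all(np.isfinite(a)):
            raise FloatingPointError(
                "Bradley-Terry abilities overflowed at penalty=0; the data are "
                "separable (deterministic outcomes) — use penalty > 0 for a "
                "finite converged fit"
            )
        if np.abs(step).max() < 1e-8:
            break
    return a


def fit_bradley_terry(
    records: pd.DataFrame,
    ids: Sequence,
    penalty: float = 0.0,
    round: int | None = None,
    tie_break: Sequence | None = None,
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> pd.DataFrame:
    """Fit Bradley-Terry abilities from win/loss records.

    Parameters
    ----------
    records
        Frame with ``winner_id``/``loser_id`` columns (pass cumulative
        records for a cumulative fit).
    ids
        Every individual to estimate, including any with no contests; those
        receive ability exactly 0 and rank after contested individuals of
        equal ability.
    penalty
        Ridge weight lambda. 0 selects the capped-iteration ML fit; any
        positive value selects the converged penalized fit (see module
        docstring).
    round
        Label recorded in the output's ``round`` column.
    tie_break
        Identifier sequence, best first, breaking ability ties in the
        ranking (defaults to ``ids`` order).
    max_iter
        Iteration cap; defaults to 25 for the ML path and 200 for the
        penalized path.

    Returns
    -------
    AbilityTable frame: round, id, ability, contest_rank, n_contests, with
    abilities summing to zero and rank 1 for the largest ability.
    """
    ids = list(ids)
    if len(records) == 0:
        raise ValueError("cannot fit a Bradley-Terry model with no contest records")
    if penalty < 0:
        raise ValueError(f"penalty must be >= 0, got {penalty}")
    index = {ident: k for k, ident in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate ids")
    i, j, wins = _aggregate(records, index)
    n = len(ids)

    if penalty > 0:
        a = _fit_ridge(i, j, wins, n, penalty, tol, max_iter or 200)
    else:
        a = _fit_ml_irls(i, j, wins, n, max_iter or ML_MAX_ITER)

    n_contests = np.zeros(n, dtype=int)
    np.add.at(n_contests, i, wins.astype(int))
    np.add.at(n_contests, j, wins.astype(int))
    # centre contested abilities only: zero-contest ids keep their prior 0
    contested = n_contests > 0
    a[contested] -= a[contested].mean()

    if round is None:
        round = int(records["round"].max()) if "round" in records.columns else 0
    table = pd.DataFrame(
        {"round": round, "id": ids, "ability": a, "n_contests": n_contests}
    )
    table["contest_rank"] = contest_ranks(table, tie_break if tie_break is not None else ids)
    return table[ABILITY_COLUMNS]


def contest_ranks(abilities: pd.DataFrame, tie_break: Sequence) -> np.ndarray:
    """Convert abilities to dense ranks 1..N (rank 1 = largest ability).

    Ties are broken by position in ``tie_break``; among tied abilities,
    individuals with zero contests rank after contested ones (their ability
    is a prior value, not an estimate).
    """
    pos = {ident: k for k, ident in enumerate(tie_break)}
    missing = set(abilities["id"]) - pos.keys()
    if missing:
        raise ValueError(f"tie_break is missing ids: {sorted(missing)[:5]}")
    ability = abilities["ability"].to_numpy()
    uncontested = abilities["n_contests"].to_numpy() == 0
    ident = abilities["id"].to_numpy()
    order = sorted(
        range(len(ability)),
        key=lambda r: (-ability[r], uncontested[r], pos[ident[r]]),
    )
    ranks = np.empty(len(ability), dtype=int)
    ranks[order] = np.arange(1, len(ability) + 1)
    return ranks
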