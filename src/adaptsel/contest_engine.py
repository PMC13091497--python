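"""Staged pairwise contests: random pairing and deterministic resolution.

A round pairs individuals at random without replacement (one uniformly chosen
individual sits out when the cohort is odd) and every pair is resolved in
favour of the strictly larger true dominance value. Outcomes are therefore
transitive by construction — the win relation is the total order induced by
dominance, observed one random pair at a time.

An optional per-round exclusion list supports the empirical protocol in which
injured individuals (e.g. after claw loss) are withdrawn from later rounds
while their earlier records are retained.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContestRecord",
    "random_pairing",
    "rank_adjacent_pairing",
    "resolve_contest",
    "play_round",
    "simulate_rounds",
    "records_to_frame",
]

CONTEST_COLUMNS = ["round", "winner_id", "loser_id"]


class ContestRecord(NamedTuple):
    round: int
    winner_id: str
    loser_id: str


def random_pairing(
    ids: Sequence, rng: np.random.Generator
) -> list[tuple]:
    """Pair identifiers uniformly at random without replacement.

    With an even count every id appears in exactly one pair; with an odd
    count one uniformly chosen id sits out.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError(f"need at least 2 ids to form pairs, got {len(ids)}")
    perm = rng.permutation(len(ids))
    n_paired = len(ids) - (len(ids) % 2)
    return [
        (ids[perm[i]], ids[perm[i + 1]]) for i in range(0, n_paired, 2)
    ]


def rank_adjacent_pairing(ranking: Sequence) -> list[tuple]:
    """Pair a best-to-worst ordering as (1 vs 2), (3 vs 4), ...

    With an odd count the last (worst-ranked) identifier sits out.
    """
    ranking = list(ranking)
    if not ranking:
        raise ValueError("cannot pair an empty ranking")
    n_paired = len(ranking) - (len(ranking) % 2)
    return [(ranking[i], ranking[i + 1]) for i in range(0, n_paired, 2)]


def resolve_contest(
    pair: tuple, dominance: Mapping[str, float], round: int
) -> ContestRecord:
    """Decide a contest: the strictly larger dominance value always wins."""
    a, b = pair
    da, db = dominance[a], dominance[b]
    if da == db:
        raise ValueError(
            f"tied dominance values for {a!r} and {b!r} ({da}); deterministic "
            "resolution requires distinct values"
        )
    winner, loser = (a, b) if da > db else (b, a)
    return ContestRecord(round=round, winner_id=winner, loser_id=loser)


def play_round(
    ids: Sequence,
    dominance: Mapping[str, float],
    rng: np.random.Generator,
    round: int,
    exclude: Iterable = (),
) -> list[ContestRecord]:
    """One round of random pairings among the non-excluded ids."""
    excluded = set(exclude)
    eligible = [i for i in ids if i not in excluded]
    pairs = random_pairing(eligible, rng)
    return [resolve_contest(p, dominance, round) for p in pairs]


def simulate_rounds(
    ids: Sequence,
    dominance: Mapping[str, float],
    n_rounds: int,
    rng: np.random.Generator,
    exclude_by_round: Mapping[int, Iterable] | None = None,
) -> pd.DataFrame:
    """Simulate ``n_rounds`` rounds; returns a round,winner_id,loser_id frame."""
    exclude_by_round = exclude_by_round or {}
    records: list[ContestRecord] = []
    for r in range(1, n_rounds + 1):
        records.extend(
            play_round(ids, dominance, rng, r, exclude=exclude_by_round.get(r, ()))
        )
    return records_to_frame(records)


def records_to_frame(records: Iterable[ContestRecord]) -> pd.DataFrame:
    return pd.DataFrame(list(records), columns=CONTEST_COLUMNS)


def write_contests_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=CONTEST_COLUMNS)


def read_contests_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"winner_id": str, "loser_id": str})
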