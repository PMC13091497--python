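"""Empirical-format ingestion: raw morphometrics to capture trajectories.

The empirical workflow starts from two CSV tables — per-individual raw
measurements (body length in mm, seven claw dimensions per claw in mm, and
repeated grip-force trials per claw in newtons) and a per-contest stream
(round, winner, loser). Claw size is summarized as the first principal
component of the seven standardized dimensions (computed separately for the
left and right claw, then averaged); claw strength is the mean of the two
per-claw maximum forces; both are standardized within sex before entering
the sex-specific composite trait score.

The "true" ranking for the capture trajectory is, by design, the
Bradley-Terry ranking fitted on all rounds through the final round — the
best available estimate of the hierarchy, not an oracle. The final-round
capture value therefore equals k by construction; the informative part of
the trajectory is how quickly earlier rounds approach it.

Because the study's measured cohort is not publicly deposited, the module
ships a synthetic fixture generator that emulates the data layout: latent
traits from the simulation noise chain, a one-factor model expanding latent
claw size into seven correlated dimensions, noisy repeated strength trials,
and ten random contest rounds plus one rank-adjacent round.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bt_rank import fit_bradley_terry
from .contest_engine import (
    ContestRecord,
    play_round,
    rank_adjacent_pairing,
    records_to_frame,
    resolve_contest,
)
from .selection_metrics import min_selected_to_capture
from .synthetic_population import (
    FEMALE_PARAMS,
    MALE_PARAMS,
    SexParams,
    generate_population,
    rank_values,
)

__all__ = [
    "CLAW_DIMENSIONS",
    "EmpiricalFixtureConfig",
    "claw_size_pc1",
    "claw_strength_summary",
    "composite_trait_score",
    "derive_traits",
    "capture_trajectory",
    "generate_empirical_fixture",
    "read_traits_csv",
    "write_traits_csv",
]

#: The seven claw dimensions measured per claw (all in mm).
CLAW_DIMENSIONS = (
    "propodus_width_carpus",
    "propodus_width_dactyl",
    "pollex_width",
    "dactylus_width",
    "propodus_length",
    "pollex_length",
    "dactylus_length",
)

N_STRENGTH_TRIALS = 3
N_STRENGTH_DAYS = 2


def _claw_cols(side: str) -> list[str]:
    return [f"{side}_{d}" for d in CLAW_DIMENSIONS]


def _strength_cols(side: str) -> list[str]:
    return [
        f"{side}_strength_d{day}_t{trial}"
        for day in range(1, N_STRENGTH_DAYS + 1)
        for trial in range(1, N_STRENGTH_TRIALS + 1)
    ]


TRAIT_CSV_COLUMNS = (
    ["id", "sex", "body_length_mm"]
    + _claw_cols("left")
    + _claw_cols("right")
    + _strength_cols("left")
    + _strength_cols("right")
)


def claw_size_pc1(dim_table: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First principal component of seven standardized claw dimensions.

    The PCA is correlation-based: each column is centred and scaled to unit
    variance before eigendecomposition, since the dimensions mix widths and
    lengths on different mm scales. The component is oriented so that larger
    claws score higher (all loadings share a sign in well-behaved data).

    Returns (per-individual scores, fraction of variance explained).
    """
    if len(dim_table) < 3:
        raise ValueError("PCA needs at least 3 individuals")
    X = dim_table[list(CLAW_DIMENSIONS)].to_numpy(dtype=float)
    if X.shape[1] != len(CLAW_DIMENSIONS):
        raise ValueError("expected all 7 claw dimensions")
    if np.isnan(X).any():
        raise ValueError("missing claw dimension values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        const = [CLAW_DIMENSIONS[k] for k in np.where(sd == 0.0)[0]]
        raise ValueError(f"degenerate PCA: constant dimension(s) {const}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v1 = eigvecs[:, -1]
    if v1.sum() < 0:  # orient: larger claws -> larger score
        v1 = -v1
    explained = float(eigvals[-1] / eigvals.sum())
    return Z @ v1, explained


def claw_strength_summary(trials_left, trials_right) -> float:
    """Mean of the per-claw maximum forces across all trials and days."""
    left = np.asarray(trials_left, dtype=float)
    right = np.asarray(trials_right, dtype=float)
    if left.size == 0 or right.size == 0:
        raise ValueError("each claw needs at least one strength reading")
    return float((left.max() + right.max()) / 2.0)


def composite_trait_score(row: pd.Series, sex: str) -> float:
    """Sex-specific equal-weight composite of standardized traits."""
    if sex == "male":
        return float(row["claw_size"] + row["claw_strength"])
    if sex == "female":
        return float(row["body_length_std"] + row["claw_strength"])
    raise ValueError(f"unknown sex label: {sex!r}")


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def derive_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """RawTraitRecord table -> DerivedTraitTable, processed within sex.

    Standardization (mean 0, s.d. 1) and the claw-size PCA are done within
    sex, matching the sex-stratified contests and rankings.
    """
    out = []
    for sex, grp in raw.groupby("sex", sort=True):
        grp = grp.reset_index(drop=True)
        left_pc1, _ = claw_size_pc1(grp[_claw_cols("left")].set_axis(list(CLAW_DIMENSIONS), axis=1))
        right_pc1, _ = claw_size_pc1(grp[_claw_cols("right")].set_axis(list(CLAW_DIMENSIONS), axis=1))
        strength = np.array(
            [
                claw_strength_summary(
                    row[_strength_cols("left")].to_numpy(dtype=float),
                    row[_strength_cols("right")].to_numpy(dtype=float),
                )
                for _, row in grp.iterrows()
            ]
        )
        derived = pd.DataFrame(
            {
                "id": grp["id"],
                "sex": sex,
                "body_length_std": _standardize(grp["body_length_mm"].to_numpy(dtype=float)),
                "claw_size": _standardize((left_pc1 + right_pc1) / 2.0),
                "claw_strength": _standardize(strength),
            }
        )
        derived["trait_score"] = [
            composite_trait_score(row, sex) for _, row in derived.iterrows()
        ]
        derived["trait_rank"] = rank_values(
            derived["trait_score"].to_numpy(), list(derived["id"])
        )
        out.append(derived)
    return pd.concat(out, ignore_index=True)


def capture_trajectory(
    records: pd.DataFrame,
    derived: pd.DataFrame,
    fit_rounds,
    k: int,
    penalty: float = 0.0,
) -> pd.DataFrame:
    """Top-k capture cost per fit round, plus the pre-contest trait value.

    The true top k is taken from the Bradley-Terry ranking on all records
    through the last fit round. Row at round 0 is trait-only selection; each
    later row refits on the cumulative records through that round.
    """
    fit_rounds = sorted(fit_rounds)
    if not fit_rounds:
        raise ValueError("fit_rounds must be non-empty")
    if k < 1 or k > len(derived):
        raise ValueError(f"k must lie in 1..{len(derived)}, got {k}")
    last = fit_rounds[-1]
    if records["round"].max() < last:
        raise ValueError(
            f"records cover rounds through {records['round'].max()}, "
            f"but a fit at round {last} was requested"
        )
    ids = list(derived["id"])
    tie_break = list(derived.sort_values("trait_rank")["id"])
    trait_ranks = dict(zip(derived["id"], derived["trait_rank"]))

    final = fit_bradley_terry(
        records[records["round"] <= last], ids, penalty=penalty, round=last,
        tie_break=tie_break,
    )
    true_top = set(final.loc[final["contest_rank"] <= k, "id"])

    rows = [
        {"round": 0, "min_selected": min_selected_to_capture(trait_ranks, true_top)}
    ]
    for rnd in fit_rounds:
        fit = fit_bradley_terry(
            records[records["round"] <= rnd], ids, penalty=penalty, round=rnd,
            tie_break=tie_break,
        )
        cranks = dict(zip(fit["id"], fit["contest_rank"]))
        rows.append(
            {"round": rnd, "min_selected": min_selected_to_capture(cranks, true_top)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EmpiricalFixtureConfig:
    """Synthetic stand-in for the measured cohort: sizes and noise levels."""

    n_males: int = 27
    n_females: int = 32
    n_random_rounds: int = 10
    rank_adjacent_round: bool = True
    factor_loading: float = 0.9  # 1-factor model for the 7 claw dimensions
    trial_noise_sd: float = 1.5  # newtons, within-individual trial scatter
    bt_penalty: float = 0.0

    # mm / newton scales used to place standardized latents on raw axes
    body_length_mm: tuple[float, float] = (85.0, 8.0)
    claw_dim_mm_base: tuple[float, ...] = (12.0, 10.0, 6.0, 6.5, 42.0, 22.0, 24.0)
    claw_dim_mm_spread: float = 0.12  # relative s.d. per dimension
    strength_newtons: tuple[float, float] = (22.0, 4.0)


def _expand_claw_dims(
    latent: np.ndarray, cfg: EmpiricalFixtureConfig, rng: np.random.Generator
) -> np.ndarray:
    """One-factor model: dim_j = loading * latent + sqrt(1-loading^2) * noise."""
    lam = cfg.factor_loading
    unique_sd = np.sqrt(1.0 - lam**2)
    z = lam * latent[:, None] + unique_sd * rng.normal(size=(len(latent), len(CLAW_DIMENSIONS)))
    base = np.asarray(cfg.claw_dim_mm_base)
    mm = base * (1.0 + cfg.claw_dim_mm_spread * z)
    return np.maximum(mm, 0.1)  # raw measurements are strictly positive


def generate_empirical_fixture(
    config: EmpiricalFixtureConfig = EmpiricalFixtureConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic raw-trait and contest tables shaped like the measured study.

    Latent standardized traits follow the simulation noise chain; the raw
    table re-expresses them on mm / newton scales with measurement layers
    (factor structure for claw dimensions, trial scatter for strength).
    Contests: ``n_random_rounds`` random rounds resolved by latent dominance,
    then optionally one round paired by adjacent preliminary Bradley-Terry
    ranks.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(97,))
    rng = np.random.default_rng(ss)
    traits_frames, contest_records = [], []
    cohorts = [
        ("male", config.n_males, MALE_PARAMS),
        ("female", config.n_females, FEMALE_PARAMS),
    ]
    for sex, n, params in cohorts:
        pop = generate_population(n, params, rng)
        bl_mean, bl_sd = config.body_length_mm
        st_mean, st_sd = config.strength_newtons

        left = _expand_claw_dims(pop["claw_size"].to_numpy(), config, rng)
        right = _expand_claw_dims(pop["claw_size"].to_numpy(), config, rng)
        strength_n = st_mean + st_sd * pop["claw_strength"].to_numpy()
        n_trials = N_STRENGTH_TRIALS * N_STRENGTH_DAYS
        trials_left = np.maximum(
            strength_n[:, None] + rng.normal(0, config.trial_noise_sd, (n, n_trials)), 0.1
        )
        trials_right = np.maximum(
            strength_n[:, None] + rng.normal(0, config.trial_noise_sd, (n, n_trials)), 0.1
        )

        frame = pd.DataFrame({"id": pop["id"], "sex": sex})
        frame["body_length_mm"] = bl_mean + bl_sd * pop["body_length"].to_numpy()
        frame[_claw_cols("left")] = left
        frame[_claw_cols("right")] = right
        frame[_strength_cols("left")] = trials_left
        frame[_strength_cols("right")] = trials_right
        traits_frames.append(frame)

        ids = list(pop["id"])
        dominance = dict(zip(pop["id"], pop["true_dominance"]))
        records: list[ContestRecord] = []
        for r in range(1, config.n_random_rounds + 1):
            records.extend(play_round(ids, dominance, rng, r))
        if config.rank_adjacent_round:
            prelim = fit_bradley_terry(
                records_to_frame(records),
                ids,
                penalty=config.bt_penalty,
                round=config.n_random_rounds,
                tie_break=list(pop.sort_values("trait_rank")["id"]),
            )
            ordering = list(prelim.sort_values("contest_rank")["id"])
            extra_round = config.n_random_rounds + 1
            for pair in rank_adjacent_pairing(ordering):
                records.append(resolve_contest(pair, dominance, extra_round))
        contest_records.append(records_to_frame(records))

    return (
        pd.concat(traits_frames, ignore_index=True)[TRAIT_CSV_COLUMNS],
        pd.concat(contest_records, ignore_index=True),
    )


def write_traits_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=TRAIT_CSV_COLUMNS)


def read_traits_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"id": str})
    missing = set(TRAIT_CSV_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"traits CSV is missing columns: {sorted(missing)[:5]}")
    return table[TRAIT_CSV_COLUMNS]
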