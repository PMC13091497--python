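"""Simulated crayfish populations with correlated traits and latent dominance.

Each individual carries three standardized traits linked by a Gaussian noise
chain: body length is standard normal, claw size is body length plus noise,
and claw strength is claw size plus further noise. A sex-specific composite
trait score (equally weighted sum of the configured components) predicts a
latent "true dominance" value: the composite score standardized to unit
variance plus one more layer of Gaussian noise (y = x + error, with x on the
standardized scale so the error s.d. is interpretable as a fraction of the
predictor's spread). Contests elsewhere in the package are decided by true
dominance; selection strategies only ever observe the traits and contest
outcomes.

All slopes in the trait chain are 1 and all intercepts 0 on the standardized
scale; only the residual standard deviations differ between the sexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VALID_COMPONENTS = ("body_length", "claw_size", "claw_strength")

__all__ = [
    "SexParams",
    "MALE_PARAMS",
    "FEMALE_PARAMS",
    "generate_population",
    "rank_values",
    "POPULATION_COLUMNS",
]

POPULATION_COLUMNS = [
    "id",
    "sex",
    "body_length",
    "claw_size",
    "claw_strength",
    "trait_score",
    "trait_rank",
    "true_dominance",
    "true_rank",
]


@dataclass(frozen=True)
class SexParams:
    """Noise chain and composite-score definition for one sex.

    Parameters
    ----------
    sex
        Label, ``"male"`` or ``"female"``.
    claw_size_noise_sd
        Residual s.d. of claw size around body length.
    strength_noise_sd
        Residual s.d. of claw strength around claw size.
    dominance_noise_sd
        Residual s.d. of true dominance around the trait score.
    trait_components
        Trait names summed (equal weights) into the composite trait score.
    """

    sex: str
    claw_size_noise_sd: float
    strength_noise_sd: float
    dominance_noise_sd: float
    trait_components: tuple[str, ...] = field(default=("claw_size", "claw_strength"))

    def __post_init__(self) -> None:
        for sd in (self.claw_size_noise_sd, self.strength_noise_sd, self.dominance_noise_sd):
            if sd < 0:
                raise ValueError(f"noise s.d. must be non-negative, got {sd}")
        if not self.trait_components:
            raise ValueError("trait_components must be non-empty")
        unknown = set(self.trait_components) - set(VALID_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown trait components: {sorted(unknown)}")


#: Male Cherax destructor defaults: composite score = claw size + claw strength.
MALE_PARAMS = SexParams(
    sex="male",
    claw_size_noise_sd=0.26,
    strength_noise_sd=0.54,
    dominance_noise_sd=0.7,
    trait_components=("claw_size", "claw_strength"),
)

#: Female defaults: composite score = body length + claw strength.
FEMALE_PARAMS = SexParams(
    sex="female",
    claw_size_noise_sd=0.22,
    strength_noise_sd=0.69,
    dominance_noise_sd=0.7,
    trait_components=("body_length", "claw_strength"),
)


def rank_values(values: Sequence[float], tie_break: Sequence) -> np.ndarray:
    """Dense 1..N ranks with rank 1 for the largest value.

    ``tie_break[i]`` is the identifier owning ``values[i]``; exact ties are
    broken by position in the sequence (the earlier identifier wins). Every
    ranking in the package goes through this one convention.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(tie_break):
        raise ValueError(
            f"values ({len(values)}) and tie_break ({len(tie_break)}) lengths differ"
        )
    # stable sort on descending value; position breaks ties
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def generate_population(
    n: int, params: SexParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one population of ``n`` individuals for one sex.

    Returns a PopulationTable with one row per individual: the three
    standardized traits, the composite trait score and its rank, and the
    latent true dominance and its rank (rank 1 = best).
    """
    if n < 2:
        raise ValueError(f"population size must be at least 2, got {n}")

    body_length = rng.normal(0.0, 1.0, size=n)
    claw_size = body_length + rng.normal(0.0, params.claw_size_noise_sd, size=n)
    claw_strength = claw_size + rng.normal(0.0, params.strength_noise_sd, size=n)

    traits = {
        "body_length": body_length,
        "claw_size": claw_size,
        "claw_strength": claw_strength,
    }
    trait_score = sum(traits[c] for c in params.trait_components)
    # The dominance noise s.d. is meaningful on the unit predictor scale, so
    # the composite score is standardized within the population before the
    # noise layer; the stored trait_score column stays on the raw-sum scale.
    score_sd = trait_score.std(ddof=1)
    predictor = (trait_score - trait_score.mean()) / score_sd if score_sd > 0 else trait_score * 0.0
    true_dominance = predictor + rng.normal(0.0, params.dominance_noise_sd, size=n)

    ids = [f"{params.sex[0]}{i:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "id": ids,
            "sex": params.sex,
            "body_length": body_length,
            "claw_size": claw_size,
            "claw_strength": claw_strength,
            "trait_score": trait_score,
            "trait_rank": rank_values(trait_score, ids),
            "true_dominance": true_dominance,
            "true_rank": rank_values(true_dominance, ids),
        }
    )
    return table


def write_population_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=POPULATION_COLUMNS)


def read_population_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})
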