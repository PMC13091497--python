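"""Raw-measurement derivations and the top-k capture trajectory."""

import numpy as np
import pandas as pd
import pytest

from adaptsel.contest_engine import ContestRecord, records_to_frame
from adaptsel.empirical_pipeline import (
    CLAW_DIMENSIONS,
    EmpiricalFixtureConfig,
    capture_trajectory,
    claw_size_pc1,
    claw_strength_summary,
    composite_trait_score,
    derive_traits,
    generate_empirical_fixture,
    read_traits_csv,
    write_traits_csv,
)
from adaptsel.contest_engine import read_contests_csv, write_contests_csv


class TestClawStrengthSummary:
    def test_mean_of_per_claw_maxima(self):
        assert claw_strength_summary([5, 7, 6], [8, 4, 4]) == 7.5

    def test_single_reading_per_claw(self):
        assert claw_strength_summary([3.0], [5.0]) == 4.0

    def test_constant_readings(self):
        assert claw_strength_summary([9, 9, 9], [9, 9, 9]) == 9.0

    def test_empty_readings_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            claw_strength_summary([], [1.0])


class TestCompositeTraitScore:
    def test_male_and_female_formulas(self):
        row = pd.Series(
            {"claw_size": 1.0, "claw_strength": -0.5, "body_length_std": 0.2}
        )
        assert composite_trait_score(row, "male") == 0.5
        row2 = pd.Series(
            {"claw_size": 9.9, "claw_strength": 0.3, "body_length_std": 0.2}
        )
        assert composite_trait_score(row2, "female") == 0.5

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="unknown sex"):
            composite_trait_score(pd.Series(dtype=float), "juvenile")


class TestClawSizePC1:
    def make_table(self, X):
        return pd.DataFrame(X, columns=list(CLAW_DIMENSIONS))

    def test_collinear_dimensions_are_rank_one(self, rng):
        factor = rng.normal(size=50)
        X = np.outer(factor, np.linspace(1.0, 3.0, 7)) + 10.0
        scores, explained = claw_size_pc1(self.make_table(X))
        assert explained == pytest.approx(1.0)
        z = (factor - factor.mean()) / factor.std(ddof=1)
        np.testing.assert_allclose(scores / np.linalg.norm(scores), z / np.linalg.norm(z), atol=1e-8)

    def test_one_factor_model_matches_correlation_oracle(self):
        # implied correlation: off-diagonal lambda^2/(lambda^2 + u^2);
        # oracle = top eigenvalue fraction of that matrix
        lam, u = 0.9, 0.44
        rho = lam**2 / (lam**2 + u**2)
        implied = np.full((7, 7), rho)
        np.fill_diagonal(implied, 1.0)
        oracle = np.linalg.eigvalsh(implied)[-1] / 7.0
        rng = np.random.default_rng(21)
        factor = rng.normal(size=200)
        X = lam * factor[:, None] + u * rng.normal(size=(200, 7))
        _, explained = claw_size_pc1(self.make_table(X))
        assert explained == pytest.approx(oracle, abs=0.04)

    def test_orientation_positive_and_permutation_invariant(self, rng):
        factor = rng.normal(size=40)
        X = 0.9 * factor[:, None] + 0.44 * rng.normal(size=(40, 7))
        scores, _ = claw_size_pc1(self.make_table(X))
        assert np.corrcoef(scores, factor)[0, 1] > 0.9  # larger claws -> larger score
        perm = rng.permutation(40)
        scores_perm, _ = claw_size_pc1(self.make_table(X[perm]))
        np.testing.assert_allclose(scores_perm, scores[perm], atol=1e-10)

    def test_degenerate_inputs_rejected(self):
        X = np.ones((10, 7))
        with pytest.raises(ValueError, match="constant dimension"):
            claw_size_pc1(self.make_table(X))
        with pytest.raises(ValueError, match="at least 3"):
            claw_size_pc1(self.make_table(np.random.default_rng(0).normal(size=(2, 7))))


class TestFixtureAndDerivation:
    def test_default_fixture_shape_matches_study_design(self):
        traits, contests = generate_empirical_fixture(seed=3)
        assert (traits["sex"] == "male").sum() == 27
        assert (traits["sex"] == "female").sum() == 32
        male_ids = set(traits.loc[traits["sex"] == "male", "id"])
        male_contests = contests[contests["winner_id"].isin(male_ids)]
        random_rounds = male_contests[male_contests["round"] <= 10]
        # 27 individuals, one sit-out per round: 13 pairs x 10 rounds
        assert 100 <= len(random_rounds) <= 140
        assert (traits.select_dtypes("number") > 0).all().all()

    def test_same_seed_identical_files(self):
        a_t, a_c = generate_empirical_fixture(seed=9)
        b_t, b_c = generate_empirical_fixture(seed=9)
        pd.testing.assert_frame_equal(a_t, b_t)
        pd.testing.assert_frame_equal(a_c, b_c)

    def test_csv_round_trip_is_exact(self, tmp_path):
        traits, contests = generate_empirical_fixture(seed=4)
        write_traits_csv(traits, tmp_path / "traits.csv")
        write_contests_csv(contests, tmp_path / "contests.csv")
        pd.testing.assert_frame_equal(read_traits_csv(tmp_path / "traits.csv"), traits)
        pd.testing.assert_frame_equal(
            read_contests_csv(tmp_path / "contests.csv"), contests
        )

    def test_noise_free_measurements_preserve_latent_ordering(self):
        cfg = EmpiricalFixtureConfig(factor_loading=1.0, trial_noise_sd=0.0)
        traits, _ = generate_empirical_fixture(cfg, seed=5)
        derived = derive_traits(traits)
        for sex in ("male", "female"):
            sub_raw = traits[traits["sex"] == sex].reset_index(drop=True)
            sub = derived[derived["sex"] == sex].reset_index(drop=True)
            # claw dims are exact multiples of the latent size: PC1 ordering
            # must match any single dimension's ordering
            raw_order = np.argsort(-sub_raw["left_propodus_length"].to_numpy())
            derived_order = np.argsort(-sub["claw_size"].to_numpy())
            np.testing.assert_array_equal(raw_order, derived_order)

    def test_standardized_columns_within_sex(self):
        traits, _ = generate_empirical_fixture(seed=6)
        derived = derive_traits(traits)
        for _, sub in derived.groupby("sex"):
            for col in ("body_length_std", "claw_size", "claw_strength"):
                assert sub[col].mean() == pytest.approx(0.0, abs=1e-9)
                assert sub[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestCaptureTrajectory:
    def test_final_round_value_is_k_by_construction(self):
        traits, contests = generate_empirical_fixture(seed=8)
        derived = derive_traits(traits)
        for sex in ("male", "female"):
            sub = derived[derived["sex"] == sex].reset_index(drop=True)
            ids = set(sub["id"])
            recs = contests[contests["winner_id"].isin(ids)]
            traj = capture_trajectory(recs, sub, fit_rounds=(2, 4, 6, 8, 10, 11), k=3)
            assert traj["min_selected"].iloc[-1] == 3
            assert traj["round"].iloc[0] == 0  # pre-contest trait-only value

    def test_trait_determined_contests_capture_at_k_every_round(self):
        # 6 individuals whose contest outcomes follow trait score exactly:
        # two full round-robins; every fit round recovers the ordering
        ids = [f"e{i}" for i in range(6)]
        derived = pd.DataFrame(
            {
                "id": ids,
                "sex": "male",
                "body_length_std": 0.0,
                "claw_size": np.linspace(1.2, -1.2, 6),
                "claw_strength": np.linspace(0.8, -0.8, 6),
            }
        )
        derived["trait_score"] = derived["claw_size"] + derived["claw_strength"]
        derived["trait_rank"] = np.arange(1, 7)
        recs = []
        for rnd in (1, 2):
            for i in range(6):
                for j in range(i + 1, 6):
                    recs.append(ContestRecord(rnd, ids[i], ids[j]))
        traj = capture_trajectory(records_to_frame(recs), derived, fit_rounds=(1, 2), k=2)
        assert traj["min_selected"].tolist() == [2, 2, 2]

    def test_default_fixture_trajectory_declines_towards_k(self):
        traits, contests = generate_empirical_fixture(seed=2)
        derived = derive_traits(traits)
        sub = derived[derived["sex"] == "male"].reset_index(drop=True)
        recs = contests[contests["winner_id"].isin(set(sub["id"]))]
        traj = capture_trajectory(recs, sub, fit_rounds=(2, 4, 6, 8, 10, 11), k=3)
        vals = traj["min_selected"].to_numpy()
        assert vals[-1] == 3
        # single-cohort trajectories fluctuate, but the broad pattern holds:
        # early rounds cost more than late rounds, ending at k
        assert vals[1] >= vals[-1]
        assert vals[1:3].mean() >= vals[-2:].mean()

    def test_bad_requests_rejected(self):
        traits, contests = generate_empirical_fixture(seed=2)
        derived = derive_traits(traits)
        sub = derived[derived["sex"] == "male"].reset_index(drop=True)
        recs = contests[contests["winner_id"].isin(set(sub["id"]))]
        with pytest.raises(ValueError, match="k must lie"):
            capture_trajectory(recs, sub, fit_rounds=(2,), k=0)
        with pytest.raises(ValueError, match="requested"):
            capture_trajectory(recs, sub, fit_rounds=(50,), k=3)
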