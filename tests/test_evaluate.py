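"""Grid combinatorics, fold splitting and cross-validated evaluation."""

import numpy as np
import pandas as pd
import pytest

import falldet as fd
from falldet.data_model import ADL, FALL
from falldet.evaluate import (
    GridPoint,
    GridSpace,
    best_configuration,
    count_feature_subsets,
    deployed_config,
    grid_size,
    index_to_grid_point,
    iter_grid,
    kfold_split,
    personalised_eval,
    results_table,
)
from falldet.features import ACCEL_POOL, FULL_POOL, feature_names


def toy_table(n_fall=60, n_adl=60, sep=10.0, seed=0, n_users=4):
    """Separable two-class feature table in the accel-only column layout."""
    rng = np.random.default_rng(seed)
    cols = feature_names(ACCEL_POOL)
    X = np.vstack(
        [rng.normal(0, 1, (n_adl, 12)), rng.normal(sep, 1, (n_fall, 12))]
    )
    df = pd.DataFrame(X, columns=cols)
    df["label"] = [ADL] * n_adl + [FALL] * n_fall
    df["user_id"] = [f"U{i % n_users:02d}" for i in range(n_adl + n_fall)]
    df["cohort"] = "YP"
    df["activity"] = [
        "D01" if lab == ADL else "F01" for lab in df["label"]
    ]
    df["trial"] = 1
    df["start"] = 0.0
    return df


class TestCombinatorics:
    def test_pool_of_twelve_gives_4095(self):
        assert count_feature_subsets(12) == 4095

    def test_pool_of_one(self):
        assert count_feature_subsets(1) == 1

    def test_pool_of_five_matches_enumeration(self):
        from itertools import combinations

        n_enum = sum(
            1 for k in range(1, 6) for _ in combinations(range(5), k)
        )
        assert count_feature_subsets(5) == n_enum == 31

    def test_default_grid_size(self):
        assert grid_size(GridSpace()) == 1_535_625

    def test_singleton_space(self):
        space = GridSpace(
            frequencies=(50.0,), window_sizes=(9.0,), algorithms=("knn3",),
            feature_pool=(("accelerometer", "max"),),
        )
        assert grid_size(space) == 1

    def test_small_space_by_enumeration(self):
        space = GridSpace(
            frequencies=(50.0, 25.0), window_sizes=(5.0, 9.0),
            algorithms=("knn1", "knn3"),
            feature_pool=(("accelerometer", "max"), ("accelerometer", "min")),
        )
        points = list(iter_grid(space))
        assert grid_size(space) == len(points) == 24
        assert len(set(map(str, points))) == 24  # no duplicates

    def test_accel_only_space(self):
        space = GridSpace(feature_pool=ACCEL_POOL)
        assert grid_size(space) == 5 * 5 * 15 * 15 == 5625

    def test_index_round_trip_covers_all_axes(self):
        space = GridSpace()
        rng = np.random.default_rng(0)
        seen_rates, seen_windows, seen_algs = set(), set(), set()
        for i in rng.integers(0, grid_size(space), size=3000):
            p = index_to_grid_point(space, int(i))
            seen_rates.add(p.rate_hz)
            seen_windows.add(p.window_s)
            seen_algs.add(p.algorithm)
            assert 1 <= len(p.subset) <= 12
        assert seen_rates == set(space.frequencies)
        assert seen_windows == set(space.window_sizes)
        assert seen_algs == set(space.algorithms)


class TestKfold:
    def test_five_folds_of_twenty(self):
        folds = kfold_split([FALL] * 50 + [ADL] * 50, k=5, seed=0)
        assert len(folds) == 5
        for _, te in folds:
            assert len(te) == 20

    def test_stratified_preserves_ratio(self):
        folds = kfold_split([FALL] * 60 + [ADL] * 40, k=5, seed=0)
        y = np.array([FALL] * 60 + [ADL] * 40)
        for _, te in folds:
            assert np.sum(y[te] == FALL) == 12
            assert np.sum(y[te] == ADL) == 8

    def test_same_seed_identical_split(self):
        y = [FALL] * 30 + [ADL] * 30
        a = kfold_split(y, seed=7)
        b = kfold_split(y, seed=7)
        for (_, ta), (_, tb) in zip(a, b):
            assert np.array_equal(ta, tb)

    def test_folds_disjoint_and_exhaustive(self):
        y = [FALL] * 35 + [ADL] * 45
        folds = kfold_split(y, k=5, seed=3)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(80))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            kfold_split([FALL] * 3 + [ADL] * 50, k=5, seed=0)


class TestCrossValidate:
    def test_separable_data_perfect_scores(self):
        res = fd.cross_validate(toy_table(sep=20.0), deployed_config(), seed=0)
        assert res.accuracy_mean == 1.0
        assert res.accuracy_sd == 0.0
        assert res.sensitivity_mean == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(5):
            table = toy_table(n_fall=100, n_adl=100, sep=0.0, seed=seed)
            table["label"] = rng.permutation(table["label"].to_numpy())
            res = fd.cross_validate(table, deployed_config(), seed=seed)
            accs.append(res.accuracy_mean)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_pooled_confusion_equals_fold_sum(self):
        res = fd.cross_validate(toy_table(sep=3.0), deployed_config(), seed=1)
        pooled = sum(res.fold_confusions, start=fd.ConfusionCounts())
        assert pooled.total == res.n_windows

    def test_missing_feature_columns_rejected(self):
        table = toy_table()
        cfg = GridPoint(50.0, 9.0, "knn3", FULL_POOL)
        with pytest.raises(ValueError, match="lacks columns"):
            fd.cross_validate(table, cfg, seed=0)

    def test_group_by_recording_mode_runs(self):
        table = toy_table(n_fall=50, n_adl=50)
        table["trial"] = np.arange(len(table)) % 10
        res = fd.cross_validate(
            table, deployed_config(), seed=0, group_by_recording=True
        )
        assert res.accuracy_mean is not None


class TestRunGrid:
    def test_budget_subsample_size_and_determinism(self, small_dataset):
        space = GridSpace(
            frequencies=(50.0, 25.0), window_sizes=(5.0,),
            algorithms=("knn1", "knn3"), feature_pool=ACCEL_POOL[:2],
        )
        r1 = fd.run_grid(small_dataset, space, budget=5, seed=2)
        r2 = fd.run_grid(small_dataset, space, budget=5, seed=2)
        assert len(r1) == 5
        assert [r.config for r in r1] == [r.config for r in r2]
        assert [r.accuracy_mean for r in r1] == [r.accuracy_mean for r in r2]

    def test_exhaustive_visits_grid_size_points(self, small_dataset):
        space = GridSpace(
            frequencies=(50.0,), window_sizes=(6.0,),
            algorithms=("knn1", "knn3"), feature_pool=ACCEL_POOL[:2],
        )
        results = fd.run_grid(small_dataset, space)
        assert len(results) == grid_size(space) == 6
        assert len({str(r.config) for r in results}) == 6

    def test_zero_budget_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="budget"):
            fd.run_grid(small_dataset, GridSpace(), budget=0)

    def test_best_configuration_is_argmax(self):
        table = toy_table(sep=20.0)
        good = fd.cross_validate(table, deployed_config(), seed=0)
        table_bad = toy_table(sep=0.0)
        bad = fd.cross_validate(table_bad, GridPoint(5.0, 9.0, "knn3", ACCEL_POOL), seed=0)
        assert best_configuration([bad, good]) is good

    def test_results_table_columns(self):
        res = fd.cross_validate(toy_table(), deployed_config(), seed=0)
        df = results_table([res])
        assert {"frequency_hz", "window_s", "algorithm", "accuracy_mean",
                "accuracy_sd", "specificity_mean", "sensitivity_mean"} <= set(df.columns)


class TestPersonalised:
    def test_single_user_separable(self):
        table = toy_table(n_fall=40, n_adl=40, sep=20.0, n_users=2)
        res = personalised_eval(table, "U00", deployed_config(), seed=0)
        assert res.accuracy_mean == 1.0

    def test_unknown_user_rejected(self):
        with pytest.raises(ValueError, match="unknown user"):
            personalised_eval(toy_table(), "U99", deployed_config())

    def test_insufficient_per_class_data_names_user(self):
        table = toy_table(n_fall=3, n_adl=40, n_users=1)
        with pytest.raises(ValueError, match="U00"):
            personalised_eval(table, "U00", deployed_config())

    def test_all_users_sd_usually_below_per_user_sd(self, small_dataset):
        # The pooled model is more stable across folds than most
        # personalised models (directional property).
        table = fd.build_feature_table(small_dataset)
        pooled = fd.cross_validate(table, deployed_config(), seed=0)
        users = sorted(table["user_id"].unique())
        wins = 0
        for uid in users:
            per = personalised_eval(table, uid, deployed_config(), seed=0)
            if pooled.accuracy_sd <= per.accuracy_sd + 1e-12:
                wins += 1
        assert wins >= len(users) / 2
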