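"""Splits, metrics, aggregation and model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmgp import evaluation as ev


def _obs_frame(n_per_env, envs=("E0", "E1", "E2")):
    rows = []
    for e in envs:
        for j in range(n_per_env):
            rows.append((e, f"L{j}", "t", float(j)))
    return pd.DataFrame(rows, columns=["environment", "line", "trait", "value"])


class TestKFold:
    def test_ten_observations_five_even_folds(self):
        obs = _obs_frame(5, envs=("E0", "E1"))
        (fa,) = ev.kfold_split(obs, k=5, seed=0)
        sizes = np.bincount(fa.labels, minlength=5)
        np.testing.assert_array_equal(sizes, [2, 2, 2, 2, 2])

    def test_inverted_roles_give_small_training_fraction(self):
        obs = _obs_frame(20)
        (fa,) = ev.kfold_split(obs, k=20, seed=0, invert_roles=True)
        train, test = next(fa.iter_folds())
        assert len(train) == len(obs) // 20  # 5% training fraction
        assert len(train) + len(test) == len(obs)

    def test_each_observation_tests_once_per_repeat(self):
        obs = _obs_frame(7)
        assignments = ev.kfold_split(obs, k=3, seed=1, repeats=2)
        assert len(assignments) == 2
        for fa in assignments:
            seen = np.concatenate([test for _, test in fa.iter_folds()])
            assert sorted(seen) == list(range(len(obs)))

    def test_stratification_covers_every_environment(self):
        obs = _obs_frame(10)
        (fa,) = ev.kfold_split(obs, k=5, seed=2)
        env = obs["environment"].to_numpy()
        for fold in range(5):
            assert set(env[fa.labels == fold]) == {"E0", "E1", "E2"}

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            ev.kfold_split(_obs_frame(5), k=1)

    @given(st.integers(0, 10**6), st.integers(2, 8), st.integers(2, 10))
    @settings(deadline=None, max_examples=60)
    def test_folds_partition_observations(self, seed, k, n_per_env):
        obs = _obs_frame(n_per_env)
        if k > len(obs):
            return
        (fa,) = ev.kfold_split(obs, k=k, seed=seed)
        sizes = np.bincount(fa.labels, minlength=k)
        assert sizes.sum() == len(obs)
        assert sizes.max() - sizes.min() <= 1


class TestLOEO:
    def test_one_assignment_per_environment(self):
        obs = _obs_frame(4, envs=("B2IR", "B5IR", "BDRT", "BLHT"))
        assignments = ev.loeo_split(obs)
        assert [a.held_out for a in assignments] == ["B2IR", "B5IR", "BDRT", "BLHT"]

    def test_train_test_partition(self):
        obs = _obs_frame(4)
        for fa in ev.loeo_split(obs):
            train, test = next(fa.iter_folds())
            assert len(train) + len(test) == len(obs)
            assert set(train) & set(test) == set()
            assert set(obs["environment"].iloc[test]) == {fa.held_out}

    def test_single_environment_rejected(self):
        with pytest.raises(ValueError):
            ev.loeo_split(_obs_frame(4, envs=("only",)))

    def test_empty_environment_excluded_with_warning(self):
        obs = _obs_frame(3, envs=("E0", "E1"))
        with pytest.warns(UserWarning, match="E9"):
            assignments = ev.loeo_split(obs, env_ids=["E0", "E1", "E9"])
        assert len(assignments) == 2


class TestMetrics:
    def test_perfect_prediction_zero_nrmse(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ev.nrmse(y, y) == 0.0

    def test_hand_computed_mean_normalization(self):
        assert ev.nrmse([2, 2, 2, 2], [1, 3, 1, 3]) == pytest.approx(0.5)

    def test_scale_invariance_under_mean_normalizer(self):
        rng = np.random.default_rng(0)
        y, p = rng.uniform(1, 2, 30), rng.uniform(1, 2, 30)
        assert ev.nrmse(y, p) == pytest.approx(ev.nrmse(10 * y, 10 * p))

    def test_zero_mean_suggests_alternative(self):
        with pytest.raises(ZeroDivisionError, match="normalizer"):
            ev.nrmse([-1.0, 1.0], [0.0, 0.0])

    def test_affine_predictions_have_unit_correlation(self):
        y = np.array([1.0, 2.0, 5.0])
        assert ev.pearson_cor(y, 2 * y + 1) == pytest.approx(1.0)
        assert ev.pearson_cor(y, -y) == pytest.approx(-1.0)

    def test_hand_computed_correlation(self):
        assert ev.pearson_cor([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            ev.pearson_cor([1, 1, 1], [1, 2, 3])

    def test_metrics_invariant_under_relabeling(self):
        rng = np.random.default_rng(1)
        y, p = rng.normal(10, 2, 40), rng.normal(10, 2, 40)
        perm = rng.permutation(40)
        assert ev.nrmse(y, p) == pytest.approx(ev.nrmse(y[perm], p[perm]))
        assert ev.pearson_cor(y, p) == pytest.approx(ev.pearson_cor(y[perm], p[perm]))


class TestAggregate:
    def _records(self, values):
        return pd.DataFrame(
            [
                {"model": "M", "trait": "t", "predictor": "G",
                 "unit": f"fold{i}", "nrmse": v, "cor": v}
                for i, v in enumerate(values)
            ]
        )

    def test_identical_records_zero_sd(self):
        out = ev.aggregate(self._records([0.1, 0.1, 0.1]))
        assert out.loc[0, "nrmse_sd"] == 0.0

    def test_two_record_mean_and_sd(self):
        out = ev.aggregate(self._records([0.09, 0.11]), ndigits=None)
        assert out.loc[0, "nrmse"] == pytest.approx(0.10)
        assert out.loc[0, "nrmse_sd"] == pytest.approx(0.0141, abs=5e-5)

    def test_group_ordering_deterministic(self):
        recs = pd.concat(
            [
                self._records([0.1]).assign(trait="b"),
                self._records([0.2]).assign(trait="a", model="Z"),
                self._records([0.3]).assign(trait="a", model="A"),
            ]
        )
        out = ev.aggregate(recs)
        assert list(zip(out["trait"], out["model"])) == [("a", "A"), ("a", "Z"), ("b", "M")]


class TestCompare:
    def test_identical_tables_no_wins_no_differences(self):
        tab = ev.load_reference_loeo()
        a = tab[tab["model"] == "GBLUP"]
        summary = ev.compare_models(a, a.copy(), model_a="X", model_b="Y")
        assert summary.win_counts("nrmse")["X"] == 0
        assert summary.win_counts("cor")["Y"] == 0
        assert (summary.relative_difference("cor", "X").abs() < 1e-12).all()

    def test_unmatched_keys_listed(self):
        tab = ev.load_reference_loeo()
        a = tab[tab["model"] == "GBLUP"]
        b = tab[tab["model"] == "DL"].iloc[:-1]
        with pytest.raises(ValueError, match="unmatched"):
            ev.compare_models(a, b)

    def test_loeo_reference_win_counts(self):
        tab = ev.load_reference_loeo()
        summary = ev.compare_models(
            tab[tab["model"] == "GBLUP"],
            tab[tab["model"] == "DL"],
            model_a="GBLUP",
            model_b="DL",
        )
        assert summary.win_counts("nrmse")["DL"] == 11
        assert summary.win_counts("cor")["DL"] == 11
        assert summary.win_counts("nrmse")["n"] == 32

    def test_5fcv_reference_grand_mean(self):
        tab = ev.load_reference_5fcv()
        summary = ev.compare_models(
            tab[tab["model"] == "GBLUP"], tab[tab["model"] == "DL"],
            model_a="GBLUP", model_b="DL",
        )
        assert summary.grand_mean("nrmse") == pytest.approx(0.0587, abs=1e-4)


class TestHyperparamSummary:
    def test_mode_and_mean(self):
        trials = pd.DataFrame(
            {
                "trait": ["t"] * 5,
                "depth": [1, 1, 2, 3, 1],
                "lam": [0.002, 0.006, 0.004, 0.004, 0.004],
            }
        )
        out = ev.summarize_hyperparams(trials, ["trait"], ["depth"], ["lam"])
        assert out.loc[0, "depth"] == 1
        assert out.loc[0, "lam"] == pytest.approx(0.004)

    def test_bimodal_tie_takes_smallest(self):
        trials = pd.DataFrame({"trait": ["t"] * 4, "depth": [2, 2, 3, 3]})
        out = ev.summarize_hyperparams(trials, ["trait"], ["depth"], [])
        assert out.loc[0, "depth"] == 2
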