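import numpy as np
import pandas as pd
import pytest

from telestress import (ExperimentConfig, FeatureRegistry, TeleworkProfile,
                        ValidationError, compute_shap, direction_statistic,
                        rank_importance, stratify, train_model)
from telestress.interpret import (DirectionStatistic,
                                  FeatureImportanceRanking,
                                  directions_for_model)
from telestress.registry import RegistryEntry

from test_modeling import toy_instance


def make_registry(names):
    return FeatureRegistry([
        RegistryEntry(n, "steps", "weekly_mean", "activity") for n in names])


def fit_on(X, y, names, seed=0, **params):
    registry = make_registry(names)
    instances = []
    for i, (row, yi) in enumerate(zip(X, y)):
        inst = toy_instance(f"P{i % 7}", 2 + i % 11, 0.0, 0.0, bool(yi))
        inst.features.values = dict(zip(names, map(float, row)))
        instances.append(inst)
    cfg = ExperimentConfig(seed=seed, **params)
    return train_model(instances, registry, cfg), registry, instances


class TestRankImportance:
    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        n, k = 500, 8
        X = rng.normal(size=(n, k))
        y = (X[:, 3] > 0).astype(int)
        names = [f"f{i}" for i in range(k)]
        model, _, _ = fit_on(X, y, names)
        ranking = rank_importance(model)
        assert ranking.top10[0] == "f3"
        assert ranking.ranked[0][1] > 10 * ranking.ranked[1][1]

    def test_unused_features_pad_top10_in_name_order(self):
        rng = np.random.default_rng(1)
        n, k = 200, 12
        X = np.zeros((n, k))
        X[:, 0] = rng.normal(size=n)  # only f00 can ever split
        y = (X[:, 0] > 0).astype(int)
        names = [f"f{i:02d}" for i in range(k)]
        model, _, _ = fit_on(X, y, names)
        ranking = rank_importance(model)
        assert ranking.top10[0] == "f00"
        assert ranking.top10[1:] == [f"f{i:02d}" for i in range(1, 10)]
        zero_gains = dict(ranking.ranked)
        assert all(zero_gains[n] == 0.0 for n in ranking.top10[1:])

    def test_duplicated_columns_rank_deterministically(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(150, 1))
        X = np.hstack([base, base, rng.normal(size=(150, 1))])
        y = (base[:, 0] > 0).astype(int)
        r1 = rank_importance(fit_on(X, y, ["a", "b", "c"], seed=3)[0])
        r2 = rank_importance(fit_on(X, y, ["a", "b", "c"], seed=3)[0])
        assert r1.ranked == r2.ranked


class TestComputeShap:
    def test_additivity_row_sums_reproduce_margins(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 5))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=120) > 0).astype(int)
        names = list("abcde")
        model, registry, _ = fit_on(X, y, names)
        Xdf = pd.DataFrame(X, columns=names)
        shap = compute_shap(model, Xdf)
        np.testing.assert_allclose(
            shap.phi.sum(axis=1) + shap.base_value, shap.margins, atol=1e-4)

    def test_constant_inputs_give_zero_phi(self):
        X = np.zeros((40, 3))
        y = np.array([0, 1] * 20)
        model, _, _ = fit_on(X, y, ["a", "b", "c"])
        shap = compute_shap(model, pd.DataFrame(X, columns=["a", "b", "c"]))
        np.testing.assert_allclose(shap.phi, 0.0, atol=1e-6)
        np.testing.assert_allclose(shap.base_value, shap.margins, atol=1e-6)

    def test_depth_one_stump_matches_two_group_decomposition(self):
        # one binary feature, a single depth-1 tree: phi must equal the
        # instance margin minus the training-set mean margin
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 300).astype(float)
        y = ((x + rng.normal(0, 0.3, 300)) > 0.5).astype(int)
        model, _, _ = fit_on(x[:, None], y, ["x"], n_estimators=1, max_depth=1)
        Xdf = pd.DataFrame({"x": x})
        shap = compute_shap(model, Xdf)
        expected_base = shap.margins.mean()  # cover-weighted leaf mean
        assert shap.base_value == pytest.approx(expected_base, abs=1e-5)
        np.testing.assert_allclose(shap.phi[:, 0],
                                   shap.margins - expected_base, atol=1e-5)


class TestDirectionStatistic:
    def test_phi_equal_to_x_gives_sd_of_x(self):
        res = direction_statistic([1, 2, 3], [1, 2, 3])
        assert res.value == pytest.approx(1.0)
        assert res.defined

    def test_constant_feature_undefined(self):
        res = direction_statistic([2, 2, 2], [0.1, -0.3, 0.2])
        assert not res.defined
        assert res.value == 0.0

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x = rng.normal(size=10)
            phi = rng.normal(size=10)
            xbar, pbar = x.mean(), phi.mean()
            cov = ((x - xbar) * (phi - pbar)).sum() / 9
            sd = np.sqrt(((x - xbar) ** 2).sum() / 9)
            res = direction_statistic(x, phi)
            assert res.value == pytest.approx(cov / sd, abs=1e-10)

    def test_invariant_under_feature_shift(self):
        rng = np.random.default_rng(10)
        x, phi = rng.normal(size=8), rng.normal(size=8)
        assert direction_statistic(x, phi).value == pytest.approx(
            direction_statistic(x + 100.0, phi).value)

    def test_scales_linearly_in_phi(self):
        rng = np.random.default_rng(11)
        x, phi = rng.normal(size=8), rng.normal(size=8)
        assert direction_statistic(x, 3.0 * phi).value == pytest.approx(
            3.0 * direction_statistic(x, phi).value)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            direction_statistic([1.0], [2.0])


def _ranking(tid, names):
    ranked = [(n, float(10 - i)) for i, n in enumerate(names)]
    return FeatureImportanceRanking(tid, ranked, names[:10])


class TestStratify:
    def _setup(self, rates):
        names = [f"f{i}" for i in range(10)]
        registry = make_registry(names)
        profiles = {f"T{i}": TeleworkProfile(f"T{i}", 0, 1, r)
                    for i, r in enumerate(rates)}
        importances = {tid: _ranking(tid, names) for tid in profiles}
        directions = {tid: {"f0": DirectionStatistic(tid, "f0", 0.5, True)}
                      for tid in profiles}
        return importances, directions, profiles, registry

    def test_all_targets_at_rate_zero_fall_in_low(self):
        imp, dirs, prof, reg = self._setup([0.0] * 5)
        table = stratify(imp, dirs, prof, reg)
        assert table.n_models == {"low": 5, "middle": 0, "high": 0}

    def test_category_counts_conserve_ten_per_model(self):
        imp, dirs, prof, reg = self._setup([0.0, 0.1, 0.3, 0.4, 0.7, 0.75])
        table = stratify(imp, dirs, prof, reg)
        for level, n in table.n_models.items():
            assert sum(table.category_counts[level].values()) == 10 * n

    def test_partition_is_exhaustive(self):
        rates = [0.0, 0.19, 0.2, 0.59, 0.6, 0.79]
        imp, dirs, prof, reg = self._setup(rates)
        table = stratify(imp, dirs, prof, reg)
        assert sum(table.n_models.values()) == len(rates)
        assert table.n_models == {"low": 2, "middle": 2, "high": 2}

    def test_missing_profile_rejected(self):
        imp, dirs, prof, reg = self._setup([0.0, 0.5])
        del prof["T1"]
        with pytest.raises(ValidationError, match="T1"):
            stratify(imp, dirs, prof, reg)

    def test_mean_rank_table_sorted_ascending(self):
        imp, dirs, prof, reg = self._setup([0.0, 0.1])
        table = stratify(imp, dirs, prof, reg)
        mr = table.mean_rank_tables["low"]["mean_rank"].to_numpy()
        assert (np.diff(mr) >= 0).all()
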