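import numpy as np
import pytest

from telestress import (DegenerateTrainingError, ExperimentConfig,
                        FeatureRegistry, TeleworkProfile, ValidationError,
                        adapt_threshold, make_splits, predict, run_experiment,
                        train_model)
from telestress.features import (StressLabel, SupervisedInstance,
                                 WeeklyFeatureVector, binarize_k6)
from telestress.registry import RegistryEntry

TOY_REGISTRY = FeatureRegistry([
    RegistryEntry("signal", "steps", "weekly_mean", "activity"),
    RegistryEntry("noise", "calories", "weekly_mean", "activity"),
])


def _label(pid, week, positive):
    total = 10 if positive else 0
    proto = binarize_k6(total)
    return StressLabel(pid, week, total, proto.k6_class, proto.binary)


def toy_instance(pid, label_week, signal, noise, positive):
    vec = WeeklyFeatureVector(pid, label_week - 1,
                              {"signal": signal, "noise": noise})
    return SupervisedInstance(pid, label_week, vec,
                              _label(pid, label_week, positive))


def toy_set(n, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        positive = bool(i % 2)
        signal = (1.0 if positive else -1.0) if separable else rng.normal()
        out.append(toy_instance(f"P{i % 5}", 2 + i % 11,
                                signal + (0 if separable else 0.0),
                                float(rng.normal()), positive))
    return out


def full_instances(pid, weeks=range(2, 13), positives=()):
    return [toy_instance(pid, w, 0.0, 0.0, w in positives) for w in weeks]


class TestMakeSplits:
    def test_proposed1_counts_for_complete_data(self):
        target = full_instances("T")
        cluster = [i for m in range(3)
                   for i in full_instances(f"C{m}")]
        plan = make_splits("proposed1", target, cluster)
        assert len(plan.train) == 3 * 11 + 6
        assert len(plan.test) == 5
        assert plan.adaptation == []

    def test_proposed2_adaptation_is_cluster_late_weeks(self):
        target = full_instances("T")
        cluster = [i for m in range(4) for i in full_instances(f"C{m}")]
        plan = make_splits("proposed2", target, cluster)
        assert len(plan.train) == 4 * 6 + 6
        assert len(plan.adaptation) == 4 * 5
        assert len(plan.test) == 5

    def test_no_target_test_weeks_leak_into_train_or_adaptation(self):
        target = full_instances("T")
        cluster = full_instances("C")
        for method in ("single", "proposed1", "proposed2"):
            plan = make_splits(method, target, cluster)
            train_keys = {(i.participant_id, i.label_week)
                          for i in (*plan.train, *plan.adaptation)}
            for inst in plan.test:
                assert (inst.participant_id, inst.label_week) not in train_keys
                assert inst.label_week >= 8


class TestAdaptThreshold:
    def test_separated_scores(self):
        scores = [0.9] * 4 + [0.1] * 4
        labels = [1] * 4 + [0] * 4
        res = adapt_threshold(scores, labels)
        assert res.threshold == pytest.approx(0.9)
        assert (res.achieved_tp, res.achieved_fp) == (1.0, 0.0)
        assert res.constraint_met

    def test_worked_example(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.55, 0.3, 0.2]
        labels = [1, 1, 1, 1, 1, 0, 0, 0]
        res = adapt_threshold(scores, labels)
        # TP > 0.8 requires all five positives (4/5 = 0.8 is not > 0.8), so
        # the threshold must drop to 0.4; FP is then 1/3.
        assert res.threshold == pytest.approx(0.4)
        assert res.achieved_tp == 1.0
        assert res.achieved_fp == pytest.approx(1 / 3)

    def test_single_candidate_degenerate_case(self):
        res = adapt_threshold([0.5, 0.5, 0.5], [1, 0, 1])
        assert res.threshold == pytest.approx(0.5)
        assert res.achieved_tp == 1.0
        assert res.achieved_fp == 1.0
        assert res.constraint_met

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            adapt_threshold([0.2, 0.6], [0, 0])

    @staticmethod
    def oracle(scores, labels, tp_target=0.8):
        """Exhaustive scan over all candidate thresholds."""
        scores = np.asarray(scores)
        labels = np.asarray(labels)
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        rows = []
        for thr in np.concatenate([np.unique(scores), [scores.max() + 1]]):
            pred = scores >= thr
            tp = (pred & (labels == 1)).sum() / n_pos
            fp = (pred & (labels == 0)).sum() / n_neg if n_neg else 0.0
            rows.append((thr, tp, fp))
        feasible = [r for r in rows if r[1] > tp_target]
        if feasible:
            return min(feasible, key=lambda r: (r[2], -r[0]))
        return min(rows, key=lambda r: (-r[1], r[2], -r[0]))

    def test_matches_exhaustive_scan_on_random_sets(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)  # rounding creates ties
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            res = adapt_threshold(scores, labels)
            thr, tp, fp = self.oracle(scores, labels)
            assert res.threshold == pytest.approx(thr)
            assert res.achieved_tp == pytest.approx(tp)
            assert res.achieved_fp == pytest.approx(fp)

    def test_raising_threshold_never_raises_rates(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        grid = np.sort(np.unique(scores))
        tps, fps = [], []
        for thr in grid:
            pred = scores >= thr
            tps.append((pred & (labels == 1)).sum())
            fps.append((pred & (labels == 0)).sum())
        assert all(a >= b for a, b in zip(tps, tps[1:]))
        assert all(a >= b for a, b in zip(fps, fps[1:]))


class TestTrainAndPredict:
    def test_separable_toy_set_fits_perfectly(self):
        instances = toy_set(40)
        model = train_model(instances, TOY_REGISTRY, ExperimentConfig(seed=0))
        records = predict(model, instances, TOY_REGISTRY)
        assert all(r.predicted == r.actual for r in records)

    def test_same_seed_identical_predictions(self):
        instances = toy_set(40, separable=False)
        r1 = predict(train_model(instances, TOY_REGISTRY,
                                 ExperimentConfig(seed=5)),
                     instances, TOY_REGISTRY)
        r2 = predict(train_model(instances, TOY_REGISTRY,
                                 ExperimentConfig(seed=5)),
                     instances, TOY_REGISTRY)
        assert r1 == r2

    def test_single_class_training_set_rejected(self):
        instances = [toy_instance("P1", 2 + i, 0.0, 0.0, False)
                     for i in range(10)]
        with pytest.raises(DegenerateTrainingError):
            train_model(instances, TOY_REGISTRY, ExperimentConfig())

    def test_score_at_threshold_predicts_positive(self):
        instances = toy_set(40)
        model = train_model(instances, TOY_REGISTRY, ExperimentConfig())
        model.threshold = 0.5
        [rec] = predict(model, instances[:1], TOY_REGISTRY)
        assert rec.predicted == int(rec.score >= 0.5)


class TestRunExperiment:
    def test_single_method_fits_one_pooled_model(self, small_cohort_prepared,
                                                 registry):
        instances, profiles = small_cohort_prepared
        cfg = ExperimentConfig(method="single", seed=1)
        result = run_experiment(instances, profiles, registry, cfg)
        assert len(result.models) == 1
        assert all(r.label_week >= 8 for r in result.records)

    def test_proposed1_fits_one_model_per_target(self, small_cohort_prepared,
                                                 registry):
        instances, profiles = small_cohort_prepared
        cfg = ExperimentConfig(method="proposed1", cluster_size=20, seed=1)
        result = run_experiment(instances, profiles, registry, cfg)
        assert len(result.models) + len(result.skipped) == len(profiles)
        for tid, members in result.clusters.items():
            assert tid not in members
            assert len(members) == min(20, len(profiles) - 1)

    def test_deterministic_given_seed(self, small_cohort_prepared, registry):
        instances, profiles = small_cohort_prepared
        cfg = ExperimentConfig(method="proposed2", seed=9)
        r1 = run_experiment(instances, profiles, registry, cfg)
        r2 = run_experiment(instances, profiles, registry, cfg)
        assert r1.records == r2.records
        assert {t: m.threshold for t, m in r1.models.items()} == \
               {t: m.threshold for t, m in r2.models.items()}
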