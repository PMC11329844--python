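import datetime as dt

import numpy as np
import pytest
from scipy import stats

from telestress import (CohortSpec, PlantedEffect, PointMassRates,
                        ValidationError, compute_teleworking_rate,
                        default_registry, generate_cohort, read_cohort_dir,
                        write_cohort)
from telestress.features import (build_instances, build_labels,
                                 build_weekly_features)
from telestress.synthetic import STUDY_START, StudyMixtureRates


def _cohort_bytes(cohort, tmp_path, tag):
    d = tmp_path / tag
    paths = write_cohort(cohort, d)
    return b"".join(p.read_bytes() for p in sorted(paths.values()))


class TestDeterminism:
    def test_same_spec_same_seed_byte_identical(self, tmp_path):
        spec = CohortSpec(n_participants=6, n_weeks=12, seed=13)
        b1 = _cohort_bytes(generate_cohort(spec), tmp_path, "a")
        b2 = _cohort_bytes(generate_cohort(spec), tmp_path, "b")
        assert b1 == b2

    def test_different_seed_differs(self, tmp_path):
        s1 = CohortSpec(n_participants=6, n_weeks=12, seed=13)
        s2 = CohortSpec(n_participants=6, n_weeks=12, seed=14)
        assert _cohort_bytes(generate_cohort(s1), tmp_path, "a") != \
            _cohort_bytes(generate_cohort(s2), tmp_path, "b")


class TestRates:
    def test_point_mass_zero_means_never_wfh(self):
        spec = CohortSpec(n_participants=5, n_weeks=12, seed=1,
                          telework_rate_distribution=PointMassRates(0.0))
        cohort = generate_cohort(spec)
        for p in cohort.participants:
            prof = compute_teleworking_rate(p.shifts, p.participant_id)
            assert prof.rate == 0.0
            assert not any(r.wfh for r in p.shifts)

    def test_empirical_rate_within_rounding_of_assigned(self):
        cohort = generate_cohort(CohortSpec(n_participants=30, n_weeks=12,
                                            seed=2))
        for p in cohort.participants:
            prof = compute_teleworking_rate(p.shifts, p.participant_id)
            assigned = cohort.assigned_rates[p.participant_id]
            assert abs(prof.rate - assigned) <= 1.0 / prof.days_worked

    def test_sampled_rates_respect_study_bounds(self):
        rng = np.random.default_rng(0)
        rates = StudyMixtureRates().sample(rng, 5000)
        assert rates.min() >= 0.0 and rates.max() <= 0.79


class TestLabelProcess:
    def test_prevalence_calibrated_with_zero_effects(self):
        spec = CohortSpec(n_participants=200, n_weeks=12, seed=3,
                          effect_table=[], positive_prevalence_target=0.3)
        cohort = generate_cohort(spec)
        prevalence = cohort.ground_truth["label"].mean()
        assert abs(prevalence - 0.3) < 0.05

    def test_prevalence_target_is_configurable(self):
        spec = CohortSpec(n_participants=100, n_weeks=12, seed=4,
                          effect_table=[], positive_prevalence_target=0.1)
        cohort = generate_cohort(spec)
        assert abs(cohort.ground_truth["label"].mean() - 0.1) < 0.05

    def test_k6_totals_consistent_with_binary_labels(self):
        cohort = generate_cohort(CohortSpec(n_participants=10, n_weeks=12,
                                            seed=5))
        truth = {(r.participant_id, r.week_index): r.label
                 for r in cohort.ground_truth.itertuples()}
        for p in cohort.participants:
            for q in p.questionnaires:
                positive = truth[(p.participant_id, q.week_index)]
                assert (q.k6_total >= 5) == bool(positive)
                assert sum(q.k6_items) == q.k6_total

    def test_planted_linear_effect_sign_recovered(self):
        """A strong positive effect of weekly step volume must produce a
        positive lagged point-biserial correlation in nearly all replicates."""
        hits = 0
        for seed in range(20):
            spec = CohortSpec(
                n_participants=30, n_weeks=12, seed=100 + seed,
                noise_scale=0.5,
                effect_table=[PlantedEffect("steps_sum", "all", "linear", 2.0)])
            cohort = generate_cohort(spec)
            registry = default_registry(include_prior_k6=False)
            xs, ys = [], []
            for p in cohort.participants:
                feats = build_weekly_features(p, registry, STUDY_START, 12)
                for inst in build_instances(feats, build_labels(p)):
                    x = inst.features.values["steps_sum"]
                    if not np.isnan(x):
                        xs.append(x)
                        ys.append(int(inst.label.positive))
            r, _ = stats.pointbiserialr(ys, xs)
            hits += r > 0
        assert hits >= 19  # >= 95% of 20 replicates


class TestWriteReadRoundTrip:
    def test_cohort_round_trips_identically(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        back = read_cohort_dir(tmp_path)
        assert back == small_cohort.participants

    def test_empty_cohort_writes_header_only_files(self, tmp_path):
        cohort = generate_cohort(CohortSpec(n_participants=0, n_weeks=12,
                                            seed=0))
        paths = write_cohort(cohort, tmp_path)
        for key in ("wearable", "shifts", "questionnaires"):
            lines = paths[key].read_text().strip().splitlines()
            assert len(lines) == 1
        assert read_cohort_dir(tmp_path) == []

    def test_missing_week_survives_round_trip(self, tmp_path):
        cohort = generate_cohort(CohortSpec(n_participants=3, n_weeks=12,
                                            seed=6, missing_prob_wearable=0.0))
        p = cohort.participants[0]
        week3 = [STUDY_START + dt.timedelta(days=d) for d in range(14, 21)]
        p.wearable = [r for r in p.wearable if r.date not in week3]
        write_cohort(cohort, tmp_path)
        back = read_cohort_dir(tmp_path)
        dates = {r.date for r in back[0].wearable}
        assert not dates & set(week3)
        assert len(back[0].wearable) == 12 * 7 - 7


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs,match", [
        (dict(n_weeks=2), "n_weeks"),
        (dict(positive_prevalence_target=0.0), "prevalence"),
        (dict(noise_scale=-1.0), "noise"),
        (dict(missing_prob_wearable=1.5), "missing_prob_wearable"),
    ])
    def test_invalid_specs_rejected_with_named_invariant(self, kwargs, match):
        with pytest.raises(ValidationError, match=match):
            CohortSpec(n_participants=5, **kwargs).validate()

    def test_effect_on_unknown_feature_rejected(self):
        spec = CohortSpec(effect_table=[
            PlantedEffect("no_such_feature", "all", "linear", 1.0)])
        with pytest.raises(ValidationError, match="no_such_feature"):
            spec.validate()

    def test_effect_on_prior_distress_rejected(self):
        spec = CohortSpec(effect_table=[
            PlantedEffect("k6_total_delta", "all", "linear", 1.0)])
        with pytest.raises(ValidationError):
            spec.validate()
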