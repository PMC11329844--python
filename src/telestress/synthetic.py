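"""Synthetic cohort generator with a planted, teleworking-level-specific
stress process.

The generator emulates the three study streams — daily wearable records,
daily work shifts, weekly questionnaires — for a configurable number of
participants and weeks.  Week-t stress labels are drawn from a logistic
model on the participant's *previous-week* feature vector: planted effects
(each scoped to a teleworking level and given a shape and a signed logit
coefficient) plus a participant random intercept and i.i.d. noise.  The
global intercept is solved numerically so the marginal positive prevalence
matches a target, which keeps class balance controllable.  The K6 total is
then drawn consistently with the binary label and split into six items.

Everything is a pure function of the spec including its seed: the same spec
yields a byte-identical cohort.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ValidationError
from .features import build_weekly_features
from .ingest import (DailyWearableRecord, ParticipantData,
                     WeeklyQuestionnaireRecord, WorkShiftRecord,
                     write_questionnaires, write_shifts, write_wearable)
from .neighborhood import assign_level
from .registry import FeatureRegistry, default_registry

#: First study Monday; weeks are Monday-Sunday from here.
STUDY_START = dt.date(2022, 1, 17)

MAX_RATE = 0.79


# ----------------------------------------------------------- rate sampling

class RateDistribution:
    """Samplable distribution of per-participant teleworking rates."""

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raise NotImplementedError

    @staticmethod
    def from_config(cfg) -> "RateDistribution":
        if cfg is None:
            return StudyMixtureRates()
        kind = cfg.get("kind", "mixture")
        if kind == "mixture":
            return StudyMixtureRates()
        if kind == "uniform":
            return UniformRates(cfg.get("low", 0.0), cfg.get("high", MAX_RATE))
        if kind == "point":
            return PointMassRates(cfg["value"])
        raise ValidationError(f"unknown rate distribution kind {kind!r}")


@dataclass(frozen=True)
class StudyMixtureRates(RateDistribution):
    """Default: uniform within each teleworking level, weighted by the level
    shares observed in the study population (43.2% low, 36.3% middle,
    20.5% high), truncated at 0.79."""

    weights: tuple[float, float, float] = (0.432, 0.363, 0.205)

    def sample(self, rng, n):
        w = np.asarray(self.weights) / sum(self.weights)
        level = rng.choice(3, size=n, p=w)
        lo = np.array([0.0, 0.2, 0.6])[level]
        hi = np.array([0.2, 0.6, MAX_RATE])[level]
        return lo + rng.random(n) * (hi - lo)


@dataclass(frozen=True)
class UniformRates(RateDistribution):
    low: float = 0.0
    high: float = MAX_RATE

    def sample(self, rng, n):
        return self.low + rng.random(n) * (self.high - self.low)


@dataclass(frozen=True)
class PointMassRates(RateDistribution):
    value: float

    def sample(self, rng, n):
        return np.full(n, self.value)


# ----------------------------------------------------------- planted effects

EFFECT_SHAPES = ("linear", "absolute_deviation", "u_shaped")
EFFECT_SCOPES = ("low", "middle", "high", "all")


@dataclass(frozen=True)
class PlantedEffect:
    """One term of the latent stress logit.

    ``linear`` uses the cohort-standardized feature value; the other shapes
    measure (absolute or squared) deviation from the participant's own mean,
    standardized across the cohort — so "higher or lower than one's usual
    value" can raise stress.  ``level_scope`` restricts the term to
    participants at one teleworking level.
    """

    feature_name: str
    level_scope: str
    shape: str
    coefficient: float

    def validate(self, registry: FeatureRegistry) -> None:
        if self.level_scope not in EFFECT_SCOPES:
            raise ValidationError(f"unknown level_scope {self.level_scope!r}")
        if self.shape not in EFFECT_SHAPES:
            raise ValidationError(f"unknown effect shape {self.shape!r}")
        if not np.isfinite(self.coefficient):
            raise ValidationError("effect coefficient must be finite")
        if self.feature_name == "k6_total_delta":
            raise ValidationError(
                "planted effects may not reference the prior distress score")
        if self.feature_name not in registry:
            raise ValidationError(
                f"effect feature {self.feature_name!r} not in registry")


def default_effect_table() -> list[PlantedEffect]:
    """Level-specific effects mirroring the qualitative stress correlates the
    framework is designed to surface: lunch skipping, shrunken sleep and
    high heart-rate variability hurt teleworkers; long hours, off-schedule
    arrival and *low* heart-rate variability hurt office workers; low
    activity hurts everyone."""
    return [
        PlantedEffect("lunches_skipped", "high", "linear", 2.0),
        PlantedEffect("hr_sd_mean", "high", "linear", 1.5),
        PlantedEffect("sleep_duration_mean", "high", "linear", -1.5),
        PlantedEffect("working_hours_mean", "middle", "linear", 1.5),
        PlantedEffect("working_hours_mean", "low", "linear", 1.5),
        PlantedEffect("hr_sd_mean", "low", "linear", -1.5),
        PlantedEffect("work_start_mean", "low", "absolute_deviation", 1.5),
        PlantedEffect("steps_sum", "all", "linear", -1.0),
    ]


# ----------------------------------------------------------- cohort spec

@dataclass
class CohortSpec:
    n_participants: int = 190
    n_weeks: int = 12
    telework_rate_distribution: RateDistribution = field(
        default_factory=StudyMixtureRates)
    positive_prevalence_target: float = 0.3
    effect_table: list[PlantedEffect] = field(default_factory=default_effect_table)
    noise_scale: float = 1.0
    random_intercept_sd: float = 0.5
    missing_prob_wearable: float = 0.05
    missing_prob_shifts: float = 0.0
    missing_prob_questionnaires: float = 0.0
    absence_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValidationError("n_participants must be >= 0")
        if self.n_weeks < 3:
            raise ValidationError(
                "n_weeks must be >= 3 (need train and test instances after lagging)")
        if not 0 < self.positive_prevalence_target < 1:
            raise ValidationError("positive_prevalence_target must be in (0, 1)")
        if self.noise_scale < 0 or self.random_intercept_sd < 0:
            raise ValidationError("noise scales must be nonnegative")
        for p in ("missing_prob_wearable", "missing_prob_shifts",
                  "missing_prob_questionnaires", "absence_prob"):
            if not 0 <= getattr(self, p) <= 1:
                raise ValidationError(f"{p} must be in [0, 1]")
        registry = default_registry(include_prior_k6=False)
        for eff in self.effect_table:
            eff.validate(registry)

    @classmethod
    def from_config(cls, cfg: dict) -> "CohortSpec":
        cfg = dict(cfg)
        if "telework_rate_distribution" in cfg:
            cfg["telework_rate_distribution"] = RateDistribution.from_config(
                cfg["telework_rate_distribution"])
        if "effect_table" in cfg:
            cfg["effect_table"] = [PlantedEffect(**e) for e in cfg["effect_table"]]
        spec = cls(**cfg)
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh) or {})


@dataclass
class SyntheticCohort:
    participants: list[ParticipantData]
    ground_truth: pd.DataFrame   # participant_id, week_index, logit, prob, label
    spec_echo: CohortSpec
    assigned_rates: dict[str, float]
    intercept: float


# ----------------------------------------------------------- generation

def _allocate_k6_items(total: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Distribute a K6 total over six items, each capped at 4."""
    items = [0] * 6
    for _ in range(total):
        open_items = [i for i in range(6) if items[i] < 4]
        items[int(rng.choice(open_items))] += 1
    return tuple(items)


def _gen_participant_streams(pid: str, rate: float, spec: CohortSpec,
                             rng: np.random.Generator):
    """Daily wearable + shift records and week-level behavior counts."""
    n_days = spec.n_weeks * 7
    # participant baselines
    sleep_mu = rng.normal(420, 35)
    eff_mu = rng.normal(93, 2)
    sleep_start_mu = rng.normal(-40, 35)          # ~23:20, signed minutes
    log_steps_mu = np.log(7500) + rng.normal(0, 0.25)
    floors_mu = rng.uniform(5, 15)
    hr_mu = rng.normal(70, 6)
    hr_sd_mu = rng.normal(9, 1.5)
    cal_mu = rng.normal(2100, 180)
    start_shift_mu = rng.normal(0, 10)            # habitual clock-in offset
    gap_mu = rng.normal(0.25, 0.3)                # habitual over/under-time, h
    p_lunch = rng.beta(1.2, 8)
    out_mu = rng.uniform(1, 4)

    wearable: list[DailyWearableRecord] = []
    for d in range(n_days):
        date = STUDY_START + dt.timedelta(days=d)
        duration = max(120.0, rng.normal(sleep_mu, 45))
        eff = float(np.clip(rng.normal(eff_mu, 2.5), 60, 100))
        start = rng.normal(sleep_start_mu, 30)
        end = start + duration * 100.0 / eff
        steps = int(np.exp(rng.normal(log_steps_mu, 0.35)))
        hr_mean = float(np.clip(rng.normal(hr_mu, 2.5), 40, 120))
        hr_sd = max(1.0, rng.normal(hr_sd_mu, 1.2))
        calories = max(1200.0, cal_mu + 0.03 * (steps - 7500) + rng.normal(0, 80))
        wearable.append(DailyWearableRecord(
            participant_id=pid, date=date,
            sleep_duration=round(duration, 1),
            sleep_efficiency=round(eff, 1),
            sleep_start=round(start, 1), sleep_end=round(end, 1),
            steps=steps, distance=round(steps * 0.00075, 3),
            floors=int(rng.poisson(floors_mu)),
            calories=round(calories, 1),
            hr_mean=round(hr_mean, 1), hr_sd=round(hr_sd, 1)))

    # Mon-Fri shifts; WFH flags drawn so the realized rate matches the
    # assigned rate to within rounding (|emp - assigned| <= 0.5/worked days).
    shifts: list[WorkShiftRecord] = []
    workdays = [STUDY_START + dt.timedelta(days=d) for d in range(n_days)
                if (STUDY_START + dt.timedelta(days=d)).weekday() < 5]
    absent_flags = rng.random(len(workdays)) < spec.absence_prob
    worked_idx = [i for i, a in enumerate(absent_flags) if not a]
    k_wfh = int(round(rate * len(worked_idx)))
    wfh_idx = set(rng.choice(worked_idx, size=k_wfh, replace=False).tolist()
                  ) if k_wfh > 0 else set()
    for i, date in enumerate(workdays):
        absent = bool(absent_flags[i])
        sched_start, sched_end, sched_hours = 540.0, 1050.0, 8.0
        if absent:
            shifts.append(WorkShiftRecord(
                participant_id=pid, date=date, scheduled_start=sched_start,
                scheduled_end=sched_end, scheduled_hours=sched_hours,
                wfh=False, absent=True))
            continue
        actual_start = round(sched_start + rng.normal(start_shift_mu, 20), 0)
        hours = max(4.0, sched_hours + rng.normal(gap_mu, 0.75))
        actual_end = round(actual_start + hours * 60, 0)
        shifts.append(WorkShiftRecord(
            participant_id=pid, date=date, scheduled_start=sched_start,
            scheduled_end=sched_end, scheduled_hours=sched_hours,
            wfh=i in wfh_idx, absent=False,
            actual_start=actual_start, actual_end=actual_end))

    # weekly behavior counts (questionnaire, K6 filled in later)
    office_days = {w: 0 for w in range(1, spec.n_weeks + 1)}
    for i, date in enumerate(workdays):
        if not absent_flags[i] and i not in wfh_idx:
            w = (date - STUDY_START).days // 7 + 1
            office_days[w] += 1
    quests: list[WeeklyQuestionnaireRecord] = []
    for w in range(1, spec.n_weeks + 1):
        outings = int(office_days[w] + rng.poisson(out_mu))
        lunches = int(rng.binomial(5, p_lunch))
        quests.append(WeeklyQuestionnaireRecord(
            participant_id=pid, week_index=w, k6_items=(0,) * 6,
            k6_total=0, outings=outings, lunches_skipped=lunches))

    # wearable missingness: whole device-days drop out
    if spec.missing_prob_wearable > 0:
        keep = rng.random(len(wearable)) >= spec.missing_prob_wearable
        wearable = [r for r, k in zip(wearable, keep) if k]
    if spec.missing_prob_shifts > 0:
        keep = rng.random(len(shifts)) >= spec.missing_prob_shifts
        shifts = [r for r, k in zip(shifts, keep) if k]

    return wearable, shifts, quests


def _standardize(col: np.ndarray) -> np.ndarray:
    mu = np.nanmean(col) if not np.all(np.isnan(col)) else 0.0
    sd = np.nanstd(col) if not np.all(np.isnan(col)) else 0.0
    z = (col - mu) / sd if sd > 0 else np.zeros_like(col)
    return np.where(np.isnan(z), 0.0, z)


def _effect_matrix(spec: CohortSpec, feats: pd.DataFrame,
                   levels: dict[str, str]) -> np.ndarray:
    """Per participant-week sum of planted-effect logit terms."""
    terms = np.zeros(len(feats))
    level_col = feats["participant_id"].map(levels).to_numpy()
    for eff in spec.effect_table:
        x = feats[eff.feature_name].to_numpy(dtype=float)
        if eff.shape == "linear":
            z = _standardize(x)
        else:
            pmean = feats.groupby("participant_id")[eff.feature_name] \
                         .transform("mean").to_numpy(dtype=float)
            dev = x - pmean
            mag = np.abs(dev) if eff.shape == "absolute_deviation" else dev ** 2
            z = _standardize(mag)
        scope = np.ones(len(feats), dtype=bool) if eff.level_scope == "all" \
            else (level_col == eff.level_scope)
        terms = terms + np.where(scope, eff.coefficient * z, 0.0)
    return terms


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a complete synthetic cohort; pure function of the spec."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n = spec.n_participants
    rates = spec.telework_rate_distribution.sample(rng, n)
    if n and (rates.min() < 0 or rates.max() > MAX_RATE):
        raise ValidationError(
            f"sampled teleworking rates outside [0, {MAX_RATE}]")
    width = max(3, len(str(max(n, 1))))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]
    assigned = dict(zip(pids, rates.tolist()))
    levels = {pid: assign_level(r) for pid, r in assigned.items()}

    participants = []
    for i, pid in enumerate(pids):
        prng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, i]))
        wearable, shifts, quests = _gen_participant_streams(
            pid, assigned[pid], spec, prng)
        participants.append(ParticipantData(pid, wearable, shifts, quests))

    if not participants:
        return SyntheticCohort([], pd.DataFrame(
            columns=["participant_id", "week_index", "logit", "prob", "label"]),
            replace(spec), assigned, 0.0)

    # weekly features on the *observed* streams drive the latent process
    registry = default_registry(include_prior_k6=False)
    rows = []
    for p in participants:
        for vec in build_weekly_features(p, registry, STUDY_START, spec.n_weeks):
            rows.append({"participant_id": p.participant_id,
                         "week_index": vec.week_index, **vec.values})
    feats = pd.DataFrame(rows)
    effect = _effect_matrix(spec, feats, levels)
    effect_by = {(r.participant_id, r.week_index): e
                 for r, e in zip(feats.itertuples(), effect)}

    lrng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    u = {pid: lrng.normal(0, spec.random_intercept_sd) for pid in pids}
    offsets, keys = [], []
    for pid in pids:
        for w in range(1, spec.n_weeks + 1):
            # label week w is driven by week w-1 features; week 1 has no lag
            eff = effect_by.get((pid, w - 1), 0.0) if w >= 2 else 0.0
            offsets.append(u[pid] + eff + lrng.normal(0, spec.noise_scale))
            keys.append((pid, w))
    offsets = np.array(offsets)

    target = spec.positive_prevalence_target
    c = brentq(lambda c0: expit(c0 + offsets).mean() - target, -30, 30)
    probs = expit(c + offsets)
    uniforms = lrng.random(len(probs))
    labels = (uniforms < probs).astype(int)

    gt = pd.DataFrame({
        "participant_id": [k[0] for k in keys],
        "week_index": [k[1] for k in keys],
        "logit": c + offsets, "prob": probs, "label": labels})

    # fill K6 answers consistent with the drawn binary labels
    label_by = {(r.participant_id, r.week_index): int(r.label)
                for r in gt.itertuples()}
    for p in participants:
        qrng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 3, pids.index(p.participant_id)]))
        kept = []
        for q in p.questionnaires:
            pos = label_by[(p.participant_id, q.week_index)]
            total = int(5 + min(qrng.poisson(3.0), 19)) if pos \
                else int(qrng.integers(0, 5))
            q.k6_total = total
            q.k6_items = _allocate_k6_items(total, qrng)
            if qrng.random() >= spec.missing_prob_questionnaires:
                kept.append(q)
        p.questionnaires = kept

    return SyntheticCohort(participants, gt, replace(spec), assigned, float(c))


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the three CSV streams (plus ground truth) to a directory.

    The files use exactly the ingest dialects, so
    :func:`telestress.ingest.read_cohort_dir` round-trips losslessly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "wearable": directory / "wearable.csv",
        "shifts": directory / "shifts.csv",
        "questionnaires": directory / "questionnaires.csv",
        "ground_truth": directory / "ground_truth.csv",
    }
    write_wearable(paths["wearable"],
                   [r for p in cohort.participants for r in p.wearable])
    write_shifts(paths["shifts"],
                 [r for p in cohort.participants for r in p.shifts])
    write_questionnaires(paths["questionnaires"],
                         [r for p in cohort.participants for r in p.questionnaires])
    cohort.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths
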