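"""Weekly feature aggregation, K6 labeling, and lagged supervised instances.

Daily streams are rolled up into one feature vector per participant-week.
The aggregation honours the study's missingness rules: a weekly mean is
omitted only when the variable is missing for the entire 7 days, and the
unbiased weekly SD is omitted when fewer than 2 daily values are present.
The six-item K6 distress total (0-24) is mapped to four severity classes and
binarized (total <= 4 -> negative, else positive).  Supervised instances pair
the feature vector of week t-1 with the stress label of week t, so a
12-week record yields at most 11 instances.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .ingest import ParticipantData
from .registry import FeatureRegistry

logger = logging.getLogger(__name__)

#: Daily variables taken directly from the wearable stream.
WEARABLE_VARS = (
    "sleep_duration", "sleep_efficiency", "sleep_start", "sleep_end",
    "steps", "distance", "floors", "calories", "hr_mean", "hr_sd",
)
#: Daily variables derived from the work-shift stream (worked days only).
WORK_VARS = (
    "working_hours", "work_start", "work_end", "working_hour_gap",
    "scheduled_hours",
)


@dataclass
class WeeklyFeatureVector:
    participant_id: str
    week_index: int
    values: dict[str, float]  # feature name -> value (NaN = missing)


@dataclass(frozen=True)
class StressLabel:
    participant_id: str
    week_index: int
    k6_total: int
    k6_class: int        # 1..4 severity class
    binary: str          # "negative" | "positive"

    @property
    def positive(self) -> bool:
        return self.binary == "positive"


@dataclass
class SupervisedInstance:
    participant_id: str
    label_week: int                # week t
    features: WeeklyFeatureVector  # week t-1
    label: StressLabel             # week t

    def __post_init__(self) -> None:
        if self.features.week_index != self.label_week - 1:
            raise ValidationError(
                f"features week {self.features.week_index} is not the week "
                f"before label week {self.label_week}")
        if self.label_week < 2:
            raise ValidationError("label_week must be >= 2 (one-week lag)")


def aggregate_week(daily_values: Sequence[Optional[float]], kind: str) -> float:
    """Aggregate up to 7 daily values into a weekly mean or unbiased SD.

    Returns NaN when no value is present (mean) or fewer than two values are
    present (SD, which uses the n-1 denominator).
    """
    if len(daily_values) > 7:
        raise ValidationError(f"a week has at most 7 values, got {len(daily_values)}")
    present = [v for v in daily_values if v is not None and not (
        isinstance(v, float) and math.isnan(v))]
    if kind == "mean":
        return float(np.mean(present)) if present else float("nan")
    if kind == "sd":
        return float(np.std(present, ddof=1)) if len(present) >= 2 else float("nan")
    raise ConfigurationError(f"unknown aggregation kind {kind!r}")


def binarize_k6(total: int) -> StressLabel:
    """Map a K6 total (0-24) to its severity class and binary stress label.

    Class 1 (negative): 0-4; class 2: 5-8; class 3: 9-12; class 4: >= 13.
    Any total of 5 or more is stress-positive.
    """
    if not 0 <= total <= 24:
        raise ValidationError(f"K6 total {total} outside [0, 24]")
    if total <= 4:
        k6_class = 1
    elif total <= 8:
        k6_class = 2
    elif total <= 12:
        k6_class = 3
    else:
        k6_class = 4
    binary = "negative" if k6_class == 1 else "positive"
    return StressLabel("", 0, total, k6_class, binary)


def build_labels(p: ParticipantData) -> list[StressLabel]:
    """One stress label per answered questionnaire week."""
    out = []
    for q in sorted(p.questionnaires, key=lambda q: q.week_index):
        proto = binarize_k6(q.k6_total)
        out.append(StressLabel(p.participant_id, q.week_index,
                               proto.k6_total, proto.k6_class, proto.binary))
    return out


def infer_study_start(participants: Sequence[ParticipantData]) -> dt.date:
    """Monday on or before the earliest dated record in the cohort."""
    dates = [r.date for p in participants for r in (*p.wearable, *p.shifts)]
    if not dates:
        raise ValidationError("no dated records in cohort")
    first = min(dates)
    return first - dt.timedelta(days=first.weekday())


def _week_of(date: dt.date, start: dt.date) -> int:
    return (date - start).days // 7 + 1


def build_weekly_features(
    p: ParticipantData,
    registry: FeatureRegistry,
    start_date: dt.date,
    n_weeks: int,
) -> list[WeeklyFeatureVector]:
    """One feature vector per study week 1..n_weeks for one participant.

    Derived daily work variables (working hours, working-hour gap, start/end
    times) are computed on worked days first, then aggregated per the
    registry.  Count features tally worked/WFH/absence days; questionnaire
    counts are copied through; baseline deviations compare each weekly mean
    against the participant's mean over all available study weeks; delta
    features are week-over-week changes and are missing in week 1.
    """
    # daily values per (var, week)
    daily: dict[str, dict[int, list[float]]] = {
        v: {w: [] for w in range(1, n_weeks + 1)}
        for v in (*WEARABLE_VARS, *WORK_VARS)
    }
    for rec in p.wearable:
        w = _week_of(rec.date, start_date)
        if not 1 <= w <= n_weeks:
            continue
        for var in WEARABLE_VARS:
            v = getattr(rec, var)
            if v is not None:
                daily[var][w].append(float(v))

    counts = {w: {"worked_days": 0, "wfh_days": 0, "absence_days": 0}
              for w in range(1, n_weeks + 1)}
    for rec in p.shifts:
        w = _week_of(rec.date, start_date)
        if not 1 <= w <= n_weeks:
            continue
        if rec.absent:
            counts[w]["absence_days"] += 1
            continue
        counts[w]["worked_days"] += 1
        if rec.wfh:
            counts[w]["wfh_days"] += 1
        daily["scheduled_hours"][w].append(rec.scheduled_hours)
        if rec.actual_start is not None:
            daily["work_start"][w].append(rec.actual_start)
        if rec.actual_end is not None:
            daily["work_end"][w].append(rec.actual_end)
        if rec.actual_start is not None and rec.actual_end is not None:
            hours = (rec.actual_end - rec.actual_start) / 60.0
            daily["working_hours"][w].append(hours)
            daily["working_hour_gap"][w].append(hours - rec.scheduled_hours)

    quest = {q.week_index: q for q in p.questionnaires}

    # weekly base values every registry entry can draw from
    base: dict[str, dict[int, float]] = {}
    for var in (*WEARABLE_VARS, *WORK_VARS):
        base[f"{var}_mean"] = {
            w: aggregate_week(daily[var][w], "mean") for w in range(1, n_weeks + 1)}
        base[f"{var}_sd"] = {
            w: aggregate_week(daily[var][w], "sd") for w in range(1, n_weeks + 1)}
    for var in ("steps", "distance", "floors", "calories"):
        base[f"{var}_sum"] = {
            w: float(np.sum(daily[var][w])) if daily[var][w] else float("nan")
            for w in range(1, n_weeks + 1)}
    for name in ("worked_days", "wfh_days", "absence_days"):
        base[name] = {w: float(counts[w][name]) for w in range(1, n_weeks + 1)}
    base["telework_rate_week"] = {
        w: (counts[w]["wfh_days"] / counts[w]["worked_days"]
            if counts[w]["worked_days"] > 0 else float("nan"))
        for w in range(1, n_weeks + 1)}
    base["outings"] = {
        w: float(quest[w].outings) if w in quest else float("nan")
        for w in range(1, n_weeks + 1)}
    base["lunches_skipped"] = {
        w: float(quest[w].lunches_skipped) if w in quest else float("nan")
        for w in range(1, n_weeks + 1)}
    base["k6_total"] = {
        w: float(quest[w].k6_total) if w in quest else float("nan")
        for w in range(1, n_weeks + 1)}

    def weekly_series(source: str) -> dict[int, float]:
        if source not in base:
            raise ConfigurationError(f"unknown registry source variable {source!r}")
        return base[source]

    vectors = []
    for w in range(1, n_weeks + 1):
        values: dict[str, float] = {}
        for entry in registry:
            if entry.aggregation == "weekly_mean":
                values[entry.name] = base[f"{entry.source}_mean"][w] \
                    if f"{entry.source}_mean" in base else _bad_source(entry)
            elif entry.aggregation == "weekly_sd":
                values[entry.name] = base[f"{entry.source}_sd"][w] \
                    if f"{entry.source}_sd" in base else _bad_source(entry)
            elif entry.aggregation in ("weekly_count", "weekly_sum"):
                key = entry.source if entry.aggregation == "weekly_count" \
                    else f"{entry.source}_sum"
                values[entry.name] = weekly_series(key)[w]
            elif entry.aggregation == "baseline_deviation":
                series = weekly_series(entry.source)
                arr = np.array(list(series.values()), dtype=float)
                baseline = float(np.nanmean(arr)) if not np.all(np.isnan(arr)) \
                    else float("nan")
                values[entry.name] = abs(series[w] - baseline)
            elif entry.aggregation == "weekly_delta":
                series = weekly_series(entry.source)
                values[entry.name] = (series[w] - series[w - 1]) if w >= 2 \
                    else float("nan")
        vectors.append(WeeklyFeatureVector(p.participant_id, w, values))
    return vectors


def _bad_source(entry):
    raise ConfigurationError(
        f"unknown registry source variable {entry.source!r} for {entry.name!r}")


def build_instances(
    features: list[WeeklyFeatureVector],
    labels: list[StressLabel],
) -> list[SupervisedInstance]:
    """Pair week-(t-1) features with week-t labels for t = 2..n_weeks.

    Weeks whose label is missing are dropped (and logged); their feature
    vector may still serve the following week's instance.
    """
    if features and labels:
        pids = {f.participant_id for f in features} | {l.participant_id for l in labels}
        if len(pids) != 1:
            raise ValidationError(f"mixed participant ids in instance build: {pids}")
    fmap = {f.week_index: f for f in features}
    lmap = {l.week_index: l for l in labels}
    out = []
    for t in sorted(fmap.keys()):
        t += 1  # label week
        if (t - 1) not in fmap:
            continue
        if t not in lmap:
            if t <= max(fmap.keys(), default=0) + 1:
                logger.debug("label missing at week %s; instance dropped", t)
            continue
        out.append(SupervisedInstance(
            participant_id=lmap[t].participant_id,
            label_week=t, features=fmap[t - 1], label=lmap[t]))
    return out


def instances_to_matrix(
    instances: Sequence[SupervisedInstance],
    registry: FeatureRegistry,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Stack instances into (X, y, meta) for the learner.

    X columns follow the registry order; missing values are NaN and are left
    to the learner's native missing-value handling (no imputation).
    """
    names = registry.names
    X = pd.DataFrame(
        [[inst.features.values.get(n, float("nan")) for n in names]
         for inst in instances],
        columns=names, dtype=float)
    y = np.array([1 if inst.label.positive else 0 for inst in instances],
                 dtype=int)
    meta = pd.DataFrame({
        "participant_id": [i.participant_id for i in instances],
        "label_week": [i.label_week for i in instances],
    })
    return X, y, meta


def features_to_frame(
    participants: Sequence[ParticipantData],
    registry: FeatureRegistry,
    start_date: Optional[dt.date] = None,
    n_weeks: Optional[int] = None,
) -> pd.DataFrame:
    """Wide per-participant-week feature table (plus k6_total and label)."""
    if start_date is None:
        start_date = infer_study_start(participants)
    if n_weeks is None:
        n_weeks = max(
            max((_week_of(r.date, start_date) for p in participants
                 for r in (*p.wearable, *p.shifts)), default=0),
            max((q.week_index for p in participants for q in p.questionnaires),
                default=0))
    rows = []
    for p in participants:
        quest = {q.week_index: q for q in p.questionnaires}
        for vec in build_weekly_features(p, registry, start_date, n_weeks):
            row = {"participant_id": vec.participant_id,
                   "week_index": vec.week_index, **vec.values}
            q = quest.get(vec.week_index)
            row["k6_total"] = q.k6_total if q else np.nan
            row["label"] = (binarize_k6(q.k6_total).binary if q else "")
            rows.append(row)
    return pd.DataFrame(rows)
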