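"""Per-target gradient-boosted stress classifiers for three training regimes.

Three ways of choosing training data are compared:

* ``single`` — one pooled model: everyone's first 7 calendar weeks train,
  everyone's last 5 weeks test, threshold fixed at 0.5.
* ``proposed1`` — per-target model: all 11 lagged instances of the target's
  neighborhood cluster plus the target's first 7 weeks train; the target's
  last 5 weeks test; threshold fixed at 0.5.
* ``proposed2`` — per-target model: cluster + target first-7-week instances
  train; the cluster's last 5 weeks adapt the decision threshold (smallest
  false-positive rate subject to true-positive rate > 0.8); the target's
  last 5 weeks test.

Because instances carry a one-week lag, "first 7 weeks" means label weeks
2-7 (6 instances, features from weeks 1-6) and "last 5 weeks" means label
weeks 8-12 (5 instances, features from weeks 7-11).  The learner is XGBoost
with max_depth=6, learning_rate=0.3, n_estimators=100 (no hyperparameter
search); missing feature values use its native missing-branch handling.
A score greater than or equal to the threshold predicts stress-positive.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .errors import (DegenerateTrainingError, SchemaError, ValidationError)
from .features import SupervisedInstance, instances_to_matrix
from .neighborhood import TeleworkProfile, extract_neighborhood
from .registry import FeatureRegistry

logger = logging.getLogger(__name__)

METHODS = ("single", "proposed1", "proposed2")


@dataclass
class ExperimentConfig:
    method: str = "proposed1"
    max_depth: int = 6
    learning_rate: float = 0.3
    n_estimators: int = 100
    fixed_threshold: float = 0.5
    tp_target: float = 0.8
    cluster_size: int = 20
    train_week_max: int = 7     # calendar week boundary of the train period
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if not 0 < self.tp_target < 1:
            raise ValidationError("tp_target must be in (0, 1)")


@dataclass
class SplitPlan:
    train: list[SupervisedInstance]
    adaptation: list[SupervisedInstance]
    test: list[SupervisedInstance]


@dataclass
class ThresholdAdaptationResult:
    threshold: float
    achieved_tp: float
    achieved_fp: float
    constraint_met: bool
    n_positives: int = 0
    n_negatives: int = 0


@dataclass
class TrainedIndividualModel:
    target_id: str
    booster: xgb.XGBClassifier
    threshold: float
    feature_names: list[str]
    adaptation: Optional[ThresholdAdaptationResult] = None


@dataclass(frozen=True)
class PredictionRecord:
    target_id: str
    label_week: int
    score: float
    predicted: int
    actual: int


@dataclass
class ExperimentResult:
    method: str
    records: list[PredictionRecord]
    models: dict[str, TrainedIndividualModel]
    clusters: dict[str, list[str]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def make_splits(
    method: str,
    target_instances: Sequence[SupervisedInstance],
    cluster_instances: Sequence[SupervisedInstance],
    train_week_max: int = 7,
) -> SplitPlan:
    """Assign instances to train/adaptation/test per the method's regime."""
    t_train = [i for i in target_instances if i.label_week <= train_week_max]
    t_test = [i for i in target_instances if i.label_week > train_week_max]
    c_early = [i for i in cluster_instances if i.label_week <= train_week_max]
    c_late = [i for i in cluster_instances if i.label_week > train_week_max]
    if method == "single":
        # one pooled model: the "cluster" is everyone else; the target's own
        # early weeks join the pooled training data
        return SplitPlan(train=[*c_early, *t_train], adaptation=[], test=t_test)
    if method == "proposed1":
        return SplitPlan(train=[*c_early, *c_late, *t_train],
                         adaptation=[], test=t_test)
    if method == "proposed2":
        return SplitPlan(train=[*c_early, *t_train],
                         adaptation=list(c_late), test=t_test)
    raise ValidationError(f"unknown method {method!r}")


def train_model(
    train_instances: Sequence[SupervisedInstance],
    registry: FeatureRegistry,
    config: ExperimentConfig,
    target_id: str = "",
    seed: Optional[int] = None,
) -> TrainedIndividualModel:
    """Fit the gradient-boosted classifier on the training instances."""
    X, y, _ = instances_to_matrix(train_instances, registry)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError(
            f"training set for target {target_id!r} contains a single class")
    clf = xgb.XGBClassifier(
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        random_state=config.seed if seed is None else seed,
        tree_method="hist",
        n_jobs=1,
        eval_metric="logloss",
    )
    clf.fit(X, y)
    return TrainedIndividualModel(
        target_id=target_id, booster=clf,
        threshold=config.fixed_threshold, feature_names=list(X.columns))


def score_instances(
    model: TrainedIndividualModel,
    instances: Sequence[SupervisedInstance],
    registry: FeatureRegistry,
) -> np.ndarray:
    X, _, _ = instances_to_matrix(instances, registry)
    if list(X.columns) != model.feature_names:
        raise SchemaError("feature names do not match the training schema")
    if len(X) == 0:
        return np.zeros(0)
    return model.booster.predict_proba(X)[:, 1]


def adapt_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    tp_target: float = 0.8,
) -> ThresholdAdaptationResult:
    """Pick the decision threshold with the lowest false-positive rate among
    those whose true-positive rate exceeds ``tp_target``.

    Candidate thresholds are the distinct observed scores plus one value
    above the maximum (predict-nothing); since predictions only change at
    observed scores, the scan is exact.  Ties on FP rate break toward the
    highest threshold.  If no candidate meets the TP constraint the
    TP-maximizing (then FP-minimizing) threshold is returned with
    ``constraint_met=False``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValidationError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0:
        raise ValidationError("threshold adaptation needs at least one positive")
    candidates = np.concatenate([np.unique(scores), [scores.max() + 1.0]])
    best = None  # (fp, -threshold) lexicographic among feasible
    fallback = None  # (-tp, fp, -threshold)
    for thr in candidates:
        pred = scores >= thr
        tp = float((pred & (labels == 1)).sum()) / n_pos
        fp = float((pred & (labels == 0)).sum()) / n_neg if n_neg else 0.0
        if tp > tp_target:
            key = (fp, -thr)
            if best is None or key < best[0]:
                best = (key, thr, tp, fp)
        key_fb = (-tp, fp, -thr)
        if fallback is None or key_fb < fallback[0]:
            fallback = (key_fb, thr, tp, fp)
    if best is not None:
        _, thr, tp, fp = best
        return ThresholdAdaptationResult(float(thr), tp, fp, True, n_pos, n_neg)
    logger.warning("TP rate > %.2f unattainable on adaptation set", tp_target)
    _, thr, tp, fp = fallback
    return ThresholdAdaptationResult(float(thr), tp, fp, False, n_pos, n_neg)


def predict(
    model: TrainedIndividualModel,
    instances: Sequence[SupervisedInstance],
    registry: FeatureRegistry,
) -> list[PredictionRecord]:
    """Score instances; predicted positive iff score >= threshold."""
    scores = score_instances(model, instances, registry)
    return [PredictionRecord(
        target_id=inst.participant_id, label_week=inst.label_week,
        score=float(s), predicted=int(s >= model.threshold),
        actual=int(inst.label.positive))
        for inst, s in zip(instances, scores)]


def _target_seed(base_seed: int, target_id: str) -> int:
    return (base_seed * 1000003 + zlib.crc32(target_id.encode())) % (2 ** 31)


def run_experiment(
    instances_by_participant: dict[str, list[SupervisedInstance]],
    profiles: dict[str, TeleworkProfile],
    registry: FeatureRegistry,
    config: ExperimentConfig,
) -> ExperimentResult:
    """Run one method over every prediction target.

    Targets are visited in ascending teleworking-rate order.  The proposed
    methods fit one model per target on its neighborhood cluster; the single
    method fits one pooled model.  Per-target failures (no test instances,
    single-class training data, no positives for adaptation) skip that
    target with a logged reason; the run continues.
    """
    config.validate()
    result = ExperimentResult(method=config.method, records=[], models={})
    order = sorted(profiles, key=lambda pid: (profiles[pid].rate, pid))

    if config.method == "single":
        all_inst = [i for pid in order
                    for i in instances_by_participant.get(pid, [])]
        train = [i for i in all_inst if i.label_week <= config.train_week_max]
        test = [i for i in all_inst if i.label_week > config.train_week_max]
        model = train_model(train, registry, config, target_id="<pooled>",
                            seed=config.seed % (2 ** 31))
        result.models["<pooled>"] = model
        result.records = predict(model, test, registry)
        return result

    for pid in order:
        target_instances = instances_by_participant.get(pid, [])
        test_n = sum(1 for i in target_instances
                     if i.label_week > config.train_week_max)
        if test_n == 0:
            result.skipped[pid] = "no test instances in the last weeks"
            logger.warning("target %s skipped: no test instances", pid)
            continue
        try:
            cluster = extract_neighborhood(
                profiles[pid], list(profiles.values()),
                n=config.cluster_size, seed=_target_seed(config.seed, pid))
            cluster_instances = [i for m in cluster.member_ids
                                 for i in instances_by_participant.get(m, [])]
            plan = make_splits(config.method, target_instances,
                               cluster_instances, config.train_week_max)
            model = train_model(plan.train, registry, config, target_id=pid,
                                seed=_target_seed(config.seed, pid))
            if config.method == "proposed2":
                ascores = score_instances(model, plan.adaptation, registry)
                alabels = [int(i.label.positive) for i in plan.adaptation]
                try:
                    adaptation = adapt_threshold(ascores, alabels,
                                                 config.tp_target)
                    model.threshold = adaptation.threshold
                    model.adaptation = adaptation
                except ValidationError as exc:
                    logger.warning("target %s keeps fixed threshold: %s",
                                   pid, exc)
            result.clusters[pid] = list(cluster.member_ids)
            result.models[pid] = model
            result.records.extend(predict(model, plan.test, registry))
        except DegenerateTrainingError as exc:
            result.skipped[pid] = str(exc)
            logger.warning("target %s skipped: %s", pid, exc)
    return result


def records_to_frame(records: Sequence[PredictionRecord],
                     method: str = "") -> pd.DataFrame:
    df = pd.DataFrame([{
        "target_id": r.target_id, "label_week": r.label_week,
        "score": r.score, "predicted": r.predicted, "actual": r.actual,
    } for r in records])
    if method:
        df["method"] = method
    return df
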