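"""Model interpretation: gain importance, TreeSHAP, direction statistics,
and teleworking-level stratification.

For each individual model the ten features with the highest gain importance
(total objective reduction contributed by splits on the feature) are
extracted.  Exact TreeSHAP values are computed on the model's evaluated
(test-week) instances via XGBoost's native ``pred_contribs`` predictor, so
per-row SHAP values sum to the model margin.  The contribution direction of
a feature is cov(feature, SHAP) / sd(feature) (unbiased forms): a positive
value means larger feature values push the predicted stress probability up.
Models are then stratified by their target's teleworking level (low /
middle / high) and the per-level category mix of top-10 features and the
per-feature direction distributions are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .errors import SchemaError, ValidationError
from .modeling import TrainedIndividualModel
from .neighborhood import LEVELS, TeleworkProfile, assign_level
from .registry import FeatureRegistry


@dataclass
class FeatureImportanceRanking:
    target_id: str
    ranked: list[tuple[str, float]]  # (feature, gain) non-increasing
    top10: list[str]

    def rank_of(self, feature: str) -> int:
        """1-based rank; unranked features share the worst rank."""
        for i, (name, _) in enumerate(self.ranked, start=1):
            if name == feature:
                return i
        return len(self.ranked) + 1


@dataclass
class ShapMatrix:
    target_id: str
    phi: np.ndarray          # (n_instances, n_features), margin units
    base_value: float
    feature_names: list[str]
    margins: np.ndarray      # model margin per instance


@dataclass(frozen=True)
class DirectionStatistic:
    target_id: str
    feature_name: str
    value: float
    defined: bool


@dataclass
class StratifiedContributionTable:
    category_counts: dict[str, dict[str, int]]      # level -> category -> count
    direction_stats: dict[str, dict[str, list[float]]]  # level -> feature -> values
    mean_rank_tables: dict[str, pd.DataFrame]       # level -> ranked feature table
    n_models: dict[str, int]                        # level -> model count


def rank_importance(model: TrainedIndividualModel,
                    top_n: int = 10) -> FeatureImportanceRanking:
    """Gain importance per feature, sorted descending (name breaks ties).

    Features never split on have zero gain; the top-10 list is padded with
    zero-importance features in stable name order when fewer than ``top_n``
    features were used.
    """
    try:
        booster = model.booster.get_booster()
    except Exception as exc:  # unfitted sklearn wrapper
        raise ValidationError(f"model for {model.target_id!r} is not fitted") from exc
    gains = booster.get_score(importance_type="gain")
    full = {name: float(gains.get(name, 0.0)) for name in model.feature_names}
    ranked = sorted(full.items(), key=lambda kv: (-kv[1], kv[0]))
    top10 = [name for name, _ in ranked[:top_n]]
    return FeatureImportanceRanking(model.target_id, ranked, top10)


def compute_shap(model: TrainedIndividualModel, X: pd.DataFrame) -> ShapMatrix:
    """Exact TreeSHAP decomposition of the model margin for each row of X."""
    if list(X.columns) != model.feature_names:
        raise SchemaError("instances do not match the training schema")
    booster = model.booster.get_booster()
    dm = xgb.DMatrix(X, missing=np.nan, feature_names=model.feature_names)
    contribs = booster.predict(dm, pred_contribs=True)
    margins = booster.predict(dm, output_margin=True)
    return ShapMatrix(
        target_id=model.target_id,
        phi=contribs[:, :-1],
        base_value=float(contribs[0, -1]) if len(contribs) else 0.0,
        feature_names=list(model.feature_names),
        margins=np.asarray(margins, dtype=float))


def direction_statistic(feature_values: Sequence[float],
                        phi_values: Sequence[float],
                        target_id: str = "",
                        feature_name: str = "") -> DirectionStatistic:
    """cov(x, phi) / sd(x) with unbiased (n-1) estimators.

    Rows where the feature is missing are dropped (SHAP is defined for a
    missing input, but a covariance with it is not).  A zero-variance
    feature yields ``defined=False`` and value 0.
    """
    x = np.asarray(feature_values, dtype=float)
    phi = np.asarray(phi_values, dtype=float)
    if len(x) != len(phi):
        raise ValidationError("feature and SHAP vectors differ in length")
    keep = ~np.isnan(x)
    x, phi = x[keep], phi[keep]
    if len(x) < 2:
        raise ValidationError("direction statistic needs >= 2 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return DirectionStatistic(target_id, feature_name, 0.0, False)
    cov = float(np.cov(x, phi, ddof=1)[0, 1])
    return DirectionStatistic(target_id, feature_name, cov / sd, True)


def directions_for_model(
    model: TrainedIndividualModel,
    X: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
) -> dict[str, DirectionStatistic]:
    """Direction statistic for each requested feature on the evaluated rows."""
    shap = compute_shap(model, X)
    features = list(features) if features is not None else model.feature_names
    out = {}
    for name in features:
        j = model.feature_names.index(name)
        try:
            out[name] = direction_statistic(
                X[name].to_numpy(), shap.phi[:, j], model.target_id, name)
        except ValidationError:
            out[name] = DirectionStatistic(model.target_id, name, 0.0, False)
    return out


def stratify(
    importances: dict[str, FeatureImportanceRanking],
    directions: dict[str, dict[str, DirectionStatistic]],
    profiles: dict[str, TeleworkProfile],
    registry: FeatureRegistry,
    merge_questionnaire_into_work: bool = False,
) -> StratifiedContributionTable:
    """Group per-target results by teleworking level and tabulate.

    Per level: counts of top-10 occurrences by registry category, the
    distribution of each feature's direction statistic over models, and the
    per-level feature table ordered by mean within-model importance rank
    (rank 1 = most important; mean-of-ranks is scale-free across models).

    ``merge_questionnaire_into_work`` collapses the questionnaire category
    into ``work`` for a strict three-category (sleep/activity/work) view.
    """
    counts = {lv: {} for lv in LEVELS}
    dstats: dict[str, dict[str, list[float]]] = {lv: {} for lv in LEVELS}
    ranks: dict[str, dict[str, list[int]]] = {lv: {} for lv in LEVELS}
    n_models = {lv: 0 for lv in LEVELS}

    for tid, ranking in importances.items():
        if tid not in profiles:
            raise ValidationError(f"no teleworking profile for target {tid!r}")
        level = assign_level(profiles[tid].rate)
        n_models[level] += 1
        for name in ranking.top10:
            cat = registry.category_of(name)
            if merge_questionnaire_into_work and cat == "questionnaire":
                cat = "work"
            counts[level][cat] = counts[level].get(cat, 0) + 1
        for name, _ in ranking.ranked:
            ranks[level].setdefault(name, []).append(ranking.rank_of(name))
        for name, stat in directions.get(tid, {}).items():
            if stat.defined:
                dstats[level].setdefault(name, []).append(stat.value)

    tables = {}
    for lv in LEVELS:
        rows = [{"feature": name,
                 "mean_rank": float(np.mean(rs)),
                 "category": registry.category_of(name),
                 "n_models": len(rs)}
                for name, rs in ranks[lv].items()]
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df.sort_values(["mean_rank", "feature"]).reset_index(drop=True)
        tables[lv] = df
    return StratifiedContributionTable(
        category_counts=counts, direction_stats=dstats,
        mean_rank_tables=tables, n_models=n_models)


def stratified_summary_frame(table: StratifiedContributionTable) -> pd.DataFrame:
    """Long-form summary: per level, category counts and per-feature median
    direction statistics."""
    rows = []
    for lv in LEVELS:
        for cat, cnt in sorted(table.category_counts[lv].items()):
            rows.append({"level": lv, "kind": "category_count",
                         "name": cat, "value": cnt})
        for feat, vals in sorted(table.direction_stats[lv].items()):
            rows.append({"level": lv, "kind": "median_direction",
                         "name": feat, "value": float(np.median(vals))})
        rows.append({"level": lv, "kind": "n_models", "name": "",
                     "value": table.n_models[lv]})
    return pd.DataFrame(rows)
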