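"""Pipeline orchestration: simulate -> featurize -> run -> evaluate -> interpret.

Each stage reads its inputs from and writes its artifacts to one output
directory, together with a small JSON manifest (config hash, seed, row
counts), so a rerun with the same config reproduces identical artifacts and
stages can be re-executed independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import xgboost as xgb
import yaml

from . import __version__
from .errors import MissingInputError, ValidationError
from .evaluation import compare_methods, pool_and_evaluate, per_target_reports
from .features import (build_instances, build_labels, build_weekly_features,
                       features_to_frame, infer_study_start,
                       instances_to_matrix)
from .ingest import ParticipantData, read_cohort_dir
from .interpret import (directions_for_model, rank_importance, stratify,
                        stratified_summary_frame)
from .modeling import (ExperimentConfig, ExperimentResult, PredictionRecord,
                       TrainedIndividualModel, records_to_frame,
                       run_experiment)
from .neighborhood import compute_teleworking_rate
from .registry import FeatureRegistry, default_registry
from .synthetic import STUDY_START, CohortSpec, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "featurize", "run", "evaluate", "interpret")


@dataclasses.dataclass
class PipelineConfig:
    outdir: Path
    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    methods: list[str] = dataclasses.field(
        default_factory=lambda: ["single", "proposed1", "proposed2"])
    experiment: dict = dataclasses.field(default_factory=dict)
    include_prior_k6: bool = True
    registry_yaml: Optional[str] = None
    rate_weeks: Optional[int] = None  # restrict rate computation to first k weeks
    interpret_method: str = "proposed1"
    merge_questionnaire_into_work: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortSpec.from_config(raw.pop("cohort", {}))
        if outdir is None:
            outdir = raw.pop("outdir", "telestress_out")
        else:
            raw.pop("outdir", None)
        cfg = cls(outdir=Path(outdir), cohort=cohort, **raw)
        if seed is not None:
            cfg.seed = seed
        cfg.cohort.seed = cfg.cohort.seed or cfg.seed
        return cfg

    def registry(self) -> FeatureRegistry:
        if self.registry_yaml:
            return FeatureRegistry.from_yaml(self.registry_yaml)
        return default_registry(include_prior_k6=self.include_prior_k6)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig,
                    **counts) -> None:
    manifest = {
        "stage": stage, "config_hash": config.config_hash(),
        "seed": config.seed, "version": __version__, **counts,
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ----------------------------------------------------------- shared loading

def _load_participants(config: PipelineConfig) -> list[ParticipantData]:
    data_dir = config.outdir / "data"
    if not (data_dir / "wearable.csv").exists():
        raise MissingInputError(
            f"no cohort data under {data_dir}; run the simulate stage first "
            "or place wearable.csv/shifts.csv/questionnaires.csv there")
    return read_cohort_dir(data_dir)


def _prepare(config: PipelineConfig, participants):
    """Instances, teleworking profiles, and the registry for a cohort."""
    registry = config.registry()
    start = infer_study_start(participants)
    n_weeks = config.cohort.n_weeks
    instances, profiles = {}, {}
    for p in participants:
        feats = build_weekly_features(p, registry, start, n_weeks)
        labels = build_labels(p)
        instances[p.participant_id] = build_instances(feats, labels)
        try:
            profiles[p.participant_id] = compute_teleworking_rate(
                p.shifts, p.participant_id,
                max_week=config.rate_weeks, start_date=start)
        except Exception as exc:
            logger.warning("participant %s excluded from clustering: %s",
                           p.participant_id, exc)
    return registry, instances, profiles, start, n_weeks


# ----------------------------------------------------------- stages

def stage_simulate(config: PipelineConfig) -> None:
    cohort = generate_cohort(config.cohort)
    write_cohort(cohort, config.outdir / "data")
    _write_manifest(config.outdir, "simulate", config,
                    n_participants=len(cohort.participants))


def stage_featurize(config: PipelineConfig) -> None:
    participants = _load_participants(config)
    frame = features_to_frame(participants, config.registry(),
                              n_weeks=config.cohort.n_weeks)
    frame.to_csv(config.outdir / "features.csv", index=False)
    _write_manifest(config.outdir, "featurize", config, n_rows=len(frame))


def stage_run(config: PipelineConfig) -> dict[str, ExperimentResult]:
    participants = _load_participants(config)
    registry, instances, profiles, _, _ = _prepare(config, participants)
    results = {}
    for method in config.methods:
        exp = ExperimentConfig(method=method, seed=config.seed,
                               **config.experiment)
        result = run_experiment(instances, profiles, registry, exp)
        results[method] = result
        records_to_frame(result.records, method).to_csv(
            config.outdir / f"predictions_{method}.csv", index=False)
        if result.clusters:
            pd.DataFrame([
                {"target_id": t, "member_id": m}
                for t, members in sorted(result.clusters.items())
                for m in members
            ]).to_csv(config.outdir / f"clusters_{method}.csv", index=False)
        model_dir = config.outdir / "models" / method
        model_dir.mkdir(parents=True, exist_ok=True)
        meta = {}
        for tid, model in result.models.items():
            fname = f"{tid.strip('<>')}.json"
            model.booster.get_booster().save_model(model_dir / fname)
            meta[tid] = {"file": fname, "threshold": model.threshold}
        (model_dir / "meta.json").write_text(json.dumps(meta, indent=2,
                                                        sort_keys=True))
    _write_manifest(config.outdir, "run", config,
                    methods=list(config.methods),
                    n_records={m: len(r.records) for m, r in results.items()})
    return results


def _load_records(config: PipelineConfig, method: str) -> list[PredictionRecord]:
    path = config.outdir / f"predictions_{method}.csv"
    if not path.exists():
        raise MissingInputError(f"{path} not found; run the run stage first")
    df = pd.read_csv(path)
    return [PredictionRecord(r.target_id, int(r.label_week), float(r.score),
                             int(r.predicted), int(r.actual))
            for r in df.itertuples()]


def stage_evaluate(config: PipelineConfig) -> pd.DataFrame:
    reports = [pool_and_evaluate(_load_records(config, m), m)
               for m in config.methods]
    if len(reports) >= 2:
        table = compare_methods(reports)
    else:
        r = reports[0]
        table = pd.DataFrame([dataclasses.asdict(r)])
    table.to_csv(config.outdir / "evaluation.csv", index=False)
    conf = pd.DataFrame([{"method": r.method, "tp": r.tp, "fp": r.fp,
                          "tn": r.tn, "fn": r.fn} for r in reports])
    conf.to_csv(config.outdir / "confusion.csv", index=False)
    per_target = pd.concat(
        [per_target_reports(_load_records(config, m), m).assign(method=m)
         for m in config.methods], ignore_index=True)
    per_target.to_csv(config.outdir / "evaluation_per_target.csv", index=False)
    _write_manifest(config.outdir, "evaluate", config, n_methods=len(reports))
    logger.info("evaluation:\n%s", table.to_string(index=False))
    return table


def _load_models(config: PipelineConfig, method: str,
                 registry) -> dict[str, TrainedIndividualModel]:
    model_dir = config.outdir / "models" / method
    meta_path = model_dir / "meta.json"
    if not meta_path.exists():
        raise MissingInputError(
            f"no model store under {model_dir}; run the run stage first")
    meta = json.loads(meta_path.read_text())
    models = {}
    for tid, entry in meta.items():
        clf = xgb.XGBClassifier()
        clf.load_model(model_dir / entry["file"])
        models[tid] = TrainedIndividualModel(
            target_id=tid, booster=clf, threshold=entry["threshold"],
            feature_names=registry.names)
    return models


def stage_interpret(config: PipelineConfig) -> None:
    method = config.interpret_method
    participants = _load_participants(config)
    registry, instances, profiles, _, _ = _prepare(config, participants)
    models = _load_models(config, method, registry)
    exp = ExperimentConfig(method=method, seed=config.seed, **config.experiment)

    importances, directions, shap_rows, imp_rows, dir_rows = {}, {}, [], [], []
    for tid, model in sorted(models.items()):
        if tid not in instances:
            continue
        test = [i for i in instances[tid]
                if i.label_week > exp.train_week_max]
        if not test:
            continue
        X, _, meta = instances_to_matrix(test, registry)
        ranking = rank_importance(model)
        importances[tid] = ranking
        directions[tid] = directions_for_model(model, X, ranking.top10)
        for rank, (name, gain) in enumerate(ranking.ranked, start=1):
            if rank <= 10:
                imp_rows.append({"target_id": tid, "feature": name,
                                 "rank": rank, "gain": gain})
        for name, stat in directions[tid].items():
            dir_rows.append({"target_id": tid, "feature": name,
                             "direction": stat.value, "defined": stat.defined})
        from .interpret import compute_shap
        shap = compute_shap(model, X)
        for row_i in range(len(X)):
            for j, name in enumerate(registry.names):
                if name in ranking.top10:
                    shap_rows.append({
                        "target_id": tid,
                        "label_week": int(meta["label_week"].iloc[row_i]),
                        "feature": name,
                        "value": float(X.iloc[row_i, j]),
                        "shap": float(shap.phi[row_i, j])})

    table = stratify(importances, directions, profiles, registry,
                     config.merge_questionnaire_into_work)
    pd.DataFrame(imp_rows).to_csv(config.outdir / "importance.csv", index=False)
    pd.DataFrame(dir_rows).to_csv(config.outdir / "directions.csv", index=False)
    pd.DataFrame(shap_rows).to_csv(config.outdir / "shap_values.csv", index=False)
    stratified_summary_frame(table).to_csv(
        config.outdir / "stratified_summary.csv", index=False)
    _write_manifest(config.outdir, "interpret", config,
                    n_models=len(importances))


def prepare_cohort(cohort_spec: CohortSpec,
                   registry: Optional[FeatureRegistry] = None):
    """Generate a synthetic cohort and build its supervised instances and
    teleworking profiles in memory.

    Returns ``(cohort, instances_by_participant, profiles, registry)``.
    """
    cohort = generate_cohort(cohort_spec)
    registry = registry or default_registry()
    start = infer_study_start(cohort.participants)
    instances, profiles = {}, {}
    for p in cohort.participants:
        feats = build_weekly_features(p, registry, start, cohort_spec.n_weeks)
        instances[p.participant_id] = build_instances(feats, build_labels(p))
        profiles[p.participant_id] = compute_teleworking_rate(
            p.shifts, p.participant_id)
    return cohort, instances, profiles, registry


def run_cohort_experiment(
    cohort_spec: CohortSpec,
    methods: Sequence[str] = ("single", "proposed1", "proposed2"),
    seed: Optional[int] = None,
    registry: Optional[FeatureRegistry] = None,
    **experiment_overrides,
) -> dict[str, ExperimentResult]:
    """Generate a synthetic cohort and run the requested methods in memory.

    Convenience entry point for simulation studies: no files are written;
    the per-method :class:`~telestress.modeling.ExperimentResult` objects
    (prediction records, fitted models, clusters) are returned directly.
    """
    if seed is None:
        seed = cohort_spec.seed
    _, instances, profiles, registry = prepare_cohort(cohort_spec, registry)
    out = {}
    for method in methods:
        exp = ExperimentConfig(method=method, seed=seed,
                               **experiment_overrides)
        out[method] = run_experiment(instances, profiles, registry, exp)
    return out


def run_pipeline(config: PipelineConfig,
                 stages: Optional[Sequence[str]] = None) -> None:
    """Execute the requested stages (default: all) in pipeline order."""
    stages = list(stages) if stages else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s): {unknown}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("stage %s ...", stage)
        {"simulate": stage_simulate, "featurize": stage_featurize,
         "run": stage_run, "evaluate": stage_evaluate,
         "interpret": stage_interpret}[stage](config)
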