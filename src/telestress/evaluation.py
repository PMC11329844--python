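"""Pooled evaluation: confusion matrix, TP/FP rates, and AUROC.

Per-target predictions are pooled over all participants and weeks (micro
evaluation) before computing rates, matching a deployment in which every
individual model's weekly alerts feed one monitoring stream.  AUROC uses
the rank (Mann-Whitney) formulation with ties counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .modeling import PredictionRecord


@dataclass
class EvaluationReport:
    method: str
    tp_rate: float
    fp_rate: float
    auroc: float          # NaN when actuals are one-class
    tp: int
    fp: int
    tn: int
    fn: int
    n_records: int


def auroc_score(scores: Sequence[float], actuals: Sequence[int]) -> float:
    """AUROC via mean rank of the positives; ties contribute one half.

    Returns NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    actuals = np.asarray(actuals, dtype=int)
    n_pos = int(actuals.sum())
    n_neg = len(actuals) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[actuals == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pool_and_evaluate(records: Sequence[PredictionRecord],
                      method: str = "") -> EvaluationReport:
    """Confusion counts and rates pooled over all prediction records."""
    if not records:
        raise ValidationError("no prediction records to evaluate")
    pred = np.array([r.predicted for r in records])
    act = np.array([r.actual for r in records])
    scores = np.array([r.score for r in records])
    tp = int(((pred == 1) & (act == 1)).sum())
    fp = int(((pred == 1) & (act == 0)).sum())
    tn = int(((pred == 0) & (act == 0)).sum())
    fn = int(((pred == 0) & (act == 1)).sum())
    tp_rate = tp / (tp + fn) if (tp + fn) else float("nan")
    fp_rate = fp / (fp + tn) if (fp + tn) else float("nan")
    return EvaluationReport(
        method=method, tp_rate=tp_rate, fp_rate=fp_rate,
        auroc=auroc_score(scores, act),
        tp=tp, fp=fp, tn=tn, fn=fn, n_records=len(records))


def per_target_reports(records: Sequence[PredictionRecord],
                       method: str = "") -> pd.DataFrame:
    """Macro diagnostics: one evaluation row per prediction target."""
    rows = []
    by_target: dict[str, list[PredictionRecord]] = {}
    for r in records:
        by_target.setdefault(r.target_id, []).append(r)
    for tid in sorted(by_target):
        rep = pool_and_evaluate(by_target[tid], method)
        rows.append({"target_id": tid, "tp_rate": rep.tp_rate,
                     "fp_rate": rep.fp_rate, "auroc": rep.auroc,
                     "n_records": rep.n_records})
    return pd.DataFrame(rows)


def compare_methods(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Side-by-side TP rate / FP rate / AUROC table, one row per method."""
    if len(reports) < 2:
        raise ValidationError("need at least two reports to compare")
    return pd.DataFrame([{
        "method": r.method, "tp_rate": r.tp_rate, "fp_rate": r.fp_rate,
        "auroc": r.auroc, "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
        "n_records": r.n_records,
    } for r in reports])
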