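"""Teleworking rates, level assignment, and neighborhood-cluster extraction.

A participant's teleworking rate is the number of days worked from home
divided by the number of days worked over the study.  Each prediction target
gets a neighborhood cluster: the 20 participants whose teleworking rates are
nearest the target's.  Ties at the cluster boundary are broken by seeded
uniform sampling, so cluster membership is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedRateError, ValidationError
from .ingest import WorkShiftRecord

logger = logging.getLogger(__name__)

LEVELS = ("low", "middle", "high")


@dataclass(frozen=True)
class TeleworkProfile:
    participant_id: str
    days_wfh: int
    days_worked: int
    rate: float


@dataclass
class NeighborhoodCluster:
    target_id: str
    member_ids: list[str]
    distances: dict[str, float] = field(default_factory=dict)
    sampling_seed: Optional[int] = None


def compute_teleworking_rate(
    shifts: Sequence[WorkShiftRecord],
    participant_id: Optional[str] = None,
    max_week: Optional[int] = None,
    start_date=None,
) -> TeleworkProfile:
    """Rate = WFH days / worked days (absences excluded from both).

    ``max_week`` (with ``start_date``) restricts the computation to the first
    k study weeks, for rate definitions that must not look past the training
    period.
    """
    rows = list(shifts)
    if max_week is not None:
        if start_date is None:
            raise ValidationError("max_week requires start_date")
        rows = [r for r in rows
                if (r.date - start_date).days // 7 + 1 <= max_week]
    if participant_id is None:
        participant_id = rows[0].participant_id if rows else ""
    worked = [r for r in rows if not r.absent]
    if not worked:
        raise UndefinedRateError(
            f"participant {participant_id!r} has no worked days; "
            "teleworking rate undefined")
    wfh = sum(1 for r in worked if r.wfh)
    return TeleworkProfile(participant_id, wfh, len(worked), wfh / len(worked))


def assign_level(rate: float) -> str:
    """Teleworking level: low (< 0.2), middle (0.2 to < 0.6), high (>= 0.6)."""
    if not 0 <= rate <= 1:
        raise ValidationError(f"teleworking rate {rate} outside [0, 1]")
    if rate < 0.2:
        return "low"
    if rate < 0.6:
        return "middle"
    return "high"


def extract_neighborhood(
    target: TeleworkProfile,
    pool: Sequence[TeleworkProfile],
    n: int = 20,
    seed: Optional[int] = None,
) -> NeighborhoodCluster:
    """Select the ``n`` pool members with teleworking rates nearest the target.

    When more candidates than needed sit exactly at the boundary distance,
    the remaining slots are filled by uniform sampling without replacement
    driven by ``seed``.  A pool smaller than ``n`` is taken whole (warning
    logged).  The target itself is excluded if present in the pool.
    """
    candidates = [p for p in pool if p.participant_id != target.participant_id]
    if not candidates:
        raise ValidationError(f"empty pool for target {target.participant_id!r}")
    dist = {p.participant_id: abs(p.rate - target.rate) for p in candidates}
    if len(candidates) <= n:
        if len(candidates) < n:
            logger.warning("pool of %d smaller than cluster size %d for %s",
                           len(candidates), n, target.participant_id)
        members = sorted(dist, key=lambda pid: (dist[pid], pid))
        return NeighborhoodCluster(target.participant_id, members,
                                   {m: dist[m] for m in members}, seed)

    ordered = sorted(candidates, key=lambda p: (dist[p.participant_id],
                                                p.participant_id))
    boundary = dist[ordered[n - 1].participant_id]
    inner = [p.participant_id for p in ordered if dist[p.participant_id] < boundary]
    tied = sorted(p.participant_id for p in ordered
                  if dist[p.participant_id] == boundary)
    need = n - len(inner)
    if len(tied) > need:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(tied, size=need, replace=False).tolist())
    else:
        chosen = tied
    members = inner + chosen
    return NeighborhoodCluster(target.participant_id, members,
                               {m: dist[m] for m in members}, seed)
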