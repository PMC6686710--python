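"""Welfare alerting: heat (oestrus), cluster-migration / dormant-drop
anomalies, calving alerts, and connectivity-aware routing.

Heat is flagged from a sudden step spike over the cow's own rolling
baseline combined with reduced lying; since the fertile window lasts only
~18 h of the 21-day cycle, the alert fires on the first qualifying day.
A sudden migration from active/normal to dormant (or a further activity
drop while dormant) flags possible illness or lameness; a slow drift
between clusters is normal and is suppressed.  A pregnant cow nearing
term that shows markedly increased lying time raises a calving alert.
Alerts route to SMS when the cloud link is up, otherwise to an on-farm
audio-visual channel.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .profiling import ClusterAssignment

__all__ = [
    "ReproRecord",
    "Alert",
    "HeatParams",
    "AnomalyParams",
    "CalvingParams",
    "detect_heat",
    "detect_activity_anomalies",
    "detect_calving",
    "route_alert",
]

logger = logging.getLogger(__name__)

_CLUSTER_RANK = {"dormant": 0, "normal": 1, "active": 2}


@dataclass(frozen=True)
class ReproRecord:
    cow_id: str
    insemination_date: Optional[dt.date]
    pregnant: bool

    def __post_init__(self) -> None:
        if self.pregnant and self.insemination_date is None:
            raise ValueError(f"{self.cow_id}: pregnant without insemination_date")


@dataclass
class Alert:
    kind: str                 # heat | migration_anomaly | dormant_drop | calving
    cow_id: str
    timestamp: dt.date
    evidence: dict[str, float] = field(default_factory=dict)
    channel: Optional[str] = None   # sms | local_audiovisual, set by routing

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("alert evidence must be non-empty")


@dataclass(frozen=True)
class HeatParams:
    spike_ratio_threshold: float = 1.8   # x rolling median steps
    baseline_window: int = 7             # days of history for the rolling median
    debounce_days: int = 2               # qualifying days this close collapse


@dataclass(frozen=True)
class AnomalyParams:
    sudden_windows: int = 2      # label drop to dormant within <= m windows
    gradual_windows: int = 3     # drifts spread over > g windows are benign
    drop_fraction: float = 0.6   # dormant-drop: steps below this x previous window


@dataclass(frozen=True)
class CalvingParams:
    gestation_days: int = 283
    window_days: int = 10        # calving window: due date +/- this
    lying_delta: float = 2.0     # hours above rolling baseline
    baseline_window: int = 7


def detect_heat(series: pd.DataFrame, params: HeatParams = HeatParams()) -> list[Alert]:
    """Scan per-cow activity for oestrus step spikes.

    A day qualifies when steps exceed ``spike_ratio_threshold`` times the
    median of the previous ``baseline_window`` days AND lying is below its
    own rolling median.  Cows with insufficient history are skipped with a
    logged notice; qualifying days within ``debounce_days`` of a previous
    alert collapse into it.
    """
    alerts: list[Alert] = []
    for cow_id, grp in series.groupby("cow_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        if len(grp) <= params.baseline_window:
            logger.info("detect_heat: %s skipped (%d days of history, need >%d)",
                        cow_id, len(grp), params.baseline_window)
            continue
        med_steps = grp["steps"].rolling(params.baseline_window).median().shift(1)
        med_lying = grp["lying_hours"].rolling(params.baseline_window).median().shift(1)
        qualifies = ((grp["steps"] > params.spike_ratio_threshold * med_steps)
                     & (grp["lying_hours"] < med_lying))
        last_alert: Optional[dt.date] = None
        for i in np.flatnonzero(qualifies.to_numpy()):
            day = pd.Timestamp(grp.loc[i, "date"]).date()
            if last_alert is not None and \
                    (day - last_alert).days <= params.debounce_days:
                continue
            alerts.append(Alert(
                kind="heat", cow_id=str(cow_id), timestamp=day,
                evidence={
                    "spike_ratio": float(grp.loc[i, "steps"] / med_steps[i]),
                    "baseline_steps": float(med_steps[i]),
                    "lying_hours": float(grp.loc[i, "lying_hours"]),
                }))
            last_alert = day
    return alerts


def _window_mean_steps(series: pd.DataFrame,
                       window: tuple[dt.date, dt.date]) -> float:
    dates = pd.to_datetime(series["date"]).dt.date
    sub = series[(dates >= window[0]) & (dates <= window[1])]
    return float(sub["steps"].mean()) if len(sub) else float("nan")


def detect_activity_anomalies(
    history: Mapping[str, Sequence[ClusterAssignment]],
    series: pd.DataFrame,
    params: AnomalyParams = AnomalyParams(),
) -> list[Alert]:
    """Flag sudden cluster migrations and activity drops within dormancy.

    ``migration_anomaly``: a cow enters the dormant cluster within
    ``sudden_windows`` of last holding its recent peak label (active or
    normal); declines spread over more than ``gradual_windows`` windows
    are treated as benign drift and suppressed.

    ``dormant_drop``: a cow dormant across consecutive windows whose
    window-mean steps fall below ``drop_fraction`` of its own previous
    window.
    """
    alerts: list[Alert] = []
    for cow_id, seq in history.items():
        if len(seq) < 2:
            continue
        labels = [a.label for a in seq]
        ranks = [_CLUSTER_RANK[l] for l in labels]
        cow_series = series[series["cow_id"] == cow_id]
        for t in range(1, len(seq)):
            if labels[t] == "dormant" and labels[t - 1] != "dormant":
                # start of the non-increasing decline run ending at t
                j = t
                while j > 0 and ranks[j - 1] >= ranks[j]:
                    j -= 1
                # last window still holding the run's peak label
                peak = max(ranks[j:t])
                p = max(i for i in range(j, t) if ranks[i] == peak)
                # transition spans (span + 1) windows from peak to dormant
                span = t - p
                if span <= params.sudden_windows and \
                        (span + 1) <= params.gradual_windows:
                    alerts.append(Alert(
                        kind="migration_anomaly", cow_id=cow_id,
                        timestamp=seq[t].window[0],
                        evidence={"windows_in_transition": float(span),
                                  "from_rank": float(peak)}))
            if labels[t] == "dormant" and labels[t - 1] == "dormant":
                prev = _window_mean_steps(cow_series, seq[t - 1].window)
                curr = _window_mean_steps(cow_series, seq[t].window)
                if np.isfinite(prev) and np.isfinite(curr) and prev > 0 \
                        and curr < params.drop_fraction * prev:
                    alerts.append(Alert(
                        kind="dormant_drop", cow_id=cow_id,
                        timestamp=seq[t].window[0],
                        evidence={"prev_mean_steps": prev,
                                  "curr_mean_steps": curr,
                                  "drop_ratio": curr / prev}))
    alerts.sort(key=lambda a: (a.timestamp, a.cow_id, a.kind))
    return alerts


def detect_calving(
    series: pd.DataFrame,
    repro: ReproRecord,
    params: CalvingParams = CalvingParams(),
) -> list[Alert]:
    """Calving alert for a pregnant cow: raised lying time near the due date.

    Fires (at most once per pregnancy) on the first day inside
    insemination + gestation ± ``window_days`` on which lying exceeds the
    cow's rolling-median baseline by ``lying_delta`` hours.
    """
    if not repro.pregnant:
        return []
    due = repro.insemination_date + dt.timedelta(days=params.gestation_days)
    lo = due - dt.timedelta(days=params.window_days)
    hi = due + dt.timedelta(days=params.window_days)
    grp = series[series["cow_id"] == repro.cow_id].sort_values("date")
    grp = grp.reset_index(drop=True)
    base = grp["lying_hours"].rolling(params.baseline_window).median().shift(1)
    for i in range(len(grp)):
        day = pd.Timestamp(grp.loc[i, "date"]).date()
        if not lo <= day <= hi or not np.isfinite(base[i]):
            continue
        if grp.loc[i, "lying_hours"] > base[i] + params.lying_delta:
            return [Alert(
                kind="calving", cow_id=repro.cow_id, timestamp=day,
                evidence={"lying_hours": float(grp.loc[i, "lying_hours"]),
                          "baseline_lying": float(base[i]),
                          "days_to_due": float((due - day).days)})]
    return []


def route_alert(alert: Alert, cloud_connected: bool) -> Alert:
    """Attach the delivery channel: SMS when connected, on-farm otherwise."""
    if alert.channel is not None:
        raise ValueError(
            f"alert for {alert.cow_id} already routed to {alert.channel}")
    return replace(alert, channel="sms" if cloud_connected else "local_audiovisual")
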