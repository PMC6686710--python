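"""Gateway-side telemetry: aggregation, store-and-forward, volume accounting.

Models the on-farm gateway that receives 6-minute pedometer messages,
aggregates them to daily activity, buffers through connectivity outages
(sensors retain up to 12 h; the gateway disk buffer is unbounded within a
run, so cloud outages delay but never lose data), and accounts for the
raw-vs-aggregated data-volume reduction of doing analytics at the edge.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .synthetic_herd import MESSAGES_PER_DAY

__all__ = [
    "OutageSchedule",
    "DeliveryLog",
    "VolumeReport",
    "aggregate_messages",
    "run_store_and_forward",
    "compute_volume_report",
]

KIB = 1024
MIB = 1024 ** 2


class OutageSchedule(BaseModel):
    """Connectivity outages as half-open [start, end) intervals."""

    cloud_outages: list[tuple[dt.datetime, dt.datetime]] = Field(default_factory=list)
    gateway_outages: list[tuple[dt.datetime, dt.datetime]] = Field(default_factory=list)
    sensor_retention_hours: float = 12.0

    @model_validator(mode="after")
    def _check(self) -> "OutageSchedule":
        for name in ("cloud_outages", "gateway_outages"):
            for start, end in getattr(self, name):
                if end < start:
                    raise ValueError(f"{name}: interval [{start}, {end}) is negative")
        if self.sensor_retention_hours < 0:
            raise ValueError("sensor_retention_hours must be >= 0")
        return self


@dataclass
class DeliveryLog:
    """Outcome of a store-and-forward run.

    ``delivered`` and ``lost`` partition the generated message keys
    (sensor_id, timestamp); ``delivered`` additionally records the time the
    message reached the cloud.
    """

    delivered: pd.DataFrame          # sensor_id, timestamp, delivered_at
    lost: pd.DataFrame               # sensor_id, timestamp
    duplicates_suppressed: int = 0
    resume_points: dict[str, pd.Timestamp] = field(default_factory=dict)

    def delivered_keys(self) -> set[tuple[str, pd.Timestamp]]:
        return set(zip(self.delivered["sensor_id"], self.delivered["timestamp"]))

    def lost_keys(self) -> set[tuple[str, pd.Timestamp]]:
        return set(zip(self.lost["sensor_id"], self.lost["timestamp"]))


@dataclass(frozen=True)
class VolumeReport:
    """Raw-vs-forwarded byte accounting for one period (1 MB = 1024^2 B)."""

    bytes_in: int
    bytes_out: int
    reduction_pct: float

    @property
    def mb_in(self) -> float:
        return round(self.bytes_in / MIB, 2)

    @property
    def mb_out(self) -> float:
        return round(self.bytes_out / MIB, 2)

    @property
    def reduction_whole_pct(self) -> int:
        return int(np.floor(self.reduction_pct + 0.5))

    def render(self) -> str:
        return (f"{self.mb_in:.2f} MB in -> {self.mb_out:.2f} MB out "
                f"({self.reduction_whole_pct}% reduction)")


def aggregate_messages(messages: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct daily activity from a 6-minute message stream.

    Exact inverse of ``emit_sensor_stream`` on lossless streams.  Duplicate
    (sensor_id, timestamp) keys are collapsed before summing; cow-days with
    fewer than 240 distinct messages are flagged ``partial``.
    """
    msgs = messages.drop_duplicates(subset=["sensor_id", "timestamp"])
    ts = pd.to_datetime(msgs["timestamp"])
    grouped = msgs.assign(date=ts.dt.date).groupby(
        ["sensor_id", "date"], sort=True)
    out = grouped.agg(
        steps=("step_increment", "sum"),
        lying_minutes=("lying_minutes", "sum"),
        swap_total=("swap_count", "sum"),
        n_messages=("step_increment", "size"),
    ).reset_index()
    out["lying_hours"] = (out["lying_minutes"] / 60.0).round(6)
    out["swaps_per_hour"] = out["swap_total"] / 24.0
    out["partial"] = out["n_messages"] < MESSAGES_PER_DAY
    out = out.rename(columns={"sensor_id": "cow_id"})
    return out[["cow_id", "date", "steps", "lying_hours",
                "swaps_per_hour", "partial"]]


def _interval_end_at(times: np.ndarray,
                     intervals: list[tuple[dt.datetime, dt.datetime]]) -> np.ndarray:
    """For each time, the end of the outage interval containing it, or NaT."""
    out = np.full(times.shape, np.datetime64("NaT"), dtype="datetime64[ns]")
    for start, end in intervals:
        s = np.datetime64(pd.Timestamp(start))
        e = np.datetime64(pd.Timestamp(end))
        mask = (times >= s) & (times < e)
        # overlapping intervals: keep the latest recovery time
        out[mask] = np.maximum(
            np.where(np.isnat(out[mask]), e, out[mask]).astype("datetime64[ns]"), e)
    return out


def run_store_and_forward(
    messages: pd.DataFrame,
    schedule: OutageSchedule,
    resume_points: Optional[Mapping[str, pd.Timestamp]] = None,
) -> DeliveryLog:
    """Deliver a message stream to the cloud under an outage schedule.

    Semantics: a message generated during a gateway outage is held on the
    sensor, which retains at most ``sensor_retention_hours`` of data — at
    gateway recovery, older messages are lost, the rest arrive.  Messages
    arriving during a cloud outage sit in the gateway's disk buffer and are
    delivered when the cloud returns; cloud outages never lose data.
    Delivery is at-least-once with (sensor_id, timestamp) deduplication and
    resumes past ``resume_points`` (last delivered timestamp per sensor).
    """
    dups = int(messages.duplicated(subset=["sensor_id", "timestamp"]).sum())
    msgs = messages.drop_duplicates(subset=["sensor_id", "timestamp"]).copy()
    msgs["timestamp"] = pd.to_datetime(msgs["timestamp"])

    if resume_points:
        already = np.zeros(len(msgs), dtype=bool)
        for sensor, upto in resume_points.items():
            already |= ((msgs["sensor_id"] == sensor).to_numpy()
                        & (msgs["timestamp"] <= pd.Timestamp(upto)).to_numpy())
        dups += int(already.sum())
        msgs = msgs[~already]

    times = msgs["timestamp"].to_numpy("datetime64[ns]")
    gw_recovery = _interval_end_at(times, schedule.gateway_outages)
    in_gw_outage = ~np.isnat(gw_recovery)
    retention = np.timedelta64(
        int(schedule.sensor_retention_hours * 3600), "s")
    lost_mask = in_gw_outage & ((gw_recovery - times) > retention)

    arrival = np.where(in_gw_outage, gw_recovery, times).astype("datetime64[ns]")
    cloud_recovery = _interval_end_at(arrival, schedule.cloud_outages)
    delivered_at = np.where(
        np.isnat(cloud_recovery), arrival, cloud_recovery).astype("datetime64[ns]")

    delivered = msgs.loc[~lost_mask, ["sensor_id", "timestamp"]].copy()
    delivered["delivered_at"] = delivered_at[~lost_mask]
    lost = msgs.loc[lost_mask, ["sensor_id", "timestamp"]].copy()

    resume = (delivered.groupby("sensor_id")["timestamp"].max().to_dict()
              if len(delivered) else {})
    return DeliveryLog(
        delivered=delivered.reset_index(drop=True),
        lost=lost.reset_index(drop=True),
        duplicates_suppressed=dups,
        resume_points=resume,
    )


def compute_volume_report(bytes_in: int, bytes_out: int) -> VolumeReport:
    """Reduction achieved by forwarding aggregates instead of raw telemetry."""
    if bytes_in <= 0:
        raise ValueError("bytes_in must be > 0 (reduction ratio undefined)")
    reduction = (bytes_in - bytes_out) / bytes_in * 100.0
    return VolumeReport(bytes_in=int(bytes_in), bytes_out=int(bytes_out),
                        reduction_pct=reduction)
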