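"""Synthetic dairy-herd activity simulator.

Generates a herd with a known latent behavioral structure (active / normal /
dormant clusters crossed with an age distribution), simulates daily activity
(step count, lying hours, lying<->standing swaps per hour) with planted
welfare events — oestrus (heat) spikes on a 21-day cycle, lameness-onset
ramps, and pre-calving lying increases — and decomposes daily activity into
the 6-minute sensor telemetry a pedometer gateway would receive.

Every downstream analytics stage (deviation profiling, clustering, alerting,
classification) is testable against this module's ground truth without any
external data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "CLUSTERS",
    "ACTIVITIES",
    "DEFAULT_AGE_COUNTS",
    "DEFAULT_CLUSTER_COUNTS",
    "ConfigurationError",
    "HerdConfig",
    "CowState",
    "ActivityDay",
    "EventTruth",
    "generate_herd",
    "simulate_activity",
    "emit_sensor_stream",
    "MESSAGES_PER_DAY",
]

CLUSTERS = ("active", "normal", "dormant")
ACTIVITIES = ("steps", "lying_hours", "swaps_per_hour")

#: 24 h of telemetry at one message per 6 minutes.
MESSAGES_PER_DAY = 240

# Age distribution of the monitored herd: 147 cows, young = 2-5 y (111),
# old = 6-12 y (36).
DEFAULT_AGE_COUNTS: dict[int, int] = {
    2: 29, 3: 31, 4: 29, 5: 22, 6: 9, 7: 7, 8: 7, 9: 5, 10: 7, 12: 1,
}

# Latent behavioral cluster per age row; marginals: 54 active, 83 normal,
# 10 dormant.
DEFAULT_CLUSTER_COUNTS: dict[int, dict[str, int]] = {
    2: {"active": 12, "normal": 17, "dormant": 0},
    3: {"active": 9, "normal": 22, "dormant": 0},
    4: {"active": 14, "normal": 14, "dormant": 1},
    5: {"active": 9, "normal": 13, "dormant": 0},
    6: {"active": 7, "normal": 2, "dormant": 0},
    7: {"active": 2, "normal": 4, "dormant": 1},
    8: {"active": 0, "normal": 4, "dormant": 3},
    9: {"active": 1, "normal": 1, "dormant": 3},
    10: {"active": 0, "normal": 6, "dormant": 1},
    12: {"active": 0, "normal": 0, "dormant": 1},
}

# Cluster offsets are balanced against the default 54/83/10 mix
# (54*active_offset + 10*dormant_offset = 0 per activity) so the herd mean
# coincides with the normal-cluster baseline.  Active cows walk more and lie
# less; dormant cows walk far less and lie most of the day.  Swap offsets
# are exact multiples of the 1/24 swap quantum so daily-total quantization
# preserves the cancellation.
DEFAULT_CLUSTER_OFFSETS: dict[str, dict[str, float]] = {
    "steps": {"active": 500.0, "normal": 0.0, "dormant": -2700.0},
    "lying_hours": {"active": -1.0, "normal": 0.0, "dormant": 5.4},
    "swaps_per_hour": {"active": 5.0 / 24.0, "normal": 0.0, "dormant": -27.0 / 24.0},
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "steps": 150.0,
    "lying_hours": 0.3,
    "swaps_per_hour": 0.05,
}


class ConfigurationError(Exception):
    """A herd configuration violates its invariants.

    Not a ValueError subclass so it surfaces unwrapped from model
    validation instead of being folded into a generic validation error.
    """


class HerdConfig(BaseModel):
    """Parameters of the simulated herd and its activity model.

    Daily activity is additive Gaussian noise around a per-cluster offset
    from the herd baseline, modified by planted welfare events.
    """

    n_cows: int = 147
    age_counts: dict[int, int] = Field(
        default_factory=lambda: dict(DEFAULT_AGE_COUNTS))
    latent_cluster_counts: dict[int, dict[str, int]] = Field(
        default_factory=lambda: {a: dict(c) for a, c in DEFAULT_CLUSTER_COUNTS.items()})

    baseline_steps: float = 5000.0           # steps/day
    baseline_lying: float = 11.0             # h/day, in [0, 24]
    baseline_swaps: float = 1.5              # swaps/hour
    cluster_offsets: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {a: dict(c) for a, c in DEFAULT_CLUSTER_OFFSETS.items()})
    noise_sd: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD))

    oestrus_cycle_days: int = 21
    heat_window_hours: float = 18.0
    heat_spike_ratio: float = 2.0            # multiplicative step spike, > 1
    heat_lying_factor: float = 0.7           # lying multiplier on the heat day

    gestation_days: int = 283                # textbook bovine mean
    calving_lying_gain: float = 3.0          # h/day added in the 2 pre-calving days
    pregnant_fraction: float = 0.3

    lameness_ramp_days: int = 5
    lameness_step_drop: float = 0.5          # fractional step loss at full ramp
    lameness_lying_gain: float = 3.0         # h/day gained at full ramp
    lame_fraction: float = 0.05

    start_date: dt.date = dt.date(2017, 5, 1)
    payload_bytes: int = 299                 # 240 msgs/day * 299 B ~= 70 KB
    seed: int = 0

    @model_validator(mode="after")
    def _check_invariants(self) -> "HerdConfig":
        if sum(self.age_counts.values()) != self.n_cows:
            raise ConfigurationError(
                f"age_counts sum to {sum(self.age_counts.values())}, "
                f"expected n_cows={self.n_cows}")
        for age, count in self.age_counts.items():
            row = self.latent_cluster_counts.get(age)
            if row is None:
                raise ConfigurationError(
                    f"latent_cluster_counts missing age row {age}")
            row_sum = sum(row.get(c, 0) for c in CLUSTERS)
            if row_sum != count:
                raise ConfigurationError(
                    f"cluster counts for age {age} sum to {row_sum}, "
                    f"expected {count}")
        extra = set(self.latent_cluster_counts) - set(self.age_counts)
        if extra:
            raise ConfigurationError(
                f"latent_cluster_counts has ages not in age_counts: {sorted(extra)}")
        if not 0.0 <= self.baseline_lying <= 24.0:
            raise ConfigurationError("baseline_lying must lie in [0, 24]")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ConfigurationError("noise SDs must be >= 0")
        if self.heat_spike_ratio <= 1.0:
            raise ConfigurationError("heat_spike_ratio must be > 1")
        return self

    def baselines(self) -> dict[str, float]:
        return {
            "steps": self.baseline_steps,
            "lying_hours": self.baseline_lying,
            "swaps_per_hour": self.baseline_swaps,
        }


@dataclass
class CowState:
    """One cow's latent state: identity, age, cluster and event schedule."""

    cow_id: str
    age_years: int
    latent_cluster: str
    cycle_phase: int = 0                      # days since last heat, < cycle length
    insemination_date: Optional[dt.date] = None
    pregnant: bool = False
    lameness_onset: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.latent_cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster {self.latent_cluster!r}")
        if self.pregnant and self.insemination_date is None:
            raise ValueError(f"{self.cow_id}: pregnant without insemination_date")


@dataclass(frozen=True)
class ActivityDay:
    """One cow's activity summary for one calendar day."""

    cow_id: str
    date: dt.date
    steps: int
    lying_hours: float
    swaps_per_hour: float

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if not 0.0 <= self.lying_hours <= 24.0:
            raise ValueError("lying_hours must lie in [0, 24]")
        if self.swaps_per_hour < 0:
            raise ValueError("swaps_per_hour must be >= 0")


@dataclass(frozen=True)
class EventTruth:
    """Ground truth for a planted welfare event (for recovery testing)."""

    cow_id: str
    kind: str                                 # oestrus | lameness | calving
    onset: dt.date
    magnitude: float


def _derive_rng(seed: int, stream: str) -> np.random.Generator:
    # Stable per-stream generators so stages can be re-run in isolation.
    ss = np.random.SeedSequence([seed, int.from_bytes(stream.encode(), "little")])
    return np.random.default_rng(ss)


def generate_herd(config: HerdConfig) -> list[CowState]:
    """Build the cow roster with ages, latent clusters and event schedules.

    The roster reproduces the configured age x cluster cross-table exactly;
    cycle phases, pregnancies and lameness onsets are drawn reproducibly
    from ``config.seed``.
    """
    rng = _derive_rng(config.seed, "roster")
    roster: list[CowState] = []
    idx = 0
    for age in sorted(config.age_counts):
        row = config.latent_cluster_counts[age]
        for cluster in CLUSTERS:
            for _ in range(row.get(cluster, 0)):
                idx += 1
                roster.append(CowState(
                    cow_id=f"cow_{idx:03d}",
                    age_years=age,
                    latent_cluster=cluster,
                    cycle_phase=int(rng.integers(0, config.oestrus_cycle_days)),
                ))
    # Plant pregnancies: insemination timed so calving falls 10-80 days into
    # a simulation starting at start_date.
    n = len(roster)
    pregnant_ids = rng.choice(n, size=round(config.pregnant_fraction * n),
                              replace=False)
    for i in pregnant_ids:
        calving_offset = int(rng.integers(10, 81))
        cow = roster[i]
        cow.pregnant = True
        cow.insemination_date = (config.start_date
                                 + dt.timedelta(days=calving_offset
                                                - config.gestation_days))
    # Plant lameness onsets mid-simulation.
    lame_ids = rng.choice(n, size=round(config.lame_fraction * n), replace=False)
    for i in lame_ids:
        roster[i].lameness_onset = (config.start_date
                                    + dt.timedelta(days=int(rng.integers(15, 46))))
    return roster


def simulate_activity(
    roster: list[CowState],
    n_days: int,
    config: HerdConfig,
    events: bool = True,
) -> tuple[pd.DataFrame, list[EventTruth]]:
    """Simulate daily activity for every cow over ``n_days``.

    Activity = herd baseline + cluster offset + Gaussian daily noise, then
    event-modified: on a heat day steps are multiplied by
    ``heat_spike_ratio`` and lying reduced; after lameness onset steps ramp
    down and lying ramps up over ``lameness_ramp_days``; in the two days
    before calving lying rises.  ``events=False`` disables all planted
    events (degenerate generator).

    Returns the activity table (one row per cow-day) and the list of
    planted-event ground truths falling inside the simulated range.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = _derive_rng(config.seed, "activity")
    n = len(roster)
    base = config.baselines()
    dates = [config.start_date + dt.timedelta(days=d) for d in range(n_days)]

    values = {}
    for act in ACTIVITIES:
        offsets = np.array([config.cluster_offsets[act][c.latent_cluster]
                            for c in roster])
        noise = rng.normal(0.0, config.noise_sd[act], size=(n, n_days))
        values[act] = base[act] + offsets[:, None] + noise

    truths: list[EventTruth] = []
    if events:
        cycle = config.oestrus_cycle_days
        for i, cow in enumerate(roster):
            if not cow.pregnant:
                # heat recurs every cycle; cycle_phase = days since last heat
                first = (cycle - cow.cycle_phase) % cycle
                for d in range(first, n_days, cycle):
                    values["steps"][i, d] *= config.heat_spike_ratio
                    values["lying_hours"][i, d] *= config.heat_lying_factor
                    truths.append(EventTruth(cow.cow_id, "oestrus", dates[d],
                                             config.heat_spike_ratio))
            if cow.lameness_onset is not None:
                onset = (cow.lameness_onset - config.start_date).days
                if 0 <= onset < n_days:
                    truths.append(EventTruth(cow.cow_id, "lameness",
                                             dates[onset],
                                             config.lameness_step_drop))
                for d in range(max(onset, 0), n_days):
                    progress = min((d - onset + 1) / config.lameness_ramp_days, 1.0)
                    values["steps"][i, d] *= 1.0 - config.lameness_step_drop * progress
                    values["lying_hours"][i, d] += config.lameness_lying_gain * progress
            if cow.pregnant and cow.insemination_date is not None:
                calving = (cow.insemination_date - config.start_date).days \
                    + config.gestation_days
                if 0 <= calving < n_days:
                    truths.append(EventTruth(cow.cow_id, "calving",
                                             dates[calving],
                                             config.calving_lying_gain))
                for d in (calving - 2, calving - 1):
                    if 0 <= d < n_days:
                        values["lying_hours"][i, d] += config.calving_lying_gain

    # Quantize so the 6-minute stream decomposition is exactly invertible:
    # integer steps, lying to 4 decimals, swaps as integer daily totals / 24.
    steps = np.maximum(np.rint(values["steps"]), 0).astype(np.int64)
    lying = np.round(np.clip(values["lying_hours"], 0.0, 24.0), 4)
    swap_totals = np.maximum(np.rint(values["swaps_per_hour"] * 24.0), 0)
    swaps = swap_totals / 24.0

    table = pd.DataFrame({
        "cow_id": np.repeat([c.cow_id for c in roster], n_days),
        "date": np.tile(dates, n),
        "steps": steps.ravel(),
        "lying_hours": lying.ravel(),
        "swaps_per_hour": swaps.ravel(),
    })
    truths.sort(key=lambda t: (t.onset, t.cow_id, t.kind))
    return table, truths


class StreamError(ValueError):
    """An activity table cannot be decomposed into whole-day telemetry."""


def emit_sensor_stream(activity: pd.DataFrame, config: HerdConfig) -> pd.DataFrame:
    """Decompose daily activity into the 6-minute sensor message stream.

    Each cow-day becomes 240 messages on a fixed 6-minute UTC grid whose
    step increments sum exactly to the day's steps (largest-remainder
    apportionment; with equal per-bin quotas the remainder goes to the
    earliest bins), lying minutes sum to lying_hours*60, and swap counts
    sum to round(swaps_per_hour*24).  Per-sensor daily volume is
    240 * payload_bytes.
    """
    required = {"cow_id", "date", "steps", "lying_hours", "swaps_per_hour"}
    missing = required - set(activity.columns)
    if missing:
        raise StreamError(f"activity table missing columns {sorted(missing)}")
    bad = activity[["steps", "lying_hours", "swaps_per_hour"]].isna().any(axis=1)
    if "partial" in activity.columns:
        bad |= activity["partial"].astype(bool)
    if bad.any():
        row = activity[bad].iloc[0]
        raise StreamError(
            f"partial day for cow {row['cow_id']} on {row['date']}: "
            "only whole days can be emitted")

    n_rows = len(activity)
    m = MESSAGES_PER_DAY
    bins = np.tile(np.arange(m), n_rows)

    steps = activity["steps"].to_numpy(dtype=np.int64)
    step_base = np.repeat(steps // m, m)
    step_rem = np.repeat(steps % m, m)
    step_inc = step_base + (bins < step_rem)

    swap_totals = np.rint(activity["swaps_per_hour"].to_numpy() * 24.0).astype(np.int64)
    swap_base = np.repeat(swap_totals // m, m)
    swap_rem = np.repeat(swap_totals % m, m)
    swap_count = swap_base + (bins < swap_rem)

    lying_minutes = np.repeat(
        activity["lying_hours"].to_numpy() * 60.0 / m, m)

    day_start = pd.to_datetime(activity["date"]).to_numpy().repeat(m)
    timestamps = day_start + bins * np.timedelta64(6, "m")

    return pd.DataFrame({
        "sensor_id": np.repeat(activity["cow_id"].to_numpy(), m),
        "timestamp": timestamps,
        "step_increment": step_inc,
        "lying_minutes": lying_minutes,
        "swap_count": swap_count,
        "payload_bytes": np.full(n_rows * m, config.payload_bytes, dtype=np.int64),
    })
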