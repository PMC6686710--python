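"""Herd-mean deviation profiling and activity-based clustering.

The core statistic is the cow's absolute deviation from the herd mean,
CAD = |Hm - Ca|, computed per day for each of the three monitored
activities (step count, lying hours, swaps per hour).  A best-of-three
directional vote over window-mean deviations assigns each cow to one of
three behavioral clusters:

* active  — above the herd mean in steps and swaps, below in lying;
* normal  — near the herd mean on a majority of activities;
* dormant — the mirror of active (fewer steps, more lying).

"Near" means the window-mean signed deviation is within ``tau`` times a
robust per-activity herd dispersion (median absolute deviation of the
daily signed deviations).  The final label is the 2-of-3 majority of the
per-activity votes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_herd import ACTIVITIES, ActivityDay, CowState

__all__ = [
    "HerdBaseline",
    "DeviationProfile",
    "ClusterAssignment",
    "AgeClusterTable",
    "compute_herd_baseline",
    "compute_deviation",
    "compute_deviation_table",
    "compute_herd_dispersion",
    "assign_clusters",
    "assign_clusters_rolling",
    "cross_tabulate",
    "YOUNG_AGES",
    "OLD_AGES",
]

YOUNG_AGES = range(2, 6)   # young cows: 2-5 years
OLD_AGES = range(6, 13)    # old cows: 6-12 years

# per-activity direction of the "more active" side of the herd mean
HIGH_ACTIVITY_SIGN = {"steps": 1, "lying_hours": -1, "swaps_per_hour": 1}


@dataclass(frozen=True)
class HerdBaseline:
    """Per-day arithmetic herd means (Hm) over cows with records that day."""

    date: dt.date
    mean_steps: float
    mean_lying: float
    mean_swaps: float
    herd_size: int

    def mean(self, activity: str) -> float:
        return {"steps": self.mean_steps,
                "lying_hours": self.mean_lying,
                "swaps_per_hour": self.mean_swaps}[activity]


@dataclass(frozen=True)
class DeviationProfile:
    """One cow-day's absolute deviations from the herd mean with signs."""

    cow_id: str
    date: dt.date
    ad_steps: float
    ad_lying: float
    ad_swaps: float
    sign_steps: str
    sign_lying: str
    sign_swaps: str


@dataclass(frozen=True)
class ClusterAssignment:
    cow_id: str
    window: tuple[dt.date, dt.date]
    label: str
    votes: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class AgeClusterTable:
    """Cluster counts by age with per-cluster totals and herd percentages."""

    counts: pd.DataFrame                     # index age, columns clusters
    totals: dict[str, int]
    pct_of_herd: dict[tuple[str, str], int]  # (age_group, cluster) -> whole %
    herd_size: int


def _sign(delta: float) -> str:
    if delta > 0:
        return "above"
    if delta < 0:
        return "below"
    return "at"


def compute_herd_baseline(activity: pd.DataFrame, date: dt.date) -> HerdBaseline:
    """Arithmetic mean of each activity over cows with a record on ``date``."""
    day = activity[pd.to_datetime(activity["date"]).dt.date == pd.Timestamp(date).date()]
    if day.empty:
        raise ValueError(f"no activity records on {date}")
    return HerdBaseline(
        date=pd.Timestamp(date).date(),
        mean_steps=float(day["steps"].mean()),
        mean_lying=float(day["lying_hours"].mean()),
        mean_swaps=float(day["swaps_per_hour"].mean()),
        herd_size=int(len(day)),
    )


def compute_deviation(baseline: HerdBaseline, day: ActivityDay) -> DeviationProfile:
    """Per-activity absolute deviation |Hm - Ca| with the side of the mean."""
    if pd.Timestamp(day.date).date() != baseline.date:
        raise ValueError(
            f"baseline date {baseline.date} does not match activity date {day.date}")
    ca = {"steps": day.steps, "lying_hours": day.lying_hours,
          "swaps_per_hour": day.swaps_per_hour}
    ad = {a: abs(baseline.mean(a) - ca[a]) for a in ACTIVITIES}
    sg = {a: _sign(ca[a] - baseline.mean(a)) for a in ACTIVITIES}
    return DeviationProfile(
        cow_id=day.cow_id, date=baseline.date,
        ad_steps=ad["steps"], ad_lying=ad["lying_hours"], ad_swaps=ad["swaps_per_hour"],
        sign_steps=sg["steps"], sign_lying=sg["lying_hours"], sign_swaps=sg["swaps_per_hour"],
    )


def compute_deviation_table(activity: pd.DataFrame) -> pd.DataFrame:
    """Daily deviation profiles for a whole activity table.

    Adds signed deviations ``dev_<activity>`` = Ca - Hm (the quantity the
    cluster vote averages) alongside the absolute deviations and signs.
    """
    df = activity.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    out = {"cow_id": df["cow_id"], "date": df["date"]}
    short = {"steps": "steps", "lying_hours": "lying", "swaps_per_hour": "swaps"}
    for act, tag in short.items():
        hm = df.groupby("date")[act].transform("mean")
        dev = df[act] - hm
        out[f"dev_{tag}"] = dev
        out[f"ad_{tag}"] = dev.abs()
        out[f"sign_{tag}"] = np.select([dev > 0, dev < 0], ["above", "below"], "at")
    return pd.DataFrame(out)


def compute_herd_dispersion(profiles: pd.DataFrame) -> dict[str, float]:
    """Robust per-activity spread: MAD of the daily signed deviations."""
    disp = {}
    for act, tag in (("steps", "steps"), ("lying_hours", "lying"),
                     ("swaps_per_hour", "swaps")):
        d = profiles[f"dev_{tag}"].to_numpy(dtype=float)
        disp[act] = float(np.median(np.abs(d - np.median(d))))
    return disp


def _vote(mean_dev: float, threshold: float, activity: str) -> str:
    """Label one activity's window-mean deviation: high / near / low activity."""
    if abs(mean_dev) <= threshold:
        return "near"
    direction = 1 if mean_dev > 0 else -1
    return "high" if direction == HIGH_ACTIVITY_SIGN[activity] else "low"


def assign_clusters(
    profiles: pd.DataFrame,
    herd_dispersion: Mapping[str, float],
    window: tuple[dt.date, dt.date],
    tau: float = 1.0,
) -> list[ClusterAssignment]:
    """Best-of-three cluster assignment over a date window.

    Each activity casts one vote from the cow's window-mean signed
    deviation: "near" within ``tau * herd_dispersion``, otherwise
    high-activity or low-activity by direction (steps above, lying below,
    swaps above is the high-activity side).  Majority rule: >=2 high ->
    active, >=2 low -> dormant, otherwise normal.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    start, end = (pd.Timestamp(window[0]).date(), pd.Timestamp(window[1]).date())
    if end < start:
        raise ValueError(f"empty window [{start}, {end}]")
    dates = pd.to_datetime(profiles["date"]).dt.date
    sub = profiles[(dates >= start) & (dates <= end)]
    if sub.empty:
        raise ValueError(f"no profiles in window [{start}, {end}]")

    means = sub.groupby("cow_id")[["dev_steps", "dev_lying", "dev_swaps"]].mean()
    assignments = []
    tags = {"steps": "dev_steps", "lying_hours": "dev_lying",
            "swaps_per_hour": "dev_swaps"}
    for cow_id, row in means.iterrows():
        votes = {act: _vote(row[col], tau * herd_dispersion[act], act)
                 for act, col in tags.items()}
        counts = list(votes.values())
        if counts.count("high") >= 2:
            label = "active"
        elif counts.count("low") >= 2:
            label = "dormant"
        else:
            label = "normal"
        assignments.append(ClusterAssignment(
            cow_id=str(cow_id), window=(start, end), label=label, votes=votes))
    return assignments


def assign_clusters_rolling(
    profiles: pd.DataFrame,
    herd_dispersion: Mapping[str, float],
    window_days: int = 7,
    tau: float = 1.0,
) -> dict[str, list[ClusterAssignment]]:
    """Consecutive non-overlapping window assignments per cow, time-ordered."""
    dates = sorted(pd.to_datetime(profiles["date"]).dt.date.unique())
    per_cow: dict[str, list[ClusterAssignment]] = {}
    for i in range(0, len(dates) - window_days + 1, window_days):
        window = (dates[i], dates[i + window_days - 1])
        for a in assign_clusters(profiles, herd_dispersion, window, tau):
            per_cow.setdefault(a.cow_id, []).append(a)
    return per_cow


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def cross_tabulate(
    assignments: Sequence[ClusterAssignment],
    roster: Sequence[CowState],
) -> AgeClusterTable:
    """Age x cluster cross-table with herd percentages by age group.

    Age groups are young (2-5 y) and old (6-12 y); percentages are of the
    whole herd, rounded to the nearest whole percent.
    """
    ages = {c.cow_id: c.age_years for c in roster}
    unknown = [a.cow_id for a in assignments if a.cow_id not in ages]
    if unknown:
        raise KeyError(f"assigned cows not in roster: {sorted(set(unknown))}")

    clusters = ("active", "normal", "dormant")
    rows = sorted({ages[a.cow_id] for a in assignments})
    counts = pd.DataFrame(0, index=rows, columns=list(clusters))
    for a in assignments:
        counts.loc[ages[a.cow_id], a.label] += 1

    herd_size = int(counts.to_numpy().sum())
    totals = {c: int(counts[c].sum()) for c in clusters}
    pct = {}
    for group, age_range in (("young", YOUNG_AGES), ("old", OLD_AGES)):
        in_group = [a for a in rows if a in age_range]
        for c in clusters:
            n = int(counts.loc[in_group, c].sum()) if in_group else 0
            pct[(group, c)] = _round_half_up(100.0 * n / herd_size)
    return AgeClusterTable(counts=counts, totals=totals,
                           pct_of_herd=pct, herd_size=herd_size)
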