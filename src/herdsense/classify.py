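"""Binary anomaly classification of cow-days with a from-scratch K-NN.

Cow-days are labeled irregular (anomalous behavior, the positive class)
or regular, the irregular window being the pre-clinical stretch between a
planted lameness onset and the first visually observable signs.  Features
derive from the quantities the profiling layer already computes:
per-activity herd-mean deviations referenced to the cow's own rolling
baseline, short-term (3-day) trends, and the cow's current behavioral
cluster.  Classification is
K-nearest neighbors (k=4) on z-scored features with Euclidean distance;
evaluation reports the confusion matrix, accuracy / sensitivity /
specificity, and the mean lead time of the first correct positive ahead
of the visual-sign onset.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .profiling import compute_deviation_table, compute_herd_dispersion, \
    assign_clusters_rolling
from .synthetic_herd import EventTruth

__all__ = [
    "LabeledExample",
    "EvalReport",
    "build_examples",
    "subsample_negatives",
    "split_examples",
    "knn_predict",
    "evaluate",
    "POSITIVE",
    "NEGATIVE",
]

POSITIVE = "irregular"
NEGATIVE = "regular"

FEATURE_NAMES = (
    "rel_steps", "rel_lying", "rel_swaps",
    "slope_steps", "slope_lying", "slope_swaps",
    "cluster_code",
)

_CLUSTER_CODE = {"active": 1.0, "normal": 0.0, "dormant": -1.0}


@dataclass(frozen=True)
class LabeledExample:
    cow_id: str
    date: dt.date
    features: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {self.label!r}")
        if np.isnan(self.features).any():
            raise ValueError("features must not contain missing values")


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float       # percent
    sensitivity: float    # percent
    specificity: float    # percent
    lead_days: Optional[float] = None


def build_examples(
    activity: pd.DataFrame,
    profiles: Optional[pd.DataFrame],
    truth: Sequence[EventTruth],
    window: int = 7,
    sign_lag: int = 3,
) -> list[LabeledExample]:
    """One labeled example per cow-day with full feature history.

    A cow-day is irregular iff it falls within [onset, onset + sign_lag]
    of a planted lameness event (``sign_lag`` models the days until visual
    signs).  Days after a lame cow's visual-sign date are dropped: they
    are post-clinical, neither early-warning positives nor honest
    negatives.  The first ``window`` days per cow are dropped for lack of
    trend/cluster history.

    Features per cow-day: each activity's signed herd-mean deviation
    relative to the cow's own rolling-median baseline (so a stable
    dormant cow scores near zero while an onset-day lame cow does not),
    each activity's 3-day deviation trend, and the current behavioral
    cluster encoded active=+1 / normal=0 / dormant=-1.
    """
    if profiles is None:
        profiles = compute_deviation_table(activity)
    dispersion = compute_herd_dispersion(profiles)
    rolling = assign_clusters_rolling(profiles, dispersion, window_days=window)

    lame_windows: dict[str, tuple[dt.date, dt.date]] = {}
    for ev in truth:
        if ev.kind == "lameness":
            onset = pd.Timestamp(ev.onset).date()
            lame_windows[ev.cow_id] = (onset, onset + dt.timedelta(days=sign_lag))

    prof = profiles.copy()
    prof["date"] = pd.to_datetime(prof["date"]).dt.date
    act = activity[["cow_id", "date", "swaps_per_hour"]].copy()
    act["date"] = pd.to_datetime(act["date"]).dt.date
    prof = prof.merge(act, on=["cow_id", "date"])

    examples: list[LabeledExample] = []
    for cow_id, grp in prof.groupby("cow_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        assignments = rolling.get(str(cow_id), [])
        devs = {t: grp[f"dev_{t}"].to_numpy(dtype=float)
                for t in ("steps", "lying", "swaps")}
        for i in range(window, len(grp)):
            day = grp.loc[i, "date"]
            if cow_id in lame_windows:
                onset, visual = lame_windows[cow_id]
                if day > visual:
                    continue
                label = POSITIVE if onset <= day <= visual else NEGATIVE
            else:
                label = NEGATIVE
            # deviation relative to the cow's own rolling-median baseline
            rel = [devs[t][i] - np.median(devs[t][i - window:i])
                   for t in ("steps", "lying", "swaps")]
            # 3-day trend: mean daily change over the last 3 days
            slopes = [(devs[t][i] - devs[t][i - 2]) / 2.0
                      for t in ("steps", "lying", "swaps")]
            cluster = _CLUSTER_CODE["normal"]
            for a in assignments:
                if a.window[0] <= day <= a.window[1]:
                    cluster = _CLUSTER_CODE[a.label]
            features = np.array(rel + slopes + [cluster], dtype=float)
            examples.append(LabeledExample(str(cow_id), day, features, label))
    return examples


def subsample_negatives(
    examples: Sequence[LabeledExample],
    negative_ratio: float,
    seed: int,
) -> list[LabeledExample]:
    """Downsample negatives to ``negative_ratio`` per positive (reproducible).

    With no positives there is nothing to balance against; the examples
    are returned unchanged.
    """
    pos = [e for e in examples if e.label == POSITIVE]
    neg = [e for e in examples if e.label == NEGATIVE]
    if not pos:
        return list(examples)
    keep = min(len(neg), int(round(negative_ratio * len(pos))))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(neg), size=keep, replace=False)
    out = pos + [neg[i] for i in sorted(idx)]
    out.sort(key=lambda e: (e.cow_id, e.date))
    return out


def split_examples(
    examples: Sequence[LabeledExample],
    train_fraction: float = 0.8,
    seed: int = 0,
    group_by_cow: bool = True,
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Disjoint, exhaustive train/test partition, stratified by label.

    By default cows are kept whole (no cow contributes to both sets) to
    prevent leakage between adjacent days of the same animal; strata are
    cows with vs without irregular days.  ``group_by_cow=False`` splits
    individual cow-days instead.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = {e.label for e in examples}
    if labels != {POSITIVE, NEGATIVE}:
        raise ValueError(
            f"both label classes required for a stratified split, got {sorted(labels)}")
    rng = np.random.default_rng(seed)

    if group_by_cow:
        cows = sorted({e.cow_id for e in examples})
        has_pos = {c: any(e.label == POSITIVE for e in examples if e.cow_id == c)
                   for c in cows}
        test_cows: set[str] = set()
        for stratum in (True, False):
            members = [c for c in cows if has_pos[c] == stratum]
            rng.shuffle(members)
            n_test = max(1, round((1.0 - train_fraction) * len(members))) \
                if members else 0
            test_cows.update(members[:n_test])
        train = [e for e in examples if e.cow_id not in test_cows]
        test = [e for e in examples if e.cow_id in test_cows]
    else:
        train, test = [], []
        for stratum in (POSITIVE, NEGATIVE):
            idx = [i for i, e in enumerate(examples) if e.label == stratum]
            rng.shuffle(idx)
            n_train = round(train_fraction * len(idx))
            train += [examples[i] for i in idx[:n_train]]
            test += [examples[i] for i in idx[n_train:]]
        train.sort(key=lambda e: (e.cow_id, e.date))
        test.sort(key=lambda e: (e.cow_id, e.date))
    if not train or not test:
        raise ValueError("split produced an empty partition")
    return list(train), list(test)


def knn_predict(
    train: Sequence[LabeledExample],
    queries: Sequence[LabeledExample] | np.ndarray,
    k: int = 4,
    metric: str = "euclidean",
) -> list[str]:
    """Majority vote of the k nearest training examples.

    Features are z-scored with the training set's statistics.  Ties on
    distance break toward the earlier training index; tied votes break
    toward the positive (irregular) class, favoring recall on welfare
    events.
    """
    if not train:
        raise ValueError("empty training set")
    if k > len(train) or k < 1:
        raise ValueError(f"k={k} must lie in [1, {len(train)}]")
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")

    X = np.stack([e.features for e in train]).astype(float)
    y = np.array([e.label for e in train])
    if isinstance(queries, np.ndarray):
        Q = np.atleast_2d(queries).astype(float)
    else:
        Q = np.stack([e.features for e in queries]).astype(float)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    Qz = (Q - mu) / sd

    d2 = ((Qz[:, None, :] - Xz[None, :, :]) ** 2).sum(axis=2)
    # stable sort keeps earlier train indices first on exact distance ties
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    out = []
    for row in order:
        votes = y[row]
        n_pos = int((votes == POSITIVE).sum())
        out.append(POSITIVE if n_pos * 2 >= k else NEGATIVE)
    return out


def rf_predict(
    train: Sequence[LabeledExample],
    queries: Sequence[LabeledExample],
    n_estimators: int = 100,
    seed: int = 0,
) -> list[str]:
    """Optional random-forest comparison behind the same interface.

    Delegates to scikit-learn; the bespoke path of this package is
    ``knn_predict``.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = np.stack([e.features for e in train])
    y = [e.label for e in train]
    Q = np.stack([e.features for e in queries])
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X, y)
    return list(clf.predict(Q))


def evaluate(
    predictions: Sequence[str],
    truth_labels: Sequence[str],
    event_onsets: Optional[Sequence[EventTruth]] = None,
    keys: Optional[Sequence[tuple[str, dt.date]]] = None,
    sign_lag: int = 3,
) -> EvalReport:
    """Confusion matrix, rates (percent) and mean detection lead time.

    ``lead_days`` — the mean, over planted lameness events with at least
    one true positive, of (visual-sign onset − first true-positive date),
    where visual signs appear ``sign_lag`` days after onset — is computed
    when ``event_onsets`` and per-prediction ``keys`` are supplied.
    """
    if len(predictions) != len(truth_labels):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(truth_labels)} truth labels")
    pred = np.array(predictions)
    true = np.array(truth_labels)
    tp = int(((pred == POSITIVE) & (true == POSITIVE)).sum())
    fp = int(((pred == POSITIVE) & (true == NEGATIVE)).sum())
    tn = int(((pred == NEGATIVE) & (true == NEGATIVE)).sum())
    fn = int(((pred == NEGATIVE) & (true == POSITIVE)).sum())
    total = tp + fp + tn + fn

    lead = None
    if event_onsets is not None and keys is not None:
        if len(keys) != len(predictions):
            raise ValueError("keys must align with predictions")
        leads = []
        for ev in event_onsets:
            if ev.kind != "lameness":
                continue
            onset = pd.Timestamp(ev.onset).date()
            visual = onset + dt.timedelta(days=sign_lag)
            tp_days = [key[1] for key, p, t in zip(keys, pred, true)
                       if key[0] == ev.cow_id and p == POSITIVE and t == POSITIVE
                       and onset <= key[1] <= visual]
            if tp_days:
                leads.append((visual - min(tp_days)).days)
        if leads:
            lead = float(np.mean(leads))

    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=100.0 * (tp + tn) / total if total else float("nan"),
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        lead_days=lead,
    )
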