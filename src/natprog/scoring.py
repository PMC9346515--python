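"""Disease severity scoring (DSS) for weekly mouse phenotyping.

Two scoring versions are implemented:

* **original** — six unit-weight factors (body weight, hanging, kyphosis,
  walking, ptosis, breathing), total in [0, 6]. The hanging factor is
  categorical, anchored at the 50 s / 10 s time-to-event cutoffs:
  mean >= 50 s -> 0, 10-50 s -> 0.5, < 10 s -> 1.
* **optimized** — four factors, total in [0, 5]: body weight (0/0.5/1 for
  gain/stabilization/decline vs the prior week in the same mouse), hanging
  as a continuous score with weight 2 (``2 * (1 - t/60)``), and the
  unchanged ordinal kyphosis and walking scores. Ptosis and breathing are
  dropped: they appear only late and do not track early progression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortDataset, HANG_COLUMNS, HANG_MAX_SECONDS

__all__ = [
    "ScoringVersion",
    "ORIGINAL",
    "OPTIMIZED",
    "get_version",
    "hanging_subscore",
    "original_hanging_subscore",
    "bodyweight_subscore",
    "categorical_subscore",
    "compute_dss",
    "score_cohort",
    "ScoringError",
]

ORDINAL_SET = (0.0, 0.5, 1.0)


class ScoringError(ValueError):
    """Invalid input to a scoring operation."""


@dataclass(frozen=True)
class ScoringVersion:
    """A named scoring scheme: ordered factors with weights and a max total."""

    name: str
    factors: tuple[str, ...]
    weights: dict = field(default_factory=dict)
    max_total: float = 0.0
    stabilization_threshold: float | None = None  # g, optimized only


ORIGINAL = ScoringVersion(
    name="original",
    factors=("body_weight", "hanging", "kyphosis", "walking", "ptosis", "breathing"),
    weights={f: 1.0 for f in
             ("body_weight", "hanging", "kyphosis", "walking", "ptosis", "breathing")},
    max_total=6.0,
    stabilization_threshold=0.25,
)

OPTIMIZED = ScoringVersion(
    name="optimized",
    factors=("body_weight", "hanging", "kyphosis", "walking"),
    weights={"body_weight": 1.0, "hanging": 2.0, "kyphosis": 1.0, "walking": 1.0},
    max_total=5.0,
    stabilization_threshold=0.25,
)

_VERSIONS = {"original": ORIGINAL, "optimized": OPTIMIZED}


def get_version(version: str | ScoringVersion) -> ScoringVersion:
    if isinstance(version, ScoringVersion):
        return version
    try:
        return _VERSIONS[version]
    except KeyError:
        raise ScoringError(
            f"unknown scoring version {version!r}; expected one of {list(_VERSIONS)}"
        ) from None


def hanging_subscore(mean_hang_time: float) -> float:
    """Continuous hanging score in [0, 2]: 0 s -> 2, 60 s -> 0, linear between."""
    t = float(mean_hang_time)
    if not 0.0 <= t <= HANG_MAX_SECONDS:
        raise ScoringError(f"mean hang time {t} s outside [0, {HANG_MAX_SECONDS:g}]")
    return 2.0 * (1.0 - t / HANG_MAX_SECONDS)


def original_hanging_subscore(mean_hang_time: float) -> float:
    """Categorical hanging score: >= 50 s -> 0, 10-50 s -> 0.5, < 10 s -> 1."""
    t = float(mean_hang_time)
    if not 0.0 <= t <= HANG_MAX_SECONDS:
        raise ScoringError(f"mean hang time {t} s outside [0, {HANG_MAX_SECONDS:g}]")
    if t >= 50.0:
        return 0.0
    if t >= 10.0:
        return 0.5
    return 1.0


def bodyweight_subscore(
    current_w: float, previous_w: float | None, threshold: float = 0.25
) -> float:
    """Weight-trend score: gain -> 0, stabilization -> 0.5, decline -> 1.

    The delta is week-over-week within the same mouse; on the first observed
    week (no prior weight) the score is 0 (healthy-gain convention).
    """
    if current_w is None or not current_w > 0:
        raise ScoringError(f"non-positive body weight {current_w!r}")
    if previous_w is None or (isinstance(previous_w, float) and np.isnan(previous_w)):
        return 0.0
    if not previous_w > 0:
        raise ScoringError(f"non-positive body weight {previous_w!r}")
    delta = float(current_w) - float(previous_w)
    if delta > threshold:
        return 0.0
    if delta < -threshold:
        return 1.0
    return 0.5


def categorical_subscore(value: float) -> float:
    """Validated pass-through for the ordinal signs (kyphosis etc.)."""
    v = float(value)
    if v not in ORDINAL_SET:
        raise ScoringError(f"ordinal sub-score {value!r} not in {{0, 0.5, 1}}")
    return v


def compute_dss(
    observation: dict | pd.Series,
    prev_weight: float | None = None,
    version: str | ScoringVersion = "optimized",
) -> dict:
    """Score a single mouse-week.

    ``observation`` must carry ``body_weight``, the three hanging trials (or
    a precomputed ``mean_hang``), and the ordinal factor columns. Returns a
    dict with per-factor sub-scores and the total.
    """
    version = get_version(version)
    obs = dict(observation)
    if "mean_hang" in obs and obs["mean_hang"] is not None:
        mean_hang = float(obs["mean_hang"])
    else:
        mean_hang = float(np.mean([obs[c] for c in HANG_COLUMNS]))

    sub = {}
    sub["body_weight"] = bodyweight_subscore(
        obs["body_weight"], prev_weight, version.stabilization_threshold
    )
    if version.name == "optimized":
        sub["hanging"] = hanging_subscore(mean_hang)
    else:
        sub["hanging"] = original_hanging_subscore(mean_hang)
    for factor in version.factors:
        if factor in ("body_weight", "hanging"):
            continue
        sub[factor] = categorical_subscore(obs[factor])

    total = float(sum(sub.values()))
    record = {"version": version.name, "total": total, **sub}
    if "mouse_id" in obs:
        record["mouse_id"] = obs["mouse_id"]
    if "week" in obs:
        record["week"] = obs["week"]
    return record


def score_cohort(
    dataset: CohortDataset, version: str | ScoringVersion = "optimized"
) -> pd.DataFrame:
    """Score every mouse-week of a cohort.

    Returns a tidy frame with one row per mouse-week: ``mouse_id, week``,
    one column per factor sub-score, ``total`` and ``version``. Weight
    deltas are computed within mouse against the previous *observed* week;
    the result is invariant to the row order of the input table.
    """
    version = get_version(version)
    obs = dataset.observations.sort_values(["mouse_id", "week"], kind="mergesort")
    if obs.duplicated(subset=["mouse_id", "week"]).any():
        raise ScoringError("duplicated (mouse_id, week) rows in observations")

    mean_hang = obs[HANG_COLUMNS].mean(axis=1).to_numpy()
    weight = obs["body_weight"].to_numpy()
    prev_weight = obs.groupby("mouse_id")["body_weight"].shift(1).to_numpy()

    rows = []
    for i in range(len(obs)):
        rec = obs.iloc[i]
        sub = {"mouse_id": rec["mouse_id"], "week": int(rec["week"])}
        sub["body_weight"] = bodyweight_subscore(
            weight[i],
            None if np.isnan(prev_weight[i]) else float(prev_weight[i]),
            version.stabilization_threshold,
        )
        if version.name == "optimized":
            sub["hanging"] = hanging_subscore(mean_hang[i])
        else:
            sub["hanging"] = original_hanging_subscore(mean_hang[i])
        for factor in version.factors:
            if factor in ("body_weight", "hanging"):
                continue
            sub[factor] = categorical_subscore(rec[factor])
        sub["total"] = float(
            sum(sub[f] for f in version.factors)
        )
        sub["version"] = version.name
        rows.append(sub)
    out = pd.DataFrame(
        rows, columns=["mouse_id", "week", *version.factors, "total", "version"]
    )
    return out.reset_index(drop=True)
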