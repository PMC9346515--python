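"""Product-limit survival estimation and threshold time-to-event analysis.

The Kaplan-Meier estimator is built directly from the risk-set table (the
at-risk and event counts are part of the returned object), with Greenwood's
variance and, by default, confidence intervals on the complementary log-log
scale so the bounds stay in [0, 1]; plain (linear-scale) Greenwood intervals
are available behind a flag. The two-group comparison is the standard
log-rank test. The hanging test is converted to time-to-event data by the
first week the three-trial mean drops below a cutoff (50 s or 10 s in the
study), with death before crossing counted as an event under the default
composite rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .cohort import CohortDataset

__all__ = [
    "SurvivalCurve",
    "kaplan_meier",
    "median_survival",
    "hanging_threshold_events",
    "logrank_test",
    "SurvivalError",
]


class SurvivalError(ValueError):
    """Invalid input to a survival operation."""


@dataclass
class SurvivalCurve:
    """Step-function survival estimate with pointwise confidence limits."""

    event_times: np.ndarray  # distinct times with >= 1 event
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float = 0.95
    n_total: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.at_risk,
                "n_event": self.events,
                "S": self.survival,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
            }
        )

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function with S(t) = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(
    outcomes: pd.DataFrame,
    level: float = 0.95,
    ci_method: str = "cloglog",
) -> SurvivalCurve:
    """Product-limit estimate from a ``(time, event)`` outcome table.

    ``outcomes`` needs columns ``time`` (>= 0) and ``event`` (1 = observed
    death). Variance by Greenwood's formula; ``ci_method`` is ``"cloglog"``
    (default; bounds clamped to [0, 1] by construction) or ``"linear"``
    (plain Greenwood). With no events the curve is constant 1 with a
    degenerate CI.
    """
    if outcomes is None or len(outcomes) == 0:
        raise SurvivalError("empty outcome table")
    if ci_method not in ("cloglog", "linear"):
        raise SurvivalError(f"unknown ci_method {ci_method!r}")
    time = np.asarray(outcomes["time"], dtype=float)
    event = np.asarray(outcomes["event"], dtype=int)
    if np.any(time < 0):
        raise SurvivalError("negative survival times")

    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    n = len(time)

    event_times, at_risk, d_events = [], [], []
    for t in np.unique(time[event == 1]):
        event_times.append(t)
        at_risk.append(int(np.sum(time >= t)))
        d_events.append(int(np.sum((time == t) & (event == 1))))
    event_times = np.asarray(event_times, dtype=float)
    at_risk = np.asarray(at_risk, dtype=int)
    d_events = np.asarray(d_events, dtype=int)

    if event_times.size == 0:
        return SurvivalCurve(
            event_times=np.array([]),
            at_risk=np.array([], dtype=int),
            events=np.array([], dtype=int),
            survival=np.array([]),
            ci_lower=np.array([]),
            ci_upper=np.array([]),
            level=level,
            n_total=n,
        )

    frac = 1.0 - d_events / at_risk
    S = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood_terms = d_events / (at_risk * (at_risk - d_events))
    greenwood_terms = np.where(at_risk == d_events, np.inf, greenwood_terms)
    cum_terms = np.cumsum(greenwood_terms)
    z = stats.norm.ppf(0.5 + level / 2.0)

    lower = np.empty_like(S)
    upper = np.empty_like(S)
    for i, s in enumerate(S):
        if s <= 0.0 or not np.isfinite(cum_terms[i]):
            lower[i], upper[i] = 0.0, 0.0 if s <= 0 else 1.0
            continue
        if s >= 1.0:
            lower[i], upper[i] = 1.0, 1.0
            continue
        if ci_method == "cloglog":
            # CI on log(-log S): S^{exp(+- z * se_theta)}
            se_theta = math.sqrt(cum_terms[i]) / abs(math.log(s))
            lower[i] = s ** math.exp(z * se_theta)
            upper[i] = s ** math.exp(-z * se_theta)
        else:
            se = s * math.sqrt(cum_terms[i])
            lower[i] = max(0.0, s - z * se)
            upper[i] = min(1.0, s + z * se)

    return SurvivalCurve(
        event_times=event_times,
        at_risk=at_risk,
        events=d_events,
        survival=S,
        ci_lower=lower,
        ci_upper=upper,
        level=level,
        n_total=n,
    )


def median_survival(curve: SurvivalCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5, or ``None`` if never reached."""
    below = np.flatnonzero(curve.survival <= 0.5)
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


def hanging_threshold_events(
    dataset: CohortDataset,
    cutoff: float,
    death_rule: str = "composite",
) -> pd.DataFrame:
    """Time-to-event table for the hanging test at a cutoff (e.g. 50 or 10 s).

    Per mouse, the event time is the first week whose three-trial mean falls
    strictly below ``cutoff``. Under ``death_rule="composite"`` (default) a
    death before crossing is an event at the death time — a dead mouse
    cannot hang; under ``"censor"`` such mice are censored at death. Mice
    never crossing and alive at study end are censored at their last
    observation. Events sit on the integer week grid of the assessments.
    """
    if not 0.0 < cutoff <= 60.0:
        raise SurvivalError(f"cutoff {cutoff} s outside (0, 60]")
    if death_rule not in ("composite", "censor"):
        raise SurvivalError(f"unknown death_rule {death_rule!r}")
    mean_hang = dataset.mean_hang().sort_values(["mouse_id", "week"], kind="mergesort")
    surv = dataset.survival.set_index("mouse_id")
    rows = []
    for mid, grp in mean_hang.groupby("mouse_id", sort=False):
        crossed = grp.loc[grp["mean_hang"] < cutoff, "week"]
        death_time = float(surv.loc[mid, "time"])
        died = bool(surv.loc[mid, "event"])
        if len(crossed):
            rows.append(
                {"mouse_id": mid, "cutoff": cutoff,
                 "time": float(crossed.iloc[0]), "event": 1}
            )
        elif died:
            rows.append(
                {"mouse_id": mid, "cutoff": cutoff, "time": death_time,
                 "event": 1 if death_rule == "composite" else 0}
            )
        else:
            rows.append(
                {"mouse_id": mid, "cutoff": cutoff,
                 "time": float(grp["week"].iloc[-1]), "event": 0}
            )
    out = pd.DataFrame(rows).sort_values("mouse_id", kind="mergesort")
    return out.reset_index(drop=True)


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi-square statistic, p)."""
    for name, g in (("A", group_a), ("B", group_b)):
        if g is None or len(g) == 0:
            raise SurvivalError(f"group {name} is empty")
    if int(group_a["event"].sum()) + int(group_b["event"].sum()) == 0:
        raise SurvivalError("no events in either group; log-rank undefined")
    res = _ll_logrank(
        np.asarray(group_a["time"], dtype=float),
        np.asarray(group_b["time"], dtype=float),
        event_observed_A=np.asarray(group_a["event"], dtype=int),
        event_observed_B=np.asarray(group_b["event"], dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)
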