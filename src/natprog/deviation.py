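"""Judging therapeutic effect against the expected-progression band,
endpoint correlations, group comparisons and study-design power.

The band-deviation framework classifies every mouse-week of a cohort as
inside the reference prediction band, outside in the *beneficial*
direction (below the band for the severity score, above it for body
weight), or outside in the adverse direction. A treatment that pushes a
substantial fraction of post-treatment mouse-weeks beneficially outside
the untreated band is the study's criterion for "improvement outside the
expected disease progression".

Also here: Kruskal-Wallis group comparison, Spearman/Pearson correlation of
post-mortem endpoints with the severity score, the Jonckheere-Terpstra
ordered-alternative trend test for dose-response, and the one-way-ANOVA
sample-size calculation used for study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .jointmodel import ProgressionBand

__all__ = [
    "BandDeviationReport",
    "CorrelationResult",
    "DeviationError",
    "band_deviation",
    "group_comparison",
    "correlate",
    "dose_response_trend",
    "jonckheere_terpstra",
    "anova_sample_size",
    "terminal_scores",
]


class DeviationError(ValueError):
    """Invalid input to a deviation-analysis operation."""


@dataclass
class BandDeviationReport:
    """Per-week and overall classification of mouse-weeks against a band."""

    outcome: str
    direction: str  # beneficial side: "below" (dss) or "above" (weight)
    per_week: pd.DataFrame  # week, n, frac_inside, frac_beneficial, frac_adverse
    n_mouse_weeks: int
    overall_inside: float
    overall_beneficial: float
    overall_adverse: float

    @property
    def overall_outside(self) -> float:
        return self.overall_beneficial + self.overall_adverse


def _cohort_values(
    cohort: CohortDataset, band: ProgressionBand, scores: pd.DataFrame | None
) -> pd.DataFrame:
    if band.outcome == "log_weight":
        df = cohort.observations[["mouse_id", "week", "body_weight"]].rename(
            columns={"body_weight": "value"}
        )
    elif band.outcome == "dss":
        if scores is None:
            from .scoring import score_cohort

            scores = score_cohort(cohort, "optimized")
        df = scores[["mouse_id", "week", "total"]].rename(columns={"total": "value"})
    else:
        raise DeviationError(f"unsupported band outcome {band.outcome!r}")
    return df


def band_deviation(
    cohort: CohortDataset,
    band: ProgressionBand,
    scores: pd.DataFrame | None = None,
    direction: str | None = None,
) -> BandDeviationReport:
    """Classify each mouse-week of ``cohort`` against a reference band.

    ``direction`` is the beneficial side; by default "below" the band for
    the severity score and "above" it for body weight. Every week present
    in the cohort must lie on the band grid (extrapolate the band first if
    needed). Fractions are invariant to mouse relabeling and row order.
    """
    if direction is None:
        direction = "below" if band.outcome == "dss" else "above"
    if direction not in ("below", "above"):
        raise DeviationError(f"unknown direction {direction!r}")
    values = _cohort_values(cohort, band, scores)
    missing = set(values["week"].unique()) - set(np.asarray(band.weeks).tolist())
    if missing:
        raise DeviationError(
            f"cohort weeks {sorted(missing)} not covered by the band grid; "
            "extrapolate the band first"
        )
    band_df = band.to_frame().set_index("week")
    merged = values.join(band_df, on="week")
    below = merged["value"] < merged["lower"]
    above = merged["value"] > merged["upper"]
    if direction == "below":
        beneficial, adverse = below, above
    else:
        beneficial, adverse = above, below
    inside = ~(below | above)

    cls = pd.DataFrame(
        {
            "week": merged["week"],
            "inside": inside,
            "beneficial": beneficial,
            "adverse": adverse,
        }
    )
    per_week = (
        cls.groupby("week")
        .agg(
            n=("inside", "size"),
            frac_inside=("inside", "mean"),
            frac_beneficial=("beneficial", "mean"),
            frac_adverse=("adverse", "mean"),
        )
        .reset_index()
    )
    n = len(cls)
    return BandDeviationReport(
        outcome=band.outcome,
        direction=direction,
        per_week=per_week,
        n_mouse_weeks=n,
        overall_inside=float(inside.mean()),
        overall_beneficial=float(beneficial.mean()),
        overall_adverse=float(adverse.mean()),
    )


def group_comparison(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across >= 2 arms; chi-square p."""
    if len(groups) < 2:
        raise DeviationError("need at least 2 groups")
    arrays = []
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise DeviationError(f"group {name!r} is empty")
        arrays.append(values)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class CorrelationResult:
    method: str
    estimate: float
    p_value: float
    n: int


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Two-sided Spearman (rank) or Pearson correlation on complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DeviationError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DeviationError("zero variance in x or y: correlation undefined")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise DeviationError(f"unknown method {method!r}")
    return CorrelationResult(method=method, estimate=float(r), p_value=float(p),
                             n=len(x))


def jonckheere_terpstra(
    groups: list[np.ndarray], alternative: str = "increasing"
) -> tuple[float, float]:
    """Jonckheere-Terpstra ordered-alternative test (normal approximation).

    ``groups`` are ordered by dose. The statistic is the sum of pairwise
    Mann-Whitney counts over ordered group pairs (ties count 1/2); the
    p-value is one-sided in the stated direction, from the tie-corrected
    normal approximation of the permutation null.
    """
    if len(groups) < 3:
        raise DeviationError("need >= 3 ordered arms for a trend test")
    if alternative not in ("increasing", "decreasing"):
        raise DeviationError(f"unknown alternative {alternative!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise DeviationError("empty group")

    J = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i][:, None], groups[j][None, :]
            J += np.sum(b > a) + 0.5 * np.sum(b == a)

    n_g = np.array([g.size for g in groups], dtype=float)
    N = n_g.sum()
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)

    mean_J = (N**2 - np.sum(n_g**2)) / 4.0
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n_g * (n_g - 1) * (2 * n_g + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = (
        np.sum(n_g * (n_g - 1) * (n_g - 2))
        * np.sum(t * (t - 1) * (t - 2))
        / (36.0 * N * (N - 1) * (N - 2))
    )
    term3 = (
        np.sum(n_g * (n_g - 1)) * np.sum(t * (t - 1)) / (8.0 * N * (N - 1))
    )
    var_J = term1 + term2 + term3
    if var_J <= 0:  # all values identical
        return float(J), 0.5
    diff = J - mean_J
    if alternative == "decreasing":
        diff = -diff
    # continuity correction: shrink toward the null mean by 1/2
    diff = diff - 0.5 * np.sign(diff) if diff != 0 else 0.0
    p = float(stats.norm.sf(diff / math.sqrt(var_J)))
    return float(J), p


def dose_response_trend(
    arms: dict[str, np.ndarray], alternative: str = "increasing"
) -> tuple[float, float]:
    """Trend test across dose-ordered arms (insertion order = dose order)."""
    return jonckheere_terpstra(list(arms.values()), alternative=alternative)


def anova_sample_size(
    k: int, f: float, alpha: float = 0.05, power: float = 0.8,
    max_n: int = 10**6,
) -> int:
    """Smallest per-group n for a one-way ANOVA to reach the target power.

    Power is evaluated exactly from the noncentral F distribution with
    noncentrality ``n * k * f**2`` and degrees of freedom
    ``(k - 1, k (n - 1))`` (Cohen's effect size f).
    """
    if k < 2:
        raise DeviationError("need k >= 2 groups")
    if not (0 < alpha < 1 and 0 < power < 1 and f > 0):
        raise DeviationError("require 0 < alpha < 1, 0 < power < 1, f > 0")
    n = 2
    while n <= max_n:
        df1, df2 = k - 1, k * (n - 1)
        ncp = n * k * f**2
        crit = stats.f.isf(alpha, df1, df2)
        achieved = stats.ncf.sf(crit, df1, df2, ncp)
        if achieved >= power:
            return n
        n += 1
    raise DeviationError(f"power {power} unreachable with n <= {max_n}")


def terminal_scores(
    cohort: CohortDataset, scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Last severity score before death/sacrifice per mouse.

    This is the value the post-mortem endpoints are correlated against.
    """
    if scores is None:
        from .scoring import score_cohort

        scores = score_cohort(cohort, "optimized")
    last = (
        scores.sort_values(["mouse_id", "week"], kind="mergesort")
        .groupby("mouse_id")
        .tail(1)[["mouse_id", "week", "total"]]
        .rename(columns={"week": "last_week", "total": "terminal_dss"})
    )
    return last.reset_index(drop=True)
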