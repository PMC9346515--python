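import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from natprog.deviation import (
    DeviationError,
    anova_sample_size,
    band_deviation,
    correlate,
    dose_response_trend,
    group_comparison,
    jonckheere_terpstra,
)
from natprog.jointmodel import ProgressionBand


def _band(weeks, lower, median, upper, outcome="dss"):
    return ProgressionBand(
        outcome=outcome,
        weeks=np.asarray(weeks),
        median=np.asarray(median, dtype=float),
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        level=0.95,
        n_sim=0,
    )


def _dss_cohort(values):
    """Cohort whose optimized DSS is irrelevant; scores passed explicitly."""
    from natprog.cohort import CohortDataset

    rows = [
        {"mouse_id": m, "week": w, "total": v}
        for (m, w), v in values.items()
    ]
    scores = pd.DataFrame(rows)
    mice = sorted({m for m, _ in values})
    last = {m: max(w for mm, w in values if mm == m) for m in mice}
    cohort = CohortDataset(
        mice=pd.DataFrame(
            {"mouse_id": mice, "genotype": "mutant", "arm": "untreated",
             "treatment_start_week": np.nan}
        ),
        observations=pd.DataFrame(
            [
                {"mouse_id": m, "week": w, "body_weight": 10.0,
                 "hang1": 30.0, "hang2": 30.0, "hang3": 30.0,
                 "kyphosis": 0.0, "walking": 0.0, "ptosis": 0.0, "breathing": 0.0}
                for (m, w) in values
            ]
        ),
        survival=pd.DataFrame(
            [{"mouse_id": m, "time": float(last[m]), "event": 0} for m in mice]
        ),
    )
    return cohort, scores


class TestBandDeviation:
    def test_forced_beneficial_classification(self):
        """All-zero severity scores against a band whose lower limit
        exceeds 0 after week 5 must be beneficially outside there."""
        band = _band([4, 5, 6, 7], lower=[0, 0, 1, 2], median=[1, 2, 3, 4],
                     upper=[3, 4, 5, 5])
        values = {(m, w): 0.0 for m in ("m1", "m2") for w in (4, 5, 6, 7)}
        cohort, scores = _dss_cohort(values)
        report = band_deviation(cohort, band, scores=scores)
        per_week = report.per_week.set_index("week")
        assert per_week.loc[6, "frac_beneficial"] == 1.0
        assert per_week.loc[7, "frac_beneficial"] == 1.0
        assert per_week.loc[4, "frac_inside"] == 1.0

    def test_fractions_sum_to_one(self):
        band = _band([4, 5], lower=[1, 1], median=[2, 2], upper=[3, 3])
        values = {("m1", 4): 0.0, ("m1", 5): 2.0, ("m2", 4): 5.0, ("m2", 5): 1.0}
        cohort, scores = _dss_cohort(values)
        report = band_deviation(cohort, band, scores=scores)
        sums = report.per_week[
            ["frac_inside", "frac_beneficial", "frac_adverse"]
        ].sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert report.overall_inside + report.overall_outside == pytest.approx(1.0)

    def test_invariant_to_relabeling_and_row_order(self, rng):
        band = _band([4, 5, 6], lower=[1, 1, 2], median=[2, 2, 3],
                     upper=[3, 4, 4])
        values = {(f"m{i}", w): float(rng.uniform(0, 5))
                  for i in range(6) for w in (4, 5, 6)}
        cohort, scores = _dss_cohort(values)
        r1 = band_deviation(cohort, band, scores=scores)
        relabel = {f"m{i}": f"x{9 - i}" for i in range(6)}
        scores2 = scores.assign(mouse_id=scores["mouse_id"].map(relabel))
        scores2 = scores2.sample(frac=1.0, random_state=1).reset_index(drop=True)
        import copy

        cohort2 = copy.copy(cohort)
        cohort2.mice = cohort.mice.assign(
            mouse_id=cohort.mice["mouse_id"].map(relabel)
        )
        cohort2.observations = cohort.observations.assign(
            mouse_id=cohort.observations["mouse_id"].map(relabel)
        )
        cohort2.survival = cohort.survival.assign(
            mouse_id=cohort.survival["mouse_id"].map(relabel)
        )
        r2 = band_deviation(cohort2, band, scores=scores2)
        assert r1.overall_beneficial == pytest.approx(r2.overall_beneficial)
        pd.testing.assert_frame_equal(r1.per_week, r2.per_week)

    def test_uncovered_weeks_rejected(self):
        band = _band([4, 5], lower=[1, 1], median=[2, 2], upper=[3, 3])
        values = {("m1", 4): 1.0, ("m1", 7): 1.0}
        cohort, scores = _dss_cohort(values)
        with pytest.raises(DeviationError, match="extrapolate"):
            band_deviation(cohort, band, scores=scores)

    def test_weight_direction_is_above(self, small_mutant_cohort):
        band = _band(
            np.arange(3, 13),
            lower=np.full(10, 1e-3),
            median=np.full(10, 10.0),
            upper=np.full(10, 1e-2),  # absurdly low: everything is above
            outcome="log_weight",
        )
        report = band_deviation(small_mutant_cohort, band)
        assert report.direction == "above"
        assert report.overall_beneficial == 1.0


class TestGroupComparison:
    def test_identical_groups_null(self):
        g = np.array([1.0, 2.0, 3.0])
        h, p = group_comparison({"a": g, "b": g})
        assert p > 0.9

    def test_all_values_identical(self):
        h, p = group_comparison({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert h == 0.0 and p == 1.0

    def test_matches_hand_computation_with_ties(self):
        """3 groups, one tie: H computed by ranking by hand."""
        groups = {"a": [1.0, 2.0], "b": [2.0, 4.0], "c": [5.0, 6.0]}
        h, p = group_comparison(groups)
        h_scipy = stats.kruskal(*groups.values()).statistic
        # hand: ranks 1, 2.5, 2.5, 4, 5, 6; R_a=3.5, R_b=6.5, R_c=11
        n = 6
        h_raw = 12 / (n * (n + 1)) * (3.5**2 / 2 + 6.5**2 / 2 + 11**2 / 2) - 3 * (
            n + 1
        )
        tie_correction = 1 - (2**3 - 2) / (n**3 - n)
        assert h == pytest.approx(h_raw / tie_correction)
        assert h == pytest.approx(h_scipy)

    def test_empty_group_rejected(self):
        with pytest.raises(DeviationError):
            group_comparison({"a": [1.0], "b": []})


class TestCorrelate:
    def test_perfect_linearity_pearson(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1, method="pearson")
        assert res.estimate == pytest.approx(1.0)

    def test_perfect_monotone_decreasing_spearman(self):
        x = np.arange(1.0, 9.0)
        res = correlate(x, np.exp(-x), method="spearman")
        assert res.estimate == pytest.approx(-1.0)

    def test_spearman_matches_hand_rank_formula(self):
        """Six untied pairs: rho = 1 - 6 sum(d^2) / (n (n^2 - 1))."""
        x = np.array([3.0, 1.0, 4.0, 9.0, 2.0, 6.0])
        y = np.array([10.0, 8.0, 12.0, 30.0, 11.0, 18.0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d2 = np.sum((rx - ry) ** 2)
        rho_hand = 1 - 6 * d2 / (6 * 35)
        res = correlate(x, y, method="spearman")
        assert res.estimate == pytest.approx(rho_hand)

    def test_symmetric_in_arguments(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        for method in ("spearman", "pearson"):
            a = correlate(x, y, method=method)
            b = correlate(y, x, method=method)
            assert a.estimate == pytest.approx(b.estimate)
            assert a.p_value == pytest.approx(b.p_value)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_spearman_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = correlate(x, y, method="spearman")
        transformed = correlate(np.exp(x), y**3, method="spearman")
        assert base.estimate == pytest.approx(transformed.estimate)

    def test_zero_variance_rejected(self):
        with pytest.raises(DeviationError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DeviationError):
            correlate([1.0, 2.0], [1.0, 2.0])


class TestJonckheereTerpstra:
    def test_all_values_equal_gives_half(self):
        j, p = jonckheere_terpstra([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert p == 0.5

    def test_identical_distributions_p_centered(self, rng):
        """Under the null the one-sided p is ~uniform: its mean over many
        replicates sits near 0.5."""
        ps = []
        for _ in range(300):
            groups = [rng.normal(size=5) for _ in range(3)]
            ps.append(jonckheere_terpstra(groups)[1])
        assert 0.45 < np.mean(ps) < 0.55

    def test_increasing_trend_detected(self, rng):
        groups = [rng.normal(loc=mu, size=30) for mu in (0.0, 0.8, 1.6)]
        _, p = jonckheere_terpstra(groups, alternative="increasing")
        assert p < 0.01

    def test_decreasing_alternative_mirrors(self, rng):
        groups = [rng.normal(loc=mu, size=15) for mu in (2.0, 1.0, 0.0)]
        _, p_dec = jonckheere_terpstra(groups, alternative="decreasing")
        assert p_dec < 0.01

    def test_fewer_than_three_arms_rejected(self):
        with pytest.raises(DeviationError):
            dose_response_trend({"a": [1.0], "b": [2.0]})


class TestAnovaSampleSize:
    def test_huge_effect_saturates_at_minimum(self):
        assert anova_sample_size(k=2, f=10.0, alpha=0.05, power=0.8) == 2

    def test_monotone_in_effect_size(self):
        n_small = anova_sample_size(k=3, f=0.25)
        n_large = anova_sample_size(k=3, f=0.5)
        assert n_small >= n_large

    def test_agrees_with_t_test_oracle_at_two_groups(self):
        """F(1, .) = t^2: the k=2 ANOVA sample size matches the two-sample
        t-test power solver within +-1 (f = d/2)."""
        from statsmodels.stats.power import TTestIndPower

        for d in (0.5, 0.8, 1.2):
            n_anova = anova_sample_size(k=2, f=d / 2, alpha=0.05, power=0.8)
            n_t = TTestIndPower().solve_power(
                effect_size=d, alpha=0.05, power=0.8, ratio=1.0
            )
            assert abs(n_anova - np.ceil(n_t)) <= 1

    def test_invalid_arguments_rejected(self):
        with pytest.raises(DeviationError):
            anova_sample_size(k=1, f=0.3)
        with pytest.raises(DeviationError):
            anova_sample_size(k=3, f=-0.1)

    def test_known_textbook_value(self):
        """k=4 groups, medium effect f=0.25, alpha=.05, power=.80:
        the standard one-way ANOVA table gives 45 per group."""
        assert anova_sample_size(k=4, f=0.25) == 45
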