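"""Clinical comparison layer: rank tests, contingency tests, survival."""

import itertools

import numpy as np
import pytest
from scipy import stats

from sepstrat import (
    SurvivalCurve,
    chi_squared,
    dunn_posthoc,
    km_estimate,
    kruskal_wallis,
    log_rank,
    proportion_ratio,
)


class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_permutation_distribution(self):
        """For {1,2,3} vs {4,5,6}, the permutation p-value of H over all
        C(6,3)=20 label splits matches the chi-squared approximation's
        extremeness ordering: observed H must be the unique maximum."""
        a, b = [1, 2, 3], [4, 5, 6]
        h_obs, _ = kruskal_wallis([a, b])
        pooled = a + b
        h_all = []
        for combo in itertools.combinations(range(6), 3):
            g1 = [pooled[i] for i in combo]
            g2 = [pooled[i] for i in range(6) if i not in combo]
            h_all.append(kruskal_wallis([g1, g2])[0])
        p_perm = np.mean([h >= h_obs - 1e-12 for h in h_all])
        # both perfect splits (a,b) and (b,a) attain the maximum
        assert p_perm == pytest.approx(2 / 20)
        assert h_obs == pytest.approx(max(h_all))

    def test_invariant_under_monotone_transform(self):
        g1, g2, g3 = [1.0, 3.0, 5.0], [2.0, 4.0], [6.0, 7.0, 9.0]
        h1, p1 = kruskal_wallis([g1, g2, g3])
        f = lambda v: [np.exp(x) for x in v]
        h2, p2 = kruskal_wallis([f(g1), f(g2), f(g3)])
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunn:
    def test_hand_computed_z_on_nine_value_fixture(self):
        # groups {1,2,3}, {4,5,6}, {7,8,9}: mean ranks 2, 5, 8; N=9, no ties
        # var_base = 9*10/12 = 7.5; se = sqrt(7.5 * 2/3) = sqrt(5)
        table = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        z01 = table.set_index(["group_a", "group_b"]).loc[(0, 1), "z"]
        assert z01 == pytest.approx((2 - 5) / np.sqrt(5), abs=1e-9)
        z02 = table.set_index(["group_a", "group_b"]).loc[(0, 2), "z"]
        assert z02 == pytest.approx((2 - 8) / np.sqrt(5), abs=1e-9)

    def test_identical_groups_pairwise_p_near_one(self):
        table = dunn_posthoc([[5, 6, 7], [5, 6, 7], [50, 60, 70]])
        p01 = table.set_index(["group_a", "group_b"]).loc[(0, 1), "p"]
        assert p01 > 0.95

    def test_symmetric_in_group_order(self):
        g = [[1, 5, 9], [2, 6, 7], [3, 4, 8]]
        t1 = dunn_posthoc(g)
        t2 = dunn_posthoc(g[::-1])
        # pair (0,1) in reversed order is pair (1,2) with sign flip
        z_a = t1.set_index(["group_a", "group_b"]).loc[(0, 1), "z"]
        z_b = t2.set_index(["group_a", "group_b"]).loc[(1, 2), "z"]
        assert z_a == pytest.approx(-z_b)

    def test_needs_three_groups_and_valid_adjustment(self):
        with pytest.raises(ValueError, match=">= 3 groups"):
            dunn_posthoc([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="p_adjust"):
            dunn_posthoc([[1], [2], [3]], p_adjust="holm")

    def test_bh_adjustment_not_smaller_than_raw(self):
        t = dunn_posthoc([[1, 2, 3], [2, 3, 4], [9, 10, 11]], p_adjust="bh")
        assert (t["p_adj"] >= t["p"] - 1e-12).all()


class TestChiSquared:
    def test_independence_table_gives_zero_statistic(self):
        margins_r = np.array([0.3, 0.7])
        margins_c = np.array([0.4, 0.6])
        table = np.outer(margins_r, margins_c) * 1000
        x2, df, p = chi_squared(table)
        assert x2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_2x2_matches_classical_closed_form(self, rng):
        a, b, c, d = 12, 5, 7, 20
        x2, df, p = chi_squared([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert x2 == pytest.approx(closed)
        assert df == 1

    def test_blood_culture_counts_reproduce_reported_p(self):
        """Endotype blood-culture positivity 23/81, 13/45, 8/54, 5/56, 1/24
        tests at p ~= 0.005 without continuity correction."""
        pos = [23, 13, 8, 5, 1]
        tot = [81, 45, 54, 56, 24]
        table = [[p_, t - p_] for p_, t in zip(pos, tot)]
        _, df, p = chi_squared(table)
        assert df == 4
        assert p == pytest.approx(0.005, abs=0.002)

    def test_icu_mortality_counts_reproduce_reported_p(self):
        """ICU 28-day mortality 16/35, 7/27, 0/5, 0/6 tests at p ~= 0.025."""
        pos = [16, 7, 0, 0]
        tot = [35, 27, 5, 6]
        table = [[p_, t - p_] for p_, t in zip(pos, tot)]
        _, _, p = chi_squared(table)
        assert p == pytest.approx(0.025, abs=0.01)

    def test_zero_marginal_rejected_and_fisher_flag(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared([[0, 5], [0, 7]])
        _, _, p = chi_squared([[8, 2], [1, 9]], use_fisher=True)
        assert p == pytest.approx(stats.fisher_exact([[8, 2], [1, 9]])[1])


class TestProportionRatio:
    def test_identical_groups_ratio_one(self):
        assert proportion_ratio(5, 20, 5, 20) == pytest.approx(1.0)

    def test_blood_culture_fold_increase(self):
        """Severe (NPS+INF) vs fair-prognosis endotypes: 2.7-fold more
        positive blood cultures."""
        ratio = proportion_ratio([23, 13], [81, 45], [8, 5, 1], [54, 56, 24])
        assert round(ratio, 1) == 2.7

    def test_reciprocal_identity(self):
        r1 = proportion_ratio(4, 10, 3, 30)
        r2 = proportion_ratio(3, 30, 4, 10)
        assert r1 * r2 == pytest.approx(1.0)

    def test_zero_denominator_positives_flagged_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert proportion_ratio(3, 10, 0, 10) == np.inf


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = [2, 4, 4, 7, 9]
        curve = km_estimate(times, [1] * 5)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(np.asarray(times) > t))

    def test_all_censored_curve_constant_one(self):
        curve = km_estimate([3, 5, 8], [0, 0, 0])
        assert curve.at(10) == 1.0
        assert len(curve.times) == 0

    def test_mixed_fixture_matches_hand_product_limit(self):
        # times 1,2,2,3,4 events 1,1,0,1,0:
        # S(1)=4/5=0.8; S(2)=0.8*3/4=0.6; S(3)=0.6*1/2=0.3
        curve = km_estimate([1, 2, 2, 3, 4], [1, 1, 0, 1, 0])
        assert list(curve.times) == [1, 2, 3]
        assert np.allclose(curve.survival, [0.8, 0.6, 0.3])
        assert list(curve.at_risk) == [5, 4, 2]

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            km_estimate([-1, 2], [1, 1])

    def test_curve_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="nonincreasing"):
            SurvivalCurve(
                times=np.array([1.0, 2.0]),
                survival=np.array([0.5, 0.8]),
                at_risk=np.array([5, 4]),
                censored_times=np.array([]),
            )

    def test_km_mean_time_consistency_on_exponential_data(self, rng):
        """Without censoring, the area under the KM curve up to the horizon
        equals the sample mean of min(time, horizon)."""
        t = rng.exponential(5.0, size=400)
        horizon = 15.0
        curve = km_estimate(t, np.ones_like(t, dtype=int))
        grid_times = np.concatenate([[0.0], curve.times[curve.times <= horizon], [horizon]])
        surv = np.concatenate([[1.0], curve.survival[curve.times <= horizon]])
        area = float(np.sum(surv * np.diff(grid_times)))
        assert area == pytest.approx(np.minimum(t, horizon).mean(), rel=0.01)


class TestLogRank:
    def test_identical_groups_near_null(self):
        t = [1, 3, 5, 7, 9, 11]
        e = [1, 1, 0, 1, 0, 1]
        x2, p = log_rank(t, e, t, e)
        assert x2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self, rng):
        t1, t2 = rng.exponential(5, 20), rng.exponential(9, 25)
        e1, e2 = np.ones(20, int), (rng.random(25) < 0.8).astype(int)
        a = log_rank(t1, e1, t2, e2)
        b = log_rank(t2, e2, t1, e1)
        assert a[0] == pytest.approx(b[0])
        assert a[1] == pytest.approx(b[1])

    @staticmethod
    def _hand_logrank(t1, e1, t2, e2):
        """Direct transcription of the log-rank statistic: observed vs
        expected group-1 events over the shared event times."""
        t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
        times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
        o_minus_e = 0.0
        var = 0.0
        for t in times:
            n1 = np.sum(t1 >= t)
            n2 = np.sum(t2 >= t)
            d1 = np.sum((t1 == t) & (e1 == 1))
            d2 = np.sum((t2 == t) & (e2 == 1))
            n, d = n1 + n2, d1 + d2
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        return o_minus_e**2 / var

    def test_statistic_matches_hand_formula(self):
        t1, e1 = [1.0, 2.0, 4.0, 6.0, 7.0], [1, 1, 1, 0, 1]
        t2, e2 = [3.0, 8.0, 9.0, 12.0, 14.0], [1, 0, 1, 1, 1]
        x2, _ = log_rank(t1, e1, t2, e2)
        assert x2 == pytest.approx(self._hand_logrank(t1, e1, t2, e2), abs=1e-9)

    def test_matches_permutation_null_on_small_fixture(self, rng):
        t1, e1 = [1.0, 2.0, 4.0, 6.0, 7.0], [1, 1, 1, 0, 1]
        t2, e2 = [3.0, 8.0, 9.0, 12.0, 14.0], [1, 0, 1, 1, 1]
        x2_obs, p_asym = log_rank(t1, e1, t2, e2)
        pooled_t = np.array(t1 + t2)
        pooled_e = np.array(e1 + e2)
        n1 = len(t1)
        count = 0
        n_perm = 5000
        for _ in range(n_perm):
            idx = rng.permutation(10)
            x2 = self._hand_logrank(
                pooled_t[idx[:n1]], pooled_e[idx[:n1]], pooled_t[idx[n1:]], pooled_e[idx[n1:]]
            )
            if x2 >= x2_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_perm - p_asym) < max(4 * se, 0.05)

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="no events"):
            log_rank([1, 2], [0, 0], [3, 4], [0, 0])
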