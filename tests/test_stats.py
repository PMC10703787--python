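import math

import numpy as np
import pytest
from scipy import stats as sps

from mksers.stats import (
    ContingencyTable2x2,
    cox_univariate,
    fnch_cdf,
    fnch_pmf,
    fnch_support,
    interaction_test,
    km_estimate,
    logrank_test,
    midp_median_unbiased_or,
    students_t_test,
)


def _brute_force_fnch_cdf(x, margins, psi):
    """Direct enumeration oracle: unnormalised weights with math.comb."""
    m1, m2, n = margins
    lo, hi = max(0, n - m2), min(n, m1)
    weights = {k: math.comb(m1, k) * math.comb(m2, n - k) * psi ** k
               for k in range(lo, hi + 1)}
    total = sum(weights.values())
    return sum(w for k, w in weights.items() if k <= x) / total


class TestFnch:
    def test_reduces_to_central_hypergeometric_at_psi_1(self, rng):
        for _ in range(100):
            m1, m2 = rng.integers(1, 40, size=2)
            n = int(rng.integers(1, m1 + m2 + 1))
            xs = fnch_support((m1, m2, n))
            x = int(rng.choice(xs))
            expected = sps.hypergeom.cdf(x, m1 + m2, m1, n)
            assert fnch_cdf(x, (int(m1), int(m2), n), 1.0) == pytest.approx(
                expected, abs=1e-12)

    def test_cdf_at_support_maximum_is_one(self, rng):
        for _ in range(20):
            m1, m2 = rng.integers(1, 30, size=2)
            n = int(rng.integers(1, m1 + m2 + 1))
            xs = fnch_support((int(m1), int(m2), n))
            for psi in (0.3, 1.0, 7.0):
                assert fnch_cdf(int(xs[-1]), (int(m1), int(m2), n), psi) == pytest.approx(
                    1.0, abs=1e-12)

    @pytest.mark.parametrize("psi", [0.5, 2.0, 10.0])
    def test_matches_direct_enumeration_oracle(self, rng, psi):
        for _ in range(30):
            m1, m2 = (int(v) for v in rng.integers(1, 15, size=2))
            n = int(rng.integers(1, m1 + m2 + 1))
            xs = fnch_support((m1, m2, n))
            x = int(rng.choice(xs))
            assert fnch_cdf(x, (m1, m2, n), psi) == pytest.approx(
                _brute_force_fnch_cdf(x, (m1, m2, n), psi), abs=1e-10)

    def test_matches_scipy_noncentral_hypergeometric(self, rng):
        # independent library cross-check of the hand-rolled pmf
        for _ in range(20):
            m1, m2 = (int(v) for v in rng.integers(2, 25, size=2))
            n = int(rng.integers(1, m1 + m2))
            psi = float(rng.uniform(0.2, 5.0))
            xs, p = fnch_pmf((m1, m2, n), psi)
            ref = sps.nchypergeom_fisher.pmf(xs, m1 + m2, m1, n, psi)
            np.testing.assert_allclose(p, ref, atol=1e-12)

    def test_nonpositive_psi_rejected(self):
        with pytest.raises(ValueError):
            fnch_cdf(1, (5, 5, 5), 0.0)
        with pytest.raises(ValueError):
            fnch_cdf(1, (5, 5, 5), -2.0)


def _grid_oracle_psi(table, step=1e-4):
    """Dense-grid search for the mid-p root, independent of the root-finder."""
    margins = table.margins
    xs = fnch_support(margins)
    a = table.a

    def midp_upper(psis):
        m1, m2, n = margins
        from scipy.special import gammaln
        base = (gammaln(m1 + 1) - gammaln(xs + 1) - gammaln(m1 - xs + 1)
                + gammaln(m2 + 1) - gammaln(n - xs + 1) - gammaln(m2 - (n - xs) + 1))
        logw = base[None, :] + np.outer(np.log(psis), xs)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)
        return w[:, xs > a].sum(axis=1) + 0.5 * w[:, xs == a].sum(axis=1)

    coarse = np.exp(np.linspace(np.log(1e-5), np.log(1e5), 2000))
    f = midp_upper(coarse) - 0.5
    idx = np.nonzero(np.diff(np.sign(f)) != 0)[0]
    if len(idx) == 0:
        return None
    lo, hi = coarse[idx[0]], coarse[idx[0] + 1]
    fine = np.arange(lo, hi + step, step)
    ff = midp_upper(fine) - 0.5
    return float(fine[np.argmin(np.abs(ff))])


class TestMidpMedianUnbiasedOr:
    def test_reproduces_printed_trial_odds_ratios(self):
        lo = midp_median_unbiased_or(ContingencyTable2x2(10, 14, 9, 34))
        assert round(lo.psi_hat, 2) == 2.65
        assert round(lo.ci_low, 2) == 0.88 and round(lo.ci_high, 2) == 8.22
        hi = midp_median_unbiased_or(ContingencyTable2x2(2, 14, 5, 46))
        assert round(hi.psi_hat, 2) == 1.36
        assert round(hi.ci_low, 2) == 0.16 and round(hi.ci_high, 2) == 7.44

    def test_symmetric_table_estimates_one(self):
        res = midp_median_unbiased_or(ContingencyTable2x2(5, 5, 5, 5))
        assert res.psi_hat == pytest.approx(1.0, abs=1e-9)
        assert res.ci_low == pytest.approx(1.0 / res.ci_high, rel=1e-6)

    def test_transposing_arms_inverts_estimate_and_swaps_ci(self, rng):
        for _ in range(10):
            a, b, c, d = (int(v) for v in rng.integers(1, 15, size=4))
            t = ContingencyTable2x2(a, b, c, d)
            r1 = midp_median_unbiased_or(t)
            r2 = midp_median_unbiased_or(t.transpose_arms())
            assert r2.psi_hat == pytest.approx(1.0 / r1.psi_hat, rel=1e-7)
            assert r2.ci_low == pytest.approx(1.0 / r1.ci_high, rel=1e-6)
            assert r2.ci_high == pytest.approx(1.0 / r1.ci_low, rel=1e-6)

    def test_agrees_with_dense_grid_oracle(self, rng):
        for _ in range(40):
            a, b, c, d = (int(v) for v in rng.integers(1, 13, size=4))
            t = ContingencyTable2x2(a, b, c, d)
            oracle = _grid_oracle_psi(t)
            res = midp_median_unbiased_or(t)
            assert res.psi_hat == pytest.approx(oracle, abs=5e-4)

    def test_zero_cell_gives_one_sided_limits(self):
        res = midp_median_unbiased_or(ContingencyTable2x2(0, 10, 5, 5))
        assert res.psi_hat == 0.0 and res.ci_low == 0.0
        assert 0 < res.ci_high < np.inf
        res = midp_median_unbiased_or(ContingencyTable2x2(10, 0, 5, 5))
        assert res.psi_hat == np.inf and res.ci_high == np.inf
        assert res.ci_low > 0

    def test_all_zero_response_margin_raises(self):
        with pytest.raises(ValueError):
            midp_median_unbiased_or(ContingencyTable2x2(0, 10, 0, 10))

    def test_exact_variant_is_more_conservative_than_midp(self):
        t = ContingencyTable2x2(10, 14, 9, 34)
        mid = midp_median_unbiased_or(t)
        exact = midp_median_unbiased_or(t, midp=False)
        assert exact.ci_low < mid.ci_low
        assert exact.ci_high > mid.ci_high

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestKaplanMeier:
    def test_no_events_means_flat_curve_at_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert curve.survival_at(2.9) == 1.0
        assert (curve.survival >= 1.0 - 1e-12).all()

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2: S(2.5)=2/3, S(3)=0
        curve = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        assert curve.survival_at(2.5) == pytest.approx(2.0 / 3.0)
        assert curve.survival_at(3.0) == pytest.approx(0.0)
        assert curve.survival_at(0.5) == 1.0

    def test_duplicating_every_record_leaves_curve_unchanged(self, rng):
        times = rng.exponential(2.0, size=30)
        events = rng.random(30) < 0.7
        c1 = km_estimate(times, events)
        c2 = km_estimate(np.concatenate([times, times]),
                         np.concatenate([events, events]))
        q = np.linspace(0, times.max(), 50)
        np.testing.assert_allclose(c1.survival_at(q), c2.survival_at(q), atol=1e-12)

    def test_all_events_equals_empirical_survival(self, rng):
        times = np.sort(rng.exponential(1.0, size=40))
        curve = km_estimate(times, np.ones(40, dtype=bool))
        q = rng.uniform(0, times.max(), size=25)
        empirical = np.array([(times > t).mean() for t in q])
        np.testing.assert_allclose(curve.survival_at(q), empirical, atol=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def _two_group_logrank_stat(times, events, mask):
    """Self-contained O-E chi-square oracle for two groups."""
    U, V = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & mask).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & mask).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U * U / V if V > 0 else 0.0


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self, rng):
        times = rng.exponential(1.0, size=25)
        events = rng.random(25) < 0.8
        stat, df, p = logrank_test(np.tile(times, 2), np.tile(events, 2),
                                   np.repeat(["a", "b"], 25))
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 1 and p == pytest.approx(1.0)

    def test_no_events_warns_and_returns_p_one(self):
        with pytest.warns(RuntimeWarning, match="no events"):
            stat, df, p = logrank_test([1, 2, 3, 4], [False] * 4, ["a", "a", "b", "b"])
        assert p == 1.0

    def test_agrees_with_permutation_oracle(self, rng):
        n = 30
        times = rng.exponential(1.0, size=n)
        mask = np.arange(n) < n // 2
        times[mask] *= 0.45  # moderate group difference
        events = rng.random(n) < 0.85
        stat, _, p_asym = logrank_test(times, events, np.where(mask, "a", "b"))
        obs = _two_group_logrank_stat(times, events, mask)
        assert stat == pytest.approx(obs, rel=1e-6)
        perm = np.array([
            _two_group_logrank_stat(times, events, rng.permutation(mask))
            for _ in range(2000)
        ])
        p_perm = (perm >= obs - 1e-12).mean()
        se = math.sqrt(max(p_perm * (1 - p_perm), 1e-4) / 2000)
        assert abs(p_perm - p_asym) < 4 * se + 0.02

    def test_invariant_to_monotone_time_rescaling(self, rng):
        times = rng.exponential(1.0, size=40)
        events = rng.random(40) < 0.7
        labels = np.repeat(["a", "b"], 20)
        s1, _, p1 = logrank_test(times, events, labels)
        s2, _, p2 = logrank_test(np.expm1(times), events, labels)
        assert s1 == pytest.approx(s2, rel=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_power_against_hazard_ratio_three(self, rng):
        rejections = 0
        n = 200
        for _ in range(200):
            t0 = rng.exponential(1.0, size=n)
            t1 = rng.exponential(1.0 / 3.0, size=n)
            times = np.concatenate([t0, t1])
            cens = rng.exponential(5.0, size=2 * n)
            obs = np.minimum(times, cens)
            events = times <= cens
            _, _, p = logrank_test(obs, events, np.repeat(["a", "b"], n))
            rejections += p < 0.05
        assert rejections / 200 > 0.9

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [True, True], ["a", "a"])


class TestCoxUnivariate:
    def test_null_covariate_behaves_like_null(self, rng):
        n = 120
        pvals, hrs = [], []
        for _ in range(40):
            times = rng.exponential(1.0, size=n)
            events = rng.random(n) < 0.8
            x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
            res = cox_univariate(times, events, x)
            pvals.append(res.p_value)
            hrs.append(res.hr)
        assert np.mean([p < 0.05 for p in pvals]) <= 0.15
        assert 0.75 < np.median(hrs) < 1.35

    def test_recovers_hazard_ratio_two(self, rng):
        hrs = []
        for _ in range(20):
            n = 500
            t0 = rng.exponential(1.0, size=n)
            t1 = rng.exponential(0.5, size=n)
            times = np.concatenate([t0, t1])
            x = np.repeat([0.0, 1.0], n)
            res = cox_univariate(times, np.ones(2 * n, bool), x)
            hrs.append(res.hr)
        assert np.mean(hrs) == pytest.approx(2.0, rel=0.1)

    def test_swapping_coding_inverts_hazard_ratio(self, rng):
        times = rng.exponential(1.0, size=60)
        events = rng.random(60) < 0.85
        x = np.repeat([0.0, 1.0], 30)
        r1 = cox_univariate(times, events, x)
        r2 = cox_univariate(times, events, 1.0 - x)
        assert r2.hr == pytest.approx(1.0 / r1.hr, rel=1e-6)

    def test_monotone_likelihood_flagged_with_unbounded_ci(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, True, True, False, False, False]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]  # no events in level 0
        res = cox_univariate(times, events, x)
        assert res.flagged
        assert res.ci_low == 0.0 and res.ci_high == np.inf

    def test_non_binary_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1, 2, 3], [True, True, False], [0.0, 0.5, 1.0])


class TestStudentsT:
    def test_identical_groups(self):
        t, df, p = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_pooled_example(self):
        t, df, p = students_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4

    def test_type_i_error_calibrated_under_null(self, rng):
        x = rng.normal(size=(5000, 20))
        y = rng.normal(size=(5000, 20))
        res = sps.ttest_ind(x, y, axis=1, equal_var=True)
        # sanity of the vectorised oracle against our scalar implementation
        t0, _, p0 = students_t_test(x[0], y[0])
        assert t0 == pytest.approx(res.statistic[0]) and p0 == pytest.approx(res.pvalue[0])
        rate = (res.pvalue < 0.05).mean()
        assert 0.035 < rate < 0.065

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            students_t_test([2.0, 2.0], [2.0, 2.0])

    def test_welch_flag_changes_df(self):
        x = [1.0, 2.0, 3.0, 9.0]
        y = [2.0, 2.1, 2.2]
        _, df_pooled, _ = students_t_test(x, y)
        _, df_welch, _ = students_t_test(x, y, welch=True)
        assert df_pooled == 5
        assert df_welch != df_pooled


class TestInteraction:
    def test_equal_probabilities_give_near_zero_coefficient(self):
        arm = np.repeat([0, 1, 0, 1], 10)
        stratum = np.repeat([0, 0, 1, 1], 10)
        response = np.tile([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], 4)  # 30% everywhere
        res = interaction_test(response, arm, stratum)
        assert res.coef == pytest.approx(0.0, abs=1e-6)

    def test_reconstructed_trial_counts_near_printed_p(self):
        # consistency check only: arm x ERS-stratum interaction on pCR
        rows = []
        for arm, stratum, n, n_resp in [(0, 0, 51, 5), (1, 0, 16, 2),
                                        (0, 1, 43, 9), (1, 1, 24, 10)]:
            rows += [(1, arm, stratum)] * n_resp + [(0, arm, stratum)] * (n - n_resp)
        resp, arm, stratum = map(np.array, zip(*rows))
        res = interaction_test(resp, arm, stratum)
        assert res.p_value is not None
        assert 0.3 < res.p_value < 0.7

    def test_planted_qualitative_interaction_detected(self, rng):
        n = 500
        cells = [(0, 0, 0.2), (1, 0, 0.5), (0, 1, 0.5), (1, 1, 0.2)]  # OR 4 vs 0.25
        resp, arm, stratum = [], [], []
        for a, s, p in cells:
            resp.extend(rng.random(n) < p)
            arm.extend([a] * n)
            stratum.extend([s] * n)
        res = interaction_test(np.array(resp, float), np.array(arm), np.array(stratum))
        assert res.p_value < 0.001

    def test_separation_is_flagged(self):
        arm = np.repeat([0, 1, 0, 1], 8)
        stratum = np.repeat([0, 0, 1, 1], 8)
        response = (arm ^ stratum).astype(float)  # deterministic interaction
        res = interaction_test(response, arm, stratum)
        assert res.flagged and res.p_value is None

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError):
            interaction_test([1, 0, 1], [0, 0, 1], [0, 0, 1])
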