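import itertools

import numpy as np
import pytest
from scipy import stats as sps

from tractshift.stats import (
    bh_fdr,
    change_correlation,
    cohens_d,
    effect_band,
    logistic_outcome,
    paired_lmm,
    percent_change,
    rank_sum,
    segment_ztest,
    speech_label,
    wilcoxon_signed_rank,
)


def _exact_signed_rank_p(diffs):
    """Enumeration oracle: exact two-sided p over all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            pre = rng.normal(0, 1, 6)
            intra = pre + rng.normal(0.4, 1, 6)
            if np.any(intra - pre == 0) or np.unique(np.abs(intra - pre)).size < 6:
                continue
            res = wilcoxon_signed_rank(pre, intra)
            assert res.p_raw == pytest.approx(_exact_signed_rank_p(intra - pre), abs=1e-12)

    def test_uniform_shift_gives_minimal_exact_p(self):
        pre = np.arange(8, dtype=float)
        res = wilcoxon_signed_rank(pre, pre + 1.0)
        assert res.p_raw == pytest.approx(2 * 0.5**8)

    def test_all_zero_differences_error(self):
        pre = np.ones(6)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(pre, pre)

    def test_too_few_nonzero_differences(self):
        pre = np.zeros(6)
        intra = np.array([1.0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_signed_rank(pre, intra)


class TestRankSum:
    def test_matches_exact_enumeration_small_groups(self, rng):
        x = np.array([1.3, 2.1, 4.5, 0.2])
        y = np.array([3.3, 5.1, 6.0])
        res = rank_sum(x, y)
        # enumeration of all group assignments of the pooled ranks
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        u_obs = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
        us = []
        for combo in itertools.combinations(range(7), 4):
            rs = ranks[list(combo)].sum() - 4 * 5 / 2
            us.append(rs)
        us = np.array(us)
        p = min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))
        assert res.p_raw == pytest.approx(p, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum(np.array([]), np.array([1.0]))


class TestCohensD:
    def test_constant_differences_flagged(self):
        d, band = cohens_d(np.zeros(4), np.ones(4))
        assert np.isinf(d) and band == "undefined"

    def test_half_sd_is_moderate_boundary(self):
        # mean 0.5, sd 1.0 -> d = 0.5 assigned to the higher band
        delta = np.array([-0.5, 0.0, 1.0, 1.5])
        assert delta.mean() == pytest.approx(0.5)
        assert delta.std(ddof=1) == pytest.approx(np.std(delta, ddof=1))
        d, band = cohens_d(np.zeros(4), delta * (1.0 / delta.std(ddof=1)) * delta.std(ddof=1))
        # construct exactly: scale so sd == 1
        delta2 = (delta - delta.mean()) / delta.std(ddof=1) + 0.5
        d, band = cohens_d(np.zeros(4), delta2)
        assert d == pytest.approx(0.5)
        assert band == "moderate"

    def test_band_edges_left_closed(self):
        assert effect_band(0.19) == "negligible"
        assert effect_band(0.2) == "small"
        assert effect_band(0.5) == "moderate"
        assert effect_band(0.8) == "large"
        assert effect_band(-0.85) == "large"

    def test_matches_spreadsheet_recomputation(self, rng):
        pre = rng.normal(10, 2, 12)
        intra = pre + rng.normal(0.5, 1, 12)
        d, _ = cohens_d(pre, intra)
        delta = intra - pre
        manual = (delta.sum() / 12) / np.sqrt(((delta - delta.sum() / 12) ** 2).sum() / 11)
        assert d == pytest.approx(manual, abs=1e-12)


class TestPairedLmm:
    def _long(self, pre, intra):
        n = len(pre)
        subj = np.repeat([f"s{i}" for i in range(n)], 2)
        tp = np.tile([0.0, 1.0], n)
        vals = np.column_stack([pre, intra]).ravel()
        return vals, tp, subj

    def test_balanced_estimate_equals_mean_difference(self, rng):
        pre = rng.normal(5, 1, 15)
        intra = pre + rng.normal(-0.7, 0.5, 15)
        vals, tp, subj = self._long(pre, intra)
        res = paired_lmm(vals, tp, subj)
        assert res.statistic == pytest.approx(np.mean(intra - pre), abs=1e-8)

    def test_orthogonal_covariate_leaves_estimate(self, rng):
        pre = rng.normal(5, 1, 12)
        intra = pre + rng.normal(0.5, 0.4, 12)
        vals, tp, subj = self._long(pre, intra)
        cov = np.repeat(rng.normal(0, 1, 12), 2)  # constant within subject
        res0 = paired_lmm(vals, tp, subj)
        res1 = paired_lmm(vals, tp, subj, cov)
        assert res1.statistic == pytest.approx(res0.statistic, abs=1e-6)

    def test_p_invariant_under_subject_relabeling(self, rng):
        pre = rng.normal(5, 1, 10)
        intra = pre + rng.normal(0.4, 0.6, 10)
        vals, tp, subj = self._long(pre, intra)
        res0 = paired_lmm(vals, tp, subj)
        perm = rng.permutation(10)
        relabeled = np.array([f"x{perm[int(s[1:])]}" for s in subj])
        res1 = paired_lmm(vals, tp, relabeled)
        assert res1.p_raw == pytest.approx(res0.p_raw, rel=1e-6)

    def test_power_on_simulated_compression_effect(self, rng):
        """A consistent multiplicative reduction is detected at alpha=0.05
        in >= 90% of 100 replicates (volume-like cohort scale)."""
        hits = 0
        for _ in range(100):
            pre = rng.normal(1.0, 0.25, 30)
            intra = pre * 0.49 + rng.normal(0, 0.1, 30)
            vals, tp, subj = self._long(pre, intra)
            res = paired_lmm(vals, tp, subj)
            hits += res.p_raw < 0.05 and res.statistic < 0
        assert hits >= 90


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            adj = bh_fdr(p)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_hand_computed_step_up(self, rng):
        for _ in range(20):
            p = rng.random(10)
            adj = bh_fdr(p)
            m = len(p)
            order = np.argsort(p)
            manual = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                manual[i] = running
            assert np.allclose(adj, manual, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSegmentTests:
    def test_zero_delta_gives_p_one(self):
        delta = np.zeros((8, 10))
        delta += np.arange(8)[:, None] * 0.0
        res = segment_ztest(np.random.default_rng(0).normal(0, 1e-12, (8, 10)) * 0)
        assert not res.tested.any() or np.allclose(res.p_raw[res.tested], 1.0)

    def test_strong_segment_has_minimal_p(self, rng):
        delta = rng.normal(0, 1, (20, 12))
        delta[:, 4] += 5 * delta[:, 4].std(ddof=1) / np.sqrt(20) * 10
        res = segment_ztest(delta)
        assert res.p_raw.idxmin() == 4

    def test_missingness_rules(self, rng):
        delta = rng.normal(0, 1, (10, 5))
        delta[:6, 2] = np.nan  # missing in 60% of subjects -> excluded
        delta[:8, 3] = np.nan  # only 2 observed -> excluded
        res = segment_ztest(delta)
        assert not res.tested[2]
        assert not res.tested[3]
        assert res.tested[[0, 1, 4]].all()

    def test_null_panel_rate_calibrated(self, rng):
        """Pure-noise panels: fraction with any BH-significant segment stays
        near the nominal 0.05 level."""
        sig = 0
        reps = 400
        for _ in range(reps):
            res = segment_ztest(rng.normal(0, 1, (30, 55)))
            sig += bool((res.p_fdr[res.tested] < 0.05).any())
        rate = sig / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestCorrelationAndOutcome:
    def test_perfect_negative(self):
        x = np.arange(8.0)
        res = change_correlation(x, -x)
        assert res.statistic == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            change_correlation(np.ones(6), np.arange(6.0))

    def test_null_pairing_uniform_p(self, rng):
        ps = []
        for _ in range(200):
            res = change_correlation(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
            ps.append(res.p_raw)
        # p uniform under the null: mean ~0.5, small |r| typical
        assert np.mean(ps) == pytest.approx(0.5, abs=0.08)
        assert np.mean(np.array(ps) < 0.05) < 0.11

    def test_injected_coupling_recovers_negative_sign(self, rng):
        hits = 0
        for _ in range(100):
            vol = rng.uniform(0.8, 1.25, 23)
            change = -30.0 * (vol - 1.0) * -1.5 + rng.normal(0, 5, 23)
            change = -45.0 - 25.0 * (vol - 1.0) + rng.normal(0, 8, 23)
            res = change_correlation(change, vol)
            hits += res.statistic < 0
        assert hits >= 95

    def test_spearman_option(self, rng):
        x = rng.normal(0, 1, 30)
        res = change_correlation(x, np.exp(x), method="spearman")
        assert res.statistic == pytest.approx(1.0)

    def test_speech_label_rules(self):
        assert speech_label(0, 0) is False
        assert speech_label(2, 3) is True
        assert speech_label(3, 2) is False
        assert speech_label(None, 3) is None
        with pytest.raises(ValueError):
            speech_label(0, 7)

    def test_logistic_separation_flagged(self):
        age = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        sex = np.zeros(8)
        label = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        res = logistic_outcome(age, sex, label)
        assert res["age"].flags["separation"]

    def test_logistic_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_outcome(np.arange(6.0), np.zeros(6), np.ones(6))

    def test_logistic_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        for _ in range(200):
            age = rng.uniform(2, 17, 40)
            sex = rng.integers(0, 2, 40).astype(float)
            label = rng.integers(0, 2, 40).astype(float)
            if label.min() == label.max():
                continue
            res = logistic_outcome(age, sex, label)
            rejections += res["age"].p_raw < 0.05
        assert rejections / 200 < 0.10

    def test_logistic_coefficients_recovered_large_n(self, rng):
        age = rng.uniform(2, 17, 4000)
        sex = rng.integers(0, 2, 4000).astype(float)
        lin = -1.0 + 0.15 * age + 0.5 * sex
        label = (rng.random(4000) < 1 / (1 + np.exp(-lin))).astype(float)
        res = logistic_outcome(age, sex, label)
        import statsmodels.api as sm

        fit = sm.Logit(label, sm.add_constant(np.column_stack([age, sex]))).fit(disp=0)
        se = fit.bse[1:]
        assert abs(res["age"].statistic - 0.15) < 2 * se[0]
        assert abs(res["sex"].statistic - 0.5) < 2 * se[1]


def test_percent_change():
    assert percent_change(24.36, 22.07) == pytest.approx(-9.4006, abs=1e-3)
    with pytest.raises(ValueError):
        percent_change(0.0, 1.0)
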