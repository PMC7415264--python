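"""Inference suite: sign-flip permutation, FDR, Bayes factors, ANOVA, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from crossmodal.inference import (
    PairedSample,
    bh_fdr,
    cohens_d_paired,
    dienes_bf,
    pearson_corr_test,
    perm_rm_anova,
    power_min_n,
    rm_anova_f,
    signflip_permutation_test,
    t_from_r,
)


class TestSignFlip:
    def test_identical_conditions_give_p_one(self):
        s = PairedSample(list("abcd"), [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = signflip_permutation_test(s, method="exhaustive")
        assert res.p_value == 1.0

    def test_exhaustive_enumeration_oracle(self):
        # diffs {1,2,3}: only the all-positive pattern reaches mean >= 2
        s = PairedSample(list("abc"), [1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        res = signflip_permutation_test(s, method="exhaustive")
        assert res.p_value == pytest.approx(1 / 8)
        assert res.n_perm == 8

    def test_mc_agrees_with_exhaustive_within_3se(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.6, 1.0, 10)
        s = PairedSample(list(range(10)), d, np.zeros(10))
        exact = signflip_permutation_test(s, method="exhaustive").p_value
        mc = signflip_permutation_test(
            s, n_perm=10000, rng=np.random.default_rng(6), method="mc"
        ).p_value
        se = np.sqrt(exact * (1 - exact) / 10000)
        assert abs(mc - exact) <= 3 * se + 1e-4  # identity draw adds <= 1/n_perm

    def test_p_floor_is_one_over_nperm(self):
        s = PairedSample(list(range(8)), np.full(8, 5.0), np.zeros(8))
        res = signflip_permutation_test(s, method="exhaustive")
        assert res.p_value == 1 / 256
        mc = signflip_permutation_test(
            s, n_perm=1000, rng=np.random.default_rng(1), method="mc"
        )
        assert mc.p_value >= 1 / 1000
        assert len(mc.null_diffs) == 1000

    def test_two_sided_and_less_alternatives(self):
        s = PairedSample(list("abc"), [-1.0, -2.0, -3.0], [0.0, 0.0, 0.0])
        assert signflip_permutation_test(
            s, method="exhaustive", alternative="less"
        ).p_value == pytest.approx(1 / 8)
        assert signflip_permutation_test(
            s, method="exhaustive", alternative="two_sided"
        ).p_value == pytest.approx(2 / 8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            PairedSample(["a"], [1.0], [np.nan])
        s = PairedSample(list("ab"), [1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            signflip_permutation_test(s, alternative="sideways")
        with pytest.raises(ValueError):
            signflip_permutation_test(s, method="mc", rng=None)


class TestBhFdr:
    def test_hand_applied_step_up(self):
        reject, p_adj = bh_fdr([0.01, 0.03, 0.04], q=0.05)
        assert reject.all()
        np.testing.assert_allclose(p_adj, [0.03, 0.04, 0.04], atol=1e-12)

    def test_all_ones_nothing_rejected(self):
        reject, p_adj = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_allclose(p_adj, 1.0)

    def test_single_p_identity(self):
        reject, p_adj = bh_fdr([0.04], q=0.05)
        assert reject[0]
        assert p_adj[0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12))
    def test_adjusted_monotone_in_raw_order(self, ps):
        _, p_adj = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(p_adj)[order]) >= -1e-12)


class TestDienesBf:
    @staticmethod
    def closed_form(mean, cs, upper):
        num = (stats.norm.cdf(mean / cs) - stats.norm.cdf((mean - upper) / cs)) / upper
        return num / stats.norm.pdf(mean, 0, cs)

    def test_null_data_supports_h0(self):
        res = dienes_bf(0.0, 0.1, 1000, sem_correction=None)
        assert res.bf == pytest.approx(0.025, abs=5e-4)

    @pytest.mark.parametrize(
        "mean,sem,n", [(0.5, 0.4, 10), (2.0, 0.8, 18), (-0.3, 0.5, 9)]
    )
    def test_matches_gaussian_cdf_oracle(self, mean, sem, n):
        res = dienes_bf(mean, sem, n)
        expected = self.closed_form(mean, res.corrected_sem, 5.0)
        assert res.bf == pytest.approx(expected, rel=1e-6)

    def test_vanishing_sem_with_real_effect_explodes(self):
        res = dienes_bf(2.5, 1e-5, 10)
        assert res.bf > 1e3

    def test_scale_invariance(self):
        a = dienes_bf(1.2, 0.5, 12, h1_upper=5.0)
        b = dienes_bf(2.4, 1.0, 12, h1_upper=10.0)
        assert a.bf == pytest.approx(b.bf, rel=1e-6)

    def test_small_sample_correction_inflates_sem(self):
        res = dienes_bf(1.0, 0.5, 5)
        assert res.corrected_sem == pytest.approx(0.5 * (1 + 20 / 16))
        assert res.corrected_sem >= res.sem

    def test_nonpositive_sem_rejected(self):
        with pytest.raises(ValueError):
            dienes_bf(1.0, 0.0, 10)


def _balanced_table(rng, n_subjects=18, objects=("triangle", "tambourine"),
                    conditions=("fixation", "onset_cue", "object_video"),
                    effects=None):
    rows = []
    for s in range(n_subjects):
        base = rng.normal(0, 3)
        for o in objects:
            for c in conditions:
                eff = (effects or {}).get((o, c), 0.0)
                rows.append(
                    dict(subject_id=s, day=1, object=o, condition=c,
                         threshold_db=base + eff + rng.normal(0, 1))
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_f_matches_statsmodels_anovarm(self):
        table = _balanced_table(np.random.default_rng(3))
        Y_effects = perm_rm_anova(
            table, n_perm=2, rng=np.random.default_rng(0)
        )
        fit = AnovaRM(
            table, "threshold_db", "subject_id", within=["object", "condition"]
        ).fit()
        sm = fit.anova_table["F Value"]
        assert Y_effects["object"].f_value == pytest.approx(sm["object"], abs=1e-9)
        assert Y_effects["condition"].f_value == pytest.approx(
            sm["condition"], abs=1e-9
        )
        assert Y_effects["objectxcondition"].f_value == pytest.approx(
            sm["object:condition"], abs=1e-9
        )

    def test_dfs_match_design(self):
        table = _balanced_table(np.random.default_rng(4))
        res = perm_rm_anova(table, n_perm=2, rng=np.random.default_rng(0))
        assert (res["object"].df_num, res["object"].df_den) == (1, 17)
        assert (res["condition"].df_num, res["condition"].df_den) == (2, 34)
        assert (res["objectxcondition"].df_num,
                res["objectxcondition"].df_den) == (2, 34)

    def test_large_object_effect_hits_permutation_floor(self):
        effects = {("triangle", c): -5.0 for c in
                   ("fixation", "onset_cue", "object_video")}
        table = _balanced_table(np.random.default_rng(5), effects=effects)
        res = perm_rm_anova(table, n_perm=500, rng=np.random.default_rng(1))
        assert res["object"].p_value == 1 / 500

    def test_unbalanced_design_rejected(self):
        table = _balanced_table(np.random.default_rng(6)).iloc[1:]
        with pytest.raises(ValueError):
            perm_rm_anova(table, n_perm=10, rng=np.random.default_rng(0))

    def test_day_repetitions_enter_as_units(self):
        rng = np.random.default_rng(7)
        parts = []
        for day in (1, 2, 3):
            t = _balanced_table(rng, n_subjects=6)
            t["day"] = day
            parts.append(t)
        table = pd.concat(parts)
        res = perm_rm_anova(table, n_perm=2, rng=np.random.default_rng(0))
        # 6 subjects x 3 days = 18 units
        assert res["condition"].df_den == 2 * 17

    def test_null_type_i_error_controlled(self):
        # null-simulation oracle: additive subject effects only; each
        # effect's rejection rate at alpha=.05 must sit near nominal
        n_datasets = 1000
        hits = {"object": 0, "condition": 0, "objectxcondition": 0}
        rng = np.random.default_rng(42)
        for _ in range(n_datasets):
            table = _balanced_table(rng, n_subjects=10)
            res = perm_rm_anova(table, n_perm=200, rng=rng)
            for k in hits:
                hits[k] += res[k].p_value <= 0.05
        for k, h in hits.items():
            assert 0.03 <= h / n_datasets <= 0.07, (k, h / n_datasets)


class TestPearson:
    def test_correlation_t_values_at_df7(self):
        assert round(t_from_r(0.62, 7), 2) == 2.09
        assert round(t_from_r(0.15, 7), 2) == 0.40

    def test_perfect_correlation_degenerates(self):
        res = pearson_corr_test([0, 1, 2, 3], [0, 2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.t == np.inf
        assert res.p == 0.0

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_corr_test(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.df == 18

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr_test([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestCohensD:
    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_paired([1.0, 1.0, 1.0])

    def test_two_point_closed_form(self):
        assert cohens_d_paired([0.0, 2.0]) == pytest.approx(1 / np.sqrt(2))

    def test_law_of_large_numbers(self):
        rng = np.random.default_rng(9)
        d = cohens_d_paired(rng.normal(1.13, 1.0, 100_000))
        assert abs(d - 1.13) < 0.01


class TestPowerMinN:
    def test_planned_sample_size(self):
        assert power_min_n(1.13, alpha=0.05, power_target=0.8, tails="one") == 7

    def test_noncentral_t_oracle_two_tailed(self):
        assert power_min_n(0.5, alpha=0.05, power_target=0.8, tails="two") == 34

    def test_floor_at_two(self):
        assert power_min_n(10.0) == 2

    def test_monotone_in_d_and_power(self):
        ns_d = [power_min_n(d) for d in (0.4, 0.6, 0.9, 1.3)]
        assert all(b <= a for a, b in zip(ns_d, ns_d[1:]))
        ns_p = [power_min_n(0.7, power_target=p) for p in (0.5, 0.8, 0.95)]
        assert all(b >= a for a, b in zip(ns_p, ns_p[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_min_n(-1.0)
        with pytest.raises(ValueError):
            power_min_n(0.5, alpha=1.2)
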