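"""Matching core: loosening, pools, match selection, imputation, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bmimatch.matching import (DonorIndex, DonorPool, LooseningExhausted,
                               MatchConfig, StatisticalMatchingModel,
                               SubgroupKey, apply_special_state_rule,
                               correct_survey, find_match, impute_measured,
                               index_donor_subgroups, loosen, run_iteration)
from bmimatch.survey import AGE_BANDS, DegenerateDatasetError, SurveyDataset
from conftest import make_donor_frame, make_recipient_frame


class TestMatchConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            MatchConfig(jitter_frac=0.2)
        with pytest.raises(ValueError):
            MatchConfig(n_iterations=0)
        with pytest.raises(ValueError):
            MatchConfig(bandwidth_step=0.0)
        with pytest.raises(ValueError):
            MatchConfig(min_subgroup_size=0)
        with pytest.raises(ValueError):
            MatchConfig(match_on="weight_only")

    def test_threshold_map_lookup(self):
        cfg = MatchConfig(min_subgroup_size={("male", "18-24"): 25, "female": 75})
        assert cfg.threshold_for("male", "18-24") == 25
        assert cfg.threshold_for("female", "40-44") == 75
        with pytest.raises(KeyError):
            cfg.threshold_for("male", "40-44")


class TestLoosen:
    def test_default_order_income_first(self):
        key = SubgroupKey.level0("male", "25-29", "hispanic", 2)
        out = loosen(key)
        assert out.income == "any" and out.race == "hispanic"
        assert out.loosen_level == 1

    def test_race_second(self):
        key = SubgroupKey("male", 1, 1, "hispanic", "any", loosen_level=1)
        out = loosen(key)
        assert out.race == "any" and out.loosen_level == 2

    def test_age_widens_one_band_each_side(self):
        key = SubgroupKey("male", 1, 1, "any", "any", loosen_level=2)
        out = loosen(key)
        assert (out.age_lo, out.age_hi) == (0, 2)  # 18-24 .. 30-34 union

    def test_age_widening_repeats_to_full_range(self):
        key = SubgroupKey("female", 6, 6, "any", "any")
        while not key.fully_loosened:
            key = loosen(key)
        assert (key.age_lo, key.age_hi) == (0, len(AGE_BANDS) - 1)

    def test_sex_never_changes(self):
        key = SubgroupKey.level0("female", "30-34", "nh_black", 4)
        for _ in range(20):
            if key.fully_loosened:
                break
            key = loosen(key)
            assert key.sex == "female"

    def test_exhausted_raises(self):
        key = SubgroupKey("male", 0, len(AGE_BANDS) - 1, "any", "any")
        with pytest.raises(LooseningExhausted):
            loosen(key)

    def test_any_nonblack_restriction_is_kept(self):
        key = SubgroupKey("male", 3, 3, "any_nonblack", 2)
        out = loosen(loosen(key))  # income, then the race move must skip
        assert out.race == "any_nonblack"


class TestHawaiiRule:
    cfg = MatchConfig()

    @pytest.mark.parametrize("race,state,expected_race", [
        ("other", "HI", "any_nonblack"),
        ("hispanic", "HI", "any_nonblack"),
        ("nh_black", "HI", "nh_black"),
        ("nh_white", "HI", "nh_white"),
        ("other", "OH", "other"),
    ])
    def test_rule_scope(self, race, state, expected_race):
        key = SubgroupKey.level0("female", "40-44", race, 3)
        out = apply_special_state_rule(key, state, self.cfg)
        assert out.race == expected_race

    def test_disabled_rule_is_identity(self):
        cfg = MatchConfig(hawaii_rule=False)
        key = SubgroupKey.level0("female", "40-44", "other", 3)
        assert apply_special_state_rule(key, "HI", cfg) == key


class TestDonorIndex:
    def test_level0_pool_not_flagged_above_threshold(self, rng):
        df = make_donor_frame(10, rng, sex="male", age_band="18-24",
                              race="nh_white", income=1)
        index = index_donor_subgroups(
            SurveyDataset(records=df, role="donor"),
            MatchConfig(min_subgroup_size=5))
        keys = index.level0_keys()
        assert len(keys) == 1
        key, size, flagged = keys[0]
        assert size == 10 and not flagged

    def test_small_pool_flagged_and_parent_resolves(self, rng):
        small = make_donor_frame(3, rng, income=2)
        big = make_donor_frame(20, rng, income=4)
        big["record_id"] = [f"B{i}" for i in range(20)]
        donor = SurveyDataset(records=pd.concat([small, big], ignore_index=True),
                              role="donor")
        index = index_donor_subgroups(donor, MatchConfig(min_subgroup_size=5))
        flagged = {k.income: f for k, _, f in index.level0_keys()}
        assert flagged[2] is True and flagged[4] is False
        pool = index.resolve(SubgroupKey.level0("male", "40-44", "nh_white", 2))
        assert pool.key.income == "any" and len(pool) == 23

    def test_pool_minimum_rank_is_half_its_weight_share(self, rng):
        df = make_donor_frame(6, rng)
        donor = SurveyDataset(records=df, role="donor")
        index = index_donor_subgroups(donor, MatchConfig(min_subgroup_size=5,
                                                         match_on="height_weight"))
        pool = index.pool(SubgroupKey.level0("male", "40-44", "nh_white", 3))
        i_min = int(np.argmin(df["self_height_cm"]))
        expected = 0.5 * pool.weights[i_min] / pool.weights.sum()
        assert pool.rank_h[i_min] == pytest.approx(expected)

    def test_exhausted_loosening_warns_and_uses_pool(self, rng):
        df = make_donor_frame(4, rng, sex="female")
        donor = SurveyDataset(records=df, role="donor")
        index = index_donor_subgroups(donor, MatchConfig(min_subgroup_size=50))
        with pytest.warns(UserWarning, match="donors"):
            pool = index.resolve(SubgroupKey.level0("female", "40-44", "nh_white", 3))
        assert len(pool) == 4

    def test_no_donors_of_sex_is_degenerate(self, rng):
        df = make_donor_frame(4, rng, sex="female")
        index = index_donor_subgroups(SurveyDataset(records=df, role="donor"),
                                      MatchConfig(min_subgroup_size=5))
        with pytest.raises(DegenerateDatasetError):
            index.resolve(SubgroupKey.level0("male", "40-44", "nh_white", 3))


def hand_pool(rank_pairs, weights):
    ranks = np.asarray(rank_pairs, float)
    n = len(ranks)
    return DonorPool(
        key=SubgroupKey.level0("male", "40-44", "nh_white", 3),
        indices=np.arange(n), weights=np.asarray(weights, float),
        rank_h=ranks[:, 0], rank_w=ranks[:, 1],
        measured_h=np.full(n, 170.0), measured_w=np.full(n, 80.0))


class TestFindMatch:
    def test_single_donor_forced(self):
        pool = hand_pool([(0.9, 0.9)], [2.0])
        idx, bw = find_match(0.1, 0.1, pool, MatchConfig(), np.random.default_rng(0))
        assert idx == 0

    def test_exact_tie_gives_zero_bandwidth(self):
        pool = hand_pool([(0.3, 0.7), (0.6, 0.2)], [1.0, 1.0])
        idx, bw = find_match(0.3, 0.7, pool, MatchConfig(), np.random.default_rng(0))
        assert idx == 0 and bw == 0.0

    def test_bandwidth_rounds_up_to_schedule(self):
        pool = hand_pool([(0.508, 0.5)], [1.0])
        _, bw = find_match(0.5, 0.5, pool, MatchConfig(bandwidth_step=0.005),
                           np.random.default_rng(0))
        assert bw == pytest.approx(0.010)

    def test_empty_pool_degenerate(self):
        pool = hand_pool([(0.5, 0.5)], [1.0])
        empty = DonorPool(key=pool.key, indices=np.empty(0, int),
                          weights=np.empty(0), rank_h=np.empty(0),
                          rank_w=np.empty(0), measured_h=np.empty(0),
                          measured_w=np.empty(0))
        with pytest.raises(DegenerateDatasetError):
            find_match(0.5, 0.5, empty, MatchConfig(), np.random.default_rng(0))


class TestImputeMeasured:
    def test_zero_jitter_identity(self):
        cfg = MatchConfig(jitter_frac=0.0)
        h, w = impute_measured(170.0, 80.0, cfg, np.random.default_rng(1))
        assert (h, w) == (170.0, 80.0)

    def test_bounds_always_hold(self):
        cfg = MatchConfig(jitter_frac=0.01)
        g = np.random.default_rng(2)
        for _ in range(500):
            h, w = impute_measured(170.0, 80.0, cfg, g)
            assert 168.3 - 1e-9 <= h <= 171.7 + 1e-9
            assert 79.2 - 1e-9 <= w <= 80.8 + 1e-9

    def test_jitter_is_mean_zero(self):
        cfg = MatchConfig(jitter_frac=0.01)
        g = np.random.default_rng(3)
        draws = np.array([impute_measured(170.0, 80.0, cfg, g)
                          for _ in range(100_000)])
        # uniform(-1%, 1%) jitter: SE of the mean ~ 170*0.01/sqrt(3)/316
        assert draws[:, 0].mean() == pytest.approx(170.0, abs=0.02)
        assert draws[:, 1].mean() == pytest.approx(80.0, abs=0.01)


class TestFit:
    def test_single_donor_pools_force_that_donor(self, rng):
        donor_df = make_donor_frame(1, rng)
        rec_df = make_recipient_frame(8, rng)
        cfg = MatchConfig(n_iterations=4, jitter_frac=0.0, min_subgroup_size=1)
        res = correct_survey(SurveyDataset(records=rec_df, role="recipient"),
                             SurveyDataset(records=donor_df, role="donor"),
                             cfg, seed=0)
        expected = (donor_df["measured_weight_kg"][0]
                    / (donor_df["measured_height_cm"][0] / 100) ** 2)
        np.testing.assert_allclose(res.corrected_bmi, expected)

    def test_same_seed_bitwise_identical(self, small_pair):
        donor, recipient = small_pair
        cfg = MatchConfig(n_iterations=5, min_subgroup_size=20)
        a = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=9)
        b = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=9)
        assert np.array_equal(a.corrected_bmi, b.corrected_bmi)

    def test_row_permutation_leaves_records_unchanged(self, small_pair):
        donor, recipient = small_pair
        cfg = MatchConfig(n_iterations=3, min_subgroup_size=20)
        base = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=4)
        shuffled = recipient.records.sample(frac=1.0, random_state=1).reset_index(drop=True)
        perm = StatisticalMatchingModel(
            SurveyDataset(records=shuffled, role="recipient"), donor, cfg).fit(seed=4)
        merged = base.corrected.merge(perm.corrected, on="record_id",
                                      suffixes=("_a", "_b"))
        np.testing.assert_array_equal(merged["corrected_bmi_a"],
                                      merged["corrected_bmi_b"])

    def test_run_iteration_equals_fit_column(self, small_pair):
        donor, recipient = small_pair
        cfg = MatchConfig(n_iterations=4, min_subgroup_size=20, keep_iterations=True)
        res = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=6)
        index = DonorIndex(donor, cfg)
        col = run_iteration(recipient, index, cfg, seed=6, iteration=2)
        np.testing.assert_array_equal(col, res.per_iteration[:, 2])

    def test_single_iteration_reduces_to_run_iteration(self, small_pair):
        donor, recipient = small_pair
        cfg = MatchConfig(n_iterations=1, min_subgroup_size=20)
        res = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=2)
        col = run_iteration(recipient, DonorIndex(donor, cfg), cfg, seed=2)
        np.testing.assert_array_equal(res.corrected_bmi, col)

    def test_corrected_mean_is_mean_of_iterations(self, small_pair):
        donor, recipient = small_pair
        cfg = MatchConfig(n_iterations=6, min_subgroup_size=20, keep_iterations=True)
        res = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=8)
        np.testing.assert_allclose(res.corrected_bmi,
                                   res.per_iteration.mean(axis=1))

    def test_corrected_within_jittered_donor_range(self, small_pair):
        donor, recipient = small_pair
        cfg = MatchConfig(n_iterations=5, min_subgroup_size=20)
        res = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=3)
        donor_bmi = donor.measured_bmi()
        j = cfg.jitter_frac
        lo = donor_bmi.min() * (1 - j) / (1 + j) ** 2
        hi = donor_bmi.max() * (1 + j) / (1 - j) ** 2
        assert res.corrected_bmi.min() >= lo
        assert res.corrected_bmi.max() <= hi

    def test_rank_concordance_within_subgroup(self, small_pair):
        donor, recipient = small_pair
        cfg = MatchConfig(n_iterations=10, min_subgroup_size=20)
        res = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=5)
        sub = res.corrected[res.corrected.sex == "male"]
        rho = stats.spearmanr(sub["self_bmi"], sub["corrected_bmi"]).statistic
        assert rho > 0.8

    def test_audit_fields_populated(self, small_pair):
        donor, recipient = small_pair
        cfg = MatchConfig(n_iterations=2, min_subgroup_size=20)
        res = StatisticalMatchingModel(recipient, donor, cfg).fit(seed=1)
        assert (res.corrected["final_loosen_level"] >= 0).all()
        assert (res.corrected["final_bandwidth"] >= 0).all()
        assert res.summary().startswith("Statistical matching")

    def test_role_mismatch_rejected(self, small_pair):
        donor, recipient = small_pair
        with pytest.raises(ValueError):
            StatisticalMatchingModel(donor, recipient)
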