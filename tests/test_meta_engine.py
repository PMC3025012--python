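import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from indirectmeta.meta_engine import (
    DegenerateTrialError,
    EffectEstimate,
    TwoArmTrial,
    dl_pool,
    pool_trials,
    read_trials_csv,
    trial_log_or,
)

from _oracles import dl_oracle, log_or_oracle


def make_effects(params):
    return [EffectEstimate(log_or=y, se=s) for y, s in params]


class TestTwoArmTrial:
    def test_rejects_event_count_above_arm_size(self):
        with pytest.raises(ValueError):
            TwoArmTrial("s", 11, 10, 0, 10)

    def test_rejects_non_integer_counts(self):
        with pytest.raises(TypeError):
            TwoArmTrial("s", 1.5, 10, 0, 10)

    def test_rejects_negative_and_zero_sizes(self):
        with pytest.raises(ValueError):
            TwoArmTrial("s", 0, 0, 0, 10)
        with pytest.raises(ValueError):
            TwoArmTrial("s", -1, 10, 0, 10)


class TestTrialLogOr:
    def test_identical_arms_give_null_log_or(self):
        e = trial_log_or(TwoArmTrial("s", 10, 100, 10, 100))
        assert e.log_or == 0.0
        assert not e.corrected

    def test_matches_direct_arithmetic(self):
        e = trial_log_or(TwoArmTrial("s", 10, 100, 5, 100))
        assert e.log_or == pytest.approx(math.log((10 / 90) / (5 / 95)), rel=1e-12)
        assert e.se == pytest.approx(math.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95), rel=1e-12)

    def test_zero_cell_triggers_correction_on_all_cells(self):
        e = trial_log_or(TwoArmTrial("s", 0, 50, 3, 50))
        assert e.corrected
        assert e.log_or == pytest.approx(math.log((0.5 / 50.5) / (3.5 / 47.5)), rel=1e-12)
        assert e.se == pytest.approx(
            math.sqrt(1 / 0.5 + 1 / 50.5 + 1 / 3.5 + 1 / 47.5), rel=1e-12
        )

    def test_double_zero_retained_as_null_effect_by_default(self):
        e = trial_log_or(TwoArmTrial("s", 0, 30, 0, 30))
        assert e.log_or == 0.0
        assert e.corrected

    def test_double_zero_dropped_under_switchable_policy(self):
        with pytest.raises(DegenerateTrialError):
            trial_log_or(TwoArmTrial("s", 0, 30, 0, 30), correction="drop-double-zero")
        with pytest.raises(DegenerateTrialError):
            trial_log_or(TwoArmTrial("s", 30, 30, 30, 30), correction="drop-double-zero")

    def test_single_participant_arm_is_degenerate(self):
        with pytest.raises(DegenerateTrialError):
            trial_log_or(TwoArmTrial("s", 0, 1, 3, 50))

    @given(
        a=st.integers(0, 40), c=st.integers(0, 40),
        n1=st.integers(2, 40), n2=st.integers(2, 40),
    )
    def test_agrees_with_oracle_on_random_tables(self, a, c, n1, n2):
        a, c = min(a, n1), min(c, n2)
        got = trial_log_or(TwoArmTrial("s", a, n1, c, n2))
        exp_y, exp_se = log_or_oracle(a, n1, c, n2)
        assert got.log_or == pytest.approx(exp_y, rel=1e-12, abs=1e-12)
        assert got.se == pytest.approx(exp_se, rel=1e-12)


class TestDlPool:
    def test_single_study_identity(self):
        r = dl_pool(make_effects([(0.3, 0.2)]))
        assert (r.pooled.log_or, r.pooled.se) == (0.3, 0.2)
        assert r.tau2_hat == 0.0 and r.q_stat == 0.0 and r.k == 1

    def test_two_equal_studies(self):
        r = dl_pool(make_effects([(0.5, 0.1), (0.5, 0.1)]))
        assert r.pooled.log_or == pytest.approx(0.5)
        assert r.q_stat == pytest.approx(0.0, abs=1e-12)
        assert r.tau2_hat == 0.0
        assert r.pooled.se == pytest.approx(0.1 / math.sqrt(2), rel=1e-12)

    def test_three_studies_match_hand_computation(self):
        params = [(0.2, 0.1), (0.6, 0.2), (-0.1, 0.15)]
        r = dl_pool(make_effects(params))
        exp_y, exp_se, exp_tau2, exp_q = dl_oracle(*zip(*params))
        assert r.pooled.log_or == pytest.approx(exp_y, rel=1e-12)
        assert r.pooled.se == pytest.approx(exp_se, rel=1e-12)
        assert r.tau2_hat == pytest.approx(exp_tau2, rel=1e-12)
        assert r.q_stat == pytest.approx(exp_q, rel=1e-12)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            dl_pool([])

    def test_oracle_agreement_on_many_random_instances(self, rng):
        for _ in range(150):
            k = int(rng.integers(2, 12))
            ys = rng.normal(0, 1, size=k)
            ses = rng.uniform(0.05, 1.0, size=k)
            r = dl_pool(make_effects(zip(ys, ses)))
            exp_y, exp_se, exp_tau2, exp_q = dl_oracle(list(ys), list(ses))
            assert r.pooled.log_or == pytest.approx(exp_y, rel=1e-10, abs=1e-10)
            assert r.pooled.se == pytest.approx(exp_se, rel=1e-10)
            assert r.tau2_hat == pytest.approx(exp_tau2, rel=1e-10, abs=1e-10)

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        checked = 0
        for _ in range(40):
            k = int(rng.integers(3, 10))
            ys = rng.normal(0, 1.2, size=k)
            ses = rng.uniform(0.05, 0.4, size=k)
            sm = combine_effects(ys, ses**2, method_re="dl")
            if float(sm.tau2) <= 0:  # statsmodels reports the untruncated moment
                continue
            r = dl_pool(make_effects(zip(ys, ses)))
            assert r.tau2_hat == pytest.approx(float(sm.tau2), rel=1e-8, abs=1e-10)
            assert r.pooled.log_or == pytest.approx(float(sm.mean_effect_re), rel=1e-8, abs=1e-10)
            assert r.pooled.se == pytest.approx(float(sm.sd_eff_w_re), rel=1e-8)
            checked += 1
        assert checked >= 15

    def test_tau2_truncated_at_zero_for_homogeneous_inputs(self):
        # Q <= k-1 here, so the moment estimate is negative before truncation
        r = dl_pool(make_effects([(0.10, 0.5), (0.11, 0.5), (0.12, 0.5)]))
        assert r.q_stat <= r.k - 1
        assert r.tau2_hat == 0.0

    def test_pooled_estimate_is_convex_combination(self, rng):
        for _ in range(30):
            ys = rng.normal(0, 1, size=5)
            ses = rng.uniform(0.1, 1.0, size=5)
            r = dl_pool(make_effects(zip(ys, ses)))
            assert ys.min() - 1e-12 <= r.pooled.log_or <= ys.max() + 1e-12
            assert r.pooled.se <= math.sqrt(ses.min() ** 2 + r.tau2_hat) + 1e-12

    @given(st.lists(
        st.tuples(st.floats(-2, 2), st.floats(0.05, 1.5)), min_size=2, max_size=8,
    ))
    def test_order_invariance_and_negation_symmetry(self, params):
        r = dl_pool(make_effects(params))
        r_rev = dl_pool(make_effects(params[::-1]))
        assert r.pooled.log_or == pytest.approx(r_rev.pooled.log_or, rel=1e-9, abs=1e-12)
        assert r.pooled.se == pytest.approx(r_rev.pooled.se, rel=1e-9)

        r_neg = dl_pool(make_effects([(-y, s) for y, s in params]))
        assert r_neg.pooled.log_or == pytest.approx(-r.pooled.log_or, rel=1e-9, abs=1e-12)
        assert r_neg.pooled.se == pytest.approx(r.pooled.se, rel=1e-9)
        assert r_neg.q_stat == pytest.approx(r.q_stat, rel=1e-9, abs=1e-12)
        assert r_neg.tau2_hat == pytest.approx(r.tau2_hat, rel=1e-9, abs=1e-12)


class TestPoolTrials:
    def test_single_null_trial(self):
        r = pool_trials([TwoArmTrial("s", 10, 100, 10, 100)])
        assert r.pooled.log_or == 0.0
        assert r.k == 1

    def test_identical_trials_are_homogeneous(self):
        trials = [TwoArmTrial(f"s{i}", 12, 80, 8, 80) for i in range(4)]
        r = pool_trials(trials)
        single = trial_log_or(trials[0])
        assert r.pooled.log_or == pytest.approx(single.log_or, rel=1e-12)
        assert r.q_stat == pytest.approx(0.0, abs=1e-10)
        assert r.tau2_hat == 0.0

    def test_composition_equals_manual_pipeline(self, rng):
        trials = [
            TwoArmTrial(f"s{i}", int(a), 50, int(c), 50)
            for i, (a, c) in enumerate(rng.integers(1, 49, size=(3, 2)))
        ]
        assert pool_trials(trials) == dl_pool([trial_log_or(t) for t in trials])

    def test_degenerate_trials_counted_not_fatal(self):
        trials = [TwoArmTrial("tiny", 0, 1, 0, 1), TwoArmTrial("ok", 10, 50, 5, 50)]
        r = pool_trials(trials)
        assert r.n_dropped == 1 and r.k == 1

    def test_all_degenerate_is_an_error(self):
        with pytest.raises(DegenerateTrialError):
            pool_trials([TwoArmTrial("tiny", 0, 1, 0, 1)])


class TestCsvInterface:
    def write(self, tmp_path, text):
        p = tmp_path / "trials.csv"
        p.write_text(text)
        return p

    def test_roundtrip(self, tmp_path):
        p = self.write(
            tmp_path,
            "study_id,comparison,events_trt,n_trt,events_ctrl,n_ctrl\n"
            "b1,BA,10,100,5,100\n"
            "c1,CA,8,60,9,60\n"
            "c2,CA,3,40,4,40\n",
        )
        groups = read_trials_csv(p)
        assert [t.study_id for t in groups["BA"]] == ["b1"]
        assert len(groups["CA"]) == 2
        assert groups["CA"][1] == TwoArmTrial("c2", 3, 40, 4, 40)

    def test_non_integer_count_is_an_error(self, tmp_path):
        p = self.write(
            tmp_path,
            "study_id,comparison,events_trt,n_trt,events_ctrl,n_ctrl\n"
            "b1,BA,10.5,100,5,100\n",
        )
        with pytest.raises(ValueError, match="non-integer"):
            read_trials_csv(p)

    def test_unknown_comparison_label_is_an_error(self, tmp_path):
        p = self.write(
            tmp_path,
            "study_id,comparison,events_trt,n_trt,events_ctrl,n_ctrl\n"
            "b1,BC,10,100,5,100\n",
        )
        with pytest.raises(ValueError, match="comparison"):
            read_trials_csv(p)

    def test_missing_column_is_an_error(self, tmp_path):
        p = self.write(tmp_path, "study_id,comparison,events_trt\nb1,BA,10\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_trials_csv(p)
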