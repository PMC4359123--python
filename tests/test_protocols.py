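import numpy as np
import pytest

import olfthresh as ot
from olfthresh.protocols import CensoredRunError, StaircaseRun, runs_to_table
from olfthresh.fixtures import HAND_TRACE_RESPONSES, HAND_TRACE_START


class TestConstantStimuli:
    def test_every_subject_gets_the_same_stimulus_multiset(self, proto16):
        table = ot.simulate_constant_stimuli([5.0, 9.0, 12.0], 1.12, proto16, seed=0)
        for _, g in table.groupby("subject_id"):
            assert sorted(g["dilution_step"]) == sorted(proto16.steps)

    def test_extreme_thresholds_hit_the_asymptotes(self, proto16):
        # a very high threshold detects every dilution; a very low one guesses
        sharp = ot.simulate_constant_stimuli([50.0] * 10, 1.12, proto16, seed=1)
        assert sharp["response"].mean() > 0.99
        blind = ot.simulate_constant_stimuli([-50.0] * 700, 1.12, proto16, seed=2)
        frac = blind["response"].mean()
        n = len(blind)
        assert abs(frac - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_fraction_correct_decreases_with_step(self, normosmic, proto16):
        rng = np.random.default_rng(5)
        t = normosmic.sample_thresholds(2000, rng)
        table = ot.simulate_constant_stimuli(t, normosmic.beta, proto16, rng)
        by_step = table.groupby("dilution_step")["response"].mean()
        # monotone decreasing on average (allow tiny sampling wiggle)
        assert (np.diff(by_step.to_numpy()) < 0.03).all()
        assert by_step.iloc[0] > 0.9 and by_step.iloc[-1] < 0.45

    def test_order_policy_does_not_change_response_law(self, normosmic):
        proto = ot.ConstantStimuliProtocol((2, 5, 8, 9, 12, 15),
                                           order_policy="random_per_subject")
        rng = np.random.default_rng(11)
        t = normosmic.sample_thresholds(4000, rng)
        shuffled = ot.simulate_constant_stimuli(t, normosmic.beta, proto, rng)
        fixed = ot.simulate_constant_stimuli(
            t, normosmic.beta, ot.ConstantStimuliProtocol((2, 5, 8, 9, 12, 15)),
            np.random.default_rng(12))
        a = shuffled.groupby("dilution_step")["response"].mean()
        b = fixed.groupby("dilution_step")["response"].mean()
        assert np.abs(a - b).max() < 0.03

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            ot.ConstantStimuliProtocol(())

    def test_target_position_schedule_recorded(self):
        proto = ot.ConstantStimuliProtocol((6, 5, 4), target_positions=(2, 1, 3))
        table = ot.simulate_constant_stimuli([2.0] * 4, 0.76, proto, seed=0)
        assert list(table["target_position"].unique()) == [2, 1, 3]


class TestStaircaseRules:
    def test_hand_traced_run(self):
        run = ot.replay_staircase(HAND_TRACE_RESPONSES, HAND_TRACE_START)
        assert run.reversal_steps == [9, 11, 9, 11, 9, 11, 9]
        assert run.terminated_by == "reversals"
        assert run.score == 10.0

    def test_confirmation_presentation_after_single_correct(self):
        run = ot.replay_staircase([1, 0, 0, 0], 15,
                                  ot.StaircaseProtocol(max_presentations=4))
        # correct at 15 -> re-present 15; incorrect -> move stronger
        assert [d for d, _ in run.presentations] == [15, 15, 14, 13]

    def test_always_incorrect_marches_to_strongest_and_censors(self):
        proto = ot.StaircaseProtocol(clamp=True, max_presentations=60)
        run = ot.replay_staircase([0] * 60, 16, proto)
        assert run.terminated_by == "cap" and run.censored
        assert len(run.reversal_steps) <= 1
        assert run.score == 1.0
        assert run.presentations[-1][0] == 1

    def test_always_correct_censors_at_weakest(self):
        proto = ot.StaircaseProtocol(clamp=True, max_presentations=60)
        run = ot.replay_staircase([1] * 60, 15, proto)
        assert run.censored and run.score == 16.0

    def test_unclamped_walk_may_leave_the_pen_range(self):
        run = ot.replay_staircase([0] * 40, 15,
                                  ot.StaircaseProtocol(max_presentations=40))
        assert run.presentations[-1][0] < 1

    @pytest.mark.parametrize("reversals,expected", [
        ([5, 6, 5, 6, 5, 6, 5], 5.5),
        ([2, 4, 2, 4, 2, 4, 2], 3.0),
        ([1, 2, 3, 16, 16, 16, 16], 16.0),
    ])
    def test_score_is_mean_of_last_four_reversals(self, reversals, expected):
        run = StaircaseRun(reversal_steps=list(reversals),
                           terminated_by="reversals")
        assert ot.score_staircase(run) == expected

    def test_too_few_reversals_is_censored_signal(self):
        run = StaircaseRun(reversal_steps=[4, 7], terminated_by="cap")
        with pytest.raises(CensoredRunError):
            ot.score_staircase(run)


class TestStaircaseSimulation:
    def test_clamped_scores_stay_inside_the_pen_range(self, normosmic):
        proto = ot.StaircaseProtocol(clamp=True)
        rng = np.random.default_rng(21)
        t = normosmic.sample_thresholds(500, rng)
        scores = ot.staircase_scores(
            ot.simulate_staircase(t, normosmic.beta, proto, rng))
        assert scores.min() >= proto.step_min
        assert scores.max() <= proto.step_max

    def test_mean_score_shows_small_positive_bias(self, normosmic):
        rng = np.random.default_rng(22)
        t = normosmic.sample_thresholds(4000, rng)
        scores = ot.staircase_scores(
            ot.simulate_staircase(t, normosmic.beta, ot.StaircaseProtocol(), rng))
        bias = scores.mean() - t.mean()
        assert 0.0 < bias < 1.0

    def test_seeded_runs_reproduce(self, nshap_gamma):
        t = nshap_gamma.sample_thresholds(50, seed=8)
        a = ot.simulate_staircase(t, nshap_gamma.beta, seed=9)
        b = ot.simulate_staircase(t, nshap_gamma.beta, seed=9)
        assert [r.presentations for r in a] == [r.presentations for r in b]

    def test_response_history_table(self):
        runs = [ot.replay_staircase(HAND_TRACE_RESPONSES, HAND_TRACE_START)]
        table = runs_to_table(runs)
        assert len(table) == len(runs[0].presentations)
        assert set(table.columns) >= {"subject_id", "presentation_index",
                                      "dilution_step", "response"}
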