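"""Error taxonomy, arcsine transform, within-subject statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_trial
from revpredict import scoring, task_engine
from revpredict.scoring import (
    DegenerateInputError,
    arcsine_transform,
    classify,
    paired_t,
    rm_anova_2x2,
    summarize,
)
from revpredict.task_engine import InputError


def reversal_sequence(error_run: int, tail_correct: int = 3):
    """Trials: 3 correct, a reversal, then `error_run` errors, then correct."""
    trials = [make_trial(i, correct=True) for i in range(3)]
    trials.append(make_trial(3, outcome_valence="punishment", correct=False,
                             expectedness="unexpected", stage_index=1))
    i = 4
    for _ in range(error_run):
        trials.append(make_trial(i, correct=False, stage_index=1))
        i += 1
    for _ in range(tail_correct):
        trials.append(make_trial(i, correct=True, stage_index=1))
        i += 1
    return trials


class TestClassify:
    def test_switch_then_two_perseverative(self):
        """Errors at t+1..t+3 after the unexpected outcome at t score as
        one switch error plus two perseverative errors."""
        scored = classify(reversal_sequence(error_run=3))
        cats = [s.category for s in scored]
        assert cats.count("reversal") == 1
        assert cats.count("switch") == 1
        assert cats.count("perseverative") == 2
        sw = scored[cats.index("switch")]
        assert not sw.trial.correct and sw.preceding_valence == "punishment"

    def test_correct_switch_trial_ends_the_episode(self):
        scored = classify(reversal_sequence(error_run=0))
        cats = [s.category for s in scored]
        assert cats.count("switch") == 1
        assert cats.count("perseverative") == 0
        assert scored[cats.index("switch")].trial.correct

    def test_block_without_reversals_is_all_non_switch(self):
        scored = classify([make_trial(i, correct=True) for i in range(10)])
        assert {s.category for s in scored} == {"non_switch"}

    def test_partition_complete_and_idempotent(self, reward_focused_agent, rng):
        b = task_engine.run_block(task_engine.BlockConfig(), reward_focused_agent, rng=rng)
        s1 = classify(b)
        s2 = classify(b)
        assert [x.category for x in s1] == [x.category for x in s2]
        assert len(s1) == len(b)
        assert all(s.category in scoring.CATEGORIES for s in s1)

    def test_out_of_order_trials_rejected(self):
        t = [make_trial(1), make_trial(0)]
        with pytest.raises(InputError):
            classify(t)

    def test_hand_built_twenty_trial_sequence(self):
        """Two reversals with distinct error structures, scored by hand:
        trial indices 0-19; reversal at 4 (UP) followed by a switch error
        and 2 perseverative errors; reversal at 13 (UR) followed by a
        correct switch trial; one lapse at 18."""
        t = []
        t += [make_trial(i, correct=True) for i in range(4)]  # 0-3
        t.append(make_trial(4, outcome_valence="punishment", correct=False,
                            expectedness="unexpected", stage_index=1))
        t.append(make_trial(5, correct=False, stage_index=1))  # switch error
        t += [make_trial(i, correct=False, stage_index=1) for i in (6, 7)]  # persev
        t += [make_trial(i, correct=True, stage_index=1) for i in range(8, 13)]
        t.append(make_trial(13, outcome_valence="reward", correct=False,
                            expectedness="unexpected", stage_index=2))
        t.append(make_trial(14, correct=True, stage_index=2))  # clean switch
        t += [make_trial(i, correct=True, stage_index=2) for i in range(15, 18)]
        t.append(make_trial(18, correct=False, stage_index=2))  # lapse
        t.append(make_trial(19, correct=True, stage_index=2))
        scored = classify(t)
        counts = summarize(scored).counts
        assert counts["n_reversals"] == 2
        assert counts["n_switch_trials"] == 2
        assert counts["n_switch_errors"] == 1
        assert counts["n_perseverative_errors"] == 2
        cats = [s.category for s in scored]
        assert cats.count("non_switch") == 20 - 2 - 2 - 2
        # the lapse at 18 is a plain non-switch error
        assert scored[18].category == "non_switch" and not scored[18].trial.correct


class TestArcsine:
    def test_boundary_identities(self):
        assert arcsine_transform(0.0) == 0.0
        assert arcsine_transform(1.0) == pytest.approx(math.pi)
        assert arcsine_transform(0.25) == pytest.approx(math.pi / 3, abs=1e-5)

    @pytest.mark.parametrize("x", [-0.1, 1.1])
    def test_out_of_range_rejected(self, x):
        with pytest.raises(InputError):
            arcsine_transform(x)

    @settings(derandomize=True, max_examples=60)
    @given(
        x=st.floats(min_value=0.0, max_value=1.0),
        y=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_and_reflection(self, x, y):
        if x < y:
            assert arcsine_transform(x) < arcsine_transform(y)
        assert arcsine_transform(1.0 - x) == pytest.approx(
            math.pi - arcsine_transform(x), abs=1e-9
        )


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_df_is_n_minus_one(self, rng):
        a = rng.normal(size=16)
        b = rng.normal(size=16)
        _, df, _ = paired_t(a, b)
        assert df == 15

    def test_matches_one_sample_oracle(self, rng):
        """Independent oracle: t = mean(d) / (sd(d)/sqrt(n)) computed from
        first principles on the differences."""
        for _ in range(20):
            n = int(rng.integers(3, 30))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            d = a - b
            t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            p_oracle = 2 * stats.t.sf(abs(t_oracle), n - 1)
            t, df, p = paired_t(a, b)
            assert t == pytest.approx(t_oracle, abs=1e-10)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_zero_variance_difference_raises(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestRmAnova:
    def test_constant_cells_give_zero_f(self):
        cells = np.tile([1.0, 1.0, 1.0, 1.0], (8, 1))
        res = rm_anova_2x2(cells)
        assert all(v[0] == 0.0 for v in res.values())

    def test_additive_structure_has_zero_interaction(self, rng):
        n = 10
        a = rng.normal(size=(n, 1))
        b = rng.normal(size=(n, 1))
        cells = np.hstack([a + b, a - b, -a + b, -a - b])  # purely additive
        res = rm_anova_2x2(cells)
        assert res["interaction"][0] == pytest.approx(0.0, abs=1e-18)

    def test_f_equals_squared_paired_t(self, rng):
        """Each effect's F must equal the squared paired t of the matching
        contrast (rows of the 2x2), to 1e-10."""
        cells = rng.normal(size=(16, 4))
        res = rm_anova_2x2(cells)
        pairs = {
            "main_A": ((cells[:, 0] + cells[:, 1]) / 2, (cells[:, 2] + cells[:, 3]) / 2),
            "main_B": ((cells[:, 0] + cells[:, 2]) / 2, (cells[:, 1] + cells[:, 3]) / 2),
            "interaction": (
                (cells[:, 0] + cells[:, 3]) / 2,
                (cells[:, 1] + cells[:, 2]) / 2,
            ),
        }
        for effect, (a, b) in pairs.items():
            t, df, p = paired_t(a, b)
            f, df1, df2, p_f = res[effect]
            assert f == pytest.approx(t**2, abs=1e-10)
            assert (df1, df2) == (1, 15)
            assert p_f == pytest.approx(p, abs=1e-10)

    def test_missing_cell_rejected(self):
        cells = np.ones((4, 4))
        cells[1, 2] = np.nan
        with pytest.raises(InputError):
            rm_anova_2x2(cells)


class TestSummarize:
    def test_stated_count_arithmetic(self):
        """54 switch trials with 12 errors give proportion 12/54 and its
        arcsine transform."""
        trials = []
        i = 0
        for k in range(54):
            trials.append(make_trial(i, outcome_valence="reward", correct=False,
                                     expectedness="unexpected", stage_index=k + 1))
            i += 1
            trials.append(make_trial(i, correct=(k >= 12), stage_index=k + 1))
            i += 1
            trials.append(make_trial(i, correct=True, stage_index=k + 1))
            i += 1
        summary = summarize(classify(trials))
        row = summary.error_rates.set_index("stratum").loc["switch"]
        assert row["n_trials"] == 54 and row["n_errors"] == 12
        assert row["proportion"] == pytest.approx(12 / 54)
        assert row["arcsine"] == pytest.approx(arcsine_transform(12 / 54))

    def test_empty_stratum_is_missing_not_zero(self):
        trials = [make_trial(i, correct=True) for i in range(6)]
        summary = summarize(classify(trials))
        row = summary.error_rates.set_index("stratum").loc["switch"]
        assert row["n_trials"] == 0
        assert np.isnan(row["proportion"]) and np.isnan(row["arcsine"])

    def test_noise_free_agent_all_zero_proportions(self, ideal_agent, rng):
        b = task_engine.run_block(task_engine.BlockConfig(), ideal_agent, rng=rng)
        summary = summarize(classify(b)[1:])  # drop the uninformed opener
        props = summary.error_rates["proportion"].dropna()
        assert (props == 0).all()

    def test_rt_means_exclude_error_and_too_late(self):
        trials = [
            make_trial(0, correct=True, rt_ms=600.0),
            make_trial(1, correct=False, rt_ms=900.0),
            make_trial(2, correct=True, response="too_late"),
            make_trial(3, correct=True, rt_ms=800.0),
        ]
        summary = summarize(classify(trials))
        row = summary.rt_means.set_index("cell").loc["non_switch"]
        assert row["n"] == 2 and row["mean_rt_ms"] == pytest.approx(700.0)

    def test_events_round_trip_matches_in_memory_scoring(self, rng):
        from revpredict import agents

        ag = agents.AgentParams(
            strategy="reward_focused", p_switch_error=0.4,
            p_persev_given_predict_punish=0.3, p_too_late=0.0,
        )
        blocks = [
            task_engine.run_block(task_engine.BlockConfig(), ag, rng=rng, block_id=b)
            for b in range(3)
        ]
        scored = []
        for b in blocks:
            scored.extend(scoring.classify(b))
        direct = summarize(scored)
        via_events = scoring.summarize_events(
            [task_engine.trials_to_events(b) for b in blocks]
        )
        assert direct.counts == via_events.counts
        assert np.allclose(
            direct.error_rates["proportion"],
            via_events.error_rates["proportion"],
            equal_nan=True,
        )
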