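"""Psychometric observer and the weighted up-down staircase."""

import numpy as np
import pytest

from imassess.perception_assay import (
    Observer,
    StaircaseConfig,
    StaircaseNonConvergence,
    StaircaseState,
    psychometric_prob,
    run_staircase,
    staircase_step,
)


@pytest.fixture
def observer():
    return Observer(threshold=40.0, slope=10.0, lapse_rate=0.02)


class TestPsychometric:
    def test_chance_level_at_zero_stimulus(self, observer):
        assert psychometric_prob(observer, 0.0) == pytest.approx(0.5, abs=1e-3)

    def test_asymptote_is_one_minus_lapse(self, observer):
        assert psychometric_prob(observer, 1e6) == pytest.approx(0.98, abs=1e-9)

    def test_target_probability_at_threshold(self, observer):
        # the parameterization pins psi(threshold) to the staircase target
        assert psychometric_prob(observer, 40.0) == pytest.approx(0.84, abs=1e-12)

    def test_monotone_in_stimulus(self, observer):
        xs = np.linspace(0, 90, 50)
        ps = [psychometric_prob(observer, x) for x in xs]
        assert all(p2 >= p1 for p1, p2 in zip(ps, ps[1:]))

    def test_negative_stimulus_rejected(self, observer):
        with pytest.raises(ValueError):
            psychometric_prob(observer, -1.0)

    def test_invalid_observer_rejected(self):
        with pytest.raises(ValueError):
            Observer(threshold=-5.0, slope=10.0)
        with pytest.raises(ValueError):
            Observer(threshold=40.0, slope=10.0, lapse_rate=0.5)


class TestStaircaseStep:
    def test_down_rule(self):
        cfg = StaircaseConfig()
        state = StaircaseState(stimulus=50.0)
        staircase_step(state, correct=True, cfg=cfg)
        assert state.stimulus == pytest.approx(48.0)

    def test_weighted_up_rule(self):
        # Kaernbach ratio p/(1-p) = 0.84/0.16 = 5.25, so step_up = 10.5
        cfg = StaircaseConfig()
        state = StaircaseState(stimulus=48.0)
        staircase_step(state, correct=False, cfg=cfg)
        assert state.stimulus == pytest.approx(58.5)

    def test_direction_change_appends_reversal(self):
        cfg = StaircaseConfig()
        state = StaircaseState(stimulus=50.0)
        staircase_step(state, True, cfg)  # down
        staircase_step(state, True, cfg)  # down
        assert state.reversal_stimuli == []
        staircase_step(state, False, cfg)  # up: reversal at 46
        assert state.reversal_stimuli == [pytest.approx(46.0)]

    def test_step_ratio_enforced(self):
        with pytest.raises(ValueError):
            StaircaseConfig(step_down=2.0, step_up=4.0)

    def test_clamp_saturation_is_not_a_reversal(self):
        cfg = StaircaseConfig(start_stimulus=89.0)
        state = StaircaseState(stimulus=89.0)
        staircase_step(state, False, cfg)  # would go to 99.5, clamps to 90
        staircase_step(state, False, cfg)  # saturated: no move at all
        staircase_step(state, True, cfg)  # down from the clamp
        assert state.reversal_stimuli == []

    def test_step_on_terminated_state_rejected(self):
        cfg = StaircaseConfig()
        state = StaircaseState(stimulus=50.0, terminated=True)
        with pytest.raises(RuntimeError):
            staircase_step(state, True, cfg)


class TestRunStaircase:
    def test_terminates_at_23_reversals(self, observer):
        result = run_staircase(observer, seed=1)
        assert len(result.reversal_stimuli) == 23

    def test_jnd_is_mean_of_last_16_reversals(self, observer):
        result = run_staircase(observer, seed=2)
        assert result.jnd == pytest.approx(np.mean(result.reversal_stimuli[7:]))

    def test_step_observer_valley_reversals_bracket_threshold(self):
        # a near-deterministic observer with a step at 30 degrees: the
        # down->up reversal valleys must lie within one step_down below it
        theta = 30.0
        cfg = StaircaseConfig()
        state = StaircaseState(stimulus=cfg.start_stimulus)
        while not state.terminated:
            staircase_step(state, state.stimulus >= theta, cfg)
        # a valley reversal is an incorrect response after descending
        valleys = [s for (s, correct, rev) in state.trial_log if rev and not correct]
        assert valleys, "no valley reversals recorded"
        for v in valleys:
            assert theta - cfg.step_down <= v < theta + cfg.step_down

    def test_convergence_to_target_probability(self, observer):
        # the weighted rule's stationary point is the psi = 0.84 stimulus
        ps = []
        for seed in range(1, 101):
            r = run_staircase(observer, seed=seed)
            ps.append(psychometric_prob(observer, r.jnd))
        assert np.mean(ps) == pytest.approx(0.84, abs=0.02)

    def test_monotone_validity(self):
        # larger true thresholds give stochastically larger JND estimates
        jnds = {}
        for theta in (25.0, 55.0):
            obs = Observer(threshold=theta, slope=8.0, lapse_rate=0.02)
            jnds[theta] = np.mean([run_staircase(obs, seed=s).jnd for s in range(40)])
        assert jnds[25.0] < jnds[55.0]

    def test_non_convergence_raises(self, observer):
        cfg = StaircaseConfig(max_trials=5)
        with pytest.raises(StaircaseNonConvergence):
            run_staircase(observer, cfg, seed=0)

    def test_seed_reproducibility(self, observer):
        r1 = run_staircase(observer, seed=9)
        r2 = run_staircase(observer, seed=9)
        assert r1 == r2
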