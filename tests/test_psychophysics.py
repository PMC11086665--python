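"""Staircase rules, trial construction, and experiment bookkeeping."""

import numpy as np
import pytest

import cttexture as ct
from cttexture.errors import InfeasibleTargetError
from cttexture.psychophysics import StaircaseState, _NPSCache, make_trial

from conftest import BODY, LUNG, SPACING


class StepObserver:
    """Always correct above a switch point, at chance below it."""

    kind = "step"

    def __init__(self, theta, seed=0):
        self.theta = theta
        self._rng = np.random.default_rng(seed)

    def p_correct(self, offset_vector):
        mag = float(np.hypot(*offset_vector))
        return 1.0 if mag > self.theta else 0.5


class AlwaysCorrectObserver:
    kind = "oracle"

    def p_correct(self, offset_vector):
        return 1.0


def new_state(cfg=None, offset=1.0, **kw):
    cfg = cfg or ct.StaircaseConfig(start_offset=offset)
    return StaircaseState(config=cfg, offset=offset, **kw)


class TestStaircaseUpdate:
    def test_three_correct_steps_down(self):
        st = new_state()
        for _ in range(3):
            ct.staircase_update(st, True)
        assert st.offset == pytest.approx(0.85)
        assert st.consecutive_correct == 0

    def test_error_steps_up_and_resets_counter(self):
        st = new_state()
        ct.staircase_update(st, True)
        ct.staircase_update(st, True)
        ct.staircase_update(st, False)
        assert st.offset == pytest.approx(1.15)
        assert st.consecutive_correct == 0

    def test_reversal_logged_on_direction_change(self):
        st = new_state()
        for resp in (True, True, True, False):
            ct.staircase_update(st, resp)
        assert st.n_reversals == 1
        assert st.trials[3].reversal
        # reversal records the offset presented at the reversing trial
        assert st.reversal_offsets[0] == pytest.approx(0.85)

    def test_reciprocal_down_step_mode(self):
        cfg = ct.StaircaseConfig(start_offset=1.0, step_down_mode="reciprocal")
        st = new_state(cfg)
        for _ in range(3):
            ct.staircase_update(st, True)
        assert st.offset == pytest.approx(1.0 / 1.15)

    def test_trajectory_reconstructs_response_sequence(self):
        rng = np.random.default_rng(4)
        st = new_state()
        responses = [bool(rng.random() < 0.7) for _ in range(60)]
        for r in responses:
            ct.staircase_update(st, r)
        # replay the log: offsets must follow deterministically from responses
        offset, cc = 1.0, 0
        for rec, resp in zip(st.trials, responses):
            assert rec.offset == pytest.approx(offset)
            assert rec.correct == resp
            if resp:
                cc += 1
                if cc == 3:
                    offset *= 0.85
                    cc = 0
            else:
                offset *= 1.15
                cc = 0
        assert all(t.offset > 0 for t in st.trials)


class TestMakeTrial:
    def test_zero_offset_shares_one_spectrum(self):
        cache = _NPSCache(32, SPACING)
        tr = make_trial(BODY, ct.canonical_directions()[0], 0.0,
                        np.random.SeedSequence(1), grid_size=32, cache=cache)
        assert np.allclose(tr.ref_hypothesis.S, tr.alt_hypothesis.S)

    def test_offset_patch_has_shifted_peak(self):
        alpha, beta = ct.solve_model_params(BODY[0] + 1.0, BODY[1])
        d = ct.characterize(ct.model_nps1d(alpha, beta))
        assert d.f_peak == pytest.approx(2.89, abs=0.02)

    def test_infeasible_negative_sigma_offset(self):
        down_sigma = ct.canonical_directions()[3]  # -sigma only
        with pytest.raises(InfeasibleTargetError):
            make_trial(LUNG, down_sigma, 2.0, np.random.SeedSequence(1),
                       grid_size=32)

    def test_correct_index_seed_determinism(self):
        cache = _NPSCache(32, SPACING)
        a = make_trial(BODY, ct.canonical_directions()[0], 0.3,
                       np.random.SeedSequence(9), grid_size=32, cache=cache)
        b = make_trial(BODY, ct.canonical_directions()[0], 0.3,
                       np.random.SeedSequence(9), grid_size=32, cache=cache)
        assert a.correct_index == b.correct_index
        assert np.array_equal(a.reference.values, b.reference.values)


class TestRunStaircase:
    def test_step_observer_converges_to_switch_point(self):
        theta = 0.5
        cfg = ct.StaircaseConfig(start_offset=4.0)
        direc = ct.canonical_directions()[0]
        estimates = []
        for i in range(50):
            obs = StepObserver(theta, seed=i)
            res = ct.run_staircase(cfg, BODY, direc, obs,
                                   np.random.SeedSequence([21, i]))
            estimates.append(res.estimate)
        med = float(np.median(estimates))
        assert theta * 0.85 ** 2 <= med <= theta * 1.15 ** 2

    def test_always_correct_observer_hits_floor_guard(self):
        cfg = ct.StaircaseConfig(start_offset=1.0, max_trials=120)
        res = ct.run_staircase(cfg, BODY, ct.canonical_directions()[0],
                               AlwaysCorrectObserver(),
                               np.random.SeedSequence(3))
        assert "max_trials_guard" in res.flags
        assert "floor_hit" in res.flags

    def test_offsets_move_only_by_step_factors(self):
        obs = ct.PsychometricObserver(threshold=0.3, seed=1)
        cfg = ct.StaircaseConfig(start_offset=1.0)
        res = ct.run_staircase(cfg, BODY, ct.canonical_directions()[0], obs,
                               np.random.SeedSequence(17))
        offsets = [t.offset for t in res.trials]
        for a, b in zip(offsets, offsets[1:]):
            ratio = b / a
            assert min(abs(ratio - 0.85), abs(ratio - 1.15),
                       abs(ratio - 1.0)) < 1e-9

    def test_persistent_ceiling_flags_no_threshold(self):
        # chance-level observer against a tight feasibility cap
        class ChanceObserver:
            kind = "chance"

            def p_correct(self, offset_vector):
                return 0.5

        cfg = ct.StaircaseConfig(start_offset=1.5, max_trials=400)
        direc = ct.canonical_directions()[3]  # -sigma; cap near sigma_ref
        res = ct.run_staircase(cfg, BODY, direc, ChanceObserver(),
                               np.random.SeedSequence(8))
        assert "no_threshold" in res.flags


class TestRunExperiment:
    def test_threshold_averages_last_five_of_six(self):
        obs = ct.PsychometricObserver(threshold=0.3)
        cfg = ct.StaircaseConfig(start_offset=1.0)
        res = ct.run_experiment(cfg, BODY, ct.canonical_directions()[:1],
                                obs, master_seed=5)
        t = res.thresholds[0]
        assert len(t.repetition_estimates) == 6
        assert t.threshold == pytest.approx(
            np.mean(t.repetition_estimates[1:]))
        assert t.d_fpeak == pytest.approx(t.threshold)
        assert t.d_sigma == 0.0

    def test_master_seed_determinism(self):
        cfg = ct.StaircaseConfig(start_offset=1.0)
        dirs = ct.canonical_directions()[:2]
        r1 = ct.run_experiment(cfg, BODY, dirs,
                               ct.PsychometricObserver(threshold=0.3), 42)
        r2 = ct.run_experiment(cfg, BODY, dirs,
                               ct.PsychometricObserver(threshold=0.3), 42)
        assert all(t1.threshold == t2.threshold
                   for t1, t2 in zip(r1.thresholds, r2.thresholds))

    def test_canonical_directions_are_unit_and_complete(self):
        dirs = ct.canonical_directions()
        assert [d.index for d in dirs] == list(range(1, 9))
        for d in dirs:
            assert np.hypot(d.u_fpeak, d.u_sigma) == pytest.approx(1.0)
        vecs = {(round(d.u_fpeak, 6), round(d.u_sigma, 6)) for d in dirs}
        assert len(vecs) == 8
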