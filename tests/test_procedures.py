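"""Controller state machines: placement rules, step schedules, estimators."""

import math

import numpy as np
import pytest

import attentrack.procedures as P
from attentrack.observers import ObserverSpec, StepObserver
from attentrack.procedures import (
    ABORT,
    CONTINUE,
    StimulusSpec,
    detect_reversals,
    make_procedure,
)
from conftest import track_rng


class TestDetectReversals:
    @pytest.mark.parametrize("levels, expected", [
        ([40, 36, 32, 34], [3]),            # single flip
        ([40, 38, 36, 34], []),             # monotone
        ([40, 36, 36, 40, 36], [3, 4]),     # zero change inherits direction
        ([40], []),
        ([], []),
    ])
    def test_examples(self, levels, expected):
        assert detect_reversals(levels) == expected

    def test_matches_incremental_track_scan(self):
        rng = np.random.default_rng(5)
        levels = np.cumsum(rng.choice([-2, 0, 2], size=60)) + 40.0
        state = P.TrackState()
        for lv in levels:
            state.record_level(lv)
        revs = detect_reversals(list(levels))
        assert state.first_reversal == (revs[0] if revs else None)


class TestSIUD:
    def _state(self, probe, prev=None, step=10.0, bracketed=False):
        return P.SiudState(probe=probe, prev_probe=prev if prev is not None else probe,
                           step=step, bracketed=bracketed)

    def test_zero_response_raises_probe_by_step(self):
        proc, state = make_procedure("siud"), self._state(40.0)
        proc.update(state, StimulusSpec(40.0, 50.0), 0)
        assert state.probe == 50.0

    def test_two_response_lowers_probe_by_step(self):
        proc, state = make_procedure("siud"), self._state(40.0)
        proc.update(state, StimulusSpec(40.0, 50.0), 2)
        assert state.probe == 30.0

    def test_first_one_response_goes_to_midpoint_and_refines_step(self):
        proc = make_procedure("siud")
        state = self._state(30.0, prev=40.0)
        proc.update(state, StimulusSpec(30.0, 40.0), 1)
        assert state.probe == 35.0
        assert state.step == 2.0 and state.bracketed

    def test_after_bracketing_one_and_zero_both_raise(self):
        proc = make_procedure("siud")
        for resp in (0, 1):
            state = self._state(20.0, step=2.0, bracketed=True)
            proc.update(state, StimulusSpec(20.0, 30.0), resp)
            assert state.probe == 22.0

    def test_catch_false_alarm_aborts_and_otherwise_no_change(self):
        proc = make_procedure("siud")
        state = self._state(40.0)
        catch = StimulusSpec(40.0, None, is_catch=True)
        assert proc.update(state, catch, 1) == CONTINUE
        assert state.probe == 40.0 and state.levels == []
        assert proc.update(state, catch, 2) == ABORT

    def test_cue_rides_10_db_above_probe(self):
        proc = make_procedure("siud")
        rng = track_rng(1)
        state = proc.start(rng)
        for _ in range(40):
            stim = proc.next_stimulus(state, rng)
            if not stim.is_catch:
                assert stim.cue_level == stim.probe_level + 10.0
            proc.update(state, stim, int(rng.integers(0, 3)))


class TestGRaBr:
    def _state(self, probe, cue, **kw):
        return P.GrabrState(probe=probe, cue=cue, delta=cue - probe, **kw)

    def test_two_response_shifts_pair_down_preserving_gap(self):
        proc = make_procedure("grabr")
        state = self._state(40.0, 50.0)
        proc.update(state, StimulusSpec(40.0, 50.0), 2)
        assert (state.probe, state.cue) == (32.0, 42.0)

    def test_first_one_response_halves_gap_about_midpoint(self):
        proc = make_procedure("grabr")
        state = self._state(40.0, 50.0)
        proc.update(state, StimulusSpec(40.0, 50.0), 1)
        assert (state.probe, state.cue) == (42.5, 47.5)
        assert state.delta == 5.0

    def test_second_one_response_narrows_gap_to_2_db_for_good(self):
        proc = make_procedure("grabr")
        state = self._state(40.0, 50.0)
        for _ in range(3):
            proc.update(state, StimulusSpec(state.probe, state.cue), 1)
        assert state.delta == 2.0
        assert state.cue - state.probe == pytest.approx(2.0)

    def test_gap_schedule_is_non_increasing_along_a_track(self):
        proc = make_procedure("grabr")
        obs = ObserverSpec.of("short_term", "NC", 0.1)
        rng = track_rng(9)
        state = proc.start(rng)
        gaps = []
        for _ in range(80):
            stim = proc.next_stimulus(state, rng)
            resp = proc.respond(stim, obs, rng)
            if proc.update(state, stim, resp) == ABORT:
                state = proc.start(rng)
                continue
            if not stim.is_catch:
                gaps.append(state.cue - state.probe)
                assert state.cue - state.probe in (10.0, 5.0, 2.0)

    def test_step_schedule_follows_8_6_3_1_after_bracketing(self):
        proc = make_procedure("grabr")
        state = self._state(20.0, 30.0)
        state.one_count = 1  # bracketed
        moves = []
        for resp in (2, 0, 2, 0, 2):  # alternate: every move after the first reverses
            before = state.probe
            proc.update(state, StimulusSpec(state.probe, state.cue), resp)
            moves.append(abs(state.probe - before))
        assert moves == [8.0, 6.0, 3.0, 1.0, 1.0]

    def test_direction_flips_before_bracketing_keep_the_search_step(self):
        proc = make_procedure("grabr")
        state = self._state(20.0, 30.0)
        for resp in (2, 0, 2, 0):
            proc.update(state, StimulusSpec(state.probe, state.cue), resp)
        assert state.reversals == 0

    def test_estimate_pools_probe_and_cue_levels(self):
        proc = make_procedure("grabr")
        state = self._state(14.0, 16.0)
        state.first_reversal = 0
        state.pair_levels = [(14.0, 16.0), (13.0, 15.0)]
        assert proc.estimate(state) == pytest.approx(14.5)


class TestAPTA:
    def test_deterministic_listener_terminates_at_threshold(self):
        proc = make_procedure("apta")
        det = StepObserver(15.0)
        rng = track_rng(2)
        state = proc.start(rng)
        for _ in range(60):
            stim = proc.next_stimulus(state, rng)
            if proc.update(state, stim, det.yes_no(stim.probe_level, rng)) == P.TERMINATED:
                break
        assert state.terminated
        assert len(state.yes_levels) == 7
        assert proc.estimate(state) == 15.0

    def test_all_no_ascends_monotonically_without_terminating(self):
        proc = make_procedure("apta")
        rng = track_rng(3)
        state = proc.start(rng)
        seen = []
        for _ in range(30):
            stim = proc.next_stimulus(state, rng)
            seen.append(stim.probe_level)
            assert proc.update(state, stim, False) == CONTINUE
        assert seen == sorted(seen) and not state.terminated


class TestSIAM:
    def test_adjustment_matrix_for_t075(self):
        m = make_procedure("siam").matrix
        assert m == {"hit": -1.0, "miss": 3.0, "false_alarm": 4.0,
                     "correct_rejection": 0.0}

    def test_matrix_for_t05_override(self):
        m = make_procedure("siam", t=0.5).matrix
        assert m == {"hit": -1.0, "miss": 1.0, "false_alarm": 2.0,
                     "correct_rejection": 0.0}

    @pytest.mark.parametrize("t", [0.5, 0.625, 0.75, 0.9])
    def test_signal_trial_drift_vanishes_at_target(self, t):
        m = make_procedure("siam", t=t).matrix
        assert t * m["hit"] + (1 - t) * m["miss"] == pytest.approx(0.0, abs=1e-12)

    def test_hit_and_correct_rejection_updates(self):
        proc = make_procedure("siam")
        state = P.SiamState(level=40.0)
        proc.update(state, StimulusSpec(40.0, signal_present=True), True)   # hit
        assert state.level == 36.0
        proc.update(state, StimulusSpec(36.0, signal_present=False), False)  # CR
        assert state.level == 36.0

    def test_step_schedule_4_2_1_keyed_to_reversals(self):
        proc = make_procedure("siam")
        state = P.SiamState(level=40.0)
        sig = StimulusSpec(0.0, signal_present=True)
        deltas = []
        for yes in (True, False, True, False, True):  # alternate hit/miss
            before = state.level
            proc.update(state, sig, yes)
            deltas.append(abs(state.level - before))
        # hit(-4), miss(rev1 +12), hit(rev2 -2), miss(rev3 +3), hit(-1)
        assert deltas == [4.0, 12.0, 2.0, 3.0, 1.0]


class TestBayesianProcedures:
    def test_quest_first_trial_is_range_midpoint(self):
        proc = make_procedure("quest_plus")
        state = proc.start(track_rng(1))
        assert proc.next_stimulus(state, track_rng(1)).probe_level == 20.0

    def test_quest_yes_at_high_level_shifts_posterior_down(self):
        proc = make_procedure("quest_plus")
        state = proc.start(track_rng(1))
        prior_mean = float(state.posterior @ proc.l50_grid)
        proc.update(state, StimulusSpec(50.0), True)
        assert float(state.posterior @ proc.l50_grid) < prior_mean

    def test_quest_opposite_responses_peak_at_the_level(self):
        proc = make_procedure("quest_plus")
        state = proc.start(track_rng(1))
        proc.update(state, StimulusSpec(23.0), True)
        proc.update(state, StimulusSpec(23.0), False)
        assert proc.estimate(state) == 23.0  # argmax of p(1-p) over the grid

    def test_quest_degenerate_posterior_ties_break_low(self):
        proc = make_procedure("quest_plus")
        state = proc.start(track_rng(1))
        point = np.zeros_like(state.posterior)
        point[np.searchsorted(proc.l50_grid, 15.0)] = 1.0
        state.posterior = point
        state.n_done = 1
        stim = proc.next_stimulus(state, track_rng(1))
        assert stim.probe_level == proc.stim_grid[0]

    def test_posterior_stays_normalized_and_levels_in_range(self):
        obs = ObserverSpec.of("short_term", "NC", 0.1)
        for key in ("quest_plus", "uml", "mlp"):
            proc = make_procedure(key)
            rng = track_rng(4)
            state = proc.start(rng)
            for _ in range(50):
                stim = proc.next_stimulus(state, rng)
                assert -10.0 <= stim.probe_level <= 50.0
                proc.update(state, stim, obs.yes_no(stim.probe_level, rng))
                if hasattr(state, "posterior"):
                    assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mlp_single_yes_selects_lowest_l50(self):
        proc = make_procedure("mlp", p_min_hypotheses=(0.0,))
        state = proc.start(track_rng(1))
        proc.update(state, StimulusSpec(30.0), True)
        # argmax likelihood = hypothesis with highest p(yes|30) = lowest L50
        assert state.next_level == pytest.approx(-8.927, abs=1e-3)

    def test_mlp_recovers_level_from_alternating_responses(self):
        proc = make_procedure("mlp", p_min_hypotheses=(0.0,))
        state = proc.start(track_rng(1))
        for i in range(60):
            proc.update(state, StimulusSpec(18.0), i % 2 == 0)
        best = proc._l50[int(np.argmax(state.loglik))]
        assert best == pytest.approx(18.0, abs=0.11)

    def test_mlp_estimate_is_median_of_presented_levels(self):
        proc = make_procedure("mlp")
        state = proc.start(track_rng(1))
        for lv, yes in [(40.0, True), (10.0, False), (16.0, True)]:
            proc.update(state, StimulusSpec(lv), yes)
        assert proc.estimate(state) == 16.0

    def test_uml_point_mass_targets(self):
        proc = make_procedure("uml")
        state = proc.start(track_rng(1))
        point = np.zeros_like(state.posterior)
        point[np.searchsorted(proc.l50_grid, 15.0)] = 1.0
        state.posterior = point
        # two consecutive yes -> lower target = posterior-mean L50 itself
        proc.update(state, StimulusSpec(15.0), True)
        proc.update(state, StimulusSpec(15.0), True)
        assert state.next_level == pytest.approx(15.0)
        # a no -> upper target at the 75% point: 15 + ln 3 / 0.5
        proc.update(state, StimulusSpec(15.0), False)
        assert state.next_level == pytest.approx(15.0 + math.log(3.0) / 0.5, abs=1e-9)


class TestThresholdEstimators:
    def test_constant_track_estimates_its_level(self):
        proc = make_procedure("siam")
        state = P.SiamState(level=15.0)
        for lv in [16, 15, 15, 15]:
            state.record_level(float(lv))
        state.first_reversal = 1
        assert proc.estimate(state) == 15.0

    def test_siam_median_discards_pre_reversal_trials(self):
        proc = make_procedure("siam")
        state = P.SiamState(level=0.0)
        for lv in [40, 36, 32, 36, 34, 36]:
            state.record_level(float(lv))
        assert state.first_reversal == 3
        assert proc.estimate(state) == 36.0

    def test_monotone_track_falls_back_to_all_levels(self):
        proc = make_procedure("siam")
        state = P.SiamState(level=0.0)
        for lv in [40, 38, 36, 34]:
            state.record_level(float(lv))
        assert state.first_reversal is None
        assert proc.estimate(state) == 37.0

    def test_unknown_procedure_key_rejected(self):
        with pytest.raises(ValueError):
            make_procedure("staircase_9000")
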