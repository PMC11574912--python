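"""Adaptive threshold-tracking procedures.

Seven controllers are implemented, each deciding the next stimulus from the
response history and supplying its own threshold estimator:

======== ===================================================== ==========
key      placement rule                                        intervals
======== ===================================================== ==========
siud     single-interval up/down with a +10 dB cue tone and a
         0/1/2 tone-counting task; 20% catch trials            2
grabr    graded-response bracketing: like SIUD but the
         probe/cue gap shrinks (10 -> 5 -> 2 dB) on "one tone"
         responses, re-centred on the previous pair midpoint   2
apta     automated pure-tone audiometry (modified
         Hughson-Westlake ascending method)                    1
quest_plus Bayesian posterior over L50; next level minimises
         the expected posterior entropy                        1
mlp      maximum-likelihood procedure: ML hypothesis, next
         level at its p-target (0.6310)                        1
uml      updated maximum-likelihood: Bayesian posterior with a
         2-down/1-up sweet-point overlay                       1
siam     single-interval adjustment matrix (t = 0.75)          1
======== ===================================================== ==========

Every controller exposes the same surface: ``start`` (fresh track state),
``next_stimulus``, ``respond`` (delegates to the observer with the
task appropriate for the procedure), ``update`` (state transition,
returning ``"continue"``, ``"abort"`` or ``"terminated"``) and
``estimate`` (interim/final threshold from the current state).  The
engine interleaves these into complete Monte-Carlo tracks.

Threshold estimators follow the per-procedure conventions: staircases
(siud/grabr/siam) take the median of main-track levels from the first
reversal onward, MLP the median of all presented levels, QUEST+ the
posterior mode, UML the posterior mean, and APTA the level of the last
"yes" response.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import expit, xlogy

from .observers import PsychometricParams, pf_eval, pf_inverse

__all__ = [
    "CONTINUE",
    "ABORT",
    "TERMINATED",
    "StimulusSpec",
    "detect_reversals",
    "AdaptiveProcedure",
    "SIUD",
    "GRaBr",
    "APTA",
    "QuestPlus",
    "MLP",
    "UML",
    "SIAM",
    "PROCEDURE_CLASSES",
    "DISPLAY_NAMES",
    "make_procedure",
]

CONTINUE = "continue"
ABORT = "abort"
TERMINATED = "terminated"

#: per-trial time budget (s): tone 0.5 s + response 1 s for one-interval
#: tasks; two tones + 0.5 s pause + response for two-tone tasks.
TAU_ONE_INTERVAL = 1.5
TAU_TWO_TONE = 2.5

STIM_RANGE = (-10.0, 50.0)
START_RANGE = (35, 45)  # discrete uniform starting levels, 1 dB spacing


@dataclass(frozen=True)
class StimulusSpec:
    """One presentation: probe level, optional cue slot (two-tone tasks;
    ``None`` = muted), signal flag (yes/no detection tasks) and whether
    the trial is a catch trial."""

    probe_level: float
    cue_level: Optional[float] = None
    signal_present: bool = True
    is_catch: bool = False


def detect_reversals(levels: Sequence[float]) -> List[int]:
    """Indices at which the track direction flips.

    A reversal is a trial whose level change has the opposite sign of the
    previous non-zero change; zero changes inherit the prior direction.
    Monotone (or too short) sequences yield an empty list.
    """
    out: List[int] = []
    last = 0
    for i in range(1, len(levels)):
        d = levels[i] - levels[i - 1]
        sign = int(d > 0) - int(d < 0)
        if sign == 0:
            continue
        if last != 0 and sign != last:
            out.append(i)
        last = sign
    return out


@dataclass
class TrackState:
    """State shared by all controllers: the main-track level log plus
    first-reversal bookkeeping for the median estimators."""

    levels: List[float] = field(default_factory=list)
    terminated: bool = False
    # incremental first-reversal scan (avoids rescanning on every interim
    # estimate); mirrors detect_reversals on self.levels
    _scan_dir: int = 0
    first_reversal: Optional[int] = None

    def record_level(self, level: float) -> None:
        if self.levels:
            d = level - self.levels[-1]
            sign = int(d > 0) - int(d < 0)
            if sign != 0:
                if self._scan_dir != 0 and sign != self._scan_dir and self.first_reversal is None:
                    self.first_reversal = len(self.levels)
                self._scan_dir = sign
        self.levels.append(level)

    def median_post_reversal(self) -> float:
        """Median of levels from the first reversal onward; falls back to
        the median of all levels if the track never reversed."""
        if self.first_reversal is None:
            return float(np.median(self.levels))
        return float(np.median(self.levels[self.first_reversal:]))


class AdaptiveProcedure(abc.ABC):
    """Common interface of the tracking controllers."""

    key: str = ""
    display_name: str = ""
    n_intervals: int = 1
    catch_rate: float = 0.0

    @property
    def tau(self) -> float:
        """Assumed time per trial (s), by task class."""
        return TAU_TWO_TONE if self.n_intervals == 2 else TAU_ONE_INTERVAL

    def start_level(self, rng: np.random.Generator) -> float:
        """Starting level: discrete uniform on {35..45} dB unless the
        procedure defines its own rule."""
        lo, hi = START_RANGE
        return float(rng.integers(lo, hi + 1))

    @abc.abstractmethod
    def start(self, rng: np.random.Generator) -> TrackState:
        ...

    @abc.abstractmethod
    def next_stimulus(self, state: TrackState, rng: np.random.Generator) -> StimulusSpec:
        ...

    def respond(self, stim: StimulusSpec, observer, rng: np.random.Generator):
        """Observer response with the procedure's task (overridden by the
        two-tone and signal-detection procedures)."""
        return observer.yes_no(stim.probe_level, rng)

    @abc.abstractmethod
    def update(self, state: TrackState, stim: StimulusSpec, response) -> str:
        ...

    @abc.abstractmethod
    def estimate(self, state: TrackState) -> float:
        ...


# ---------------------------------------------------------------------------
# two-tone counting procedures (SIUD, GRaBr)
# ---------------------------------------------------------------------------


class _TwoToneProcedure(AdaptiveProcedure):
    """Shared catch-trial logic: each trial is independently a catch trial
    (cue muted) with probability ``catch_rate``; a reported count of 2 on
    a catch trial is a false alarm on the muted cue and aborts the track.
    Catch trials never adjust levels and do not count as main trials."""

    n_intervals = 2
    catch_rate = 0.2

    def respond(self, stim: StimulusSpec, observer, rng: np.random.Generator) -> int:
        return observer.count(stim.probe_level, stim.cue_level, rng)

    @staticmethod
    def _catch_outcome(response: int) -> str:
        return ABORT if response == 2 else CONTINUE


@dataclass
class SiudState(TrackState):
    probe: float = 0.0
    prev_probe: float = 0.0
    step: float = 10.0
    bracketed: bool = False  # first "one tone" response seen


class SIUD(_TwoToneProcedure):
    """Single-interval up/down: cue fixed 10 dB above the probe; counting
    task.  Step 10 dB until the first "one tone" response, which sets the
    probe to the midpoint of the previous two probe levels; 2 dB steps
    thereafter.  After bracketing, "two" lowers the probe and "zero"/"one"
    (probe inaudible) raises it."""

    key = "siud"
    display_name = "SIUD"

    def __init__(self, cue_offset: float = 10.0, initial_step: float = 10.0,
                 refined_step: float = 2.0, catch_rate: float = 0.2):
        self.cue_offset = cue_offset
        self.initial_step = initial_step
        self.refined_step = refined_step
        self.catch_rate = catch_rate

    def start(self, rng: np.random.Generator) -> SiudState:
        lv = self.start_level(rng)
        return SiudState(probe=lv, prev_probe=lv, step=self.initial_step)

    def next_stimulus(self, state: SiudState, rng: np.random.Generator) -> StimulusSpec:
        is_catch = rng.random() < self.catch_rate
        cue = None if is_catch else state.probe + self.cue_offset
        return StimulusSpec(probe_level=state.probe, cue_level=cue, is_catch=is_catch)

    def update(self, state: SiudState, stim: StimulusSpec, response: int) -> str:
        if stim.is_catch:
            return self._catch_outcome(response)
        state.record_level(state.probe)
        if not state.bracketed:
            if response == 1:
                new = 0.5 * (state.probe + state.prev_probe)
                state.bracketed = True
                state.step = self.refined_step
            elif response == 2:
                new = state.probe - state.step
            else:
                new = state.probe + state.step
        else:
            if response == 2:
                new = state.probe - state.step
            else:  # probe not heard (0 or 1)
                new = state.probe + state.step
        state.prev_probe = state.probe
        state.probe = new
        return CONTINUE

    def estimate(self, state: SiudState) -> float:
        return state.median_post_reversal()


@dataclass
class GrabrState(TrackState):
    probe: float = 0.0
    cue: float = 0.0
    delta: float = 10.0
    one_count: int = 0
    reversals: int = 0
    shift_dir: int = 0
    pair_levels: List[tuple] = field(default_factory=list)


class GRaBr(_TwoToneProcedure):
    """Graded-response bracketing.

    The probe/cue pair moves down on "two", up on "zero" (gap unchanged);
    a "one tone" response means the threshold lies between the two tones,
    so the gap shrinks (10 -> 5 on the first "one", 5 -> 2 on the second)
    and the smaller bracket is re-centred on the midpoint of the previous
    pair.  The pair-shift step follows 8/6/3/1 dB keyed to reversals of
    the shift direction ("one" responses are not themselves reversals).
    """

    key = "grabr"
    display_name = "GRaBr"

    def __init__(self, deltas: Sequence[float] = (10.0, 5.0, 2.0),
                 step_schedule: Sequence[float] = (8.0, 6.0, 3.0, 1.0),
                 catch_rate: float = 0.2):
        self.deltas = tuple(deltas)
        self.step_schedule = tuple(step_schedule)
        self.catch_rate = catch_rate

    def start(self, rng: np.random.Generator) -> GrabrState:
        lv = self.start_level(rng)
        return GrabrState(probe=lv, cue=lv + self.deltas[0], delta=self.deltas[0])

    def next_stimulus(self, state: GrabrState, rng: np.random.Generator) -> StimulusSpec:
        is_catch = rng.random() < self.catch_rate
        cue = None if is_catch else state.cue
        return StimulusSpec(probe_level=state.probe, cue_level=cue, is_catch=is_catch)

    def update(self, state: GrabrState, stim: StimulusSpec, response: int) -> str:
        if stim.is_catch:
            return self._catch_outcome(response)
        # both tones are informative in GRaBr, so the estimation track pools
        # them; the reversal scan runs on the pair midpoint (re-centring
        # moves keep the midpoint fixed and are direction-neutral)
        state.record_level(0.5 * (state.probe + state.cue))
        state.pair_levels.append((state.probe, state.cue))
        if response == 1:
            state.one_count += 1
            state.delta = self.deltas[min(state.one_count, len(self.deltas) - 1)]
            mid = 0.5 * (state.probe + state.cue)
            state.probe = mid - 0.5 * state.delta
            state.cue = mid + 0.5 * state.delta
        else:
            direction = -1 if response == 2 else 1
            # the 8/6/3/1 refinement engages once the threshold is bracketed
            # (first "one tone" response), as in SIUD where the step change
            # is keyed to the first "1"; direction flips before bracketing
            # (e.g. a lapse far above threshold) keep the search step large
            if (state.one_count > 0 and state.shift_dir != 0
                    and direction != state.shift_dir):
                state.reversals += 1
            state.shift_dir = direction
            step = self.step_schedule[min(state.reversals, len(self.step_schedule) - 1)]
            state.probe += direction * step
            state.cue += direction * step
        return CONTINUE

    def estimate(self, state: GrabrState) -> float:
        start = state.first_reversal if state.first_reversal is not None else 0
        pooled = [lv for pair in state.pair_levels[start:] for lv in pair]
        return float(np.median(pooled))


# ---------------------------------------------------------------------------
# APTA (modified Hughson-Westlake ascending audiometry)
# ---------------------------------------------------------------------------


@dataclass
class AptaState(TrackState):
    level: float = -10.0
    phase: int = 1
    yes_levels: List[float] = field(default_factory=list)


class APTA(AdaptiveProcedure):
    """Automated pure-tone audiometry.

    Phase 1 ascends in 5 dB steps from -10 dB until the first "yes";
    phase 2 resets to -10 dB and ascends until the second "yes"; phase 3
    starts 5 dB below the second "yes" level and runs repeated ascents
    (drop 10 dB after each "yes", ascend in 5 dB steps).  The track
    terminates once at least ``min_yes`` "yes" responses were given and
    the last two "yes" levels differ by less than ``yes_tolerance`` dB.
    Threshold: the level of the last "yes" response.
    """

    key = "apta"
    display_name = "APTA"

    def __init__(self, floor: float = -10.0, ascend_step: float = 5.0,
                 drop_after_yes: float = 10.0, entry_drop: float = 5.0,
                 min_yes: int = 7, yes_tolerance: float = 3.0):
        self.floor = floor
        self.ascend_step = ascend_step
        self.drop_after_yes = drop_after_yes
        self.entry_drop = entry_drop
        self.min_yes = min_yes
        self.yes_tolerance = yes_tolerance

    def start_level(self, rng: np.random.Generator) -> float:
        return self.floor

    def start(self, rng: np.random.Generator) -> AptaState:
        return AptaState(level=self.floor)

    def next_stimulus(self, state: AptaState, rng: np.random.Generator) -> StimulusSpec:
        return StimulusSpec(probe_level=state.level)

    def update(self, state: AptaState, stim: StimulusSpec, response: bool) -> str:
        state.record_level(state.level)
        if response:
            state.yes_levels.append(state.level)
        if state.phase == 1:
            if response:
                state.phase = 2
                state.level = self.floor
            else:
                state.level += self.ascend_step
        elif state.phase == 2:
            if response:
                state.phase = 3
                state.level = state.yes_levels[-1] - self.entry_drop
            else:
                state.level += self.ascend_step
        else:
            if response:
                ys = state.yes_levels
                if len(ys) >= self.min_yes and abs(ys[-1] - ys[-2]) < self.yes_tolerance:
                    state.terminated = True
                    return TERMINATED
                state.level -= self.drop_after_yes
            else:
                state.level += self.ascend_step
        return CONTINUE

    def estimate(self, state: AptaState) -> float:
        if state.yes_levels:
            return state.yes_levels[-1]
        return state.level  # provisional: no detection yet


# ---------------------------------------------------------------------------
# Bayesian / maximum-likelihood procedures
# ---------------------------------------------------------------------------


@dataclass
class QuestState(TrackState):
    posterior: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_done: int = 0


class QuestPlus(AdaptiveProcedure):
    """QUEST+ with the midpoint threshold L50 as the only free parameter.

    The posterior over an L50 grid is updated by Bayes' rule with the
    logistic PF likelihood (p_min = 0, p_max = 1, s fixed); the next level
    minimises the expected posterior Shannon entropy over the two response
    outcomes (ties -> lowest level).  The first trial uses the procedure's
    own starting rule: the midpoint of the stimulus range.  Threshold:
    posterior mode (with a uniform prior this is the ML estimate).
    """

    key = "quest_plus"
    display_name = "QUEST+"

    def __init__(self, l50_range=STIM_RANGE, l50_spacing: float = 1.0,
                 stim_range=STIM_RANGE, stim_spacing: float = 1.0,
                 s: float = 0.125, p_min: float = 0.0, p_max: float = 1.0):
        self.l50_grid = np.arange(l50_range[0], l50_range[1] + 0.5 * l50_spacing, l50_spacing)
        self.stim_grid = np.arange(stim_range[0], stim_range[1] + 0.5 * stim_spacing, stim_spacing)
        self.stim_range = stim_range
        pf_kwargs = dict(p_min=p_min, p_max=p_max, s=s)
        # P(yes | level, L50): rows = candidate levels, cols = hypotheses
        self._pyes = np.empty((self.stim_grid.size, self.l50_grid.size))
        for j, l50 in enumerate(self.l50_grid):
            self._pyes[:, j] = pf_eval(self.stim_grid, PsychometricParams(l50=l50, **pf_kwargs))

    def start_level(self, rng: np.random.Generator) -> float:
        return 0.5 * (self.stim_range[0] + self.stim_range[1])

    def start(self, rng: np.random.Generator) -> QuestState:
        prior = np.full(self.l50_grid.size, 1.0 / self.l50_grid.size)
        return QuestState(posterior=prior)

    def next_stimulus(self, state: QuestState, rng: np.random.Generator) -> StimulusSpec:
        if state.n_done == 0:
            return StimulusSpec(probe_level=self.start_level(rng))
        w = self._pyes * state.posterior          # joint mass, yes branch
        v = (1.0 - self._pyes) * state.posterior  # no branch
        p1 = w.sum(axis=1)
        p0 = v.sum(axis=1)
        expected_h = (-xlogy(w, w).sum(axis=1) + xlogy(p1, p1)
                      - xlogy(v, v).sum(axis=1) + xlogy(p0, p0))
        return StimulusSpec(probe_level=float(self.stim_grid[int(np.argmin(expected_h))]))

    def update(self, state: QuestState, stim: StimulusSpec, response: bool) -> str:
        state.record_level(stim.probe_level)
        i = int(np.argmin(np.abs(self.stim_grid - stim.probe_level)))
        like = self._pyes[i] if response else 1.0 - self._pyes[i]
        post = state.posterior * like
        total = post.sum()
        if total <= 0.0:  # all hypotheses contradicted (degenerate PF only)
            raise FloatingPointError("posterior mass vanished in QUEST+ update")
        state.posterior = post / total
        state.n_done += 1
        return CONTINUE

    def estimate(self, state: QuestState) -> float:
        return float(self.l50_grid[int(np.argmax(state.posterior))])


@dataclass
class MlpState(TrackState):
    loglik: np.ndarray = field(default_factory=lambda: np.empty(0))
    next_level: float = 0.0


class MLP(AdaptiveProcedure):
    """Maximum-likelihood procedure.

    Hypotheses: logistic PFs with L50 on a fine grid, a small set of
    false-alarm floors, fixed slope and p_max = 1.  After each trial the
    hypothesis with the highest likelihood of the whole response history
    is selected (ties -> lowest L50) and the next level is that PF's
    inverse at the p-target (0.6310), clamped to the stimulus range.
    Threshold: the median of all presented levels.
    """

    key = "mlp"
    display_name = "MLP"

    def __init__(self, l50_range=STIM_RANGE, l50_spacing: float = 0.1,
                 p_min_hypotheses: Sequence[float] = (0.0, 0.05, 0.1),
                 s: float = 0.125, p_target: float = 0.6310,
                 stim_range=STIM_RANGE):
        n = int(round((l50_range[1] - l50_range[0]) / l50_spacing)) + 1
        l50 = l50_range[0] + l50_spacing * np.arange(n)
        pmins = np.asarray(p_min_hypotheses, dtype=float)
        # L50-major flattening so that argmax ties resolve to the lowest L50
        self._l50 = np.repeat(l50, pmins.size)
        self._pmin = np.tile(pmins, l50.size)
        self.s = s
        self.p_target = p_target
        self.stim_range = stim_range
        self._offset = {  # level offset from L50 to the p-target point
            pm: pf_inverse(p_target, PsychometricParams(p_min=pm, s=s, l50=0.0))
            for pm in pmins
        }

    def start(self, rng: np.random.Generator) -> MlpState:
        lv = self.start_level(rng)
        return MlpState(loglik=np.zeros(self._l50.size), next_level=lv)

    def next_stimulus(self, state: MlpState, rng: np.random.Generator) -> StimulusSpec:
        return StimulusSpec(probe_level=state.next_level)

    def update(self, state: MlpState, stim: StimulusSpec, response: bool) -> str:
        level = stim.probe_level
        state.record_level(level)
        p = self._pmin + (1.0 - self._pmin) * expit(4.0 * self.s * (level - self._l50))
        state.loglik += np.log(p) if response else np.log1p(-p)
        best = int(np.argmax(state.loglik))
        target = self._l50[best] + self._offset[self._pmin[best]]
        state.next_level = float(np.clip(target, *self.stim_range))
        return CONTINUE

    def estimate(self, state: MlpState) -> float:
        return float(np.median(state.levels))


@dataclass
class UmlState(TrackState):
    posterior: np.ndarray = field(default_factory=lambda: np.empty(0))
    consecutive_yes: int = 0
    target_p: float = 0.75
    next_level: float = 0.0
    started: bool = False


class UML(AdaptiveProcedure):
    """Updated maximum-likelihood procedure (L50-only posterior).

    Bayesian update as in QUEST+; placement follows a two-down one-up
    sweet-point overlay on the posterior-mean PF: after two consecutive
    "yes" responses the lower target (the 50% point, i.e. the posterior
    mean itself) is used and the counter resets; after any "no" the upper
    target (75% point); otherwise the current target is kept.  Threshold:
    posterior mean.
    """

    key = "uml"
    display_name = "UML"

    def __init__(self, l50_range=STIM_RANGE, l50_spacing: float = 1.0,
                 s: float = 0.125, lower_target: float = 0.5,
                 upper_target: float = 0.75, stim_range=STIM_RANGE):
        self.l50_grid = np.arange(l50_range[0], l50_range[1] + 0.5 * l50_spacing, l50_spacing)
        self.s = s
        self.lower_target = lower_target
        self.upper_target = upper_target
        self.stim_range = stim_range

    def _target_level(self, mean_l50: float, target_p: float) -> float:
        offset = pf_inverse(target_p, PsychometricParams(s=self.s, l50=0.0))
        return float(np.clip(mean_l50 + offset, *self.stim_range))

    def start(self, rng: np.random.Generator) -> UmlState:
        prior = np.full(self.l50_grid.size, 1.0 / self.l50_grid.size)
        return UmlState(posterior=prior, target_p=self.upper_target,
                        next_level=self.start_level(rng))

    def next_stimulus(self, state: UmlState, rng: np.random.Generator) -> StimulusSpec:
        return StimulusSpec(probe_level=state.next_level)

    def update(self, state: UmlState, stim: StimulusSpec, response: bool) -> str:
        level = stim.probe_level
        state.record_level(level)
        like = expit(4.0 * self.s * (level - self.l50_grid))
        post = state.posterior * (like if response else 1.0 - like)
        total = post.sum()
        if total <= 0.0:
            raise FloatingPointError("posterior mass vanished in UML update")
        state.posterior = post / total
        if response:
            state.consecutive_yes += 1
            if state.consecutive_yes >= 2:
                state.target_p = self.lower_target
                state.consecutive_yes = 0
        else:
            state.target_p = self.upper_target
            state.consecutive_yes = 0
        state.next_level = self._target_level(self.estimate(state), state.target_p)
        return CONTINUE

    def estimate(self, state: UmlState) -> float:
        return float(state.posterior @ self.l50_grid)


# ---------------------------------------------------------------------------
# SIAM
# ---------------------------------------------------------------------------


@dataclass
class SiamState(TrackState):
    level: float = 0.0
    reversals: int = 0
    move_dir: int = 0


class SIAM(AdaptiveProcedure):
    """Single-interval adjustment matrix staircase.

    Each trial contains a tone with probability 0.5.  The level change is
    the current step times the adjustment-matrix entry for the target
    proportion correct ``t`` (Kaernbach 1990): hit -1, miss +t/(1-t),
    false alarm +1/(1-t), correct rejection 0 — built so the expected
    drift on signal trials vanishes exactly at p(yes|signal) = t.  Step
    schedule: 4 dB, halved after the second reversal, 1 dB from the third
    onward.  Threshold: median of levels from the first reversal onward.
    """

    key = "siam"
    display_name = "SIAM"

    def __init__(self, t: float = 0.75, initial_step: float = 4.0,
                 signal_rate: float = 0.5):
        if not 0.0 < t < 1.0:
            raise ValueError(f"target proportion t must be in (0, 1), got {t}")
        self.t = t
        self.initial_step = initial_step
        self.signal_rate = signal_rate

    @property
    def matrix(self) -> dict:
        """Adjustment-matrix entries in step units."""
        return {
            "hit": -1.0,
            "miss": self.t / (1.0 - self.t),
            "false_alarm": 1.0 / (1.0 - self.t),
            "correct_rejection": 0.0,
        }

    def _step(self, reversals: int) -> float:
        if reversals >= 3:
            return 1.0
        if reversals == 2:
            return self.initial_step / 2.0
        return self.initial_step

    def start(self, rng: np.random.Generator) -> SiamState:
        return SiamState(level=self.start_level(rng))

    def next_stimulus(self, state: SiamState, rng: np.random.Generator) -> StimulusSpec:
        return StimulusSpec(probe_level=state.level,
                            signal_present=bool(rng.random() < self.signal_rate))

    def respond(self, stim: StimulusSpec, observer, rng: np.random.Generator) -> bool:
        level = stim.probe_level if stim.signal_present else -math.inf
        return observer.yes_no(level, rng)

    def update(self, state: SiamState, stim: StimulusSpec, response: bool) -> str:
        state.record_level(state.level)
        m = self.matrix
        if stim.signal_present:
            coef = m["hit"] if response else m["miss"]
        else:
            coef = m["false_alarm"] if response else m["correct_rejection"]
        if coef != 0.0:
            direction = 1 if coef > 0 else -1
            if state.move_dir != 0 and direction != state.move_dir:
                state.reversals += 1
            state.move_dir = direction
            state.level += coef * self._step(state.reversals)
        return CONTINUE

    def estimate(self, state: SiamState) -> float:
        return state.median_post_reversal()


PROCEDURE_CLASSES = {
    cls.key: cls for cls in (SIUD, GRaBr, APTA, QuestPlus, MLP, UML, SIAM)
}
DISPLAY_NAMES = {key: cls.display_name for key, cls in PROCEDURE_CLASSES.items()}
PROCEDURE_KEYS = tuple(PROCEDURE_CLASSES)


def make_procedure(key: str, **overrides) -> AdaptiveProcedure:
    """Instantiate a procedure by key with optional parameter overrides."""
    try:
        cls = PROCEDURE_CLASSES[key]
    except KeyError:
        raise ValueError(f"unknown procedure {key!r}; known: {sorted(PROCEDURE_CLASSES)}") from None
    return cls(**overrides)
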