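"""Seeded Monte-Carlo experiment runner.

Runs complete adaptive tracks (procedure x observer), the full evaluation
grid, and the bookkeeping the downstream metrics need: per-trial interim
threshold estimates (for convergence curves), catch-trial counts and
abort/restart statistics.

Reproducibility contract: every track draws from its own random
substream derived with :class:`numpy.random.SeedSequence` from
``(master_seed, procedure index, observer index, run index)``, so results
are bit-identical for a given configuration and independent of the order
in which conditions are executed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .observers import (
    CONCENTRATIONS,
    DEFAULT_P_MINS,
    INATTENTION_TYPES,
    ObserverSpec,
    make_observer_grid,
)
from .procedures import (
    ABORT,
    PROCEDURE_KEYS,
    TERMINATED,
    AdaptiveProcedure,
    make_procedure,
)

__all__ = [
    "SimConfig",
    "TrackResult",
    "GridResults",
    "condition_rng",
    "draw_start_level",
    "run_track",
    "run_grid",
]

#: restart attempts allowed per run before aborts stop restarting the track
MAX_ATTEMPTS = 20


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a Monte-Carlo experiment (defaults: the full
    7-procedure x 18-observer grid, 1000 runs of 50 trials each)."""

    procedures: Tuple[str, ...] = PROCEDURE_KEYS
    observer_types: Tuple[str, ...] = INATTENTION_TYPES
    concentrations: Tuple[str, ...] = CONCENTRATIONS
    p_mins: Tuple[float, ...] = DEFAULT_P_MINS
    n_runs: int = 1000
    n_trials: int = 50
    master_seed: int = 0
    n_bootstrap: int = 1000
    bootstrap_size: int = 10000
    true_l50: float = 15.0
    procedure_params: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def observers(self) -> List[ObserverSpec]:
        return make_observer_grid(self.observer_types, self.concentrations, self.p_mins)

    def build_procedure(self, key: str) -> AdaptiveProcedure:
        return make_procedure(key, **self.procedure_params.get(key, {}))


@dataclass
class TrackResult:
    """One completed adaptive track."""

    estimate: float
    interim: np.ndarray  # threshold estimate after each main trial (len n_trials)
    n_main_trials: int   # < n_trials only if the procedure terminated early
    n_catch: int
    aborted_attempts: int
    attempts: int
    flags: Tuple[str, ...] = ()


def draw_start_level(procedure, rng: np.random.Generator) -> float:
    """Starting level of a procedure (by instance or key): discrete uniform
    on {35..45} dB except APTA (-10 dB floor) and QUEST+ (range midpoint)."""
    if isinstance(procedure, str):
        procedure = make_procedure(procedure)
    return procedure.start_level(rng)


def run_track(procedure: AdaptiveProcedure, observer, rng: np.random.Generator,
              n_trials: int = 50, max_attempts: int = MAX_ATTEMPTS) -> TrackResult:
    """Run one adaptive track to completion.

    Catch trials do not count toward the ``n_trials`` main trials.  A
    false alarm on a catch trial aborts the attempt and restarts the
    track from a freshly drawn starting level; after ``max_attempts``
    attempts further aborts are recorded but no longer restart (flagged).
    """
    aborted = 0
    flags: List[str] = []
    attempt = 0
    while True:
        attempt += 1
        allow_restart = attempt < max_attempts
        state = procedure.start(rng)
        interim = np.empty(n_trials)
        n_main = 0
        n_catch = 0
        restarted = False
        while n_main < n_trials and not state.terminated:
            stim = procedure.next_stimulus(state, rng)
            response = procedure.respond(stim, observer, rng)
            status = procedure.update(state, stim, response)
            if status == ABORT:
                aborted += 1
                if allow_restart:
                    restarted = True
                    break
                flags.append("attempt_cap")
                continue  # keep going without restarting
            if stim.is_catch:
                n_catch += 1
                continue
            interim[n_main] = procedure.estimate(state)
            n_main += 1
        if restarted:
            continue
        if n_main == 0:  # defensive: cannot happen with n_trials >= 1
            raise RuntimeError("track completed without any main trial")
        interim[n_main:] = interim[n_main - 1]  # early termination: carry forward
        if state.first_reversal is None and getattr(state, "levels", None) is not None:
            # median estimators fall back to all levels when no reversal occurred
            if procedure.key in ("siud", "grabr", "siam"):
                flags.append("no_reversal")
        return TrackResult(
            estimate=float(interim[n_trials - 1]),
            interim=interim,
            n_main_trials=n_main,
            n_catch=n_catch,
            aborted_attempts=aborted,
            attempts=attempt,
            flags=tuple(dict.fromkeys(flags)),
        )


def condition_rng(master_seed: int, procedure_key: str, observer: ObserverSpec,
                  run: int) -> np.random.Generator:
    """Per-track substream keyed to the procedure and observer identity (not
    their positions), so any subset of the grid reproduces the full grid's
    tracks exactly."""
    obs_tag = f"{observer.inattention_type}|{observer.concentration}|{observer.p_min}"
    ss = np.random.SeedSequence([
        master_seed,
        zlib.crc32(procedure_key.encode()),
        zlib.crc32(obs_tag.encode()),
        run,
    ])
    return np.random.Generator(np.random.PCG64(ss))


@dataclass
class GridResults:
    """Tidy per-track table plus interim-estimate arrays per condition.

    ``tracks`` has one row per (procedure, observer, run); ``interim``
    maps condition keys ``(procedure_key, observer_type, concentration,
    p_min)`` to arrays of shape ``(n_runs, n_trials)``.
    """

    tracks: pd.DataFrame
    interim: Dict[Tuple[str, str, str, float], np.ndarray]
    config: SimConfig

    def condition_keys(self):
        return list(self.interim.keys())


def run_grid(cfg: SimConfig, progress: Optional[callable] = None) -> GridResults:
    """Run the full grid of procedures x observers x runs.

    ``progress``, if given, is called with a short label after each
    (procedure, observer) condition completes.
    """
    observers = cfg.observers()
    rows = []
    interim: Dict[Tuple[str, str, str, float], np.ndarray] = {}
    for key in cfg.procedures:
        procedure = cfg.build_procedure(key)
        for obs in observers:
            cond = (key, obs.inattention_type, obs.concentration, obs.p_min)
            block = np.empty((cfg.n_runs, cfg.n_trials))
            for run in range(cfg.n_runs):
                rng = condition_rng(cfg.master_seed, key, obs, run)
                res = run_track(procedure, obs, rng, n_trials=cfg.n_trials)
                block[run] = res.interim
                rows.append((
                    key, obs.inattention_type, obs.concentration, obs.p_min,
                    run, res.estimate, res.aborted_attempts, res.attempts,
                    res.n_catch, res.n_main_trials, ";".join(res.flags),
                ))
            interim[cond] = block
            if progress is not None:
                progress(f"{key} {obs.inattention_type}/{obs.concentration}/p_min={obs.p_min}")
    tracks = pd.DataFrame(rows, columns=[
        "procedure", "inattention_type", "concentration", "p_min",
        "run", "estimate", "aborted_attempts", "attempts",
        "n_catch", "n_main_trials", "flags",
    ])
    return GridResults(tracks=tracks, interim=interim, config=cfg)
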