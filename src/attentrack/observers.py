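"""Simulated inattentive listeners for adaptive threshold tracking.

A virtual listener is described by a four-parameter logistic psychometric
function (PF) mapping sound level (dB) to the probability of a "yes"
(detect) response::

    p(L) = p_min + (p_max - p_min) / (1 + exp(-4 s (L - L50)))

where ``p_min`` is the false-alarm floor (lower asymptote), ``1 - p_max``
the miss (lapse) rate, ``s`` the slope at the midpoint (per dB) and
``L50`` the threshold, i.e. the level of the half-way point.

Two modes of inattention are modelled:

* **long-term** (sustained) inattention: a stationary PF whose upper
  asymptote ``p_max`` is reduced; the same PF governs every trial.
* **short-term** (sporadic) inattention: a nested two-state process.  On
  each trial the listener is, with probability ``p_inatt``, in an
  *inattentive* state and answers at random (p("yes") = 0.5 regardless of
  level); otherwise the regular PF applies.  Averaged over many trials
  this behaves like a deformed stationary PF (see
  :func:`equivalent_expected_pf`), but the trial-by-trial process differs.

Concentration labels follow the convention: fully (FC), moderately (MC)
and non-concentrated (NC) listeners, encoded as p_max = 1 / 0.95 / 0.9
for the long-term model and p_inatt = 0 / 0.1 / 0.2 for the short-term
model.  Combined with three false-alarm floors (0, 0.05, 0.1) and the two
inattention modes this yields the standard 18-listener evaluation grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "LONG_TERM",
    "SHORT_TERM",
    "CONCENTRATIONS",
    "PMAX_BY_CONCENTRATION",
    "PINATT_BY_CONCENTRATION",
    "PsychometricParams",
    "pf_eval",
    "pf_inverse",
    "ObserverSpec",
    "StepObserver",
    "equivalent_expected_pf",
    "make_observer_grid",
]

LONG_TERM = "long_term"
SHORT_TERM = "short_term"
INATTENTION_TYPES = (LONG_TERM, SHORT_TERM)

CONCENTRATIONS = ("FC", "MC", "NC")
PMAX_BY_CONCENTRATION = {"FC": 1.0, "MC": 0.95, "NC": 0.9}
PINATT_BY_CONCENTRATION = {"FC": 0.0, "MC": 0.1, "NC": 0.2}

DEFAULT_P_MINS = (0.0, 0.05, 0.1)


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of the four-parameter logistic psychometric function.

    Defaults are the study conditions used throughout: no false alarms,
    no lapses, slope 0.125/dB and a true threshold of 15 dB.
    """

    p_min: float = 0.0
    p_max: float = 1.0
    s: float = 0.125
    l50: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_min < self.p_max <= 1.0):
            raise ValueError(
                f"require 0 <= p_min < p_max <= 1, got p_min={self.p_min}, "
                f"p_max={self.p_max}"
            )
        if self.s <= 0:
            raise ValueError(f"slope s must be positive, got {self.s}")


def pf_eval(level, pf: PsychometricParams):
    """Probability of a "yes" response at ``level`` (dB).

    Accepts scalars or arrays; ±inf evaluate to the asymptotes exactly.
    """
    return pf.p_min + (pf.p_max - pf.p_min) * expit(4.0 * pf.s * (np.asarray(level, dtype=float) - pf.l50))


def pf_inverse(p: float, pf: PsychometricParams) -> float:
    """Level at which the PF attains probability ``p`` (strictly between
    the asymptotes)."""
    if not (pf.p_min < p < pf.p_max):
        raise ValueError(
            f"p={p} outside the open asymptote interval ({pf.p_min}, {pf.p_max})"
        )
    return pf.l50 + math.log((p - pf.p_min) / (pf.p_max - p)) / (4.0 * pf.s)


@dataclass(frozen=True)
class ObserverSpec:
    """A simulated listener: inattention mode plus its base PF.

    ``p_inatt`` is the per-trial probability of the inattentive state
    (short-term mode only; must be 0 for long-term).  ``p_inattentive_yes``
    is the "yes" probability while inattentive (0.5: random guessing).
    ``concentration`` is a convenience label (FC/MC/NC) for reporting.
    """

    inattention_type: str = LONG_TERM
    p_inatt: float = 0.0
    base_pf: PsychometricParams = field(default_factory=PsychometricParams)
    p_inattentive_yes: float = 0.5
    concentration: str = "FC"

    def __post_init__(self) -> None:
        if self.inattention_type not in INATTENTION_TYPES:
            raise ValueError(f"unknown inattention_type {self.inattention_type!r}")
        if not (0.0 <= self.p_inatt <= 1.0):
            raise ValueError(f"p_inatt must be a probability, got {self.p_inatt}")
        if self.inattention_type == LONG_TERM and self.p_inatt != 0.0:
            raise ValueError("long-term observers must have p_inatt = 0")

    @classmethod
    def of(cls, inattention_type: str, concentration: str, p_min: float) -> "ObserverSpec":
        """Build a grid observer from (mode, FC/MC/NC label, false-alarm rate)."""
        if concentration not in CONCENTRATIONS:
            raise ValueError(f"unknown concentration {concentration!r}")
        if inattention_type == LONG_TERM:
            pf = PsychometricParams(p_min=p_min, p_max=PMAX_BY_CONCENTRATION[concentration])
            return cls(LONG_TERM, 0.0, pf, concentration=concentration)
        if inattention_type == SHORT_TERM:
            pf = PsychometricParams(p_min=p_min, p_max=1.0)
            return cls(SHORT_TERM, PINATT_BY_CONCENTRATION[concentration], pf,
                       concentration=concentration)
        raise ValueError(f"unknown inattention_type {inattention_type!r}")

    @property
    def p_min(self) -> float:
        return self.base_pf.p_min

    def _attentive(self, rng: np.random.Generator) -> bool:
        if self.inattention_type == SHORT_TERM and self.p_inatt > 0.0:
            return rng.random() >= self.p_inatt
        return True

    def yes_no(self, level: float, rng: np.random.Generator) -> bool:
        """Single-interval yes/no response at ``level`` (may be -inf for a
        signal-absent presentation)."""
        if self._attentive(rng):
            p = float(pf_eval(level, self.base_pf))
        else:
            p = self.p_inattentive_yes
        return rng.random() < p

    def count(self, probe_level: Optional[float], cue_level: Optional[float],
              rng: np.random.Generator) -> int:
        """Tone-counting response for a two-tone trial.

        ``None`` marks a muted slot.  One attention-state draw governs the
        whole trial; while attentive each presented tone is heard
        independently with its PF probability and a muted slot is "heard"
        with the false-alarm probability ``p_min``; while inattentive each
        slot is "heard" independently with probability 0.5.
        """
        if probe_level is None and cue_level is None:
            raise ValueError("at least one of probe/cue must be presented")
        attentive = self._attentive(rng)
        heard = 0
        for lv in (probe_level, cue_level):
            if attentive:
                p = self.base_pf.p_min if lv is None else float(pf_eval(lv, self.base_pf))
            else:
                p = self.p_inattentive_yes
            if rng.random() < p:
                heard += 1
        return heard


def equivalent_expected_pf(obs: ObserverSpec) -> PsychometricParams:
    """Stationary PF equal to the track-averaged expectation of the
    short-term nested process.

    With inattentive guessing at 0.5 the expectation of the two-state
    process is again a logistic PF with the same slope and midpoint but
    deformed asymptotes::

        p_max_short = 1 - p_inatt / 2
        p_min_short = (1 - p_inatt) p_min + p_inatt / 2

    (for p_min = 0 the lower asymptote reduces to p_inatt / 2).
    Raises for long-term observers, whose PF is already stationary.
    """
    if obs.inattention_type != SHORT_TERM:
        raise ValueError("equivalent expected PF is defined for short-term observers")
    pf = obs.base_pf
    pi = obs.p_inatt
    g = obs.p_inattentive_yes
    return PsychometricParams(
        p_min=(1.0 - pi) * pf.p_min + pi * g,
        p_max=(1.0 - pi) * pf.p_max + pi * g,
        s=pf.s,
        l50=pf.l50,
    )


@dataclass(frozen=True)
class StepObserver:
    """Deterministic diagnostic listener: hears a tone iff its level is at
    or above ``threshold``; never false-alarms.  Useful for checking that
    a tracking procedure homes in on a known threshold exactly."""

    threshold: float = 15.0

    def yes_no(self, level: float, rng: np.random.Generator) -> bool:
        return level >= self.threshold

    def count(self, probe_level: Optional[float], cue_level: Optional[float],
              rng: np.random.Generator) -> int:
        if probe_level is None and cue_level is None:
            raise ValueError("at least one of probe/cue must be presented")
        return sum(1 for lv in (probe_level, cue_level)
                   if lv is not None and lv >= self.threshold)


def make_observer_grid(
    types: Sequence[str] = INATTENTION_TYPES,
    concentrations: Sequence[str] = CONCENTRATIONS,
    p_mins: Sequence[float] = DEFAULT_P_MINS,
) -> list[ObserverSpec]:
    """The evaluation grid of observers (default: 2 modes x 3 concentration
    levels x 3 false-alarm rates = 18 listeners)."""
    return [
        ObserverSpec.of(t, c, pm)
        for t in types
        for c in concentrations
        for pm in p_mins
    ]
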