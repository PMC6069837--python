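"""Two-interval perception-threshold task: observer, weighted staircase, JND.

The perturbation is a rotation of the control space in degrees.  A
simulated observer answers a two-interval forced-choice ("which of the two
lift trials behaved differently?") through a cumulative-Gaussian
psychometric function with guess rate 0.5 and a small lapse rate.  The
stimulus track follows a weighted up-down staircase (Kaernbach 1991) whose
asymmetric steps make it converge on the stimulus detected with the target
probability 0.84; the track stops at 23 reversals and the just-noticeable
difference (JND) is the mean of the late reversal stimuli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "Observer",
    "StaircaseConfig",
    "StaircaseState",
    "StaircaseResult",
    "StaircaseNonConvergence",
    "psychometric_prob",
    "staircase_step",
    "run_staircase",
]

TARGET_P = 0.84
STOP_REVERSALS = 23
DISCARD_REVERSALS = 7  # approach phase; JND averages the remaining 16


@dataclass(frozen=True)
class Observer:
    """Cumulative-Gaussian 2IFC observer.

    ``threshold`` is the stimulus (degrees of rotation) at which the
    observer performs at the staircase target probability; the location of
    the underlying Gaussian is derived from it.  ``slope`` is the Gaussian
    SD in degrees.  ``guess_rate`` is fixed at 0.5 by the two-interval
    design; ``lapse_rate`` caps the upper asymptote at 1 - lapse.
    """

    threshold: float
    slope: float
    guess_rate: float = 0.5
    lapse_rate: float = 0.02
    target_p: float = TARGET_P

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0 <= self.lapse_rate <= 0.06:
            raise ValueError("lapse rate outside [0, 0.06]")
        if not 0 < self.target_p < 1 - self.lapse_rate:
            raise ValueError("target_p must lie strictly inside the psychometric range")

    @property
    def location(self) -> float:
        """Gaussian mean such that psi(threshold) == target_p."""
        inner = (self.target_p - self.guess_rate) / (
            1.0 - self.guess_rate - self.lapse_rate
        )
        return self.threshold - self.slope * norm.ppf(inner)


def psychometric_prob(obs: Observer, stimulus: float) -> float:
    """P(correct) at a rotation ``stimulus`` >= 0 degrees.

    psi(x) = guess + (1 - guess - lapse) * Phi((x - mu) / slope), with mu
    chosen so psi(threshold) equals the staircase target probability.  At
    zero stimulus far below threshold this is the 0.5 chance level of the
    two-interval task; for large stimuli it saturates at 1 - lapse.
    """
    if stimulus < 0:
        raise ValueError("stimulus must be non-negative")
    z = (stimulus - obs.location) / obs.slope
    return obs.guess_rate + (1.0 - obs.guess_rate - obs.lapse_rate) * float(
        norm.cdf(z)
    )


@dataclass(frozen=True)
class StaircaseConfig:
    """Weighted up-down track on control-space rotation.

    ``step_up / step_down`` must equal ``target_p / (1 - target_p)``
    (5.25 at the 0.84 target) — the ratio that places the track's
    equilibrium exactly at the target-probability stimulus.
    """

    target_p: float = TARGET_P
    start_stimulus: float = 75.0
    step_down: float = 2.0
    step_up: float | None = None  # defaults to step_down * p/(1-p)
    stop_reversals: int = STOP_REVERSALS
    min_stimulus: float = 0.0
    max_stimulus: float = 90.0
    max_trials: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.target_p < 1:
            raise ValueError("target_p must be in (0, 1)")
        if self.step_up is None:
            ratio = self.target_p / (1.0 - self.target_p)
            object.__setattr__(self, "step_up", self.step_down * ratio)
        ratio = self.target_p / (1.0 - self.target_p)
        if abs(self.step_up / self.step_down - ratio) > 1e-9:
            raise ValueError(
                "step_up/step_down must equal target_p/(1-target_p) "
                f"= {ratio:.6f} for convergence at the target probability"
            )
        if not 0 <= self.min_stimulus < self.max_stimulus <= 90.0:
            raise ValueError("stimulus bounds must satisfy 0 <= min < max <= 90")


@dataclass
class StaircaseState:
    stimulus: float
    direction: int = 0  # -1 moving down, +1 moving up, 0 before first move
    reversal_stimuli: list[float] = field(default_factory=list)
    trial_log: list[tuple[float, bool, bool]] = field(default_factory=list)
    terminated: bool = False


@dataclass(frozen=True)
class StaircaseResult:
    jnd: float
    reversal_stimuli: tuple[float, ...]
    trial_log: tuple[tuple[float, bool, bool], ...]  # (stimulus, correct, reversal)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "jnd_deg": self.jnd,
                    "n_reversals": len(self.reversal_stimuli),
                    "reversal_stimuli_deg": list(self.reversal_stimuli),
                    "n_trials": len(self.trial_log),
                },
                indent=2,
            )
        )

    def to_rows(self) -> list[dict]:
        return [
            {
                "trial_pair_id": i,
                "stimulus_deg": s,
                "response_correct": int(c),
                "reversal_flag": int(r),
            }
            for i, (s, c, r) in enumerate(self.trial_log)
        ]


class StaircaseNonConvergence(RuntimeError):
    """The track failed to accumulate the required reversals within the cap."""


def staircase_step(
    state: StaircaseState, correct: bool, cfg: StaircaseConfig
) -> StaircaseState:
    """Advance the track by one response.

    Correct responses step the stimulus down by ``step_down``; incorrect
    ones step it up by ``step_up``.  A change of direction appends the
    presented stimulus to the reversal log.  The stimulus is clamped to
    [min, max]; a move truncated by the clamp is a boundary hit that
    leaves the direction state untouched, so saturation at a bound cannot
    produce spurious reversals.
    """
    if state.terminated:
        raise RuntimeError("staircase already terminated")
    presented = state.stimulus
    move = -1 if correct else +1
    raw = presented + (cfg.step_up if move > 0 else -cfg.step_down)
    clamped = min(max(raw, cfg.min_stimulus), cfg.max_stimulus)

    reversal = False
    if raw == clamped:  # a full, unclamped move
        if state.direction != 0 and move != state.direction:
            reversal = True
            state.reversal_stimuli.append(presented)
        state.direction = move
    state.trial_log.append((presented, correct, reversal))
    state.stimulus = clamped
    if len(state.reversal_stimuli) >= cfg.stop_reversals:
        state.terminated = True
    return state


def run_staircase(
    obs: Observer, cfg: StaircaseConfig | None = None, seed: int = 0
) -> StaircaseResult:
    """Run the track against ``obs`` to termination and estimate the JND.

    The JND is the mean of the reversal stimuli after discarding the first
    seven (the approach from the 75 degree start); with the 23-reversal
    stop this averages 16 reversals.
    """
    cfg = cfg or StaircaseConfig()
    rng = np.random.default_rng(seed)
    state = StaircaseState(stimulus=cfg.start_stimulus)
    for _ in range(cfg.max_trials):
        p = psychometric_prob(obs, state.stimulus)
        correct = bool(rng.random() < p)
        staircase_step(state, correct, cfg)
        if state.terminated:
            break
    else:
        raise StaircaseNonConvergence(
            f"only {len(state.reversal_stimuli)} reversals in {cfg.max_trials} trials"
        )
    used = state.reversal_stimuli[DISCARD_REVERSALS:]
    jnd = float(np.mean(used))
    return StaircaseResult(
        jnd=jnd,
        reversal_stimuli=tuple(state.reversal_stimuli),
        trial_log=tuple(state.trial_log),
    )


def run_staircase_with_responses(
    responses: Sequence[bool], cfg: StaircaseConfig | None = None
) -> StaircaseState:
    """Drive a track with a fixed response sequence (for replaying logs)."""
    cfg = cfg or StaircaseConfig()
    state = StaircaseState(stimulus=cfg.start_stimulus)
    for r in responses:
        staircase_step(state, bool(r), cfg)
        if state.terminated:
            break
    return state
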