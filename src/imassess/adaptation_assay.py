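"""Trial-by-trial adaptation-rate estimation from activation traces.

Per trial, the error angle is the angle between the mean activation vector
in the first 500 ms and the hand-close axis (the target direction).  The
adaptation rate is minus the slope of the first-difference regression

    error_{n+1} - error_n = beta1 * error_n + beta0

so a rate of one means the next trial fully compensates the previous
trial's error, zero means no trial-to-trial correction, and values above
one indicate overshoot (reported as-is; interpretation is left to the
report layer).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .control_mapping import ActivationSample

__all__ = [
    "TrialError",
    "AdaptationFit",
    "InsufficientDataError",
    "UndefinedFitError",
    "trial_error_angle",
    "fit_adaptation",
]

DEFAULT_WINDOW_MS = 500.0


class InsufficientDataError(ValueError):
    """Fewer than three usable trials: the first-difference fit is undefined."""


class UndefinedFitError(ValueError):
    """Zero variance in the regressor (all error angles identical)."""


@dataclass(frozen=True)
class TrialError:
    trial_n: int
    error_angle: float  # degrees, signed; sign follows the thumb component
    missing: bool = False  # all-zero analysis window


@dataclass(frozen=True)
class AdaptationFit:
    beta1: float
    beta0: float
    adaptation_rate: float  # -beta1, by definition
    n_pairs: int
    r_squared: float
    excluded_trials: tuple[int, ...] = field(default_factory=tuple)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "beta1": self.beta1,
                    "beta0": self.beta0,
                    "adaptation_rate": self.adaptation_rate,
                    "n_pairs": self.n_pairs,
                    "r_squared": self.r_squared,
                    "excluded_trials": list(self.excluded_trials),
                },
                indent=2,
            )
        )


def trial_error_angle(
    trace: Sequence[ActivationSample],
    window_ms: float = DEFAULT_WINDOW_MS,
    trial_n: int = 0,
) -> TrialError:
    """Signed error angle of one trial's feedforward intent.

    The activation vector is averaged over the first ``window_ms`` of the
    trace (mean, not endpoint, for robustness to within-window noise) and
    the angle to the +hand-close axis is returned in degrees, signed by the
    thumb component.  An all-zero window is flagged missing rather than
    assigned an angle; the fit drops both consecutive-trial pairs touching
    such a trial.
    """
    if not trace:
        raise ValueError("empty trace")
    t0 = trace[0].t
    horizon = t0 + window_ms / 1000.0
    in_win = [s for s in trace if s.t <= horizon]
    if trace[-1].t < horizon - 1e-12:
        raise ValueError("trace shorter than the analysis window")
    mh = float(np.mean([s.a_hand for s in in_win]))
    mt = float(np.mean([s.a_thumb for s in in_win]))
    if mh == 0.0 and mt == 0.0:
        return TrialError(trial_n=trial_n, error_angle=math.nan, missing=True)
    angle = math.degrees(math.atan2(mt, mh))
    return TrialError(trial_n=trial_n, error_angle=angle)


def fit_adaptation(errors: Sequence[TrialError | float]) -> AdaptationFit:
    """Fit the first-difference error model by ordinary least squares.

    Accepts either ``TrialError`` records or raw error angles in degrees.
    Consecutive-trial pairs are formed only between adjacent usable trials;
    a missing trial removes the pair before and after it.
    """
    recs: list[TrialError] = [
        e if isinstance(e, TrialError) else TrialError(i, float(e))
        for i, e in enumerate(errors)
    ]
    excluded = tuple(r.trial_n for r in recs if r.missing)

    x_list, y_list = [], []
    for prev, nxt in zip(recs, recs[1:]):
        if prev.missing or nxt.missing:
            continue
        x_list.append(prev.error_angle)
        y_list.append(nxt.error_angle - prev.error_angle)

    usable = len(recs) - len(excluded)
    if usable < 3 or len(x_list) < 2:
        raise InsufficientDataError(
            f"need >= 3 usable trials forming >= 2 pairs, got {usable} trials / "
            f"{len(x_list)} pairs"
        )

    x = np.asarray(x_list, dtype=float)
    y = np.asarray(y_list, dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise UndefinedFitError("zero variance in error_n; slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    beta1 = sxy / sxx
    beta0 = float(y.mean() - beta1 * x.mean())

    resid = y - (beta0 + beta1 * x)
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else 1.0

    return AdaptationFit(
        beta1=beta1,
        beta0=beta0,
        adaptation_rate=-beta1,
        n_pairs=len(x_list),
        r_squared=r2,
        excluded_trials=excluded,
    )
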