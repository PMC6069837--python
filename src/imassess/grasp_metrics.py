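"""Performance metrics: submovements, virtual-egg breaks, completion stats.

Trial submovements (TS) counts discrete force corrections within a grasp:
the force profile is smoothed, differentiated three times, and the number
of zero-crossing pairs of the third derivative is returned — each
submovement (a smooth sigmoidal force adjustment) contributes one full
sign-reversal cycle of the force jerk.  The instrumented virtual egg (iVE)
"breaks" when grip force exceeds a preset threshold of approximately
3.1 N; completion rate and mean completion time summarize break-free
transfers in the performance block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "ForceProfile",
    "TrialOutcome",
    "count_submovements",
    "detect_break",
    "completion_rate",
    "mean_completion_time",
]

BREAK_THRESHOLD_N = 3.1
DEFAULT_SMOOTH_CUTOFF_HZ = 8.0
MIN_SAMPLES = 64
# third-derivative excursions below this fraction of the peak magnitude are
# treated as numerical chatter, not sign changes
HYSTERESIS_FRACTION = 0.01


@dataclass(frozen=True)
class ForceProfile:
    """Uniformly sampled grip force in newtons."""

    t: np.ndarray  # seconds
    force: np.ndarray  # newtons, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "force", f)
        if t.size != f.size:
            raise ValueError("t and force must have equal length")
        if t.size < 2:
            raise ValueError("profile too short")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class TrialOutcome:
    success: bool
    broken: bool
    completion_time: float  # seconds
    block: str = "performance"

    def __post_init__(self) -> None:
        if self.broken and self.success:
            raise ValueError("a broken trial cannot be a success")


def count_submovements(
    fp: ForceProfile, smooth_cutoff: float = DEFAULT_SMOOTH_CUTOFF_HZ
) -> int:
    """Count zero-crossing pairs of the third derivative of the force.

    The force is low-pass filtered with a zero-phase Butterworth filter
    before differentiation because triple differentiation amplifies noise
    as the cube of frequency.  Central differences give the third
    derivative; samples whose magnitude is below 1% of the peak are
    ignored (amplitude hysteresis) and the remaining sign changes are
    paired: one pair = one excursion away from zero and back.
    """
    if fp.t.size < MIN_SAMPLES:
        raise ValueError(f"profile must have >= {MIN_SAMPLES} samples")
    fs = fp.fs
    if smooth_cutoff >= fs / 2:
        raise ValueError("smooth_cutoff must be below the Nyquist frequency")
    sos = signal.butter(4, smooth_cutoff, btype="low", fs=fs, output="sos")
    smoothed = signal.sosfiltfilt(sos, fp.force)
    d3 = smoothed
    for _ in range(3):
        d3 = np.gradient(d3, fp.t)

    peak = float(np.max(np.abs(d3)))
    # noise floor: triple differentiation of a flat profile leaves only
    # float rounding error of order eps * |force| * fs^3; stay scale- and
    # offset-invariant by tying the floor to the force scale
    floor = 1e3 * np.finfo(float).eps * float(np.max(np.abs(fp.force))) * fs**3
    if peak <= floor:
        return 0
    signs = np.sign(d3[np.abs(d3) >= HYSTERESIS_FRACTION * peak])
    if signs.size == 0:
        return 0
    changes = int(np.count_nonzero(np.diff(signs)))
    return changes // 2


def detect_break(fp: ForceProfile, threshold: float = BREAK_THRESHOLD_N) -> bool:
    """True iff any force sample strictly exceeds ``threshold`` newtons.

    The comparison is strict — the egg breaks when force is *larger than*
    the preset value — and latched for the whole trial.
    """
    if fp.force.size == 0:
        raise ValueError("empty profile")
    return bool(np.any(fp.force > threshold))


def completion_rate(outcomes: Iterable[TrialOutcome]) -> float:
    """Percentage of successful break-free transfers."""
    outs = list(outcomes)
    if not outs:
        raise ValueError("completion_rate needs at least one outcome")
    return 100.0 * sum(o.success for o in outs) / len(outs)


def mean_completion_time(outcomes: Iterable[TrialOutcome]) -> float | None:
    """Mean completion time over successful, unbroken trials.

    Returns None (a declared-missing value) when no trial succeeded.
    """
    times = [o.completion_time for o in outcomes if o.success and not o.broken]
    if not times:
        return None
    return float(np.mean(times))


def trial_submovement_summary(
    profiles: Sequence[ForceProfile], smooth_cutoff: float = DEFAULT_SMOOTH_CUTOFF_HZ
) -> dict:
    """Per-trial submovement counts plus their mean (the TS measure)."""
    counts = [count_submovements(fp, smooth_cutoff) for fp in profiles]
    return {"per_trial": counts, "mean": float(np.mean(counts)) if counts else None}
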