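"""Synthetic-subject generator with known ground truth.

Emulates a prosthesis user going through the assessment protocol so that
every assay in the package can be validated by parameter recovery:

* trial-to-trial error dynamics are first-order, ``e_{n+1} = (1-a) e_n + eta``
  with ``eta ~ N(0, sd^2)`` — the unique linear generative model whose
  first-difference OLS fit returns the adaptation rate ``a`` in expectation;
* the perception task is answered by a cumulative-Gaussian two-interval
  observer with guess rate 0.5 and a lapse rate;
* grasp-force profiles are built from a known number of smooth submovement
  pulses (minimum-jerk-like sigmoidal force increments) so the submovement
  counter can be checked exactly;
* transfer trials succeed when the generated grip force stays below the
  virtual egg's ~3.1 N break threshold within the time limit.

A session seed derives per-block child seeds by fixed offsets, so each
block is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grasp_metrics import BREAK_THRESHOLD_N, ForceProfile, TrialOutcome, detect_break
from .perception_assay import Observer, StaircaseConfig, StaircaseResult, run_staircase

__all__ = [
    "SubjectParams",
    "ProtocolConfig",
    "SessionDataset",
    "simulate_error_series",
    "simulate_force_trial",
    "simulate_session",
]

DEFAULT_INITIAL_ERROR_DEG = 30.0
DEFAULT_FS_HZ = 100.0

# fixed child-seed offsets per block
_SEED_ADAPTATION = 1
_SEED_STAIRCASE = 2
_SEED_TRANSFER = 3


@dataclass(frozen=True)
class SubjectParams:
    """Generative ground truth for one synthetic subject."""

    true_adaptation_rate: float = 0.75  # dimensionless, typ. 0-1.3
    error_noise_sd: float = 2.0  # degrees
    true_jnd: float = 50.0  # degrees of control-space rotation
    psychometric_slope: float = 10.0  # degrees (Gaussian SD)
    lapse_rate: float = 0.02
    guess_rate: float = 0.5  # fixed by the 2-interval design
    submovements_mean: float = 3.5  # pulses per grasp trial
    peak_force_range: tuple[float, float] = (2.4, 4.0)  # newtons
    completion_time_mean: float = 8.35  # s, subject's typical transfer time
    completion_time_sd: float = 0.7  # s, trial-to-trial scatter
    initial_error: float = DEFAULT_INITIAL_ERROR_DEG  # degrees
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 1 or not 0 <= self.guess_rate <= 1:
            raise ValueError("rates must be probabilities in [0, 1]")
        if self.error_noise_sd < 0:
            raise ValueError("error_noise_sd must be >= 0")
        if self.true_jnd <= 0:
            raise ValueError("true_jnd must be positive")
        lo, hi = self.peak_force_range
        if not (0 < lo < hi):
            raise ValueError("peak_force_range must be a positive interval")

    def observer(self) -> Observer:
        return Observer(
            threshold=self.true_jnd,
            slope=self.psychometric_slope,
            guess_rate=self.guess_rate,
            lapse_rate=self.lapse_rate,
        )


@dataclass(frozen=True)
class ProtocolConfig:
    """Block structure of the assessment protocol."""

    n_training_trials: int = 40  # 25 fragile + 15 rigid
    n_training_fragile: int = 25
    n_adaptation_trials: int = 40
    adaptation_time_limit: float = 5.0  # s
    staircase_trial_time: float = 4.0  # s
    n_transfer_trials: int = 20
    transfer_time_limit: float = 10.0  # s
    break_threshold: float = BREAK_THRESHOLD_N  # newtons
    fs: float = DEFAULT_FS_HZ  # force/activation sampling rate, Hz

    def __post_init__(self) -> None:
        for name in ("n_training_trials", "n_adaptation_trials", "n_transfer_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "adaptation_time_limit",
            "staircase_trial_time",
            "transfer_time_limit",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def simulate_error_series(
    a: float,
    sd: float,
    n: int,
    e0: float = DEFAULT_INITIAL_ERROR_DEG,
    seed: int = 0,
) -> np.ndarray:
    """Generate ``n`` trial error angles under first-order adaptation.

    ``e_{n+1} = (1 - a) e_n + eta`` with ``eta ~ N(0, sd^2)``.  With
    ``sd = 0`` the series is the exact geometric decay ``(1-a)^k * e0``;
    a = 1 zeroes every error after the first (perfect adaptation), a = 0
    leaves the error untouched.
    """
    if n < 3:
        raise ValueError("n must be >= 3 (the downstream fit needs >= 2 pairs)")
    if not np.isfinite(a):
        raise ValueError("adaptation rate must be finite")
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    e = np.empty(n, dtype=float)
    e[0] = e0
    for i in range(n - 1):
        eta = rng.normal(0.0, sd) if sd > 0 else 0.0
        e[i + 1] = (1.0 - a) * e[i] + eta
    return e


def _raised_cosine_cubed_rate(tau: np.ndarray) -> np.ndarray:
    """Unit-support C^5 bell: ((1 - cos(2 pi tau)) / 2)^3 on [0, 1]."""
    r = np.zeros_like(tau)
    inside = (tau >= 0.0) & (tau <= 1.0)
    r[inside] = ((1.0 - np.cos(2.0 * np.pi * tau[inside])) / 2.0) ** 3
    return r


_RATE_MEAN = 5.0 / 16.0  # integral of sin^6 over one period


def simulate_force_trial(
    k_submovements: int,
    duration: float = 5.0,
    fs: float = DEFAULT_FS_HZ,
    peak: float = 2.5,
    seed: int = 0,
) -> ForceProfile:
    """Build a grasp-force profile from ``k`` smooth submovement pulses.

    Each submovement is a sigmoidal force increment whose rate is a
    raised-cosine-cubed bell, so the force is C^6 inside each pulse and the
    third derivative traces one clean +/-/+ sign cycle per pulse.  The
    grasp builds up progressively: the first pulse establishes 0.65 * peak
    and the remaining ``k - 1`` pulses share a further 0.25 * peak, so the
    force is a monotone staircase of corrective increments.  Supports
    never overlap; pulse centers are jittered within their slots by
    ``seed``.  Noise-free output satisfies
    ``count_submovements(profile) == k`` and ``max force <= peak``.
    """
    if k_submovements < 0:
        raise ValueError("k_submovements must be >= 0")
    n = int(round(fs * duration))
    if n < 64:
        raise ValueError("fs * duration must give at least 64 samples")
    t = np.arange(n) / fs

    baseline = 0.05 * peak
    if k_submovements == 0:
        return ForceProfile(t=t, force=np.full(n, baseline))

    slot = duration / k_submovements
    width = min(0.8, 0.6 * slot)
    if width < 0.25:
        raise ValueError(
            f"{k_submovements} pulse supports of >= 0.25 s cannot fit in "
            f"{duration} s"
        )
    rng = np.random.default_rng(seed)

    rate = np.zeros(n)
    for i in range(k_submovements):
        # height: grasp onset, then smaller corrective increments
        delta = 0.65 * peak if i == 0 else 0.25 * peak / (k_submovements - 1)
        slot_lo = i * slot + 0.5 * (slot - width)
        jitter = rng.uniform(-0.1, 0.1) * (slot - width)
        start = np.clip(slot_lo + jitter, i * slot, (i + 1) * slot - width)
        amp = delta / (width * _RATE_MEAN)
        rate += amp * _raised_cosine_cubed_rate((t - start) / width)

    force = baseline + np.cumsum(rate) / fs
    return ForceProfile(t=t, force=force)


@dataclass
class SessionDataset:
    """All logs one synthetic subject produces in a session.

    Serialized as four flat files: ``trials.csv`` (time-sampled activation
    and force), ``outcomes.csv`` (per-trial success/break/time),
    ``staircase.csv`` (stimulus/response track) and ``config.json``.
    """

    trials: pd.DataFrame
    outcomes: pd.DataFrame
    staircase: pd.DataFrame
    config: dict
    error_angles: np.ndarray = field(repr=False)
    staircase_result: StaircaseResult = field(repr=False)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.staircase.to_csv(out / "staircase.csv", index=False)
        (out / "config.json").write_text(json.dumps(self.config, indent=2))
        return out

    @staticmethod
    def read(in_dir: str | Path) -> "SessionDataset":
        p = Path(in_dir)
        trials = pd.read_csv(p / "trials.csv")
        outcomes = pd.read_csv(p / "outcomes.csv")
        staircase = pd.read_csv(p / "staircase.csv")
        config = json.loads((p / "config.json").read_text())
        return SessionDataset(
            trials=trials,
            outcomes=outcomes,
            staircase=staircase,
            config=config,
            error_angles=np.array([]),
            staircase_result=None,  # type: ignore[arg-type]
        )


def _adaptation_block(
    params: SubjectParams, protocol: ProtocolConfig, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Activation + force logs for the adaptation-rate test block.

    Within a trial the activation is a constant-direction ramp toward the
    trial's error direction (the study does not describe within-trial
    trajectories beyond the 500 ms analysis window; a ramp is the simplest
    profile consistent with it).
    """
    errors = simulate_error_series(
        a=params.true_adaptation_rate,
        sd=params.error_noise_sd,
        n=protocol.n_adaptation_trials,
        e0=params.initial_error,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1000)
    fs = protocol.fs
    n_samp = int(round(fs * protocol.adaptation_time_limit))
    t = np.arange(n_samp) / fs
    ramp = np.clip(t / 0.5, 0.0, 1.0)  # reach full activation at 500 ms

    frames = []
    for trial, err in enumerate(errors):
        theta = np.radians(err)
        k = int(np.clip(rng.poisson(params.submovements_mean), 1, 5))
        peak = rng.uniform(*params.peak_force_range)
        fp = simulate_force_trial(
            k, duration=protocol.adaptation_time_limit, fs=fs, peak=peak,
            seed=int(rng.integers(2**31 - 1)),
        )
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial,
                    "block": "adaptation",
                    "t": t,
                    "a_hand": ramp * np.cos(theta),
                    "a_thumb": ramp * np.sin(theta),
                    "force_N": fp.force,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), errors


def _transfer_block(
    params: SubjectParams, protocol: ProtocolConfig, seed: int
) -> pd.DataFrame:
    """Outcome log for the barrier-transfer performance block.

    A trial breaks the egg when its generated grip force exceeds the
    threshold (latched); success requires no break and completion within
    the time limit.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(protocol.n_transfer_trials):
        k = int(np.clip(rng.poisson(params.submovements_mean), 1, 5))
        peak = rng.uniform(*params.peak_force_range)
        fp = simulate_force_trial(
            k, duration=protocol.transfer_time_limit, fs=protocol.fs,
            peak=peak, seed=int(rng.integers(2**31 - 1)),
        )
        broken = detect_break(fp, protocol.break_threshold)
        completion = float(
            np.clip(
                rng.normal(params.completion_time_mean, params.completion_time_sd),
                5.0, 12.0,
            )
        )
        success = (not broken) and completion <= protocol.transfer_time_limit
        rows.append(
            {
                "trial_id": trial,
                "success": int(success),
                "broken": int(broken),
                "completion_time_s": completion,
            }
        )
    return pd.DataFrame(rows)


def simulate_session(
    params: SubjectParams, protocol: ProtocolConfig | None = None
) -> SessionDataset:
    """Run one synthetic subject through the full protocol.

    Emits the adaptation-block error/activation/force logs, the staircase
    response stream (delegating to the two-interval observer), and the
    transfer-trial outcome log.  Fully reproducible from ``params.rng_seed``.
    """
    protocol = protocol or ProtocolConfig()
    seed = int(params.rng_seed)

    trials, errors = _adaptation_block(params, protocol, seed + _SEED_ADAPTATION)

    sc_result = run_staircase(
        params.observer(), StaircaseConfig(), seed=seed + _SEED_STAIRCASE
    )
    staircase = pd.DataFrame(sc_result.to_rows())

    outcomes = _transfer_block(params, protocol, seed + _SEED_TRANSFER)

    config = {
        "subject": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(params).items()
        },
        "protocol": asdict(protocol),
    }
    return SessionDataset(
        trials=trials,
        outcomes=outcomes,
        staircase=staircase,
        config=config,
        error_angles=errors,
        staircase_result=sc_result,
    )


def outcomes_from_frame(df: pd.DataFrame) -> list[TrialOutcome]:
    """Rehydrate TrialOutcome records from an outcomes.csv frame."""
    return [
        TrialOutcome(
            success=bool(r.success),
            broken=bool(r.broken),
            completion_time=float(r.completion_time_s),
        )
        for r in df.itertuples()
    ]
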