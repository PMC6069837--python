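"""Classifier gating, control-space rotation and audio-feedback mapping.

The decoder emits simultaneous proportional activations on two degrees of
freedom — hand open/close and thumb adduction/abduction.  Classifier-style
control gates these so at most one DOF is active at a time (winner-take-all
with a deadband).  Perturbations for the perception task are rotations of
the (hand, thumb) activation plane.  Audio feedback assigns one carrier
frequency per DOF direction with amplitude proportional to activation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ActivationSample",
    "AudioMapConfig",
    "AudioEvent",
    "gate_winner_take_all",
    "rotate_control",
    "audio_map",
]

DEFAULT_DEADBAND = 0.05  # fraction of full-scale activation


@dataclass(frozen=True)
class ActivationSample:
    """One time-stamped sample of the 2-DOF control signal.

    Sign convention: positive ``a_hand`` closes the hand, positive
    ``a_thumb`` adducts the thumb.  Activations are normalized to [-1, 1].
    """

    t: float
    a_hand: float
    a_thumb: float


@dataclass(frozen=True)
class AudioMapConfig:
    """Frequency assignment for the audio feedback channel.

    Hand open/close carry 500/400 Hz; thumb adduction/abduction carry
    900/800 Hz.  Amplitude is ``gain`` times the absolute activation.
    """

    f_open: float = 500.0
    f_close: float = 400.0
    f_adduct: float = 900.0
    f_abduct: float = 800.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        freqs = {self.f_open, self.f_close, self.f_adduct, self.f_abduct}
        if len(freqs) != 4:
            raise ValueError("the four DOF-direction frequencies must be distinct")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass(frozen=True)
class AudioEvent:
    t: float
    frequency: float
    amplitude: float


def gate_winner_take_all(
    s: ActivationSample, deadband: float = DEFAULT_DEADBAND
) -> ActivationSample:
    """Retain only the larger-magnitude DOF; zero both below the deadband.

    Ties go to the hand DOF (the task-primary channel in every block).
    Idempotent: gating a gated sample is a no-op.
    """
    if deadband < 0:
        raise ValueError("deadband must be non-negative")
    ah, at = s.a_hand, s.a_thumb
    if abs(ah) < deadband and abs(at) < deadband:
        return ActivationSample(s.t, 0.0, 0.0)
    if abs(ah) >= abs(at):
        return ActivationSample(s.t, ah, 0.0)
    return ActivationSample(s.t, 0.0, at)


def rotate_control(s: ActivationSample, angle_deg: float) -> ActivationSample:
    """Rotate the activation vector counter-clockwise in the (hand, thumb) plane.

    A 90 degree rotation maps a pure thumb activation onto the hand axis
    (up to sign) — the perturbation used by the perception-threshold task.
    Norm-preserving.
    """
    if not math.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    th = math.radians(angle_deg)
    c, sn = math.cos(th), math.sin(th)
    return ActivationSample(
        s.t,
        c * s.a_hand - sn * s.a_thumb,
        sn * s.a_hand + c * s.a_thumb,
    )


def audio_map(
    trace: Iterable[ActivationSample], cfg: AudioMapConfig | None = None
) -> list[AudioEvent]:
    """Map an activation trace to a stream of audio events.

    Each nonzero DOF direction emits its assigned carrier with amplitude
    ``gain * |activation|``; rest emits nothing.  The mapping is positively
    homogeneous: doubling activations doubles amplitudes, frequencies fixed.
    """
    cfg = cfg or AudioMapConfig()
    events: list[AudioEvent] = []
    for s in trace:
        if s.a_hand > 0:
            events.append(AudioEvent(s.t, cfg.f_close, cfg.gain * s.a_hand))
        elif s.a_hand < 0:
            events.append(AudioEvent(s.t, cfg.f_open, cfg.gain * -s.a_hand))
        if s.a_thumb > 0:
            events.append(AudioEvent(s.t, cfg.f_adduct, cfg.gain * s.a_thumb))
        elif s.a_thumb < 0:
            events.append(AudioEvent(s.t, cfg.f_abduct, cfg.gain * -s.a_thumb))
    return events


def audio_events_to_rows(events: Sequence[AudioEvent]) -> list[dict]:
    """Rows for CSV serialization (t, freq_hz, amplitude)."""
    return [
        {"t": e.t, "freq_hz": e.frequency, "amplitude": e.amplitude} for e in events
    ]
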