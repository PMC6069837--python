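"""End-to-end assessment of a recorded (or simulated) session.

Turns the raw session logs — time-sampled activations and forces,
staircase track, transfer outcomes — into the six outcome measures:
adaptation rate, JND, internal-model uncertainty, completion rate, mean
completion time and trial submovements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adaptation_assay import TrialError, fit_adaptation, trial_error_angle
from .control_mapping import ActivationSample
from .grasp_metrics import ForceProfile, trial_submovement_summary
from .internal_model import compute_pparam
from .perception_assay import DISCARD_REVERSALS
from .stats_report import OutcomeSet
from .synthetic_subject import SessionDataset, outcomes_from_frame
from .grasp_metrics import completion_rate, mean_completion_time

__all__ = ["error_angles_from_trials", "jnd_from_staircase", "assess_session"]


def error_angles_from_trials(trials: pd.DataFrame, window_ms: float = 500.0) -> list[TrialError]:
    """Per-trial signed error angles from a trials.csv frame (adaptation block)."""
    adapt = trials[trials["block"] == "adaptation"]
    errors = []
    for trial_id, g in adapt.groupby("trial_id", sort=True):
        trace = [
            ActivationSample(t=row.t, a_hand=row.a_hand, a_thumb=row.a_thumb)
            for row in g.itertuples()
        ]
        errors.append(trial_error_angle(trace, window_ms=window_ms, trial_n=int(trial_id)))
    return errors


def jnd_from_staircase(staircase: pd.DataFrame) -> float:
    """Recompute the JND from a logged staircase track.

    Mean of the reversal stimuli after the approach phase (first seven
    reversals discarded), identical to the live estimator.
    """
    rev = staircase.loc[staircase["reversal_flag"] == 1, "stimulus_deg"].to_numpy()
    if rev.size <= DISCARD_REVERSALS:
        raise ValueError("too few reversals logged to estimate a JND")
    return float(np.mean(rev[DISCARD_REVERSALS:]))


def force_profiles_from_trials(trials: pd.DataFrame) -> list[ForceProfile]:
    adapt = trials[trials["block"] == "adaptation"]
    return [
        ForceProfile(t=g["t"].to_numpy(), force=g["force_N"].to_numpy())
        for _, g in adapt.groupby("trial_id", sort=True)
    ]


def assess_session(ds: SessionDataset, condition: str = "NF") -> OutcomeSet:
    """Compute all six outcome measures for one session."""
    errors = error_angles_from_trials(ds.trials)
    fit = fit_adaptation(errors)
    jnd = jnd_from_staircase(ds.staircase)
    pparam = compute_pparam(fit.adaptation_rate, jnd)

    outs = outcomes_from_frame(ds.outcomes)
    cr = completion_rate(outs)
    mct = mean_completion_time(outs)

    ts = trial_submovement_summary(force_profiles_from_trials(ds.trials))

    return OutcomeSet(
        condition=condition,
        adaptation_rate=fit.adaptation_rate,
        jnd=jnd,
        p_param=pparam.p_param,
        cr=cr,
        mct=mct,
        ts=ts["mean"],
    )
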