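"""Staircase convergence experiment: does the JND sit at the 0.84 point?

Runs 200 seeded weighted up-down staircases against a cumulative-Gaussian
observer (threshold 40 deg, slope 10 deg, lapse 0.02) and evaluates the
observer's analytic detection probability at each estimated JND.  The
weighted rule's stationary point is the stimulus answered correctly with
probability 0.84, so the mean of these probabilities should match that
target.  Writes results/staircase_convergence.json.
"""

import json
from pathlib import Path

import numpy as np

from imassess.perception_assay import Observer, psychometric_prob, run_staircase

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    obs = Observer(threshold=40.0, slope=10.0, lapse_rate=0.02)
    jnds, probs, n_trials = [], [], []
    for seed in range(1, 201):
        r = run_staircase(obs, seed=seed)
        jnds.append(r.jnd)
        probs.append(psychometric_prob(obs, r.jnd))
        n_trials.append(len(r.trial_log))

    summary = {
        "observer": {"threshold_deg": 40.0, "slope_deg": 10.0, "lapse": 0.02},
        "n_runs": len(jnds),
        "mean_jnd_deg": float(np.mean(jnds)),
        "sd_jnd_deg": float(np.std(jnds, ddof=1)),
        "mean_detection_prob_at_jnd": float(np.mean(probs)),
        "target_probability": 0.84,
        "mean_trials_per_staircase": float(np.mean(n_trials)),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "staircase_convergence.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
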