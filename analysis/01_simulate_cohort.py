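"""Simulate the study cohort: 7 subjects x 2 feedback conditions, plus retest.

Ground-truth subject parameters are drawn around the group-level reference
values for each condition (no-augmented feedback NF: adaptation rate 0.75,
JND 58.5 deg, ~3.3 submovements/trial; audio-augmented feedback AF: rate
1.2, JND 44.6 deg, ~3.9 submovements/trial), with between-subject scatter.
AF subjects also grip more carefully (lower peak forces against the 3.1 N
break threshold), which is what produces their higher completion rate.

Session logs (trials/outcomes/staircase CSVs) go to scratch/sessions/;
the cohort manifest with each subject's ground truth goes to
results/cohort_manifest.json.
"""

import json
from pathlib import Path

import numpy as np

from imassess.synthetic_subject import ProtocolConfig, SubjectParams, simulate_session

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"

N_SUBJECTS = 7
MASTER_SEED = 20260925

CONDITIONS = {
    "NF": {"rate": 0.75, "rate_sd": 0.15, "jnd": 58.5, "jnd_sd": 12.5,
           "submovements": 3.26, "peak_range": (2.6, 4.2)},
    "AF": {"rate": 1.20, "rate_sd": 0.25, "jnd": 44.6, "jnd_sd": 10.0,
           "submovements": 3.94, "peak_range": (2.2, 3.6)},
}


def draw_subject(cond_cfg: dict, rng: np.random.Generator, seed: int) -> SubjectParams:
    # subject traits: grip-force tendency and typical transfer pace vary
    # between subjects (this between-subject variance is what the
    # test-retest ICC of CR and MCT measures)
    force_shift = float(rng.normal(0.0, 0.3))
    lo, hi = cond_cfg["peak_range"]
    return SubjectParams(
        true_adaptation_rate=float(rng.normal(cond_cfg["rate"], cond_cfg["rate_sd"])),
        error_noise_sd=2.0,
        true_jnd=float(np.clip(rng.normal(cond_cfg["jnd"], cond_cfg["jnd_sd"]), 10, 85)),
        submovements_mean=cond_cfg["submovements"],
        peak_force_range=(lo + force_shift, hi + force_shift),
        completion_time_mean=float(rng.normal(8.35, 0.45)),
        completion_time_sd=0.35,
        rng_seed=seed,
    )


def main() -> None:
    rng = np.random.default_rng(MASTER_SEED)
    protocol = ProtocolConfig()
    manifest = {"protocol": "default", "sessions": []}

    # each subject does NF, then AF, then retests NF; the retest keeps the
    # subject's NF ground truth (same person, new session) with a new seed
    for subj in range(N_SUBJECTS):
        nf_params = draw_subject(CONDITIONS["NF"], rng, 0)
        af_params = draw_subject(CONDITIONS["AF"], rng, 0)
        for session_name, cond, base in (("NF", "NF", nf_params),
                                         ("AF", "AF", af_params),
                                         ("NF_retest", "NF", nf_params)):
            seed = MASTER_SEED + 1000 * subj + {"NF": 1, "AF": 2, "NF_retest": 3}[session_name]
            params = SubjectParams(**{**base.__dict__, "rng_seed": seed})
            ds = simulate_session(params, protocol)
            out = SESSIONS / f"subj{subj:02d}_{session_name}"
            ds.write(out)
            manifest["sessions"].append(
                {
                    "subject": subj,
                    "session": session_name,
                    "condition": cond,
                    "dir": str(out.relative_to(ROOT)),
                    "truth": {
                        "adaptation_rate": params.true_adaptation_rate,
                        "jnd": params.true_jnd,
                        "submovements_mean": params.submovements_mean,
                    },
                }
            )
            print(f"subject {subj} {session_name}: "
                  f"true rate {params.true_adaptation_rate:.2f}, "
                  f"true JND {params.true_jnd:.1f} deg -> {out.name}")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"\n{len(manifest['sessions'])} sessions written under {SESSIONS}")


if __name__ == "__main__":
    main()
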