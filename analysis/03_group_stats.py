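"""Group-level comparison of the two feedback conditions, plus NF retest.

Builds the study report from results/outcomes.csv: per-condition summary
(mean, SD, the 1.97-SD confidence interval), Levene-gated paired tests
between conditions for all six measures, the completion-rate ratio, and
the test-retest ICC block (two-way mixed, absolute agreement) for the NF
condition.  Writes results/report.json and results/report.md.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from imassess.stats_report import OutcomeSet, build_report, report_to_json, report_to_markdown

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

MEASURES = ("adaptation_rate", "jnd", "p_param", "cr", "mct", "ts")


def to_outcome_sets(df: pd.DataFrame, condition: str) -> list[OutcomeSet]:
    return [
        OutcomeSet(condition=condition, **{m: float(r[m]) for m in MEASURES})
        for _, r in df.sort_values("subject").iterrows()
    ]


def main() -> None:
    df = pd.read_csv(RESULTS / "outcomes.csv")
    nf = df[df["session"] == "NF"]
    af = df[df["session"] == "AF"]
    retest = df[df["session"] == "NF_retest"]

    outcomes = {"AF": to_outcome_sets(af, "AF"), "NF": to_outcome_sets(nf, "NF")}

    retest_matrices = {}
    for m in ("adaptation_rate", "jnd", "p_param", "cr", "mct"):
        first = nf.sort_values("subject")[m].to_numpy()
        second = retest.sort_values("subject")[m].to_numpy()
        retest_matrices[m] = np.column_stack([first, second])

    report = build_report(outcomes, retest=retest_matrices)
    report_to_json(report, RESULTS / "report.json")
    (RESULTS / "report.md").write_text(report_to_markdown(report))

    print(report_to_markdown(report))
    print(f"wrote {RESULTS / 'report.json'} and report.md")


if __name__ == "__main__":
    main()
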