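"""Statistical comparison layer and study report assembly.

The comparison rule mirrors the study design: Levene's test gates each
paired contrast at alpha = 0.05 — homogeneous variances go to a two-sample
paired t-test, nonhomogeneous ones to a Wilcoxon signed-rank test.
Test-retest reliability uses the intraclass correlation from a two-way
mixed-effects model with absolute agreement, single measure (ICC(A,1) in
McGraw & Wong's taxonomy).  Confidence intervals follow the reported
convention mean +/- 1.97 * SD (the multiplier is kept verbatim).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeSet",
    "ComparisonResult",
    "choose_and_run_comparison",
    "icc_absolute_agreement",
    "ci95",
    "cr_ratio",
    "build_report",
]

ALPHA = 0.05
CI_MULTIPLIER = 1.97  # reported convention; deliberately not 1.96

OUTCOME_MEASURES = ("adaptation_rate", "jnd", "p_param", "cr", "mct", "ts")
ICC_MEASURES = ("adaptation_rate", "jnd", "p_param", "cr", "mct")


@dataclass(frozen=True)
class OutcomeSet:
    """One subject's outcome measures under one feedback condition."""

    condition: str  # "NF" (no augmented feedback) or "AF" (audio feedback)
    adaptation_rate: float | None = None
    jnd: float | None = None  # degrees
    p_param: float | None = None
    cr: float | None = None  # percent
    mct: float | None = None  # seconds
    ts: float | None = None  # submovements per trial


@dataclass(frozen=True)
class ComparisonResult:
    measure: str
    test_name: str  # levene-gated: "paired_t" or "wilcoxon_signed_rank"
    statistic: float
    dof: int | None
    p_value: float
    levene_p: float
    significant: bool


def ci95(mean: float, sd: float) -> tuple[float, float]:
    """95% CI as mean +/- 1.97 * SD, per the reporting convention."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    half = CI_MULTIPLIER * sd
    return (mean - half, mean + half)


def cr_ratio(cr_af: float, cr_nf: float) -> float:
    """Ratio of completion rates between two conditions (AF over NF)."""
    if cr_nf <= 0:
        raise ValueError("reference completion rate must be positive")
    return cr_af / cr_nf


def choose_and_run_comparison(
    x: Sequence[float], y: Sequence[float], measure: str = ""
) -> ComparisonResult:
    """Levene-gated paired comparison of two equal-length paired samples.

    Levene p >= alpha (homogeneous variances) selects the paired t-test;
    otherwise the Wilcoxon signed-rank test (exact distribution for
    n <= 25, normal approximation with continuity correction above).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")

    lev_stat, lev_p = stats.levene(x, y)

    if lev_p >= ALPHA:
        if np.array_equal(x, y):
            # identical samples: zero difference everywhere, no evidence
            stat, p, dof, name = 0.0, 1.0, n - 1, "paired_t"
        else:
            t_res = stats.ttest_rel(x, y)
            stat, p, dof, name = (
                float(t_res.statistic),
                float(t_res.pvalue),
                n - 1,
                "paired_t",
            )
    else:
        method = "exact" if n <= 25 else "approx"
        w_res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=(method == "approx"),
            mode=method,
        )
        stat, p, dof, name = (
            float(w_res.statistic),
            float(w_res.pvalue),
            None,
            "wilcoxon_signed_rank",
        )

    return ComparisonResult(
        measure=measure,
        test_name=name,
        statistic=stat,
        dof=dof,
        p_value=p,
        levene_p=float(lev_p),
        significant=bool(p < ALPHA),
    )


def independent_t(x: Sequence[float], y: Sequence[float], measure: str = "") -> dict:
    """Two-sample independent t-test (used for trial-level submovements)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = stats.ttest_ind(x, y)
    return {
        "measure": measure,
        "test_name": "independent_t",
        "statistic": float(res.statistic),
        "dof": int(x.size + y.size - 2),
        "p_value": float(res.pvalue),
    }


def icc_absolute_agreement(matrix: np.ndarray) -> float:
    """ICC(A,1): two-way model, absolute agreement, single measure.

    ``matrix`` is subjects x sessions with no missing cells.  Computed via
    pingouin's intraclass correlation (its single-measure absolute-
    agreement row, the McGraw-Wong ICC(A,1) coefficient).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 sessions")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not allowed")

    import pingouin as pg

    n_sub, n_ses = m.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_sub), n_ses),
            "session": np.tile(np.arange(n_ses), n_sub),
            "score": m.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="session", ratings="score"
    )
    # pingouin labels the single-measure absolute-agreement row ICC(A,1)
    # in recent versions and ICC2 in older ones
    row = table[table["Type"].isin(["ICC(A,1)", "ICC2"])]
    return float(row["ICC"].iloc[0])


def _summary(values: Sequence[float]) -> dict:
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        return {"mean": None, "sd": None, "ci95": None, "n": 0}
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return {"mean": mean, "sd": sd, "ci95": list(ci95(mean, sd)), "n": int(vals.size)}


def build_report(
    outcomes: Mapping[str, Sequence[OutcomeSet]],
    retest: Mapping[str, np.ndarray] | None = None,
) -> dict:
    """Assemble the per-condition outcome report.

    ``outcomes`` maps condition name -> one OutcomeSet per subject.
    ``retest``, if given, maps measure name -> subjects x sessions matrix
    for the test-retest reliability block (ICC per measure).  Pure
    function of its inputs; missing assay outputs are flagged, not fatal.
    """
    report: dict = {"conditions": {}, "comparisons": [], "missing": []}

    for cond, sets in outcomes.items():
        report["conditions"][cond] = {
            m: _summary([getattr(s, m) for s in sets]) for m in OUTCOME_MEASURES
        }

    conds = list(outcomes)
    if len(conds) == 2:
        a, b = conds
        for m in OUTCOME_MEASURES:
            xa = [getattr(s, m) for s in outcomes[a]]
            xb = [getattr(s, m) for s in outcomes[b]]
            if any(v is None for v in xa + xb) or len(xa) != len(xb) or len(xa) < 3:
                report["missing"].append(m)
                continue
            res = choose_and_run_comparison(xa, xb, measure=m)
            report["comparisons"].append(asdict(res))

        cr_a = report["conditions"][a]["cr"]["mean"]
        cr_b = report["conditions"][b]["cr"]["mean"]
        if cr_a is not None and cr_b and cr_b > 0:
            report["cr_ratio"] = {"numerator": a, "denominator": b,
                                  "value": cr_ratio(cr_a, cr_b)}

    if retest is not None:
        report["test_retest"] = {}
        for m in ICC_MEASURES:
            if m not in retest:
                report["missing"].append(f"retest:{m}")
                continue
            report["test_retest"][m] = {"icc": icc_absolute_agreement(retest[m])}

    return report


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def report_to_markdown(report: dict) -> str:
    """Compact markdown rendering of a study report."""
    lines = ["# Internal-model assessment report", "", "## Outcome measures", ""]
    header = "| measure | " + " | ".join(report["conditions"]) + " |"
    lines += [header, "|" + "---|" * (len(report["conditions"]) + 1)]
    for m in OUTCOME_MEASURES:
        cells = []
        for cond in report["conditions"]:
            s = report["conditions"][cond][m]
            cells.append(
                "-" if s["mean"] is None else f"{s['mean']:.3g} ± {s['sd']:.2g}"
            )
        lines.append(f"| {m} | " + " | ".join(cells) + " |")
    if report.get("comparisons"):
        lines += ["", "## Paired comparisons", ""]
        for c in report["comparisons"]:
            lines.append(
                f"- {c['measure']}: {c['test_name']} statistic={c['statistic']:.3g}, "
                f"p={c['p_value']:.3g}"
                + (" (significant)" if c["significant"] else "")
            )
    if "cr_ratio" in report:
        r = report["cr_ratio"]
        lines.append(
            f"- completion-rate ratio {r['numerator']}/{r['denominator']}: "
            f"{r['value']:.2f}"
        )
    if "test_retest" in report:
        lines += ["", "## Test-retest reliability (ICC, absolute agreement)", ""]
        for m, v in report["test_retest"].items():
            lines.append(f"- {m}: ICC = {v['icc']:.3g}")
    return "\n".join(lines) + "\n"
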