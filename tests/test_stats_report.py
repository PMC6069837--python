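"""Comparison layer: Levene gating, paired tests, ICC, CI convention."""

import numpy as np
import pytest
from scipy import stats

from imassess.stats_report import (
    OutcomeSet,
    build_report,
    choose_and_run_comparison,
    ci95,
    cr_ratio,
    icc_absolute_agreement,
    report_to_markdown,
)


def icc_a1_oracle(m):
    """From-scratch two-way ANOVA variance-components ICC(A,1)."""
    m = np.asarray(m, float)
    n, k = m.shape
    gm = m.mean()
    ssr = k * np.sum((m.mean(axis=1) - gm) ** 2)
    ssc = n * np.sum((m.mean(axis=0) - gm) ** 2)
    sse = np.sum((m - gm) ** 2) - ssr - ssc
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestComparison:
    def test_identical_samples_no_difference(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = choose_and_run_comparison(x, x)
        assert res.test_name == "paired_t"
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_paired_t_matches_hand_formula(self):
        x = np.array([1.2, 0.8, 1.5, 1.1, 0.9])
        y = np.array([0.7, 0.9, 1.0, 0.8, 0.6])
        res = choose_and_run_comparison(x, y)
        assert res.test_name == "paired_t"
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_hand, abs=1e-9)
        assert res.dof == 4

    def test_heteroscedastic_fixture_takes_wilcoxon_branch(self):
        # y's variance is ~400x x's; Levene must flag inhomogeneity
        x = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.97, 1.01]
        y = [10.0, -8.0, 14.0, -12.0, 9.0, -11.0, 13.0, -7.0]
        assert stats.levene(x, y).pvalue < 0.05  # fixture sanity
        res = choose_and_run_comparison(x, y)
        assert res.test_name == "wilcoxon_signed_rank"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            choose_and_run_comparison([1, 2, 3], [1, 2])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            choose_and_run_comparison([1, 2], [3, 4])


class TestICC:
    def test_identical_sessions_give_unity(self):
        m = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            assert icc_absolute_agreement(m) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(200, 2))
        assert abs(icc_absolute_agreement(m)) < 0.1

    def test_matches_variance_components_oracle(self):
        m = np.array(
            [[9.0, 2.0], [8.0, 1.0], [7.0, 4.0], [10.0, 6.0], [6.0, 3.0], [4.0, 2.0]]
        )
        assert icc_absolute_agreement(m) == pytest.approx(icc_a1_oracle(m), abs=1e-9)

    def test_recovers_generative_reliability(self):
        rng = np.random.default_rng(1)
        sb2, se2 = 2.0, 1.0
        subj = rng.normal(0, np.sqrt(sb2), size=(200, 1))
        m = subj + rng.normal(0, np.sqrt(se2), size=(200, 2))
        assert icc_absolute_agreement(m) == pytest.approx(sb2 / (sb2 + se2), abs=0.05)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
        with pytest.raises(ValueError):
            icc_absolute_agreement(m)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.array([[1.0, 2.0], [3.0, 4.0]]))


class TestCI95:
    def test_printed_formula(self):
        lo, hi = ci95(0.75, 0.15)
        assert lo == pytest.approx(0.75 - 1.97 * 0.15, abs=1e-12)
        assert hi == pytest.approx(0.75 + 1.97 * 0.15, abs=1e-12)
        assert (lo, hi) == pytest.approx((0.4545, 1.0455))

    def test_degenerate_sd(self):
        assert ci95(3.2, 0.0) == (3.2, 3.2)

    def test_symmetric_about_mean(self):
        lo, hi = ci95(-1.4, 2.3)
        assert (lo + hi) / 2 == pytest.approx(-1.4, abs=1e-12)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ci95(0.0, -1.0)


def _cohort(condition, rng, shift=0.0):
    return [
        OutcomeSet(
            condition=condition,
            adaptation_rate=rng.normal(0.9 + shift, 0.1),
            jnd=rng.normal(50 - 10 * shift, 5),
            p_param=rng.normal(1.0 - shift, 0.2),
            cr=rng.normal(50 + 20 * shift, 8),
            mct=rng.normal(8.4, 0.5),
            ts=rng.normal(3.5 + shift / 2, 0.3),
        )
        for _ in range(7)
    ]


@pytest.fixture(scope="module")
def report():
    rng = np.random.default_rng(5)
    outcomes = {"AF": _cohort("AF", rng, shift=0.3), "NF": _cohort("NF", rng)}
    retest = {
        m: np.random.default_rng(6).normal(size=(6, 2)) + np.arange(6)[:, None]
        for m in ("adaptation_rate", "jnd", "p_param", "cr", "mct")
    }
    return build_report(outcomes, retest=retest)


class TestBuildReport:
    def test_six_measures_per_condition(self, report):
        for cond in ("AF", "NF"):
            assert set(report["conditions"][cond]) == {
                "adaptation_rate", "jnd", "p_param", "cr", "mct", "ts",
            }

    def test_all_pairwise_comparisons_present(self, report):
        assert len(report["comparisons"]) == 6

    def test_retest_block_covers_five_measures(self, report):
        assert set(report["test_retest"]) == {
            "adaptation_rate", "jnd", "p_param", "cr", "mct",
        }

    def test_cr_ratio_present(self, report):
        assert report["cr_ratio"]["value"] > 0

    def test_pure_function_of_inputs(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        r1 = build_report({"AF": _cohort("AF", rng1), "NF": _cohort("NF", rng1)})
        r2 = build_report({"AF": _cohort("AF", rng2), "NF": _cohort("NF", rng2)})
        assert r1 == r2

    def test_missing_measure_flagged_not_fatal(self):
        rng = np.random.default_rng(7)
        af = _cohort("AF", rng)
        nf = [OutcomeSet(condition="NF", adaptation_rate=0.8) for _ in range(7)]
        rep = build_report({"AF": af, "NF": nf})
        assert "jnd" in rep["missing"]

    def test_markdown_rendering(self, report):
        md = report_to_markdown(report)
        assert "adaptation_rate" in md and "ICC" in md


class TestCRRatio:
    def test_printed_group_means(self):
        assert cr_ratio(65.0, 37.34) == pytest.approx(1.74, abs=0.005)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            cr_ratio(50.0, 0.0)
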