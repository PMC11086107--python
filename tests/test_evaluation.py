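"""BP extraction, regression metrics, BHS/AAMI grading, Bland-Altman."""

import numpy as np
import pytest

from dsrunet.evaluation import (
    BPTriple, EvaluationReport, aami_check, bhs_grade, bland_altman,
    evaluate_run, extract_bp, metrics,
)

# Reference percentage triples spanning the grade boundaries (an ablation
# grid of 7 models x SBP/DBP/MBP) with the letters the worst-of-three rule
# assigns.  Note (79.09, 89.96, 94.95): 94.95 < 95 at the 15 mmHg threshold,
# so the strict rule yields B even though such results are sometimes reported
# rounded up to grade A.
BHS_CASES = [
    ((62.08, 80.52, 89.88), "C"), ((78.16, 92.83, 97.03), "A"), ((81.30, 94.65, 97.66), "A"),
    ((72.58, 88.16, 94.38), "B"), ((83.85, 94.11, 98.16), "A"), ((85.49, 95.04, 97.94), "A"),
    ((76.37, 89.63, 95.18), "A"), ((84.93, 94.86, 97.96), "A"), ((86.59, 94.99, 97.61), "A"),
    ((79.09, 89.96, 94.95), "B"), ((84.54, 94.26, 97.86), "A"), ((86.08, 94.85, 97.86), "A"),
    ((78.71, 89.91, 95.57), "A"), ((85.95, 95.34, 98.22), "A"), ((86.18, 94.77, 97.75), "A"),
    ((79.93, 89.63, 95.45), "A"), ((85.54, 94.84, 98.14), "A"), ((87.06, 95.38, 97.76), "A"),
    ((81.44, 90.38, 95.79), "A"), ((85.46, 94.39, 98.00), "A"), ((87.22, 95.07, 97.73), "A"),
]


class TestExtractBP:
    def test_span_example(self):
        bp = extract_bp(np.array([80.0, 100.0, 120.0, 90.0]))
        assert (bp.sbp, bp.dbp) == (120.0, 80.0)
        assert bp.mbp == pytest.approx(93.3333, abs=1e-3)

    def test_constant_waveform(self):
        bp = extract_bp(np.full(100, 100.0))
        assert bp == BPTriple(100.0, 100.0, 100.0)

    def test_matches_scan_oracle_and_ordering(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.normal(100.0, 15.0, size=200)
            bp = extract_bp(w)
            hi = lo = w[0]
            for v in w:
                hi, lo = max(hi, v), min(lo, v)
            assert (bp.sbp, bp.dbp) == (hi, lo)
            assert bp.dbp <= bp.mbp <= bp.sbp

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            extract_bp(np.array([]))
        with pytest.raises(ValueError, match="finite"):
            extract_bp(np.array([1.0, np.nan]))


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = metrics(y, y)
        assert (m.me, m.mae, m.mse, m.std_eq20) == (0.0, 0.0, 0.0, 0.0)
        assert m.r2 == 1.0 and m.r == pytest.approx(1.0)

    def test_arithmetic_example(self):
        m = metrics(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))
        assert m.me == pytest.approx(0.0)
        assert m.mae == pytest.approx(2.0 / 3.0, abs=1e-4)
        assert m.mse == pytest.approx(2.0 / 3.0, abs=1e-4)
        assert m.std_eq20 == pytest.approx(0.8165, abs=1e-4)
        assert m.r2 == pytest.approx(0.0)

    def test_correlation_scale_invariance(self):
        y = np.random.default_rng(1).normal(size=50)
        m = metrics(y, 2.0 * y + 1.0)
        assert m.r == pytest.approx(1.0)

    def test_internal_consistency_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.normal(120, 15, size=100)
            yh = y + rng.normal(0, 5, size=100)
            m = metrics(y, yh)
            assert m.std_eq20**2 == pytest.approx(m.mse, abs=1e-9)
            assert m.mae >= abs(m.me)
            assert -1.0 <= m.r <= 1.0

    def test_zero_variance_flagged(self):
        m = metrics(np.full(5, 1.0), np.arange(5.0))
        assert np.isnan(m.r2) and np.isnan(m.r)


class TestBHS:
    @pytest.mark.parametrize("pct,grade", BHS_CASES)
    def test_published_grade_letters(self, pct, grade):
        assert bhs_grade(pct_within=pct).grade == grade

    def test_boundary_conventions(self):
        assert bhs_grade(pct_within=(100.0, 100.0, 100.0)).grade == "A"
        assert bhs_grade(pct_within=(30.0, 50.0, 70.0)).grade == "D"
        # exact grade-A minima are inclusive
        assert bhs_grade(pct_within=(60.0, 85.0, 95.0)).grade == "A"

    def test_from_raw_errors_with_le_comparison(self):
        # errors exactly at 5/10/15 count as within the thresholds
        res = bhs_grade(abs_errors=[5.0, 10.0, 15.0, 0.0])
        assert res.pct_within == (50.0, 75.0, 100.0)
        assert res.per_threshold == ("B", "B", "A")
        assert res.grade == "B"

    def test_percentages_non_decreasing(self):
        rng = np.random.default_rng(3)
        e = np.abs(rng.normal(0, 8, size=500))
        p = bhs_grade(abs_errors=e).pct_within
        assert p[0] <= p[1] <= p[2]


class TestAAMI:
    @pytest.mark.parametrize("me,sd,n", [(-0.15, 6.71, 244), (-0.54, 4.54, 244)])
    def test_published_verdicts_pass(self, me, sd, n):
        assert aami_check(me, sd, n).passed

    @pytest.mark.parametrize("me,sd,n,ok", [
        (5.1, 7.0, 100, False),   # mean error too large
        (0.0, 8.5, 100, False),   # dispersion too large
        (0.0, 7.0, 84, False),    # too few subjects
        (5.0, 8.0, 85, True),     # boundaries inclusive
    ])
    def test_boundaries(self, me, sd, n, ok):
        assert aami_check(me, sd, n).passed is ok


class TestBlandAltman:
    def test_zero_differences(self):
        y = np.arange(10.0)
        ba = bland_altman(y, y)
        assert ba.loa == (0.0, 0.0) and ba.mean_diff == 0.0

    def test_two_point_example(self):
        ba = bland_altman(np.array([0.0, 0.0]), np.array([-1.0, 1.0]))
        assert ba.mean_diff == 0.0 and ba.sd_diff == 1.0
        assert ba.loa == pytest.approx((-1.96, 1.96))

    def test_matches_mean_std_oracle_and_symmetry(self):
        rng = np.random.default_rng(4)
        y = rng.normal(120, 10, size=300)
        yh = y + rng.normal(1.5, 4.0, size=300)
        ba = bland_altman(y, yh)
        d = yh - y
        assert ba.mean_diff == pytest.approx(d.mean())
        assert ba.sd_diff == pytest.approx(d.std())
        lo, hi = ba.loa
        assert (lo + hi) / 2 == pytest.approx(ba.mean_diff)
        assert 0.9 < ba.frac_within_loa <= 1.0


class TestEvaluateRun:
    def _windows(self, n=30, L=128, seed=5):
        rng = np.random.default_rng(seed)
        t = np.arange(L) / 125.0
        targets = np.stack([
            90.0 + rng.uniform(20, 60) * 0.5 * (1 + np.sin(2 * np.pi * 1.2 * t))
            for _ in range(n)
        ])
        return targets

    def test_identity_predictor_is_perfect(self, tmp_path):
        targets = self._windows()
        report = evaluate_run(targets.copy(), targets, out_dir=str(tmp_path),
                              make_plots=False)
        assert report.waveform.mae == 0.0
        for p in ("sbp", "dbp", "mbp"):
            assert report.bhs[p].grade == "A"
            assert report.per_parameter[p].mae == 0.0
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "metrics.csv").exists()

    def test_report_json_roundtrip(self):
        targets = self._windows()
        preds = targets + np.random.default_rng(6).normal(0, 2.0, targets.shape)
        report = evaluate_run(preds, targets, make_plots=False)
        back = EvaluationReport.from_json(report.to_json())
        assert back == report

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            evaluate_run(np.zeros((3, 10)), np.zeros((4, 10)))
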