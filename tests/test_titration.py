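import itertools
import warnings

import numpy as np
import pytest

from rostrack import synthetic, titration, units
from rostrack.exceptions import DomainError, FitError, NoPlateauError
from rostrack.titration import (PhaseModel, TitrationCurve, analyze_titration,
                                fit_phase_lines, intersect_sparse,
                                segment_phases, to_density_axis, total_oh)

# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately different code paths)
# ---------------------------------------------------------------------------

def _oracle_fit(x, y, labels):
    """SSE of the three-phase fit via numpy lstsq/polyfit."""
    x, y, labels = np.asarray(x), np.asarray(y), np.asarray(labels)
    sse = 0.0
    for phase in (1, 3):
        m = labels == phase
        s, *_ = np.linalg.lstsq(x[m, None], y[m], rcond=None)
        s = max(float(s[0]), 0.0)
        sse += float(np.sum((y[m] - s * x[m]) ** 2))
    m = labels == 2
    coeffs = np.polyfit(x[m], y[m], 1)
    sse += float(np.sum((y[m] - np.polyval(coeffs, x[m])) ** 2))
    return sse, coeffs


def _oracle_contiguous_best(x, y, min_per_phase=2):
    """Minimum-SSE contiguous partition by plain enumeration."""
    n = len(x)
    best = None
    for i in range(min_per_phase, n - 2 * min_per_phase + 1):
        for j in range(i + min_per_phase, n - min_per_phase + 1):
            labels = [1] * i + [2] * (j - i) + [3] * (n - j)
            sse, coeffs = _oracle_fit(x, y, labels)
            m1 = np.asarray(labels) == 1
            s1 = float(np.dot(x[m1], y[m1]) / np.dot(x[m1], x[m1]))
            b2 = float(coeffs[0])
            if s1 - b2 <= 1e-9 * max(abs(s1), abs(b2), 1e-30):
                continue
            span = x[j - 1] - x[i]
            if best is None or (sse, -span) < (best[0], -best[2]):
                best = (sse, tuple(labels), span)
    return best


@pytest.fixture(scope="module")
def density_grid():
    return np.array([units.molar_to_per_um(c * 1e-3)
                     for c in synthetic.PAPER_DMPO_GRID_MM])


class TestToDensityAxis:
    def test_top_grid_point(self, xray_curve):
        d = to_density_axis(xray_curve)
        assert d.density_per_um[-1] == pytest.approx(1004.9, abs=0.05)

    def test_lowest_grid_point(self, xray_curve):
        d = to_density_axis(xray_curve)
        assert d.density_per_um[0] == pytest.approx(67.0, abs=0.1)

    def test_order_and_metadata_preserved(self, xray_curve):
        d = to_density_axis(xray_curve)
        assert list(d.density_per_um) == sorted(d.density_per_um)
        assert d.dose_Gy == xray_curve.dose_Gy
        assert d.dmpoh_uM == xray_curve.dmpoh_uM

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            TitrationCurve((1.0, 2.0), (0.1, 0.2), dose_Gy=32.0)


class TestCurveValidation:
    def test_non_increasing_dmpo_rejected(self):
        with pytest.raises(DomainError):
            TitrationCurve((1, 2, 2, 4, 5, 6), (1, 2, 3, 4, 5, 6), 32.0)

    def test_negative_values_rejected(self):
        with pytest.raises(DomainError):
            TitrationCurve((1, 2, 3, 4, 5, 6), (1, -2, 3, 4, 5, 6), 32.0)

    def test_zero_dose_rejected(self):
        with pytest.raises(DomainError):
            TitrationCurve((1, 2, 3, 4, 5, 6), (1, 2, 3, 4, 5, 6), 0.0)


class TestFitPhaseLines:
    def test_exact_origin_line(self):
        model = fit_phase_lines([1, 2, 10, 20, 100, 200],
                                [2, 4, 5, 5, 30, 60],
                                [1, 1, 2, 2, 3, 3])
        assert model.s1 == pytest.approx(2.0)

    def test_phase3_slope_hand_value(self):
        # sum(xy)/sum(x^2) on the two rounded third-phase points
        model = fit_phase_lines([1, 2, 10, 20, 712.0, 1005.0],
                                [1, 2, 5, 5, 9.78, 11.30],
                                [1, 1, 2, 2, 3, 3])
        assert model.s3 == pytest.approx(0.012077, abs=1e-6)

    def test_phase2_ols_on_generated_points(self):
        x2 = [166.0, 200.0, 250.0, 333.0, 500.0]
        y2 = [6.1 + 0.00517 * x for x in x2]
        x = [1.0, 2.0] + x2 + [900.0, 1000.0]
        y = [0.0433, 0.0866] + y2 + [10.0, 11.0]
        model = fit_phase_lines(x, y, [1, 1, 2, 2, 2, 2, 2, 3, 3])
        assert model.b2 == pytest.approx(0.00517, abs=1e-3)
        assert model.a2 == pytest.approx(6.10, abs=1e-3)

    def test_sse_matches_oracle(self, xray_curve):
        d = to_density_axis(xray_curve)
        labels = [1, 1, 1, 2, 2, 2, 2, 2, 3, 3]
        model = fit_phase_lines(d.density_per_um, d.dmpoh_uM, labels)
        sse, _ = _oracle_fit(d.density_per_um, d.dmpoh_uM, labels)
        assert model.sse == pytest.approx(sse, rel=1e-9, abs=1e-12)

    def test_short_phase_rejected(self):
        with pytest.raises(FitError):
            fit_phase_lines([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6],
                            [1, 2, 2, 3, 3, 3])

    def test_non_contiguous_rejected(self):
        with pytest.raises(FitError):
            fit_phase_lines([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6],
                            [1, 2, 1, 2, 3, 3])


class TestSegmentPhases:
    def test_noiseless_fixture_partition(self, xray_curve):
        # phase 1: densities <= 126, phase 2: 166-500, phase 3: 712-1005
        model = segment_phases(to_density_axis(xray_curve))
        assert model.assignment == (1, 1, 1, 2, 2, 2, 2, 2, 3, 3)

    def test_matches_contiguous_brute_force_noiseless(self, xray_curve):
        d = to_density_axis(xray_curve)
        x, y = np.asarray(d.density_per_um), np.asarray(d.dmpoh_uM)
        model = segment_phases(d)
        best = _oracle_contiguous_best(x, y)
        assert model.assignment == best[1]
        assert model.sse == pytest.approx(best[0], rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_contiguous_brute_force_noisy(self, seed):
        curve = synthetic.generate_titration(
            synthetic.xray_truth(noise_sd_uM=0.3, seed=seed))
        d = to_density_axis(curve)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = segment_phases(d)
            best = _oracle_contiguous_best(
                np.asarray(d.density_per_um), np.asarray(d.dmpoh_uM))
        assert model.sse == pytest.approx(best[0], rel=1e-9, abs=1e-12)
        assert model.assignment == best[1]

    def test_single_origin_line_has_no_plateau(self):
        x = [10.0, 20.0, 40.0, 80.0, 160.0, 320.0]
        curve = titration.DensityCurve(tuple(x), tuple(2.0 * v for v in x), 32.0)
        with pytest.raises(NoPlateauError):
            segment_phases(curve)

    def test_order_invariance(self, xray_curve):
        d = to_density_axis(xray_curve)
        perm = [3, 0, 9, 5, 1, 7, 2, 8, 4, 6]
        shuffled = titration.DensityCurve(
            tuple(d.density_per_um[i] for i in perm),
            tuple(d.dmpoh_uM[i] for i in perm), d.dose_Gy)
        assert segment_phases(shuffled) == segment_phases(d)

    def test_too_few_points(self):
        curve = titration.DensityCurve((1, 2, 3, 4, 5), (1, 2, 3, 4, 5), 32.0)
        with pytest.raises(DomainError):
            segment_phases(curve)

    def test_non_contiguous_labellings_out_of_model(self, xray_curve):
        # Phase membership is contiguous in density by construction.  A
        # non-contiguous labelling can reach a lower raw SSE on data whose
        # above-knee points are collinear, but it does not describe ordered
        # titration phases: the contiguous optimum must beat every labelling
        # whose phase blocks are ordered, and the scattered ones are rejected.
        d = to_density_axis(xray_curve)
        x, y = np.asarray(d.density_per_um), np.asarray(d.dmpoh_uM)
        model = segment_phases(d)
        for labels in itertools.product((1, 2, 3), repeat=len(x)):
            counts = [labels.count(p) for p in (1, 2, 3)]
            if min(counts) < 2:
                continue
            if list(labels) == sorted(labels):  # ordered = contiguous
                sse, _ = _oracle_fit(x, y, labels)
                assert model.sse <= sse + 1e-9
            else:
                with pytest.raises(FitError):
                    fit_phase_lines(x, y, labels)


class TestIntersectSparse:
    def test_unit_case(self):
        model = PhaseModel((1, 1, 2, 2, 3, 3), s1=1.0, a2=1.0, b2=0.0, s3=1.0, sse=0.0)
        assert intersect_sparse(model) == (1.0, 1.0)

    def test_synthetic_truth_values(self):
        model = PhaseModel((1, 1, 2, 2, 3, 3), s1=0.0433, a2=6.10, b2=0.00517,
                           s3=0.0113, sse=0.0)
        x_star, y_star = intersect_sparse(model)
        assert x_star == pytest.approx(160.0, abs=0.1)
        assert y_star == pytest.approx(6.93, abs=0.01)

    def test_linear_in_intercept(self):
        m1 = PhaseModel((1, 1, 2, 2, 3, 3), 0.05, 2.0, 0.01, 0.01, 0.0)
        m2 = PhaseModel((1, 1, 2, 2, 3, 3), 0.05, 4.0, 0.01, 0.01, 0.0)
        x1, y1 = intersect_sparse(m1)
        x2, y2 = intersect_sparse(m2)
        assert x2 == pytest.approx(2 * x1)
        assert y2 == pytest.approx(2 * y1)

    def test_parallel_lines_rejected(self):
        model = PhaseModel((1, 1, 2, 2, 3, 3), s1=0.01, a2=1.0, b2=0.01,
                           s3=0.01, sse=0.0)
        with pytest.raises(FitError):
            intersect_sparse(model)


class TestTotalOh:
    def test_printed_total(self):
        model = PhaseModel((1, 1, 2, 2, 3, 3), 0.04, 6.0, 0.005, 0.0113, 0.0)
        assert total_oh(model) == pytest.approx(11.3)

    def test_zero_slope(self):
        model = PhaseModel((1, 1, 2, 2, 3, 3), 0.04, 6.0, 0.005, 0.0, 0.0)
        assert total_oh(model) == 0.0

    def test_fitted_slope(self):
        model = PhaseModel((1, 1, 2, 2, 3, 3), 0.04, 6.0, 0.005, 0.012077, 0.0)
        assert total_oh(model) == pytest.approx(12.077)

    def test_linear_in_reference_density(self):
        model = PhaseModel((1, 1, 2, 2, 3, 3), 0.04, 6.0, 0.005, 0.0113, 0.0)
        assert total_oh(model, 2000.0) == pytest.approx(2 * total_oh(model, 1000.0))


class TestAnalyzeTitration:
    def test_end_to_end_xray_fixture(self, xray_estimate):
        assert xray_estimate.sparse_density_per_um == pytest.approx(160.0, rel=1e-6)
        assert xray_estimate.sparse_concentration_mM == pytest.approx(6.8, rel=5e-3)

    def test_scale_equivariance(self, xray_curve, xray_estimate):
        scaled = TitrationCurve(xray_curve.dmpo_mM,
                                tuple(2 * y for y in xray_curve.dmpoh_uM),
                                xray_curve.dose_Gy)
        est = analyze_titration(scaled)
        assert est.sparse_amount_uM == pytest.approx(2 * xray_estimate.sparse_amount_uM)
        assert est.total_amount_uM == pytest.approx(2 * xray_estimate.total_amount_uM)
        assert est.sparse_density_per_um == pytest.approx(
            xray_estimate.sparse_density_per_um)

    def test_manual_phase_override(self, xray_curve, xray_estimate):
        est = analyze_titration(xray_curve, phases=(3, 5, 2))
        assert est == xray_estimate

    def test_bad_manual_phases(self, xray_curve):
        with pytest.raises(DomainError):
            analyze_titration(xray_curve, phases=(3, 3, 2))

    def test_plateau_flat_option(self, xray_curve):
        est = analyze_titration(xray_curve, plateau_flat=True)
        assert est.model.b2 == 0.0
        # intersection still near the sparse knee (flat plateau biases upward)
        assert est.sparse_density_per_um == pytest.approx(160.0, rel=0.2)

    def test_noiseless_recovery_grid(self):
        # density exact, amount biased upward by exactly (A_d/d_d) * d_s
        for d_s in (100.0, 160.0, 220.0, 300.0):
            for a_s in (2.0, 6.1, 12.0):
                truth = synthetic.TitrationTruth(a_s, d_s, 51.7, 1e4)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = analyze_titration(synthetic.generate_titration(truth))
                assert est.sparse_density_per_um == pytest.approx(d_s, rel=0.005)
                expected_bias = 51.7 / 1e4 * d_s
                assert est.sparse_amount_uM == pytest.approx(
                    a_s + expected_bias, rel=1e-6)

    def test_noisy_recovery_median(self):
        errors = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(200):
                truth = synthetic.xray_truth(noise_sd_uM=0.2, seed=seed)
                est = analyze_titration(synthetic.generate_titration(truth))
                errors.append(abs(est.sparse_density_per_um - 160.0) / 160.0)
        assert np.median(errors) < 0.10
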