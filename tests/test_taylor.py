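"""Tests of the delta-method sign conditions, predictions and boundaries."""

import numpy as np
import pytest

from lipidcomp.exceptions import DegenerateBoundaryError, ValidationError
from lipidcomp.moments import SummaryMoments, pearson
from lipidcomp.synthetic_data import random_summary_moments, simulate_from_moments
from lipidcomp.taylor import (boundary_biomarker, boundary_total,
                              predicted_corr_biomarker, predicted_corr_total,
                              round_half_away, sign_condition_biomarker,
                              sign_condition_total)


class TestSignConditionBiomarker:
    def test_linoleic_acid_worked_example(self, la_moments):
        cond = sign_condition_biomarker(la_moments)
        assert round_half_away(la_moments.cv1) == 0.20
        assert round_half_away(la_moments.cv2) == 0.26
        assert round_half_away(cond.left_term) == 0.12
        assert round_half_away(cond.right_term) == 0.23
        assert cond.predicted_sign == "negative"

    def test_oleic_acid_worked_example(self, oa_moments):
        cond = sign_condition_biomarker(oa_moments)
        assert round_half_away(oa_moments.cv1) == 0.32
        assert round_half_away(oa_moments.cv2) == 0.21
        assert round_half_away(cond.left_term) == 0.29
        assert round_half_away(cond.right_term) == 0.17
        assert cond.predicted_sign == "positive"

    def test_constant_remainder_gives_focal_sign(self):
        m = SummaryMoments(mu1=2, sigma1=0.5, mu2=8, sigma2=0.0, rho1=0.4)
        assert sign_condition_biomarker(m).predicted_sign == "positive"

    def test_nonpositive_means_rejected(self):
        m = SummaryMoments(mu1=0.0, sigma1=0.5, mu2=8, sigma2=1.0)
        with pytest.raises(ValidationError, match="means"):
            sign_condition_biomarker(m)

    def test_exact_zero_maps_to_zero_sign(self):
        m = SummaryMoments(mu1=2, sigma1=0.5, mu2=2, sigma2=0.5,
                           rho1=0.4, rho2=0.4)
        assert sign_condition_biomarker(m).predicted_sign == "zero"


class TestSignConditionTotal:
    def test_perfect_symmetry_is_zero(self):
        m = SummaryMoments(mu1=3, sigma1=0.5, mu2=3, sigma2=0.5, rho12=0.4)
        assert sign_condition_total(m).sign_term == pytest.approx(0.0, abs=1e-15)

    def test_equal_sigmas_zero_rho_sign_from_means(self):
        # focal has the larger CV when its mean is smaller
        m = SummaryMoments(mu1=2, sigma1=0.5, mu2=8, sigma2=0.5, rho12=0.0)
        assert sign_condition_total(m).predicted_sign == "positive"

    def test_small_focal_cv_with_nonneg_rho_is_negative(self):
        m = SummaryMoments(mu1=10, sigma1=0.2, mu2=5, sigma2=2.0, rho12=0.3)
        cond = sign_condition_total(m)
        assert cond.predicted_sign == "negative"
        # Monte-Carlo check of the sign at large n
        x1, x2, _ = simulate_from_moments(m, n=100_000, seed=3)
        pct = 100 * x1 / (x1 + x2)
        assert pearson(x1 + x2, pct) < 0


class TestFormulationIdentities:
    def test_cv_product_and_sign_term_agree(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            m = random_summary_moments(rng)
            cond = sign_condition_biomarker(m)
            assert np.sign(cond.sign_term) == np.sign(
                m.rho1 * m.cv1 - m.rho2 * m.cv2)
            cond_t = sign_condition_total(m)
            assert np.sign(cond_t.sign_term) == np.sign(
                cond_t.left_term - cond_t.right_term)

    def test_unit_invariance_of_conditions_and_predictions(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = random_summary_moments(rng)
            m_scaled = m.scaled(1000.0)  # e.g. mmol/l -> umol/l
            assert (sign_condition_biomarker(m).predicted_sign
                    == sign_condition_biomarker(m_scaled).predicted_sign)
            assert predicted_corr_biomarker(m).value == pytest.approx(
                predicted_corr_biomarker(m_scaled).value, abs=1e-12)
            assert predicted_corr_total(m).value == pytest.approx(
                predicted_corr_total(m_scaled).value, abs=1e-12)


class TestPredictedCorrBiomarker:
    def test_sign_matches_condition(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = random_summary_moments(rng)
            pred = predicted_corr_biomarker(m)
            cond = sign_condition_biomarker(m)
            if pred.value != 0:
                assert ("negative" if pred.value < 0 else "positive") \
                    == cond.predicted_sign

    def test_la_prediction_is_negative(self, la_moments):
        assert predicted_corr_biomarker(la_moments).value < 0

    def test_equal_cvs_equal_rhos_give_zero(self):
        m = SummaryMoments(mu1=2, sigma1=0.4, mu2=10, sigma2=2.0,
                           rho12=0.5, rho1=0.6, rho2=0.6)
        assert predicted_corr_biomarker(m).value == pytest.approx(0.0, abs=1e-12)

    def test_independent_of_sigma_y(self, la_moments):
        import dataclasses

        big = dataclasses.replace(la_moments, sigmaY=123.0)
        assert predicted_corr_biomarker(big).value == pytest.approx(
            predicted_corr_biomarker(la_moments).value, abs=1e-12)

    def test_degenerate_at_perfect_coupling(self):
        m = SummaryMoments(mu1=2, sigma1=0.4, mu2=10, sigma2=2.0, rho12=1.0)
        with pytest.raises(DegenerateBoundaryError):
            predicted_corr_biomarker(m)

    def test_monte_carlo_oracle_two_sets(self):
        # acceptance runs the full 20-set sweep; spot-check two here
        rng = np.random.default_rng(5)
        for _ in range(2):
            m = random_summary_moments(rng)
            x1, x2, y = simulate_from_moments(m, n=100_000, seed=17)
            pct = 100 * x1 / (x1 + x2)
            emp = pearson(y, pct)
            assert predicted_corr_biomarker(m).value == pytest.approx(emp, abs=0.05)


class TestPredictedCorrTotal:
    def test_symmetric_moments_give_zero(self):
        m = SummaryMoments(mu1=3, sigma1=0.5, mu2=3, sigma2=0.5, rho12=0.2)
        assert predicted_corr_total(m).value == pytest.approx(0.0, abs=1e-12)

    def test_sign_agreement_property_sweep(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            m = random_summary_moments(rng)
            pred = predicted_corr_total(m)
            cond = sign_condition_total(m)
            if pred.value != 0:
                assert ("negative" if pred.value < 0 else "positive") \
                    == cond.predicted_sign

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(29)
        m = random_summary_moments(rng)
        x1, x2, _ = simulate_from_moments(m, n=100_000, seed=31)
        pct = 100 * x1 / (x1 + x2)
        emp = pearson(x1 + x2, pct)
        assert predicted_corr_total(m).value == pytest.approx(emp, abs=0.05)


class TestBoundaries:
    def test_equal_rhos_give_diagonal(self):
        assert boundary_biomarker(0.5, 0.5).slope == pytest.approx(1.0)

    def test_la_boundary_and_observed_point(self):
        curve = boundary_biomarker(0.60, 0.87)
        assert curve.slope == pytest.approx(0.87 / 0.60)
        # observed (CV_others, CV_focal) = (0.26, 0.20) sits in the
        # negative region below the boundary
        assert curve.classify(0.26, 0.20) == "negative"
        assert curve.region_labels["below"] == "negative"

    def test_oa_observed_point_is_positive(self):
        curve = boundary_biomarker(0.90, 0.82)
        assert curve.classify(0.21, 0.32) == "positive"

    def test_zero_rho1_is_degenerate(self):
        with pytest.raises(DegenerateBoundaryError):
            boundary_biomarker(0.0, 0.5)

    def test_negative_rho1_flips_regions(self):
        curve = boundary_biomarker(-0.6, 0.3)
        assert curve.region_labels["below"] == "positive"

    def test_total_boundary_equal_sigmas_diagonal(self):
        for rho in (-0.5, 0.0, 0.8):
            assert boundary_total(1.3, 1.3, rho).slope == pytest.approx(1.0)

    def test_total_boundary_zero_rho_slope(self):
        # with rho = 0 the sign term is sigma1^2 mu2 - sigma2^2 mu1, so the
        # boundary in the CV plane (sds fixed) is y = (sigma2/sigma1) x
        assert boundary_total(1.0, 2.0, 0.0).slope == pytest.approx(2.0)

    def test_total_boundary_vertical_degenerate(self):
        with pytest.raises(DegenerateBoundaryError, match="vertical"):
            boundary_total(1.0, 1.0, -1.0)

    def test_points_straddling_total_boundary_match_sign_condition(self):
        rng = np.random.default_rng(41)
        eps = 1e-6
        for _ in range(300):
            sigma1, sigma2 = rng.uniform(0.2, 3.0, size=2)
            rho = rng.uniform(-0.9, 0.9)
            curve = boundary_total(sigma1, sigma2, rho)
            x = rng.uniform(0.05, 0.5)
            y0 = curve.slope * x
            if y0 <= eps:
                continue
            for y, want in ((y0 * (1 + eps), "positive" if curve.negative_below
                             else "negative"),
                            (y0 * (1 - eps), "negative" if curve.negative_below
                             else "positive")):
                # classify via the boundary, confirm with the sign condition
                assert curve.classify(x, y) == want
                m = SummaryMoments(mu1=sigma1 / y, sigma1=sigma1,
                                   mu2=sigma2 / x, sigma2=sigma2, rho12=rho)
                assert sign_condition_total(m).predicted_sign == want

    def test_sample_starts_at_origin(self):
        x, y = boundary_biomarker(0.6, 0.87).sample(x_max=0.5, num=11)
        assert x[0] == 0.0 and y[0] == 0.0
        assert len(x) == 11
        np.testing.assert_allclose(y, (0.87 / 0.6) * x)


def test_round_half_away():
    assert round_half_away(0.125) == 0.13
    assert round_half_away(-0.125) == -0.13
    assert round_half_away(0.1249) == 0.12
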