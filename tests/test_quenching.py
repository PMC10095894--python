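"""Stern-Volmer machinery: ratios, segmented fits, constants, mechanism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchbind.errors import AnalysisError, DataWarning, DomainError
from quenchbind.quenching import (
    classify_mechanism,
    fit_piecewise,
    quenching_constants,
    sv_ratios,
)
from quenchbind.spectra_io import TitrationPoint, TitrationSeries

from conftest import brute_force_breakpoint, make_series


class TestSvRatios:
    def test_constant_intensity_gives_unit_ratios(self):
        s = make_series(np.arange(4) * 1e-6, [100.0] * 4)
        assert np.allclose(sv_ratios(s)[:, 1], 1.0)

    def test_hand_computed_ratios(self):
        s = make_series([0.0, 2e-6, 10e-6], [100.0, 80.0, 50.0])
        assert np.allclose(sv_ratios(s)[:, 1], [1.0, 1.25, 2.0])

    def test_first_pair_is_zero_one(self):
        s = make_series(np.arange(5) * 1e-6, 1000.0 / (1 + 3e5 * np.arange(5) * 1e-6))
        pairs = sv_ratios(s)
        assert pairs[0, 0] == 0.0 and pairs[0, 1] == 1.0


class TestFitPiecewise:
    def test_collinear_points_give_single_segment(self):
        x = np.arange(0, 11) * 1e-6
        y = 1.0 + 3e5 * x
        fit = fit_piecewise(np.column_stack([x, y]))
        assert not fit.two_segment
        assert fit.slope1 == pytest.approx(3e5, rel=1e-9)
        assert fit.intercept1 == pytest.approx(1.0, rel=1e-9)

    def test_exact_two_segment_recovery(self):
        """Noiseless continuous elbow: slopes and breakpoint recovered exactly."""
        x = np.arange(10, dtype=float)
        join = 4.0
        y = np.where(x <= join, 1.0 + 3.0e5 * x, 1.0 + 3.0e5 * join + 1.5e5 * (x - join))
        fit = fit_piecewise(np.column_stack([x, y]))
        assert fit.two_segment
        assert fit.slope1 == pytest.approx(3.0e5, rel=1e-9)
        assert fit.slope2 == pytest.approx(1.5e5, rel=1e-9)
        k_oracle, sse_oracle, _ = brute_force_breakpoint(x, y)
        assert fit.breakpoint_index == k_oracle
        assert fit.sse_total == pytest.approx(sse_oracle, abs=1e-12)

    def test_noisy_single_line_rarely_split(self):
        """Linear data + 0.5%-of-range noise stays single-segment >= 95% of runs."""
        rng = np.random.default_rng(2024)
        x = np.arange(11, dtype=float)
        sigma = 0.005 * (1 + 3e5 * 10e-6 - 1)  # 0.5% of the y-range
        n_single = 0
        for _ in range(200):
            y = 1 + 3e5 * (x * 1e-6) + rng.normal(0, sigma, 11)
            fit = fit_piecewise(np.column_stack([x, y]), require_slope_decrease=True)
            n_single += not fit.two_segment
        assert n_single >= 190

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Same breakpoint and SSE as naive enumeration on random data."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(6, 21)
            x = np.sort(rng.uniform(0, 10, n))
            x += np.arange(n) * 1e-9
            y = rng.normal(0, 1, n)
            fit = fit_piecewise(np.column_stack([x, y]), alpha=1.1)  # always accept
            k_oracle, sse_oracle, _ = brute_force_breakpoint(x, y)
            assert fit.breakpoint_index == k_oracle
            assert fit.sse_total == pytest.approx(sse_oracle, rel=1e-9, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            fit_piecewise(np.array([[0.0, 1.0], [1.0, 2.0]]))

    def test_non_increasing_x_rejected(self):
        with pytest.raises(DomainError):
            fit_piecewise(np.array([[0.0, 1.0], [0.0, 2.0], [1.0, 3.0]]))

    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_equivariance(self, shift, scale):
        """y + c shifts intercepts only; x*c divides slopes by c."""
        rng = np.random.default_rng(99)
        x = np.arange(12, dtype=float)
        y = 1 + 0.5 * x + 0.3 * np.maximum(x - 6, 0) + rng.normal(0, 0.05, 12)
        base = fit_piecewise(np.column_stack([x, y]))
        shifted = fit_piecewise(np.column_stack([x, y + shift]))
        assert shifted.slope1 == pytest.approx(base.slope1, rel=1e-9)
        assert shifted.intercept1 - base.intercept1 == pytest.approx(shift, abs=1e-9)
        scaled = fit_piecewise(np.column_stack([x * scale, y]))
        assert scaled.slope1 == pytest.approx(base.slope1 / scale, rel=1e-9)


class TestQuenchingConstants:
    def test_kq_is_ksv_over_tau0(self):
        x = np.arange(0, 11) * 1e-6
        fit = fit_piecewise(np.column_stack([x, 1.0 + 3.0e5 * x]))
        res = quenching_constants(fit, tau0=5.9e-9)
        assert res.kq1 == pytest.approx(3.0e5 / 5.9e-9)  # 5.08e13
        assert res.kq1 * res.tau0 == pytest.approx(res.ksv1, rel=1e-15)

    def test_identity_case(self):
        x = np.arange(0, 6, dtype=float)
        fit = fit_piecewise(np.column_stack([x, 1.0 + x]))
        res = quenching_constants(fit, tau0=1.0)
        assert res.kq1 == pytest.approx(1.0)

    def test_negative_slope_rejected(self):
        x = np.arange(0, 6, dtype=float)
        fit = fit_piecewise(np.column_stack([x, 10.0 - x]))
        with pytest.raises(AnalysisError, match="not a quencher"):
            quenching_constants(fit)


class TestClassifyMechanism:
    def _result(self, ksv, tau0=5.9e-9):
        x = np.arange(0, 11) * 1e-6
        fit = fit_piecewise(np.column_stack([x, 1.0 + ksv * x]))
        return quenching_constants(fit, tau0=tau0)

    def test_corrected_table_trend_is_static(self):
        """K_SV1 falling with temperature and K_q far above the diffusion
        limit: the study system's signature of static quenching."""
        by_T = {25.0: self._result(3.0e5), 35.0: self._result(2.4e5), 45.0: self._result(2.1e5)}
        assert classify_mechanism(by_T) == "static"

    def test_increasing_ksv_with_low_kq_is_dynamic(self):
        by_T = {25.0: self._result(1.0, tau0=1.0), 35.0: self._result(2.0, tau0=1.0)}
        assert classify_mechanism(by_T) == "dynamic"

    def test_non_monotone_trend_is_indeterminate(self):
        by_T = {25.0: self._result(3e5), 35.0: self._result(3.5e5), 45.0: self._result(2e5)}
        assert classify_mechanism(by_T) == "indeterminate"

    def test_single_temperature_warns_indeterminate(self):
        with pytest.warns(DataWarning):
            assert classify_mechanism({25.0: self._result(3e5)}) == "indeterminate"
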