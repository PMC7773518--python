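"""Balance metrics: eEI geometry, ellipse area, path length, DFA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sotpipe import (
    DegenerateInputError,
    DfaConfig,
    DomainError,
    EiParams,
    compute_metrics,
    dfa_alpha,
    ellipse_area_95,
    estimated_equilibrium_index,
    path_length,
    sway_angles,
)
from sotpipe.metrics import CHI2_95_2DF

from conftest import make_trace


def peak_trace(peak_ant: float, peak_post: float, n: int = 100):
    """Zero-mean-ish AP trace with exact anterior/posterior peaks."""
    ap = np.zeros(n)
    ap[n // 3] = peak_ant
    ap[2 * n // 3] = -peak_post
    return make_trace(ap)


class TestSwayAngles:
    def test_zero_trace_gives_zero_angles(self):
        assert sway_angles(peak_trace(0, 0), height=1.7) == (0.0, 0.0)

    def test_closed_form_inverse_sine(self):
        # height 1.0 m -> COG height 0.56 m; peaks +/- 0.056 m -> asin(0.1)
        expected = math.degrees(math.asin(0.1))
        ant, post = sway_angles(peak_trace(0.056, 0.056), height=1.0)
        assert ant == pytest.approx(expected, abs=1e-12)
        assert post == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(5.739, abs=5e-4)

    def test_excursion_beyond_cog_height_rejected(self):
        with pytest.raises(DomainError):
            sway_angles(peak_trace(0.6, 0.0), height=1.0)

    def test_one_sided_trace_contributes_zero_other_side(self):
        ap = np.concatenate([np.zeros(50), np.full(50, 0.02)])
        ant, post = sway_angles(make_trace(ap), height=1.0)
        assert post == 0.0 and ant > 0.0


def trace_with_combined_angle(theta_total_deg: float, height: float = 1.0):
    """Symmetric AP peaks realizing an exact combined sway angle."""
    h = 0.56 * height
    half = math.radians(theta_total_deg / 2.0)
    return peak_trace(h * math.sin(half), h * math.sin(half))


class TestEstimatedEquilibriumIndex:
    def test_no_sway_scores_100(self):
        assert estimated_equilibrium_index(peak_trace(0, 0), height=1.7) == 100.0

    def test_sway_at_limit_scores_0(self):
        score = estimated_equilibrium_index(trace_with_combined_angle(12.5), height=1.0)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_half_limit_scores_50(self):
        score = estimated_equilibrium_index(trace_with_combined_angle(6.25), height=1.0)
        assert score == pytest.approx(50.0, abs=1e-9)

    def test_beyond_limit_clamps_to_0(self):
        score = estimated_equilibrium_index(trace_with_combined_angle(15.0), height=1.0)
        assert score == 0.0

    def test_invariant_to_ml_channel(self, rng):
        ap = rng.normal(0, 0.005, 200)
        ap -= ap.mean()
        a = estimated_equilibrium_index(make_trace(ap), height=1.7)
        b = estimated_equilibrium_index(
            make_trace(ap, rng.normal(0, 0.05, 200)), height=1.7
        )
        assert a == b

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.001, 0.1), st.floats(1.0, 2.0))
    def test_monotone_nonincreasing_in_peak_sway(self, peak, factor):
        small = estimated_equilibrium_index(peak_trace(peak, peak), height=2.0)
        large = estimated_equilibrium_index(
            peak_trace(factor * peak, factor * peak), height=2.0
        )
        assert large <= small


class TestEllipseArea:
    def test_identical_samples_give_zero(self):
        assert ellipse_area_95(peak_trace(0, 0)) == 0.0

    def test_circular_gaussian_matches_analytic_area(self, rng):
        sigma = 0.01
        n = 100_000
        trace = make_trace(rng.normal(0, sigma, n), rng.normal(0, sigma, n))
        area = ellipse_area_95(trace)
        assert area == pytest.approx(math.pi * CHI2_95_2DF * sigma**2, rel=0.03)

    def test_quadratic_scaling(self, random_trace):
        a1 = ellipse_area_95(random_trace)
        doubled = make_trace(2 * random_trace.ap, 2 * random_trace.ml)
        assert ellipse_area_95(doubled) == pytest.approx(4 * a1, rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DegenerateInputError):
            ellipse_area_95(make_trace([0.0, 0.01]))

    def test_translation_invariance(self, random_trace):
        shifted = make_trace(random_trace.ap + 0.3, random_trace.ml - 0.2)
        assert ellipse_area_95(shifted) == pytest.approx(
            ellipse_area_95(random_trace), rel=1e-9
        )


class TestPathLength:
    def test_constant_trace_has_zero_path(self):
        assert path_length(peak_trace(0, 0)) == 0.0

    def test_three_four_five_step(self):
        trace = make_trace([0.0, 0.03], [0.0, 0.04])
        assert path_length(trace) == pytest.approx(0.05, abs=1e-15)

    def test_matches_per_step_loop_oracle(self, rng):
        ap = rng.normal(0, 0.01, 500)
        ml = rng.normal(0, 0.01, 500)
        expected = sum(
            math.sqrt((ap[i + 1] - ap[i]) ** 2 + (ml[i + 1] - ml[i]) ** 2)
            for i in range(499)
        )
        assert path_length(make_trace(ap, ml)) == pytest.approx(expected, abs=1e-12)

    def test_translation_invariance(self, random_trace):
        shifted = make_trace(random_trace.ap + 1.0, random_trace.ml + 2.0)
        assert path_length(shifted) == pytest.approx(
            path_length(random_trace), abs=1e-9
        )


class TestDfaAlpha:
    def test_white_noise_alpha_near_half(self, rng):
        alphas = [dfa_alpha(rng.normal(0, 1, 2000)) for _ in range(10)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.06)

    def test_integrated_noise_alpha_near_three_halves(self, rng):
        alphas = [dfa_alpha(np.cumsum(rng.normal(0, 1, 2000))) for _ in range(10)]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.12)

    def test_amplitude_invariance(self, rng):
        x = rng.normal(0, 1, 1000)
        assert dfa_alpha(3.7 * x) == pytest.approx(dfa_alpha(x), abs=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            dfa_alpha(np.arange(10, dtype=float))

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            dfa_alpha(np.zeros(500))

    def test_config_validation(self):
        with pytest.raises(Exception):
            DfaConfig(min_box=2, poly_order=1)


class TestComputeMetrics:
    def test_zero_trace_composite(self):
        m = compute_metrics(peak_trace(0, 0, n=500), height=1.7)
        assert m.eei == 100.0
        assert m.ellipse_area_95 == 0.0
        assert m.path_length == 0.0
        assert math.isnan(m.dfa_alpha_ap)  # DFA undefined, surfaced as missing

    def test_deterministic(self, random_trace):
        a = compute_metrics(random_trace, height=1.7)
        b = compute_metrics(random_trace, height=1.7)
        assert a == b

    def test_time_reversal_preserves_area_and_path(self, random_trace):
        rev = make_trace(random_trace.ap[::-1], random_trace.ml[::-1])
        assert ellipse_area_95(rev) == pytest.approx(
            ellipse_area_95(random_trace), rel=1e-12
        )
        assert path_length(rev) == pytest.approx(
            path_length(random_trace), rel=1e-12
        )

    def test_custom_ei_params(self):
        # a wider limit makes the same sway score higher
        trace = trace_with_combined_angle(6.25)
        default = estimated_equilibrium_index(trace, height=1.0)
        wide = estimated_equilibrium_index(
            trace, height=1.0, params=EiParams(theta_limit_deg=25.0)
        )
        assert wide > default
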