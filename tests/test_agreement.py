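"""ICC, Pearson, Bland-Altman and the interpretation bins."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sotpipe import (
    InsufficientDataError,
    PairedScores,
    UndefinedStatisticError,
    analyze_pairs,
    bland_altman,
    icc,
    interpret_icc,
    interpret_r,
    pearson,
)


def pairs_of(x, y):
    x = np.asarray(x, float)
    return PairedScores(pids=tuple(f"P{i}" for i in range(len(x))), x=x, y=y)


def anova_icc_oracle(x, y):
    """Brute-force two-way mean-squares decomposition of the n x 2 table,
    computed with explicit loops, and the two single-measure ICCs."""
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    icc_c = (msr - mse) / (msr + mse)
    icc_a = (msr - mse) / (msr + mse + (2 / n) * (msc - mse))
    return icc_a, icc_c


TOY_X = [71.0, 85.0, 78.0, 90.0, 64.0, 82.0]
TOY_Y = [74.0, 83.0, 81.0, 95.0, 60.0, 86.0]


class TestIcc:
    def test_perfect_agreement_is_one(self):
        p = pairs_of(TOY_X, TOY_X)
        assert icc(p, "absolute") == pytest.approx(1.0, abs=1e-12)
        assert icc(p, "consistency") == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_distinguishes_the_two_forms(self):
        p = pairs_of(TOY_X, np.asarray(TOY_X) + 10.0)
        assert icc(p, "consistency") == pytest.approx(1.0, abs=1e-12)
        assert icc(p, "absolute") < 1.0

    def test_matches_anova_oracle_on_toy_table(self):
        p = pairs_of(TOY_X, TOY_Y)
        icc_a, icc_c = anova_icc_oracle(TOY_X, TOY_Y)
        assert icc(p, "absolute") == pytest.approx(icc_a, abs=1e-10)
        assert icc(p, "consistency") == pytest.approx(icc_c, abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = len(TOY_X)
        df = pd.DataFrame(
            {
                "targets": list(range(n)) * 2,
                "raters": ["a"] * n + ["b"] * n,
                "scores": TOY_X + TOY_Y,
            }
        )
        table = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        p = pairs_of(TOY_X, TOY_Y)
        assert icc(p, "absolute") == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert icc(p, "consistency") == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            icc(pairs_of([1.0, 2.0], [1.0, 2.0]))

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc(pairs_of([5.0] * 4, [5.0] * 4))

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(-30, 30))
    def test_consistency_invariant_under_device_shift(self, c):
        base = pairs_of(TOY_X, TOY_Y)
        shifted = pairs_of(TOY_X, np.asarray(TOY_Y) + c)
        assert icc(shifted, "consistency") == pytest.approx(
            icc(base, "consistency"), abs=1e-9
        )
        # growing the offset away from an offset-free baseline strictly
        # lowers absolute agreement but leaves consistency untouched
        offset_free = pairs_of(TOY_X, TOY_X)
        with_offset = pairs_of(TOY_X, np.asarray(TOY_X) + c)
        if abs(c) > 1e-6:
            assert icc(with_offset, "absolute") < icc(offset_free, "absolute")
            halfway = pairs_of(TOY_X, np.asarray(TOY_X) + c / 2)
            assert icc(with_offset, "absolute") < icc(halfway, "absolute")


class TestPearson:
    def test_perfect_positive_affine(self):
        r, p = pearson(pairs_of(TOY_X, 2 * np.asarray(TOY_X) + 1))
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative(self):
        r, _ = pearson(pairs_of(TOY_X, -np.asarray(TOY_X)))
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_t_transform_oracle(self, rng):
        x = rng.normal(70, 10, 20)
        y = 0.6 * x + rng.normal(0, 8, 20)
        n = len(x)
        sx, sy = x - x.mean(), y - y.mean()
        r_oracle = float(np.sum(sx * sy) / math.sqrt(np.sum(sx**2) * np.sum(sy**2)))
        t = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
        r, p = pearson(pairs_of(x, y))
        assert r == pytest.approx(r_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_constant_variable_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson(pairs_of([1.0] * 5, TOY_X[:5]))

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.01, 50), st.floats(-100, 100))
    def test_invariant_under_positive_affine_transform(self, a, b):
        r0, _ = pearson(pairs_of(TOY_X, TOY_Y))
        r1, _ = pearson(pairs_of(TOY_X, a * np.asarray(TOY_Y) + b))
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestBlandAltman:
    def test_identical_scores_give_zero_limits(self):
        ba = bland_altman(TOY_X, TOY_X)
        assert (ba.mean_diff, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)

    def test_two_point_sd_oracle(self):
        # differences {-1, +1}: mean 0, sd = sqrt(2), limits +/- 1.96 sqrt(2)
        ba = bland_altman([0.0, 0.0], [-1.0, 1.0])
        assert ba.mean_diff == 0.0
        assert ba.loa_high == pytest.approx(1.96 * math.sqrt(2), abs=1e-12)
        assert ba.loa_low == pytest.approx(-1.96 * math.sqrt(2), abs=1e-12)

    def test_translation_equivariance(self):
        base = bland_altman(TOY_X, TOY_Y)
        shifted = bland_altman(TOY_X, np.asarray(TOY_Y) + 7.5)
        assert shifted.mean_diff == pytest.approx(base.mean_diff + 7.5, abs=1e-10)
        assert shifted.loa_low == pytest.approx(base.loa_low + 7.5, abs=1e-10)
        assert shifted.loa_high == pytest.approx(base.loa_high + 7.5, abs=1e-10)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [2.0])


class TestInterpretationBins:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.2, "poor"),
            (0.49999, "poor"),
            (0.5, "moderate"),
            (0.6, "moderate"),
            (0.75, "good"),
            (0.89, "good"),
            (0.9, "excellent"),
            (0.95, "excellent"),
        ],
    )
    def test_icc_bins(self, value, label):
        assert interpret_icc(value) == label

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.1, "negligible"),
            (-0.45, "weak"),
            (0.3, "weak"),
            (0.55, "moderate"),
            (-0.506, "moderate"),
            (0.7, "strong"),
            (0.95, "very strong"),
            (-0.99, "very strong"),
        ],
    )
    def test_r_bins_use_magnitude(self, value, label):
        assert interpret_r(value) == label


class TestAnalyzePairs:
    def test_full_panel_is_internally_consistent(self):
        res = analyze_pairs(pairs_of(TOY_X, TOY_Y))
        assert res.n == 6
        assert res.ba_loa_low <= res.ba_mean_diff <= res.ba_loa_high
        assert -1.0 <= res.pearson_r <= 1.0
        assert res.icc_absolute <= 1.0 and res.icc_consistency <= 1.0
        assert res.icc_label == interpret_icc(res.icc_absolute)
        assert res.r_label == interpret_r(res.pearson_r)
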