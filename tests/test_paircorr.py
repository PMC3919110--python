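import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import assume, given, strategies as st
from hypothesis.extra import numpy as hnp

from pathdiffcorr import paircorr as pc
from pathdiffcorr.errors import DegenerateFitError


class TestFitLine:
    def test_exact_collinearity(self):
        slope, intercept, sq = pc.fit_line([1, 2, 3], [2, 4, 6])
        assert slope == 2.0
        assert intercept == 0.0
        assert sq.tolist() == [0.0, 0.0, 0.0]

    def test_normal_equations_hand_oracle(self):
        # x=[1,2,3,4], y=[1,3,2,4]: Sxx=5, Sxy=4 -> slope 0.8, intercept 0.5
        slope, intercept, sq = pc.fit_line([1, 2, 3, 4], [1, 3, 2, 4])
        assert slope == pytest.approx(0.8, abs=1e-15)
        assert intercept == pytest.approx(0.5, abs=1e-15)
        np.testing.assert_allclose(
            sq, [0.09, 0.81, 0.81, 0.09], atol=1e-15
        )

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(DegenerateFitError):
            pc.fit_line([0, 1], [0, 1])

    def test_constant_x_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            pc.fit_line([2, 2, 2], [1, 2, 3])

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            slope, intercept, _ = pc.fit_line(x, y)
            ref = scipy.stats.linregress(x, y)
            assert abs(slope - ref.slope) < 1e-12
            assert abs(intercept - ref.intercept) < 1e-12


class TestPearson:
    def test_positive_affine_of_x_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pc.pearson(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-15)

    def test_negation_gives_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pc.pearson(x, -x) == pytest.approx(-1.0, abs=1e-15)

    def test_product_moment_hand_oracle(self):
        # x=[1,2,3,4], y=[1,3,2,4]: Sxy=4, Sxx=Syy=5 -> r = 4/5
        assert pc.pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(
            0.8, abs=1e-15
        )

    def test_constant_vector_is_undefined(self):
        assert math.isnan(pc.pearson([1, 1, 1], [1, 2, 3]))
        assert math.isnan(pc.pearson([1, 2, 3], [5, 5, 5]))

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(3, 60))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert abs(
                pc.pearson(x, y) - scipy.stats.pearsonr(x, y).statistic
            ) < 1e-12

    @given(
        hnp.arrays(
            np.float64, st.integers(4, 30),
            elements=st.floats(-100, 100, width=64),
        ),
        st.data(),
    )
    def test_symmetry_and_affine_invariance(self, x, data):
        y = data.draw(
            hnp.arrays(
                np.float64, x.size, elements=st.floats(-100, 100, width=64)
            )
        )
        assume(np.ptp(x) > 1e-3 and np.ptp(y) > 1e-3)
        r = pc.pearson(x, y)
        r_swapped = pc.pearson(y, x)
        if math.isnan(r):
            assert math.isnan(r_swapped)
            return
        assert r == r_swapped  # exact symmetry
        scale = data.draw(st.floats(0.1, 10))
        shift = data.draw(st.floats(-50, 50))
        assert pc.pearson(scale * x + shift, y) == pytest.approx(
            r, abs=1e-9
        )


class TestClassify:
    @pytest.mark.parametrize(
        ("r", "expected"),
        [
            (0.46, pc.CLASS_COEXPRESSED),
            (0.45, pc.CLASS_UNRELATED),
            (0.45 + 1e-12, pc.CLASS_COEXPRESSED),
            (-0.45, pc.CLASS_UNRELATED),
            (-0.45 - 1e-12, pc.CLASS_REVERSE),
            (-0.46, pc.CLASS_REVERSE),
            (0.0, pc.CLASS_UNRELATED),
            (1.0, pc.CLASS_COEXPRESSED),
            (-1.0, pc.CLASS_REVERSE),
            (float("nan"), pc.CLASS_UNDEFINED),
        ],
    )
    def test_strict_thresholds(self, r, expected):
        assert pc.classify(r) == expected

    @given(st.floats(-0.45, 0.45))
    def test_unrelated_is_the_closed_interval(self, r):
        assert pc.classify(r) == pc.CLASS_UNRELATED


class TestDiscardOutliers:
    def test_collinear_data_discards_nothing(self):
        result = pc.discard_outliers([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert result.threshold == 0.0
        assert result.keep_mask.all()

    def test_single_gross_outlier_is_discarded(self):
        # 20 on-line points plus one offset by 100: brute-force oracle
        x = np.arange(21.0)
        y = 2 * x + 1
        y[10] += 100.0
        slope, intercept, sq = pc.fit_line(x, y)
        threshold = sq.mean() + 3 * sq.std(ddof=0)
        expected_keep = sq <= threshold
        assert expected_keep.sum() == 20  # oracle flags exactly the outlier
        result = pc.discard_outliers(x, y)
        np.testing.assert_array_equal(result.keep_mask, expected_keep)
        assert not result.keep_mask[10]

    def test_retention_floor_caps_discards(self):
        # n=10 with 4 gross outliers: never more than floor(0.2*10)=2 discarded
        x = np.arange(10.0)
        y = x.copy()
        y[[2, 5, 7, 9]] += [50.0, 60.0, 80.0, 70.0]
        result = pc.discard_outliers(x, y)
        assert result.n_discarded <= 2

    def test_cap_keeps_largest_residuals_when_binding(self):
        # with a 1*SD multiplier many points exceed the threshold, so the
        # retention floor binds and only the largest residuals go
        x = np.arange(15.0)
        y = x.copy()
        y[[1, 4, 7, 10, 13]] += [30.0, 31.0, 32.0, 33.0, 34.0]
        config = pc.CorrelationConfig(sd_multiplier=1.0)
        result = pc.discard_outliers(x, y, config)
        flagged = result.squared_residuals > result.threshold
        cap = math.floor(0.2 * 15)
        assert flagged.sum() > cap  # the cap is actually exercised
        assert result.n_discarded == cap
        order = np.argsort(-result.squared_residuals, kind="stable")
        assert set(np.flatnonzero(~result.keep_mask)) == set(order[:cap])

    def test_degenerate_fit_keeps_everything(self):
        result = pc.discard_outliers([3.0, 3.0, 3.0], [1.0, 5.0, 9.0])
        assert result.keep_mask.all()
        assert math.isnan(result.threshold)

    @given(
        hnp.arrays(
            np.float64, st.integers(3, 50),
            elements=st.floats(-1e6, 1e6, width=64),
        ),
        st.data(),
    )
    def test_never_discards_more_than_twenty_percent(self, x, data):
        y = data.draw(
            hnp.arrays(
                np.float64, x.size, elements=st.floats(-1e6, 1e6, width=64)
            )
        )
        result = pc.discard_outliers(x, y)
        assert result.n_discarded <= math.floor(0.2 * x.size)

    def test_adversarial_forty_percent_contamination_keeps_eighty(self):
        rng = np.random.default_rng(0)
        n = 50
        x = rng.standard_normal(n)
        y = 0.5 * x + 0.1 * rng.standard_normal(n)
        y[: n * 2 // 5] += 500.0  # 40% contaminated
        result = pc.discard_outliers(x, y)
        assert result.n_discarded <= math.floor(0.2 * n)
        assert result.keep_mask.sum() >= math.ceil(0.8 * n)

    def test_filter_barely_moves_r_on_clean_bivariate_data(self):
        # outlier-free bivariate normal, n=200: the filter shifts r by less
        # than 0.05 in >=99% of replicates at rho=+/-0.8. At rho=0 the OLS
        # residual is the full y variance, so trimming its tail moves r
        # more; there the shift stays below 0.1 in >=99% of replicates.
        rng = np.random.default_rng(2024)
        for rho, bound in ((-0.8, 0.05), (0.0, 0.1), (0.8, 0.05)):
            n_ok = 0
            n_rep = 1000
            for _ in range(n_rep):
                z = rng.standard_normal((2, 200))
                x = z[0]
                y = rho * z[0] + math.sqrt(1 - rho * rho) * z[1]
                result = pc.discard_outliers(x, y)
                r_raw = pc.pearson(x, y)
                r_filtered = pc.pearson(
                    x[result.keep_mask], y[result.keep_mask]
                )
                n_ok += abs(r_filtered - r_raw) < bound
            assert n_ok / n_rep >= 0.99, f"rho={rho}: {n_ok / n_rep}"


class TestCorrelatePair:
    def test_planted_correlation_recovered(self, ):
        rng = np.random.default_rng(11)
        n = 200
        rho = 0.9
        z = rng.standard_normal((2, n))
        x = z[0]
        y = rho * z[0] + math.sqrt(1 - rho * rho) * z[1]
        n_total, n_used, r = pc.correlate_arrays(x, y)
        assert n_total == n
        assert abs(r - pc.pearson(x, y)) < 0.03  # filtering barely moves r
        assert abs(r - rho) < 0.05

    def test_missing_sample_reduces_n_total(self, tiny_matrix):
        result = pc.correlate_pair(
            tiny_matrix, "p1", "p3", ["s1", "s2", "s3", "s4"],
            config=pc.CorrelationConfig(min_samples=3),
        )
        assert result.n_total == 3  # p3 missing in s4

    def test_constant_probe_is_undefined(self, tiny_matrix):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        y = np.full(10, 4.0)
        n_total, n_used, r = pc.correlate_arrays(x, y)
        assert math.isnan(r)
        assert pc.classify(r) == pc.CLASS_UNDEFINED

    def test_below_min_samples_is_undefined(self):
        x = np.arange(5.0)
        y = np.arange(5.0)
        n_total, n_used, r = pc.correlate_arrays(
            x, y, pc.CorrelationConfig(min_samples=10)
        )
        assert n_total == 5
        assert math.isnan(r)


class TestLog2FoldChange:
    def test_identical_means_give_zero(self, tiny_matrix, two_condition_design):
        lfc = pc.log2_fold_change(
            tiny_matrix, "p1", two_condition_design, "nonrelapse", "relapse"
        )
        # p1: nonrelapse mean (1+2)/2 = 1.5; relapse mean (3+4)/2 = 3.5
        assert lfc == pytest.approx(2.0)

    def test_unit_shift(self, two_condition_design):
        import pandas as pd
        from pathdiffcorr.expression_io import ExpressionMatrix

        matrix = ExpressionMatrix(
            pd.DataFrame(
                [[2.0, 2.0, 3.0, 3.0]], index=["p"],
                columns=["s1", "s2", "s3", "s4"],
            )
        )
        assert pc.log2_fold_change(
            matrix, "p", two_condition_design, "nonrelapse", "relapse"
        ) == pytest.approx(1.0)

    def test_missing_values_excluded(self, tiny_matrix, two_condition_design):
        # p3 relapse values: 6.0 and NaN -> mean 6.0; nonrelapse mean 5.25
        assert pc.log2_fold_change(
            tiny_matrix, "p3", two_condition_design, "nonrelapse", "relapse"
        ) == pytest.approx(6.0 - 5.25)

    def test_all_missing_condition_is_nan(self, two_condition_design):
        import pandas as pd
        from pathdiffcorr.expression_io import ExpressionMatrix

        matrix = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2.0, np.nan, np.nan]], index=["p"],
                columns=["s1", "s2", "s3", "s4"],
            )
        )
        assert math.isnan(
            pc.log2_fold_change(
                matrix, "p", two_condition_design, "nonrelapse", "relapse"
            )
        )
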