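import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdmnir import (
    GridConfig,
    PretreatmentSpec,
    apply_column_scaler,
    apply_pipeline,
    build_grid,
    fit_column_scaler,
    norm2,
    savitzky_golay,
    snv,
    wls_baseline,
)


def windowed_lsq_oracle(row, width, polyorder, deriv):
    """Independent per-window polynomial fit evaluated at window centers."""
    half = width // 2
    out = np.empty_like(row, dtype=float)
    x = np.arange(-half, half + 1, dtype=float)
    for i in range(half, row.size - half):
        coef = np.polynomial.polynomial.polyfit(x, row[i - half : i + half + 1], polyorder)
        d = np.polynomial.polynomial.polyder(coef, deriv) if deriv else coef
        out[i] = np.polynomial.polynomial.polyval(0.0, np.atleast_1d(d))
    return out[half:-half]


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self):
        x = np.arange(30, dtype=float)
        row = 3 + 0.5 * x - 0.02 * x**2
        for width in (5, 11, 21):
            out = savitzky_golay(row[None, :], width, polyorder=2, deriv=0)
            np.testing.assert_allclose(out[0], row, atol=1e-10)

    def test_linear_first_derivative_constant(self):
        row = 2.0 * np.arange(20)
        out = savitzky_golay(row[None, :], 5, polyorder=2, deriv=1)
        np.testing.assert_allclose(out[0], 2.0, atol=1e-10)

    def test_matches_windowed_lsq_oracle(self, rng):
        row = rng.standard_normal(40)
        for deriv in (0, 1, 2):
            got = savitzky_golay(row[None, :], 7, polyorder=2, deriv=deriv)[0][3:-3]
            want = windowed_lsq_oracle(row, 7, 2, deriv)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_constant_row_derivative_is_zero(self):
        out = savitzky_golay(np.full((1, 15), 3.3), 5, deriv=1)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("width", [4, 101])
    def test_bad_width_rejected(self, width):
        with pytest.raises(ValueError):
            savitzky_golay(np.ones((1, 20)), width)


class TestSNV:
    def test_unit_sd_case(self):
        out = snv(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]], atol=1e-12)

    def test_rows_normalized(self, rng):
        out = snv(rng.standard_normal((5, 30)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            snv(np.array([[1.0, 2.0], [5.0, 5.0]]))

    def test_idempotent(self, rng):
        X = rng.standard_normal((3, 20))
        np.testing.assert_allclose(snv(snv(X)), snv(X), atol=1e-10)


class TestWLSBaseline:
    def test_pure_line_removed(self):
        x = np.linspace(0, 1, 50)
        row = (2.0 + 3.0 * x)[None, :]
        out = wls_baseline(row, order=1)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_constant_row_order_zero(self):
        out = wls_baseline(np.full((1, 20), 7.0), order=0)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_peak_preserved_line_removed(self):
        # line + one positive Gaussian peak; oracle = polynomial fitted to
        # the peak-free points only
        p = 200
        x = np.linspace(0, 1, p)
        line = 0.5 + 1.2 * x
        peak = 0.8 * np.exp(-0.5 * ((x - 0.5) / 0.03) ** 2)
        row = line + peak
        peak_free = peak < 1e-6
        coef = np.polynomial.polynomial.polyfit(x[peak_free], row[peak_free], 2)
        oracle = row - np.polynomial.polynomial.polyval(x, coef)
        out = wls_baseline(row[None, :], order=2)[0]
        apex = np.argmax(peak)
        assert abs(out[apex] - oracle[apex]) < 0.02 * peak.max()

    def test_order_too_large_rejected(self):
        with pytest.raises(ValueError):
            wls_baseline(np.ones((1, 4)), order=4)


class TestNorm2:
    def test_three_four_five(self):
        np.testing.assert_allclose(norm2(np.array([[3.0, 4.0]])), [[0.6, 0.8]], atol=1e-15)

    def test_unit_norms(self, rng):
        out = norm2(rng.standard_normal((4, 25)))
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            norm2(np.zeros((1, 5)))


class TestColumnScalers:
    def test_train_columns_centered_and_scaled(self, rng):
        X = rng.standard_normal((12, 6)) * 3 + 1
        f = fit_column_scaler(X, "autoscale")
        out = apply_column_scaler(f, X)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_test_row_at_train_means_maps_to_zero(self, rng):
        X = rng.standard_normal((8, 4))
        f = fit_column_scaler(X, "mean_center")
        out = apply_column_scaler(f, X.mean(axis=0)[None, :])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_manual_formula_on_test_split(self, rng):
        X = rng.standard_normal((20, 5))
        tr, te = X[:15], X[15:]
        f = fit_column_scaler(tr, "autoscale")
        manual = (te - tr.mean(axis=0)) / tr.std(axis=0, ddof=1)
        np.testing.assert_allclose(apply_column_scaler(f, te), manual, atol=1e-12)

    def test_constant_column_gets_unit_scale_with_warning(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            f = fit_column_scaler(X, "autoscale")
        assert f.scales[0] == 1.0

    def test_no_train_test_leakage(self, rng):
        # fitting on train-only vs train+test must change test output
        X = rng.standard_normal((10, 3))
        tr, te = X[:7], X[7:]
        out_clean = apply_column_scaler(fit_column_scaler(tr, "mean_center"), te)
        out_leaky = apply_column_scaler(fit_column_scaler(X, "mean_center"), te)
        assert not np.allclose(out_clean, out_leaky)


class TestSpecDSL:
    @pytest.mark.parametrize(
        "text", ["SM(W=23)+N+MC", "1D(W=15)+MC", "WLS+N+MC", "2D(W=3)+N+MC", "SNV+MC", "AS"]
    )
    def test_parse_print_round_trip(self, text):
        assert str(PretreatmentSpec.parse(text)) == text

    def test_two_filters_rejected(self):
        with pytest.raises(ValueError, match="at most one"):
            PretreatmentSpec.parse("SM(W=5)+1D(W=5)+MC")

    def test_scaler_must_be_last(self):
        with pytest.raises(ValueError, match="last"):
            PretreatmentSpec.parse("MC+N")

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            PretreatmentSpec.parse("SM(W=4)+MC")


class TestGrid:
    def test_default_grid_size_78(self):
        specs = build_grid(GridConfig())
        assert len(specs) == 78
        assert len({str(s) for s in specs}) == 78

    def test_derivative_only_single_width(self):
        cfg = GridConfig(
            widths=(15,),
            filters=("deriv1", "deriv2"),
            include_no_filter=False,
            norm_options=("none",),
        )
        assert len(build_grid(cfg)) == 6

    def test_contains_published_winners(self):
        names = {str(s) for s in build_grid(GridConfig())}
        assert "1D(W=15)+MC" in names
        assert "N+MC" in names
        assert "SM(W=23)+N+MC" in names
        assert "WLS+N+MC" in names

    def test_empty_options_rejected(self):
        with pytest.raises(ValueError):
            build_grid(GridConfig(scatter_options=()))


class TestPipeline:
    def test_mean_center_idempotent_on_centered_data(self, rng):
        X = rng.standard_normal((6, 4))
        X = X - X.mean(axis=0)
        out, _ = apply_pipeline(X, PretreatmentSpec.parse("MC"))
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_composition_matches_manual(self, rng):
        X = rng.standard_normal((5, 10)) + 2
        spec = PretreatmentSpec.parse("N+MC")
        out, _ = apply_pipeline(X, spec)
        manual = norm2(X)
        manual = manual - manual.mean(axis=0)
        np.testing.assert_allclose(out, manual, atol=1e-12)

    def test_fitted_scaler_reused_on_test(self, rng):
        X = rng.standard_normal((8, 5))
        spec = PretreatmentSpec.parse("SNV+MC")
        _, fitted = apply_pipeline(X, spec)
        Xt = rng.standard_normal((3, 5))
        out, _ = apply_pipeline(Xt, spec, fitted)
        manual = snv(Xt) - fitted.means
        np.testing.assert_allclose(out, manual, atol=1e-12)

    @given(perm_seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_row_operators_commute_with_row_permutation(self, perm_seed):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((6, 20)) + 3
        perm = np.random.default_rng(perm_seed).permutation(6)
        spec = PretreatmentSpec.parse("SM(W=5)+SNV+N")
        from gdmnir.pretreat import apply_row_steps

        np.testing.assert_allclose(
            apply_row_steps(X, spec)[perm], apply_row_steps(X[perm], spec), atol=1e-12
        )
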