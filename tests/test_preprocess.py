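import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirpls import (
    PreprocessChain,
    SpectraError,
    SpectraMatrix,
    apply_chain,
    column_weights,
    restrict_range,
    sg_derivative,
    snv,
)


def make(nu, rows, ids=None):
    rows = np.atleast_2d(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return SpectraMatrix(ids, nu, rows)


class TestSNV:
    def test_simple_row(self):
        out = snv(make([1.0, 2.0, 3.0], [3.0, 4.0, 5.0]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-14)

    def test_rows_have_zero_mean_unit_sample_sd(self, rng):
        out = snv(make(np.arange(50.0), rng.normal(2.0, 3.0, size=(6, 50))))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_constant_row_rejected_naming_sample(self):
        with pytest.raises(SpectraError, match="s0"):
            snv(make([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], ids=["s0"]))

    def test_idempotent(self, rng):
        s = make(np.arange(30.0), rng.normal(size=(4, 30)))
        once = snv(s)
        np.testing.assert_allclose(snv(once).absorbance, once.absorbance, atol=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=20)
        if np.std(x, ddof=1) < 1e-9:
            return
        s = make(np.arange(20.0), x)
        t = make(np.arange(20.0), a * x + b)
        np.testing.assert_allclose(snv(t).absorbance, snv(s).absorbance,
                                   atol=1e-8, rtol=1e-8)


class TestSGDerivative:
    nu = np.arange(4000.0, 4000.0 + 4.0 * 60, 4.0)

    def test_constant_gives_zero(self):
        out = sg_derivative(make(self.nu, np.full((1, 60), 3.3)))
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_linear_gives_slope(self):
        out = sg_derivative(make(self.nu, 0.002 * self.nu + 7.0))
        np.testing.assert_allclose(out.absorbance, 0.002, atol=1e-12)

    def test_quadratic_gives_analytic_derivative(self):
        out = sg_derivative(make(self.nu, self.nu ** 2))
        np.testing.assert_allclose(out.absorbance[0], 2.0 * out.wavenumbers, atol=1e-9)

    def test_axis_trimmed_by_half_window(self):
        out = sg_derivative(make(self.nu, self.nu * 0.0), window=21)
        assert out.wavenumbers.size == 60 - 20
        np.testing.assert_array_equal(out.wavenumbers, self.nu[10:-10])

    def test_decreasing_axis_same_derivative(self):
        inc = sg_derivative(make(self.nu, self.nu ** 2))
        dec = sg_derivative(make(self.nu[::-1].copy(), (self.nu ** 2)[::-1]))
        np.testing.assert_allclose(dec.absorbance[0], 2.0 * dec.wavenumbers, atol=1e-9)
        np.testing.assert_allclose(sorted(dec.absorbance[0]), sorted(inc.absorbance[0]),
                                   atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(SpectraError, match="odd"):
            sg_derivative(make(self.nu, self.nu), window=20)

    def test_too_few_points_rejected(self):
        with pytest.raises(SpectraError, match="21"):
            sg_derivative(make(self.nu[:10], self.nu[:10]))

    def test_linearity(self, rng):
        x = rng.normal(size=(1, 60))
        y = rng.normal(size=(1, 60))
        a, b = 2.5, -1.3
        lhs = sg_derivative(make(self.nu, a * x + b * y)).absorbance
        rhs = (a * sg_derivative(make(self.nu, x)).absorbance
               + b * sg_derivative(make(self.nu, y)).absorbance)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestRestrictRange:
    def test_inclusive_bounds(self):
        nu = np.arange(3300.0, 12000.0, 100.0)
        out = restrict_range(make(nu, np.zeros((1, nu.size))), 4000.0, 8998.0)
        assert out.wavenumbers.min() >= 4000.0
        assert out.wavenumbers.max() <= 8998.0
        assert 4000.0 in out.wavenumbers  # endpoint kept

    def test_invalid_bounds_rejected(self):
        nu = np.arange(10.0)
        with pytest.raises(SpectraError, match="lo"):
            restrict_range(make(nu, np.zeros((1, 10))), 5.0, 4.0)

    def test_full_span_is_identity(self, small_spectra):
        out = restrict_range(small_spectra, small_spectra.wavenumbers.min() - 1,
                             small_spectra.wavenumbers.max() + 1)
        assert out == small_spectra

    def test_nested_composition(self):
        nu = np.arange(0.0, 100.0)
        s = make(nu, np.arange(100.0)[None, :])
        outer_then_inner = restrict_range(restrict_range(s, 10.0, 90.0), 20.0, 80.0)
        inner_only = restrict_range(s, 20.0, 80.0)
        assert outer_then_inner == inner_only


class TestColumnWeights:
    def test_inverse_sample_sd(self):
        s = make([1.0, 2.0], np.array([[0.0, 0.0], [4.0, 2.0]]))
        w = column_weights(s)
        sd = np.array([4.0, 2.0]) / np.sqrt(2)  # ddof=1 for two samples
        np.testing.assert_allclose(w, 1.0 / sd)

    def test_zero_variance_column_named(self):
        s = make([1.0, 2.0], np.array([[1.0, 0.0], [1.0, 2.0]]))
        with pytest.raises(SpectraError, match="1.000"):
            column_weights(s)

    def test_scaling_column_scales_weight_inversely(self, rng):
        X = rng.normal(size=(8, 3))
        s1 = make([1.0, 2.0, 3.0], X)
        X2 = X.copy()
        X2[:, 1] *= 5.0
        s2 = make([1.0, 2.0, 3.0], X2)
        np.testing.assert_allclose(column_weights(s2)[1],
                                   column_weights(s1)[1] / 5.0)


class TestChain:
    def test_order_is_snv_then_sg_then_range(self, rng):
        # on a scatter-perturbed curved spectrum the two orders differ
        nu = np.arange(4000.0, 4000.0 + 4.0 * 80, 4.0)
        base = 1e-6 * nu ** 2
        rows = np.vstack([base, 2.5 * base + 0.3])
        s = make(nu, rows)
        chain_order = sg_derivative(snv(s)).absorbance
        other_order = snv(sg_derivative(s)).absorbance
        assert not np.allclose(chain_order, other_order)
        chain = PreprocessChain(range_lo=nu[15], range_hi=nu[-15],
                                weight_columns=False)
        got = apply_chain(chain, s)
        # matches the documented order applied by hand
        manual = restrict_range(sg_derivative(snv(s)), nu[15], nu[-15])
        assert got == manual

    def test_empty_chain_is_identity(self, small_spectra):
        chain = PreprocessChain(snv=False, sg_window=None, range_lo=None,
                                weight_columns=False)
        assert apply_chain(chain, small_spectra) == small_spectra

    def test_weights_fitted_once_and_reused(self, rng):
        nu = np.arange(4000.0, 4000.0 + 4.0 * 60, 4.0)
        cal = make(nu, rng.normal(size=(10, 60)))
        new = make(nu, rng.normal(size=(3, 60)), ids=["n0", "n1", "n2"])
        chain = PreprocessChain(range_lo=None, sg_window=21)
        chain.fit_transform(cal)
        w_cal = chain.fitted_column_weights.copy()
        chain.transform(new)
        np.testing.assert_array_equal(chain.fitted_column_weights, w_cal)

    def test_transform_requires_fit(self, small_spectra):
        chain = PreprocessChain(sg_window=None, range_lo=None)
        with pytest.raises(SpectraError, match="not fitted"):
            chain.transform(small_spectra)

    def test_invalid_window_rejected(self):
        with pytest.raises(SpectraError):
            PreprocessChain(sg_window=2, sg_polyorder=2)
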