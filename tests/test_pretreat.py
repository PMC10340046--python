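"""Scatter correction and gap-segment derivative math."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import faecalnirs as fn
from faecalnirs.pretreat import DegenerateSpectrumError, _boxcar


class TestTreatmentCode:
    @pytest.mark.parametrize(
        "code, expected",
        [
            ("1,5,5,1", (1, 5, 5, 1)),
            ("2,10,5,1", (2, 10, 5, 1)),
            ("0,0,1,1", (0, 0, 1, 1)),
        ],
    )
    def test_parse(self, code, expected):
        t = fn.parse_treatment_code(code)
        assert (t.derivative, t.gap, t.smooth1, t.smooth2) == expected

    def test_format_round_trips(self):
        for t in fn.STANDARD_TREATMENTS:
            assert fn.parse_treatment_code(str(t)) == t

    @pytest.mark.parametrize("bad", ["1,5,5", "a,b,c,d", "1;5;5;1", "", "1,5,5,1,2"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            fn.parse_treatment_code(bad)

    def test_standard_treatment_list(self):
        codes = [str(t) for t in fn.STANDARD_TREATMENTS]
        assert codes == ["1,4,4,1", "1,8,4,1", "1,5,5,1", "1,10,5,1",
                         "2,4,4,1", "2,8,4,1", "2,5,5,1", "2,10,5,1"]


class TestSnv:
    def test_three_point_example(self):
        np.testing.assert_allclose(fn.snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_output_mean_zero_sd_one(self, rng):
        X = rng.standard_normal((20, 50)) * 3 + 5
        out = fn.snv(X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            fn.snv(np.full(10, 5.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, seed, a, b):
        """snv(a*x + b) == snv(x) for any a > 0 and offset b."""
        x = np.random.default_rng(seed).standard_normal(64)
        np.testing.assert_allclose(fn.snv(a * x + b), fn.snv(x), atol=1e-8)


class TestDetrend:
    wl = fn.DEFAULT_GRID.wavelengths

    def test_exact_quadratic_removed(self):
        y = 3.0 + 0.01 * self.wl + 1e-6 * self.wl**2
        out = fn.detrend(y, fn.DEFAULT_GRID, degree=2)
        assert np.max(np.abs(out)) <= 1e-8

    def test_residuals_orthogonal_to_basis(self, rng):
        y = rng.standard_normal(700)
        out = fn.detrend(y, fn.DEFAULT_GRID, degree=2)
        scale = np.abs(y).sum()
        assert abs(out.sum()) <= 1e-6 * scale
        assert abs(out @ self.wl) <= 1e-6 * scale * np.abs(self.wl).max()

    def test_degree_zero_is_mean_centring(self, rng):
        y = rng.standard_normal(700)
        np.testing.assert_allclose(fn.detrend(y, fn.DEFAULT_GRID, degree=0), y - y.mean(), atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fn.detrend(np.array([1.0, 2.0]), np.array([1100.0, 1102.0]), degree=2)


class TestGapSegmentDerivative:
    def test_constant_annihilated(self):
        for code in fn.STANDARD_TREATMENTS:
            out, _ = fn.gap_segment_derivative(np.full(700, 0.7), code)
            np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_unit_ramp_first_derivative(self):
        y = np.arange(700, dtype=float)
        out, _ = fn.gap_segment_derivative(y, fn.parse_treatment_code("1,5,1,1"))
        np.testing.assert_allclose(out, 10.0)
        assert out.size == 700 - 2 * 5

    def test_second_derivative_annihilates_lines(self):
        y = 2.0 + 0.3 * np.arange(700)
        out, _ = fn.gap_segment_derivative(y, fn.parse_treatment_code("2,5,5,1"))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    @pytest.mark.parametrize("code_str", ["1,5,5,1", "2,10,5,1", "1,4,4,1", "0,0,5,3"])
    def test_matches_loop_oracle(self, code_str, rng):
        """Composition smooth -> gap difference -> smooth, index by index."""
        import warnings as _warnings

        code = fn.parse_treatment_code(code_str)
        wl = fn.DEFAULT_GRID.wavelengths
        y = 0.5 * np.exp(-0.5 * ((wl - 1700) / 80) ** 2) + 0.01 * rng.standard_normal(700)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # even widths warn; covered elsewhere
            out, grid = fn.gap_segment_derivative(y, code, fn.DEFAULT_GRID)
        s1 = code.smooth1 + (code.smooth1 % 2 == 0)
        s2 = code.smooth2 + (code.smooth2 % 2 == 0)
        g = code.gap if code.derivative else 0

        def smooth(v, w):
            h = w // 2
            return np.array([v[i - h : i + h + 1].mean() for i in range(h, v.size - h)])

        stage = smooth(y, s1)
        if code.derivative == 1:
            stage = np.array([stage[i + g] - stage[i - g] for i in range(g, stage.size - g)])
        elif code.derivative == 2:
            stage = np.array(
                [stage[i + g] - 2 * stage[i] + stage[i - g] for i in range(g, stage.size - g)]
            )
        stage = smooth(stage, s2)
        np.testing.assert_allclose(out, stage, atol=1e-10)
        assert grid.n_points == out.size

    def test_too_short_spectrum_reports_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            fn.gap_segment_derivative(np.arange(10.0), fn.parse_treatment_code("1,10,5,1"))

    def test_even_window_widened_with_warning(self):
        with pytest.warns(UserWarning, match="even"):
            out, _ = fn.gap_segment_derivative(np.arange(100.0), fn.parse_treatment_code("1,4,4,1"))
        assert out.size == 100 - 2 * (2 + 4 + 0)  # s1 4->5 trims 2, gap 4, s2 1


class TestApplyTreatment:
    def test_identity_code_without_scatter(self, small_set):
        code = fn.parse_treatment_code("0,0,1,1", scatter="none")
        out = fn.apply_treatment(small_set, code)
        np.testing.assert_array_equal(out.absorbance, small_set.absorbance)

    def test_scatter_family_collapses_under_snv_dt(self, rng):
        """Multiplicative copies a_k * x become identical after SNV + DT."""
        wl = fn.DEFAULT_GRID.wavelengths
        base = 0.4 + 0.2 * np.exp(-0.5 * ((wl - 1900) / 90) ** 2)
        scales = np.array([0.5, 1.0, 1.7, 3.2])
        meta = pd.DataFrame({"sample_id": list("abcd"), "replicate_id": ["1"] * 4})
        sset = fn.SpectraSet(fn.DEFAULT_GRID, np.outer(scales, base), meta)
        out = fn.apply_treatment(sset, fn.parse_treatment_code("1,5,5,1"))
        for row in out.absorbance[1:]:
            np.testing.assert_allclose(row, out.absorbance[0], atol=1e-9)

    def test_truncation_rule_and_grid(self, small_set):
        code = fn.parse_treatment_code("1,5,5,1")
        out = fn.apply_treatment(small_set, code)
        trim = 5 // 2 + 5 + 1 // 2
        assert out.grid.n_points == 700 - 2 * trim
        assert out.grid.start_nm == 1100 + 2 * trim

    def test_order_stability_under_permutation(self, small_set, rng):
        code = fn.parse_treatment_code("1,5,5,1")
        out = fn.apply_treatment(small_set, code)
        perm = rng.permutation(len(small_set))
        permuted = fn.SpectraSet(small_set.grid, small_set.absorbance[perm], small_set.meta.iloc[perm])
        out_p = fn.apply_treatment(permuted, code)
        np.testing.assert_allclose(out_p.absorbance, out.absorbance[perm], atol=1e-12)

    def test_derivative_first_order_differs(self, small_set):
        code = fn.parse_treatment_code("1,5,5,1")
        a = fn.apply_treatment(small_set, code, order="scatter_first")
        b = fn.apply_treatment(small_set, code, order="derivative_first")
        assert a.grid == b.grid
        assert not np.allclose(a.absorbance, b.absorbance)
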