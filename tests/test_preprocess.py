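"""Replicate averaging, Savitzky-Golay derivatives, region/point lookup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsalt import PreprocessConfig, io, preprocess
from nirsalt.exceptions import ValidationError

GRID = io.default_grid()


def spectra_from(rows, replicate_of=None, grid=GRID):
    ids = [f"m{i}" for i in range(len(rows))]
    return io.SpectraMatrix(ids, grid, np.asarray(rows, float), replicate_of)


class TestPreprocessConfig:
    @pytest.mark.parametrize("window,poly", [(16, 2), (3, 4), (1, 0)])
    def test_bad_window_rejected(self, window, poly):
        with pytest.raises(ValidationError):
            PreprocessConfig(sg_window=window, sg_polyorder=poly)

    def test_derivative_cannot_exceed_polyorder(self):
        with pytest.raises(ValidationError):
            PreprocessConfig(derivative_order=3, sg_polyorder=2)


class TestAverageReplicates:
    def test_identical_replicates_unchanged(self):
        row = np.sin(GRID / 500.0)
        m = spectra_from([row, row], {"m0": "s", "m1": "s"})
        out = preprocess.average_replicates(m)
        assert out.sample_ids == ["s"]
        np.testing.assert_allclose(out.absorbance[0], row)

    def test_opposite_replicates_cancel(self):
        row = np.cos(GRID / 700.0)
        m = spectra_from([row, -row], {"m0": "s", "m1": "s"})
        np.testing.assert_allclose(
            preprocess.average_replicates(m).absorbance, 0.0, atol=1e-15
        )

    def test_counts_and_first_occurrence_order(self, small_dataset):
        out = preprocess.average_replicates(small_dataset.spectra)
        assert out.absorbance.shape[0] == len(small_dataset.reference)
        assert out.sample_ids == small_dataset.reference.sample_ids

    def test_requires_replicate_mapping(self):
        m = spectra_from([np.ones(GRID.size)])
        with pytest.raises(ValidationError, match="replicate"):
            preprocess.average_replicates(m)


class TestSgDerivative:
    def test_constant_gives_zero(self):
        m = spectra_from([np.full(GRID.size, 3.7)])
        out = preprocess.sg_derivative(m, PreprocessConfig())
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_quadratic_matches_analytic_derivative(self):
        # y = a x^2 + b x + c  ->  y' = 2 a x + b, exact for polyorder >= 2
        a, b, c = 3e-8, -2e-4, 1.0
        m = spectra_from([a * GRID**2 + b * GRID + c])
        out = preprocess.sg_derivative(m, PreprocessConfig(sg_window=17, sg_polyorder=2))
        interior = slice(8, -8)
        np.testing.assert_allclose(
            out.absorbance[0][interior], (2 * a * GRID + b)[interior], atol=1e-8
        )

    def test_linear_slope_recovered_everywhere(self):
        s = 5e-5
        m = spectra_from([s * GRID + 0.2])
        out = preprocess.sg_derivative(m, PreprocessConfig())
        np.testing.assert_allclose(out.absorbance[0], s, rtol=1e-9)

    def test_window_larger_than_grid_rejected(self):
        small = io.default_grid(4100, 4000, 16.0)  # 7 points
        m = io.SpectraMatrix(["a"], small, np.ones((1, small.size)))
        with pytest.raises(ValidationError, match="window"):
            preprocess.sg_derivative(m, PreprocessConfig(sg_window=17))

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(-2, 2),
        b=st.floats(-2, 2),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, GRID.size))
        cfg = PreprocessConfig()
        d = lambda rows: preprocess.sg_derivative(spectra_from(rows), cfg).absorbance
        np.testing.assert_allclose(
            d([a * x + b * y])[0], a * d([x])[0] + b * d([y])[0], atol=1e-9
        )

    def test_commutes_with_replicate_averaging(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(4, GRID.size))
        rep = {"m0": "s1", "m1": "s1", "m2": "s2", "m3": "s2"}
        cfg = PreprocessConfig()
        m = spectra_from(rows, rep)
        avg_then_d = preprocess.sg_derivative(preprocess.average_replicates(m), cfg)
        d_then_avg = preprocess.average_replicates(
            preprocess.sg_derivative(m, cfg).copy_with(replicate_of=rep)
        )
        np.testing.assert_allclose(avg_then_d.absorbance, d_then_avg.absorbance, atol=1e-12)


class TestRegionAndLookup:
    def test_full_region_is_identity(self):
        m = spectra_from([np.arange(GRID.size, dtype=float)])
        out = preprocess.select_region(m, 4000, 12000)
        np.testing.assert_array_equal(out.wavenumbers, GRID)

    def test_region_5000_6000_has_63_columns(self):
        m = spectra_from([np.zeros(GRID.size)])
        out = preprocess.select_region(m, 5000, 6000)
        assert out.wavenumbers.size == 63
        assert out.wavenumbers[0] == 6000 and out.wavenumbers[-1] == 5008

    def test_empty_overlap_rejected(self):
        m = spectra_from([np.zeros(GRID.size)])
        with pytest.raises(ValidationError, match="overlap"):
            preprocess.select_region(m, 13000, 14000)

    def test_nearest_point_for_5537_is_5536(self):
        m = spectra_from([GRID.astype(float)])
        values, used = preprocess.value_at(m, 5537)
        assert used == 5536
        assert values[0] == 5536

    def test_exact_grid_value_returned(self):
        m = spectra_from([GRID.astype(float)])
        _, used = preprocess.value_at(m, 8000)
        assert used == 8000

    def test_midpoint_tie_goes_to_higher_wavenumber(self):
        m = spectra_from([GRID.astype(float)])
        _, used = preprocess.value_at(m, 8008)  # midway between 8016 and 8000
        assert used == 8016
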