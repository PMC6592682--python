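"""Window correlation, peak location, cycle alignment, vector validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopiv.piv import (
    AperiodicStackError,
    CorrelationPlane,
    CycleAlignment,
    DegenerateWindowError,
    EmptyPhaseBinError,
    FrameStack,
    InterrogationGrid,
    VelocityField,
    align_cycles,
    correlate_window_pair,
    ensemble_correlation,
    locate_peak,
    validate_vectors,
)


from conftest import zncc_direct


class TestCorrelateWindowPair:
    def test_matches_direct_sum_oracle(self, rng):
        fa = rng.random((80, 80))
        fb = rng.random((80, 80))
        for w, r, pred in ((16, 5, (0, 0)), (32, 8, (3, -2))):
            plane = correlate_window_pair(fa, fb, (40, 40), w, r, pred)
            oracle = zncc_direct(fa, fb, (40, 40), w, r, pred)
            np.testing.assert_allclose(plane.values, oracle, atol=1e-10)

    def test_matches_skimage_match_template(self, rng):
        # second independent route: normalized template matching
        from skimage.feature import match_template

        fa, fb = rng.random((64, 64)), rng.random((64, 64))
        w, r = 16, 5
        plane = correlate_window_pair(fa, fb, (32, 32), w, r)
        big = fb[32 - 8 - r: 32 - 8 + w + r, 32 - 8 - r: 32 - 8 + w + r]
        tmpl = fa[32 - 8: 32 + 8, 32 - 8: 32 + 8]
        np.testing.assert_allclose(plane.values, match_template(big, tmpl), atol=1e-10)

    def test_integer_shift_peaks_at_shift_with_unit_value(self, rng):
        fa = rng.random((64, 64))
        fb = np.roll(np.roll(fa, 1, axis=0), 3, axis=1)  # content moves (+3, +1)
        plane = correlate_window_pair(fa, fb, (32, 32), 16, 5)
        iy, ix = np.unravel_index(np.argmax(plane.values), plane.values.shape)
        assert (ix - 5, iy - 5) == (3, 1)
        assert plane.values[iy, ix] == pytest.approx(1.0, abs=1e-12)

    def test_identity_peaks_at_zero(self, rng):
        fa = rng.random((64, 64))
        plane = correlate_window_pair(fa, fa, (32, 32), 16, 5)
        assert np.unravel_index(np.argmax(plane.values), (11, 11)) == (5, 5)

    def test_antisymmetry_of_located_displacement(self, speckle_pair):
        fa, fb = speckle_pair
        fwd = locate_peak(correlate_window_pair(fa, fb, (48, 48), 32, 6))
        rev = locate_peak(correlate_window_pair(fb, fa, (48, 48), 32, 6))
        assert fwd.dx == pytest.approx(-rev.dx, abs=0.05)
        assert fwd.dy == pytest.approx(-rev.dy, abs=0.05)

    def test_zero_variance_window_flagged_degenerate(self):
        flat = np.zeros((64, 64))
        tex = np.random.default_rng(0).random((64, 64))
        plane = correlate_window_pair(flat, tex, (32, 32), 16, 5)
        assert plane.degenerate
        np.testing.assert_array_equal(plane.values, 0.0)

    def test_out_of_bounds_window_rejected(self, rng):
        fa = rng.random((64, 64))
        with pytest.raises(ValueError):
            correlate_window_pair(fa, fa, (4, 32), 16, 5)

    def test_values_bounded_by_one(self, rng):
        fa, fb = rng.normal(size=(64, 64)), rng.normal(size=(64, 64))
        plane = correlate_window_pair(fa, fb, (32, 32), 16, 8)
        assert np.all(np.abs(plane.values) <= 1.0)


class TestLocatePeak:
    @staticmethod
    def _plane(values, r):
        return CorrelationPlane(values=np.asarray(values, float), search_radius=r)

    def test_symmetric_integer_peak(self):
        vals = np.zeros((11, 11))
        vals[6, 8] = 1.0  # lag (dx=3, dy=1)
        vals[6, 7] = vals[6, 9] = vals[5, 8] = vals[7, 8] = 0.5
        fit = locate_peak(self._plane(vals, 5))
        assert (fit.dx, fit.dy) == (3.0, 1.0)

    def test_gaussian_triplet_recovers_subpixel_offset(self):
        # peak sampled from exp(-(x-0.3)^2/2): three-point fit is exact
        xs = np.array([-1.0, 0.0, 1.0])
        col = np.exp(-((xs - 0.3) ** 2) / 2.0)
        vals = np.zeros((5, 5))
        vals[2, 1:4] = col
        vals[1:4, 2] = np.exp(-(xs ** 2) / 2.0) * col[1]
        fit = locate_peak(self._plane(vals, 2))
        assert fit.dx == pytest.approx(0.3, abs=1e-9)
        assert fit.dy == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_plane_raises_degenerate(self):
        with pytest.raises(DegenerateWindowError):
            locate_peak(CorrelationPlane(np.zeros((11, 11)), 5, degenerate=True))
        with pytest.raises(DegenerateWindowError):
            locate_peak(self._plane(np.ones((11, 11)), 5))

    def test_border_peak_flagged_without_subpixel_fit(self):
        vals = np.zeros((11, 11))
        vals[5, 10] = 1.0
        fit = locate_peak(self._plane(vals, 5))
        assert fit.border_limited and fit.dx == 5.0

    def test_tie_breaks_toward_smaller_displacement(self):
        vals = np.zeros((11, 11))
        vals[5, 3] = vals[5, 9] = 1.0  # lags dx=-2 and dx=+4
        fit = locate_peak(self._plane(vals, 5))
        assert fit.dx == pytest.approx(-2.0, abs=0.5)

    def test_peak_ratio_reflects_secondary_peak(self):
        vals = np.zeros((11, 11))
        vals[5, 5] = 1.0
        vals[2, 8] = 0.5
        fit = locate_peak(self._plane(vals, 5))
        assert fit.peak_ratio == pytest.approx(2.0)


def tiled_stack(period, n_frames, seed=0, shape=(24, 24)):
    """Noise-free stack that repeats one random cycle exactly."""
    rng = np.random.default_rng(seed)
    cycle = rng.random((period, *shape))
    reps = int(np.ceil(n_frames / period))
    frames = np.tile(cycle, (reps, 1, 1))[:n_frames]
    return FrameStack(frames, pixel_size=1.0, frame_interval=10.0)


class TestAlignCycles:
    def test_recovers_constructed_integer_period(self):
        al = align_cycles(tiled_stack(30, 510))
        assert al.period == pytest.approx(30.0, abs=1e-3)
        assert al.n_cycles == pytest.approx(17.0, abs=1e-3)
        assert al.n_phase_bins == 30

    def test_constant_stack_is_aperiodic(self):
        with pytest.raises(AperiodicStackError):
            align_cycles(FrameStack(np.full((100, 16, 16), 3.0), 1.0, 10.0))

    def test_noise_stack_is_aperiodic(self, rng):
        with pytest.raises(AperiodicStackError):
            align_cycles(FrameStack(rng.normal(10, 2, (200, 24, 24)), 1.0, 10.0))

    def test_too_short_stack_rejected(self):
        with pytest.raises(ValueError):
            align_cycles(FrameStack(np.random.default_rng(0).random((6, 16, 16)), 1.0, 10.0))

    def test_bins_partition_frames(self):
        al = align_cycles(tiled_stack(25, 250), n_phase_bins=25)
        assert al.bin_of_frame.min() == 0 and al.bin_of_frame.max() == 24
        assert np.all(np.bincount(al.bin_of_frame, minlength=25) == 10)

    def test_phase_follows_frame_index(self):
        al = CycleAlignment.from_period(30.0, 120)
        np.testing.assert_allclose(al.phase_of_frame, np.mod(np.arange(120) / 30.0, 1.0))


class TestEnsembleCorrelation:
    def test_single_pair_equals_window_pair(self, rng):
        frames = rng.random((2, 48, 48))
        stack = FrameStack(frames, 1.0, 10.0)
        grid = InterrogationGrid.cover((48, 48), 16, 16)
        ens = ensemble_correlation(stack, CycleAlignment.steady(2), grid, 0, search_radius=4)
        cy, cx = grid.y[1], grid.x[1]
        single = correlate_window_pair(frames[0], frames[1], (cx, cy), 16, 4)
        np.testing.assert_allclose(ens.values[1, 1], single.values, atol=1e-12)

    def test_identical_cycles_average_to_single_pair_plane(self):
        stack = tiled_stack(10, 101, shape=(48, 48))
        al = CycleAlignment.from_period(10.0, 101)
        grid = InterrogationGrid.cover((48, 48), 16, 16)
        ens = ensemble_correlation(stack, al, grid, 3, search_radius=4)
        assert ens.n_pairs_pooled == 10
        single = correlate_window_pair(
            stack.frames[3], stack.frames[4], (grid.x[1], grid.y[1]), 16, 4
        )
        np.testing.assert_allclose(ens.values[1, 1], single.values, atol=1e-10)

    def test_empty_bin_rejected_by_name(self):
        stack = tiled_stack(10, 41, shape=(48, 48))
        al = CycleAlignment.from_period(10.0, 41, n_phase_bins=50)
        grid = InterrogationGrid.cover((48, 48), 16, 16)
        with pytest.raises(EmptyPhaseBinError, match="37"):
            ensemble_correlation(stack, al, grid, 37, search_radius=4)


def uniform_field(nb=1, ny=6, nx=8, u0=2.0, v0=0.5):
    shape = (nb, ny, nx)
    return VelocityField(
        x=np.arange(8, 8 + 4 * nx, 4, dtype=float),
        y=np.arange(8, 8 + 4 * ny, 4, dtype=float),
        u=np.full(shape, u0), v=np.full(shape, v0),
        valid=np.ones(shape, bool), source=np.zeros(shape, np.uint8),
        peak_ratio=np.full(shape, np.inf), pixel_size=1.75, frame_interval=15.0,
    )


class TestValidateVectors:
    def test_identical_field_flags_nothing(self):
        f = validate_vectors(uniform_field())
        assert f.valid.all()
        assert (f.source == 0).all()

    def test_single_outlier_flagged_and_replaced_by_neighbor_median(self):
        f = uniform_field()
        f.u[0, 3, 4] = 9.0
        out = validate_vectors(f)
        assert not out.valid[0, 3, 4]
        assert out.u[0, 3, 4] == pytest.approx(2.0)
        assert out.source[0, 3, 4] == 1
        assert out.valid.sum() == f.valid.size - 1

    def test_smooth_shear_passes_unflagged(self):
        # hand check on the interior: neighbors' median equals the center
        # value for a linear ramp, so the residual is zero everywhere
        f = uniform_field(ny=7, nx=7)
        f.u[0] = 0.1 * np.arange(7)[:, None] * np.ones(7)
        out = validate_vectors(f)
        assert out.valid.all()

    def test_invalid_vectors_filled_from_neighbors(self):
        f = uniform_field()
        f.valid[0, 2, 2] = False
        f.u[0, 2, 2] = np.nan
        out = validate_vectors(f)
        assert out.u[0, 2, 2] == pytest.approx(2.0)
        assert not out.valid[0, 2, 2]
        assert out.source[0, 2, 2] == 1

    def test_units_conversion_is_exact(self):
        f = uniform_field()
        np.testing.assert_array_equal(f.u_um_s, f.u * 1.75 / 0.015)

    @given(st.floats(1.0, 4.0), st.floats(-3.0, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_uniform_fields_never_flagged(self, u0, v0):
        out = validate_vectors(uniform_field(u0=u0, v0=v0))
        assert out.valid.all()


class TestInterrogationGrid:
    def test_windows_fit_inside_frame(self):
        g = InterrogationGrid.cover((128, 512), 48, 24)
        assert g.x[0] >= 24 and g.x[-1] <= 512 - 24
        assert g.y[0] >= 24 and g.y[-1] <= 128 - 24

    def test_final_pass_resolution_is_7_microns(self):
        # 4-px vector spacing at 1.75 µm/px
        g = InterrogationGrid.cover((128, 512), 16, 4)
        assert np.all(np.diff(g.x) == 4)
        assert 4 * 1.75 == pytest.approx(7.0)

    def test_spacing_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            InterrogationGrid.cover((128, 128), 16, 24)
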