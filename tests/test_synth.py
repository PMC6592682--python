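"""Synthetic-movie generator: seeding, advection, rendering, waveforms."""

import numpy as np
import pytest
from scipy.special import erf

from cardiopiv.flow import fundamental_harmonic_index
from cardiopiv.synth import (
    AcquisitionParams,
    FlowFieldSpec,
    ParticleCloud,
    advect,
    generate_sequence,
    make_particle_cloud,
    make_waveform,
    render_frame,
)

FOV = (0.0, 100.0, 0.0, 50.0)


class TestParticleCloud:
    def test_zero_density_gives_empty_cloud(self):
        assert len(make_particle_cloud(0.0, FOV, seed=1)) == 0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            make_particle_cloud(-0.1, FOV, seed=1)

    def test_same_seed_reproduces_cloud_exactly(self):
        a = make_particle_cloud(0.02, FOV, seed=7)
        b = make_particle_cloud(0.02, FOV, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.brightness, b.brightness)

    def test_count_is_poisson_with_mean_density_times_area(self):
        # oracle: mean of Poisson(d*A) over many seeds within 3 standard errors
        d, area = 0.01, (100.0 - 0.0) * (50.0 - 0.0)
        counts = [len(make_particle_cloud(d, FOV, seed=s)) for s in range(1000)]
        expect = d * area
        se = np.sqrt(expect / len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_positions_lie_in_fov_plus_margin(self):
        c = make_particle_cloud(0.05, FOV, seed=3, margin=10.0)
        assert c.positions[:, 0].min() >= -10.0 and c.positions[:, 0].max() <= 110.0
        assert c.positions[:, 1].min() >= 0.0 and c.positions[:, 1].max() <= 50.0


class TestAdvect:
    def test_uniform_flow_translates_exactly(self):
        flow = FlowFieldSpec.steady("uniform", 100.0, FOV)
        c = make_particle_cloud(0.02, (10, 90, 5, 45), seed=1)
        c2 = advect(c, flow, 0.0, 0.01)
        np.testing.assert_allclose(c2.positions[:, 0], c.positions[:, 0] + 1.0, atol=1e-9)
        np.testing.assert_allclose(c2.positions[:, 1], c.positions[:, 1], atol=1e-12)

    def test_zero_flow_leaves_positions_unchanged(self):
        flow = FlowFieldSpec.steady("uniform", 0.0, FOV)
        c = make_particle_cloud(0.02, FOV, seed=1)
        np.testing.assert_array_equal(advect(c, flow, 0.0, 0.5).positions, c.positions)

    def test_poiseuille_wall_and_centerline(self):
        flow = FlowFieldSpec.steady("poiseuille", 100.0, (0, 100, 10, 50))
        c = ParticleCloud([[50.0, 10.0], [50.0, 30.0]], 3.0, 1.0)
        c2 = advect(c, flow, 0.0, 0.01)
        assert c2.positions[0, 0] == pytest.approx(50.0)  # wall particle unmoved
        assert c2.positions[1, 0] == pytest.approx(51.0)  # centerline at peak speed

    def test_wrap_recycles_at_inflow_edge(self):
        flow = FlowFieldSpec.steady("uniform", 1000.0, FOV)
        c = ParticleCloud([[99.0, 25.0]], 3.0, 1.0)
        c2 = advect(c, flow, 0.0, 0.01, wrap=(-5.0, 105.0, 0.0, 50.0))
        assert -5.0 <= c2.positions[0, 0] < 0.0  # reinserted upstream

    def test_nonpositive_dt_rejected(self):
        flow = FlowFieldSpec.steady("uniform", 1.0, FOV)
        with pytest.raises(ValueError):
            advect(ParticleCloud([[1.0, 1.0]], 3.0, 1.0), flow, 0.0, 0.0)


class TestRenderFrame:
    ACQ = AcquisitionParams(image_shape=(64, 64), pixel_size=1.0, frame_interval=10.0,
                            n_frames=2, noise_sigma=0.0, background_level=5.0)

    def test_particle_at_pixel_center_peaks_there(self):
        c = ParticleCloud([[30.0, 20.0]], 3.0, 100.0)
        f = render_frame(c, self.ACQ)
        assert np.unravel_index(np.argmax(f), f.shape) == (20, 30)

    def test_empty_cloud_gives_flat_background(self):
        f = render_frame(make_particle_cloud(0.0, FOV, 1), self.ACQ)
        np.testing.assert_array_equal(f, np.full((64, 64), 5.0))

    def test_total_intensity_conserves_particle_mass(self):
        # oracle: the pixel-integrated Gaussian sums to erf-bounded mass; with
        # all particles well inside the frame, total (minus background) must
        # match the summed brightness to better than 1%
        c = make_particle_cloud(0.02, (10, 54, 10, 54), seed=5)
        f = render_frame(c, self.ACQ)
        total = (f - 5.0).sum()
        assert total == pytest.approx(c.brightness.sum(), rel=0.01)

    def test_single_spot_matches_erf_integration_oracle(self):
        c = ParticleCloud([[30.4, 20.7]], 3.0, 100.0)
        f = render_frame(c, self.ACQ) - 5.0
        sigma = 3.0 / 2.355
        xs = np.arange(64)

        def mass(centers, x0):
            a = erf((centers + 0.5 - x0) / (sigma * np.sqrt(2)))
            b = erf((centers - 0.5 - x0) / (sigma * np.sqrt(2)))
            return 0.5 * (a - b)

        expected = 100.0 * np.outer(mass(xs, 20.7), mass(xs, 30.4))
        # renderer truncates the stamp at ~4 sigma; tails are < 1e-6 units
        np.testing.assert_allclose(f, expected, atol=1e-6)

    def test_noise_is_seed_deterministic(self):
        acq = AcquisitionParams(image_shape=(32, 32), pixel_size=1.0, frame_interval=10.0,
                                n_frames=2, noise_sigma=2.0, background_level=10.0)
        c = make_particle_cloud(0.02, (0, 32, 0, 32), seed=2)
        np.testing.assert_array_equal(render_frame(c, acq, 9), render_frame(c, acq, 9))


class TestGenerateSequence:
    def test_rejects_span_shorter_than_two_periods(self):
        acq = AcquisitionParams(image_shape=(32, 64), pixel_size=1.0, frame_interval=10.0,
                                n_frames=30, noise_sigma=0.0)
        flow = FlowFieldSpec.pulsatile(100.0, 50.0, period=1.0, lumen=(0, 64, 4, 28))
        with pytest.raises(ValueError, match="period"):
            generate_sequence(flow, acq, 0.01, seed=1)

    def test_uniform_steady_flow_translates_consecutive_frames(self):
        # 2 px/frame exact translation; compare interior crops
        acq = AcquisitionParams(image_shape=(48, 96), pixel_size=1.0, frame_interval=10.0,
                                n_frames=4, noise_sigma=0.0, background_level=0.0)
        flow = FlowFieldSpec.steady("uniform", 200.0, (0, 96, 0, 48))
        rec = generate_sequence(flow, acq, 0.02, seed=8)
        a = rec.stack.frames[0][:, 10:70]
        b = rec.stack.frames[1][:, 12:72]
        # recycling only affects the margins; interior must match to float accuracy
        np.testing.assert_allclose(a, b, atol=1e-6 * max(1.0, a.max()))

    def test_zero_drift_oscillatory_flow_repeats_exactly_each_cycle(self):
        # pure oscillation (no mean flow): particle configurations, and hence
        # noise-free frames, are exactly periodic with the flow
        acq = AcquisitionParams(image_shape=(32, 64), pixel_size=1.0, frame_interval=10.0,
                                n_frames=45, noise_sigma=0.0, background_level=2.0)
        flow = FlowFieldSpec(kind="pulsatile_oscillatory", mean_speed=0.0, period=0.2,
                             lumen=(0, 64, 4, 28),
                             harmonics=(__import__("cardiopiv").synth.Harmonic(1, 150.0),))
        rec = generate_sequence(flow, acq, 0.02, seed=3, tissue=True)
        np.testing.assert_allclose(rec.stack.frames[0], rec.stack.frames[20], atol=1e-8)
        np.testing.assert_allclose(rec.stack.frames[7], rec.stack.frames[27], atol=1e-8)

    def test_oscillatory_flow_changes_sign_within_cycle(self):
        flow = FlowFieldSpec.from_retrograde_fraction(100.0, 0.4, 0.5, (0, 64, 4, 28))
        t = np.linspace(0, 0.5, 100, endpoint=False)
        w = flow.waveform(t)
        assert w.max() > 0 > w.min()
        assert flow.retrograde_fraction == pytest.approx(0.4, abs=0.02)

    def test_particle_count_stays_stationary(self):
        # recycling keeps per-frame rendered mass within 10% of its mean
        acq = AcquisitionParams(image_shape=(48, 96), pixel_size=1.0, frame_interval=10.0,
                                n_frames=120, noise_sigma=0.0, background_level=0.0)
        flow = FlowFieldSpec.pulsatile(300.0, 100.0, period=0.3, lumen=(0, 96, 8, 40))
        rec = generate_sequence(flow, acq, 0.02, seed=4, tissue=False)
        mass = rec.stack.frames.sum(axis=(1, 2))
        assert mass.std() / mass.mean() < 0.10

    def test_identical_seed_reproduces_stack_bitwise(self):
        acq = AcquisitionParams(image_shape=(32, 64), pixel_size=1.0, frame_interval=10.0,
                                n_frames=25, noise_sigma=1.0, background_level=5.0)
        flow = FlowFieldSpec.pulsatile(200.0, 100.0, period=0.1, lumen=(0, 64, 4, 28))
        a = generate_sequence(flow, acq, 0.02, seed=6)
        b = generate_sequence(flow, acq, 0.02, seed=6)
        np.testing.assert_array_equal(a.stack.frames, b.stack.frames)


class TestFlowFieldSpec:
    def test_field_is_zero_outside_lumen_and_finite_inside(self):
        flow = FlowFieldSpec.pulsatile(200.0, 100.0, 0.4, (10, 90, 20, 40))
        pts = np.array([[50.0, 30.0], [50.0, 10.0], [5.0, 30.0], [50.0, 45.0]])
        v = flow.evaluate(pts, 0.1)
        assert np.all(np.isfinite(v))
        assert v[0, 0] != 0.0
        np.testing.assert_array_equal(v[1:], 0.0)

    def test_field_is_exactly_periodic(self):
        flow = FlowFieldSpec.pulsatile(200.0, 300.0, 0.37, (0, 100, 0, 50))
        pts = np.array([[30.0, 25.0], [60.0, 10.0]])
        np.testing.assert_allclose(
            flow.evaluate(pts, 0.123), flow.evaluate(pts, 0.123 + 0.37), atol=1e-9
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FlowFieldSpec(kind="vortex", mean_speed=1.0, period=1.0, lumen=(0, 1, 0, 1))
        with pytest.raises(ValueError):
            FlowFieldSpec(kind="uniform", mean_speed=1.0, period=0.0, lumen=(0, 1, 0, 1))
        with pytest.raises(ValueError):
            FlowFieldSpec.from_retrograde_fraction(100.0, 0.7, 1.0, (0, 1, 0, 1))


class TestMakeWaveform:
    def test_control_waveform_never_reverses(self):
        prof = make_waveform("control", 2.0, 1.0, 64)
        assert prof.Q.min() == pytest.approx(1.0)
        assert prof.Q.min() > 0

    def test_ablated_waveform_reverses(self):
        prof = make_waveform("ablated", 1.0, 3.0, 64)
        assert prof.Q.min() == pytest.approx(-2.0)

    def test_analytic_fhi_is_amplitude_over_mean(self):
        for kind, m, a in (("control", 2.0, 1.0), ("ablated", 1.0, 3.0)):
            h = fundamental_harmonic_index(make_waveform(kind, m, a, 64))
            assert h.FHI == pytest.approx(a / m, abs=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_waveform("control", 1.0, 2.0, 64)
        with pytest.raises(ValueError):
            make_waveform("ablated", 2.0, 1.0, 64)
        with pytest.raises(ValueError):
            make_waveform("control", 2.0, 1.0, 3)
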