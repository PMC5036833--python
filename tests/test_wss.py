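import numpy as np
import pytest
from scipy.interpolate import CubicSpline

import cineshear as cs
from cineshear import ConfigurationError, OutOfDomainError, WallPointSample

from conftest import true_circle_mask


def _ellipse_contour(a, b, center, n=64):
    theta = 2 * np.pi * np.arange(n) / n
    v = np.column_stack([center[0] + a * np.cos(theta), center[1] + b * np.sin(theta)])
    return cs.LumenContour(vertices=v, source_spacing=0.2)


class TestInwardNormals:
    def test_circle_normals_point_at_center(self):
        contour = cs.circle_contour(2.8, (6.4, 6.4), 64, spacing=0.2)
        points, normals = cs.inward_normals(contour)
        to_center = (np.array([6.4, 6.4]) - points)
        to_center /= np.linalg.norm(to_center, axis=1, keepdims=True)
        angles = np.arccos(np.clip(np.sum(normals * to_center, axis=1), -1, 1))
        assert angles.max() < 1e-6

    def test_ellipse_normals_match_closed_form(self):
        """2:1 ellipse sampled at 64 vertices: normals within 1 degree of
        the analytic inward normal (b cos t, a sin t)-direction."""
        a, b = 4.0, 2.0
        contour = _ellipse_contour(a, b, (6.4, 6.4))
        points, normals = cs.inward_normals(contour)
        theta = 2 * np.pi * np.arange(64) / 64
        exact = -np.column_stack([b * np.cos(theta), a * np.sin(theta)])
        exact /= np.linalg.norm(exact, axis=1, keepdims=True)
        dots = np.abs(np.sum(normals * exact, axis=1))
        assert np.degrees(np.arccos(np.clip(dots, -1, 1))).max() < 1.0

    def test_square_corner_normal_bisects(self):
        """At a square's corner vertex the normal is the interior bisector."""
        side = np.linspace(0, 4, 17)[:-1]
        sq = np.concatenate([
            np.column_stack([side, np.zeros_like(side)]),
            np.column_stack([np.full_like(side, 4.0), side]),
            np.column_stack([4.0 - side, np.full_like(side, 4.0)]),
            np.column_stack([np.zeros_like(side), 4.0 - side]),
        ]) + 2.0
        contour = cs.LumenContour(vertices=sq, source_spacing=0.2)
        points, normals = cs.inward_normals(contour)
        corner = np.where((points == [2.0, 2.0]).all(axis=1))[0][0]
        bisector = np.array([1.0, 1.0]) / np.sqrt(2)
        assert np.allclose(normals[corner], bisector, atol=1e-9)

    def test_duplicate_vertices_rejected(self):
        contour = cs.circle_contour(2.8, (6.4, 6.4), 64, spacing=0.2)
        v = contour.vertices.copy()
        v[5] = v[4]
        bad = object.__new__(cs.LumenContour)
        object.__setattr__(bad, "vertices", v)
        object.__setattr__(bad, "source_spacing", 0.2)
        with pytest.raises(ConfigurationError):
            cs.inward_normals(bad)


class TestSampleNormalVelocities:
    def test_constant_field_sampled_exactly(self):
        v = np.zeros((2, 16, 16, 3))
        v[..., 2] = 0.37
        series = cs.CineVelocitySeries(
            velocities=v, magnitude=np.ones((2, 16, 16)), pixel_spacing=1.0, frame_duration=100.0
        )
        sample = cs.sample_normal_velocities(
            series, point=(8.0, 8.0), normal=(1.0, 0.0), offsets=(1.5, 3.0), frame=0
        )
        assert np.allclose(sample.velocities[1:, 2], 0.37)
        assert np.all(sample.velocities[0] == 0.0)

    def test_affine_field_reproduced_by_bilinear(self):
        n = 16
        x = (np.arange(n) + 0.5)
        xg, yg = np.meshgrid(x, x, indexing="xy")
        v = np.zeros((1, n, n, 3))
        v[0, :, :, 2] = 0.01 * xg - 0.004 * yg + 0.02
        series = cs.CineVelocitySeries(
            velocities=v, magnitude=np.ones((1, n, n)), pixel_spacing=1.0, frame_duration=100.0
        )
        normal = np.array([0.6, 0.8])
        sample = cs.sample_normal_velocities(series, (4.0, 9.0), normal, (1.5, 3.0), 0)
        for row, d in zip(sample.velocities[1:], (1.5, 3.0)):
            px, py = np.array([4.0, 9.0]) + d * normal
            assert row[2] == pytest.approx(0.01 * px - 0.004 * py + 0.02, rel=1e-12)

    def test_poiseuille_profile_sampled_within_1pct(self, cca_geometry):
        acq = cs.AcquisitionSpec(pixel_spacing=0.1, frame_duration=500.0, snr=None)
        series = cs.render_series(cca_geometry, cs.steady_waveform(2.5), acq)
        vmax = 2 * 2.5e-6 / (np.pi * 2.8e-3**2)
        sample = cs.sample_normal_velocities(
            series, point=(6.4 + 2.8, 6.4), normal=(-1.0, 0.0), offsets=(0.5, 1.0), frame=0
        )
        for row, d in zip(sample.velocities[1:], (0.5, 1.0)):
            r = 2.8 - d
            expected = vmax * (1 - (r / 2.8) ** 2)
            assert row[2] == pytest.approx(expected, rel=0.01)

    def test_outside_grid_rejected(self):
        v = np.zeros((1, 8, 8, 3))
        series = cs.CineVelocitySeries(
            velocities=v, magnitude=np.ones((1, 8, 8)), pixel_spacing=1.0, frame_duration=100.0
        )
        with pytest.raises(OutOfDomainError):
            cs.sample_normal_velocities(series, (7.0, 7.0), (1.0, 0.0), (1.5, 3.0), 0)


class TestWallShearRate:
    def test_linear_profile_recovered_exactly(self):
        g = 120.0  # 1/s
        d1, d2 = 1.5e-3, 3.0e-3
        sample = WallPointSample(
            position=np.zeros(2), normal=np.array([1.0, 0.0]), offsets=(1.5, 3.0),
            velocities=np.array([[0, 0, 0], [0, 0, g * d1], [0, 0, g * d2]]),
        )
        assert cs.wall_shear_rate(sample)[2] == pytest.approx(g, rel=1e-12)

    def test_quadratic_through_printed_example(self):
        """(0,0), (1.5, 3.0), (3.0, 4.0) in mm and mm/s: slope at wall 8/3 1/s."""
        sample = WallPointSample(
            position=np.zeros(2), normal=np.array([1.0, 0.0]), offsets=(1.5, 3.0),
            velocities=np.array([[0, 0, 0], [0, 0, 3.0e-3], [0, 0, 4.0e-3]]),
        )
        assert cs.wall_shear_rate(sample)[2] == pytest.approx(8.0 / 3.0, rel=1e-12)

    def test_matches_not_a_knot_cubic_spline(self):
        """The closed-form quadratic equals scipy's not-a-knot spline
        derivative on three knots (independent route)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            d1, d2 = np.sort(rng.uniform(0.5, 4.0, 2))
            if d2 - d1 < 1e-3:
                continue
            v = rng.normal(size=(2, 3))
            sample = WallPointSample(
                position=np.zeros(2), normal=np.array([1.0, 0.0]), offsets=(d1, d2),
                velocities=np.vstack([np.zeros(3), v]),
            )
            ours = cs.wall_shear_rate(sample)
            for c in range(3):
                spline = CubicSpline(
                    [0.0, d1 * 1e-3, d2 * 1e-3], [0.0, v[0, c], v[1, c]], bc_type="not-a-knot"
                )
                assert ours[c] == pytest.approx(float(spline(0.0, 1)), rel=1e-9, abs=1e-12)

    def test_non_monotone_offsets_rejected(self):
        with pytest.raises(ConfigurationError):
            WallPointSample(
                position=np.zeros(2), normal=np.array([1.0, 0.0]), offsets=(3.0, 1.5),
                velocities=np.zeros((3, 3)),
            )

    def test_coarse_samples_under_read_poiseuille_wall_shear(self, cca_geometry):
        """Quadratic through R/4, R/2 samples of the rendered parabola stays
        below the analytic 4Q/(pi R^3) but within 15%."""
        acq = cs.AcquisitionSpec(pixel_spacing=0.1, frame_duration=500.0, snr=None)
        series = cs.render_series(cca_geometry, cs.steady_waveform(2.5), acq)
        contour = cs.circle_contour(2.8, (6.4, 6.4), 64, spacing=0.1)
        field = cs.wss_field(series, contour, viscosity=1.0, offsets=(0.7, 1.4))
        wsr_mean = cs.mean_wss(field)[0]
        analytic = 4 * 2.5e-6 / (np.pi * 2.8e-3**3)
        assert wsr_mean < analytic
        assert wsr_mean == pytest.approx(analytic, rel=0.15)


class TestWSSField:
    def test_steady_poiseuille_wss_near_closed_form(self, cca_geometry):
        """tau = 4 mu Q / (pi R^3) ~ 0.145 Pa recovered within 15%."""
        acq = cs.AcquisitionSpec(pixel_spacing=0.1, frame_duration=500.0, snr=None)
        series = cs.render_series(cca_geometry, cs.steady_waveform(2.5), acq)
        contour = cs.circle_contour(2.8, (6.4, 6.4), 64, spacing=0.1)
        field = cs.wss_field(series, contour, viscosity=1e-3, offsets=(0.7, 1.4))
        scalar, _ = cs.mean_wss(field)
        assert scalar == pytest.approx(4e-3 * 2.5e-6 / (np.pi * 2.8e-3**3), rel=0.15)

    def test_zero_velocity_gives_zero_wss(self):
        v = np.zeros((3, 32, 32, 3))
        series = cs.CineVelocitySeries(
            velocities=v, magnitude=np.ones((3, 32, 32)), pixel_spacing=0.4, frame_duration=100.0
        )
        contour = cs.circle_contour(2.8, (6.4, 6.4), 64, spacing=0.4)
        field = cs.wss_field(series, contour)
        assert np.all(field.vectors == 0.0)

    def test_viscosity_linearity_exact(self, steady_series):
        contour = cs.circle_contour(2.8, (6.4, 6.4), 64, spacing=0.2)
        f1 = cs.wss_field(steady_series, contour, viscosity=1e-3)
        f2 = cs.wss_field(steady_series, contour, viscosity=2e-3)
        assert np.allclose(f2.vectors, 2.0 * f1.vectors, rtol=1e-12)

    def test_wss_is_tangential(self, fine_pulsatile_series):
        contour = cs.circle_contour(2.8, (6.4, 6.4), 64, spacing=0.2)
        field = cs.wss_field(fine_pulsatile_series, contour)
        n3 = np.column_stack([field.normals, np.zeros(field.n_points)])
        dots = np.einsum("pfc,pc->pf", field.vectors, n3)
        assert np.abs(dots).max() < 1e-15


class TestMeanWSS:
    def test_constant_field(self):
        field = cs.WSSField(
            vectors=np.tile([0.0, 0.0, 0.2], (8, 5, 1)), wall_points=np.zeros((8, 2)),
            normals=np.tile([1.0, 0.0], (8, 1)), frame_duration=100.0, viscosity=1e-3,
        )
        scalar, per_point = cs.mean_wss(field)
        assert scalar == pytest.approx(0.2)
        assert np.allclose(per_point, 0.2)

    def test_alternating_magnitudes_average(self):
        vectors = np.zeros((4, 6, 3))
        vectors[:, ::2, 2] = 0.1
        vectors[:, 1::2, 2] = 0.2
        field = cs.WSSField(
            vectors=vectors, wall_points=np.zeros((4, 2)),
            normals=np.tile([1.0, 0.0], (4, 1)), frame_duration=100.0, viscosity=1e-3,
        )
        scalar, per_point = cs.mean_wss(field)
        assert np.allclose(per_point, 0.15)
        assert scalar == pytest.approx(0.15)

    def test_mean_wss_decreases_with_coarser_spacing(self, cca_geometry, carotid_wave):
        """Partial volume flattens the near-wall profile: coarser grids
        under-read WSS (spatial-resolution dependence)."""
        values = []
        for spacing in (0.2, 0.5, 1.0):
            acq = cs.AcquisitionSpec(pixel_spacing=spacing, frame_duration=100.0, snr=None)
            series = cs.render_series(cca_geometry, carotid_wave, acq)
            contour = cs.circle_contour(2.8, (series.grid_shape[1] * spacing / 2,) * 2,
                                        64, spacing=spacing)
            values.append(cs.mean_wss(cs.wss_field(series, contour))[0])
        assert values[0] > values[1] > values[2]
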