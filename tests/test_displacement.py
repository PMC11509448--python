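"""Centre of velocity, flow displacement, rotational angle and gating."""

import numpy as np
import pytest

from aortaflow import (
    CardiacPhases,
    LumenMaskSeries,
    PhantomParams,
    center_of_velocity,
    displacement_trace,
    fd_averages,
    ground_truth_indices,
    render_phantom,
    rotational_angle_change,
)
from aortaflow.displacement import DisplacementTrace

from conftest import make_series


def disk_mask(n, c, radius_px):
    yy, xx = np.indices((n, n))
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def trace_from(v, mask, n_pad=4, spacing=1.0, phases=None):
    """Displacement trace of a single repeated frame."""
    v4 = np.stack([v] * n_pad)
    series = make_series(v4, spacing=(spacing, spacing))
    masks = LumenMaskSeries(np.stack([mask] * n_pad))
    phases = phases or CardiacPhases(0, 0, n_pad - 1, n_pad)
    return displacement_trace(series, masks, phases)


class TestCenterOfVelocity:
    def test_weighted_mean(self):
        v = np.zeros((1, 11))
        v[0, 0] = 30.0
        v[0, 10] = 10.0
        row, col = center_of_velocity(v, np.ones_like(v, dtype=bool))
        assert (row, col) == (0.0, pytest.approx(2.5))

    def test_uniform_plug_gives_mask_centroid(self):
        mask = disk_mask(21, 10, 7)
        v = np.where(mask, 50.0, 0.0)
        row, col = center_of_velocity(v, mask)
        assert (row, col) == (pytest.approx(10.0), pytest.approx(10.0))

    def test_antegrade_weighting_ignores_retrograde(self):
        v = np.zeros((3, 3))
        v[0, 0] = 10.0
        v[2, 2] = -40.0  # clamped to zero weight
        row, col = center_of_velocity(v, np.ones_like(v, dtype=bool))
        assert (row, col) == (0.0, 0.0)

    def test_no_antegrade_pixel_flagged(self):
        v = -np.ones((3, 3))
        with pytest.raises(ValueError, match="antegrade"):
            center_of_velocity(v, np.ones_like(v, dtype=bool))

    def test_fine_grid_gaussian_recovery(self):
        # Gaussian jet centred 4 mm off-centre, 0.2 mm grid: COV within 0.1 mm
        sp, R, sigma = 0.2, 15.0, 3.0
        n = 180
        y = (np.arange(n) + 0.5) * sp
        xg, yg = np.meshgrid(y, y)
        c = n * sp / 2
        mask = (xg - c) ** 2 + (yg - c) ** 2 <= R**2
        d2 = (xg - (c + 4.0)) ** 2 + (yg - c) ** 2
        v = np.where(mask, 150 * np.exp(-d2 / (2 * sigma**2)), 0.0)
        row, col = center_of_velocity(v, mask)
        # pixel index j has its centre at (j + 0.5) * sp
        assert (col + 0.5) * sp == pytest.approx(c + 4.0, abs=0.1)
        assert (row + 0.5) * sp == pytest.approx(c, abs=0.1)


class TestDisplacementTrace:
    def test_fd_and_angle_east(self):
        # lumen R = 10 mm, all weight 5 mm east of centre: FD 25%, RA 0
        mask = disk_mask(25, 12, 10)
        v = np.zeros((25, 25))
        v[12, 17] = 80.0
        t = trace_from(v, mask)
        assert t.fd_pct[0] == pytest.approx(25.0, abs=0.5)
        assert t.ra_deg[0] == pytest.approx(0.0, abs=1e-9)

    def test_angle_north_is_90(self):
        mask = disk_mask(25, 12, 10)
        v = np.zeros((25, 25))
        v[7, 12] = 80.0  # 5 mm up (-rows)
        t = trace_from(v, mask)
        assert t.ra_deg[0] == pytest.approx(90.0)

    def test_unwrap_across_180(self):
        # raw angles 170 then -170 must unwrap to 170, 190
        mask = disk_mask(41, 20, 15)
        v = np.zeros((4, 41, 41))
        for k, ang in enumerate([170.0, -170.0, -170.0, -170.0]):
            r = 10.0
            row = 20 - int(round(r * np.sin(np.radians(ang))))
            col = 20 + int(round(r * np.cos(np.radians(ang))))
            v[k, row, col] = 50.0
        series = make_series(v)
        masks = LumenMaskSeries(np.stack([mask] * 4))
        t = displacement_trace(series, masks, CardiacPhases(0, 0, 3, 4))
        assert t.ra_deg[0] == pytest.approx(170.0, abs=3)
        assert t.ra_deg[1] == pytest.approx(190.0, abs=3)

    def test_gate_flag_matches_threshold(self):
        mask = disk_mask(25, 12, 10)
        v = np.zeros((25, 25))
        v[12, 13] = 80.0  # 1 mm offset -> FD 5% -> gated
        t = trace_from(v, mask)
        assert t.gated[0]
        assert (t.fd_pct <= t.gate_pct).all() == t.gated.all()

    def test_fd_invariant_to_weight_scaling(self):
        mask = disk_mask(25, 12, 10)
        rng = np.random.default_rng(5)
        v = np.where(mask, rng.uniform(0, 100, (25, 25)), 0.0)
        t1 = trace_from(v, mask)
        t2 = trace_from(3.7 * v, mask)
        np.testing.assert_allclose(t1.fd_pct, t2.fd_pct, rtol=1e-12)
        np.testing.assert_allclose(t1.ra_deg, t2.ra_deg, rtol=1e-12)

    def test_fd_invariant_under_translation_and_rotation(self):
        mask = disk_mask(31, 12, 9)
        rng = np.random.default_rng(6)
        v = np.where(mask, rng.uniform(0, 100, (31, 31)), 0.0)
        base = trace_from(v, mask)
        shifted = trace_from(np.roll(v, (3, -2), (0, 1)),
                             np.roll(mask, (3, -2), (0, 1)))
        assert shifted.fd_pct[0] == pytest.approx(base.fd_pct[0], rel=1e-12)
        assert shifted.ra_deg[0] == pytest.approx(base.ra_deg[0], rel=1e-12)
        rot = trace_from(np.rot90(v), np.rot90(mask))
        assert rot.fd_pct[0] == pytest.approx(base.fd_pct[0], rel=1e-12)
        delta = (rot.ra_deg[0] - base.ra_deg[0]) % 360.0
        assert delta == pytest.approx(90.0, abs=1e-9)


class TestFdAverages:
    @staticmethod
    def _trace(frames, fd):
        n = len(frames)
        return DisplacementTrace(
            frames=np.asarray(frames),
            cov_px=np.zeros((n, 2)),
            centroid_px=np.zeros((n, 2)),
            d_eff_mm=np.full(n, 30.0),
            fd_pct=np.asarray(fd, dtype=float),
            ra_deg=np.zeros(n),
            gated=np.asarray(fd, dtype=float) <= 12.0,
        )

    def test_window_means(self):
        t = self._trace([1, 2, 3], [10.0, 20.0, 30.0])
        phases = CardiacPhases(onset=1, peak=2, end_sys=3, n_frames=5)
        fds, fdls = fd_averages(t, phases)
        assert (fds, fdls) == (pytest.approx(20.0), pytest.approx(25.0))

    def test_constant_fd(self):
        t = self._trace([0, 1, 2], [15.0, 15.0, 15.0])
        phases = CardiacPhases(onset=0, peak=1, end_sys=2, n_frames=4)
        assert fd_averages(t, phases) == (pytest.approx(15.0), pytest.approx(15.0))

    def test_no_gating_in_averages(self):
        # values below the gate still enter the averages
        t = self._trace([0, 1, 2], [5.0, 5.0, 35.0])
        phases = CardiacPhases(onset=0, peak=1, end_sys=2, n_frames=4)
        fds, _ = fd_averages(t, phases)
        assert fds == pytest.approx(15.0)


class TestRotationalAngle:
    @staticmethod
    def _trace(frames, ra, fd=None):
        n = len(frames)
        fd = np.full(n, 30.0) if fd is None else np.asarray(fd, dtype=float)
        return DisplacementTrace(
            frames=np.asarray(frames),
            cov_px=np.zeros((n, 2)),
            centroid_px=np.zeros((n, 2)),
            d_eff_mm=np.full(n, 30.0),
            fd_pct=fd,
            ra_deg=np.asarray(ra, dtype=float),
            gated=fd <= 12.0,
        )

    def test_stabilised_then_rotated(self):
        t = self._trace([2, 3, 4, 5, 6], [10.0, 30.0, 30.0, 30.0, 90.0])
        phases = CardiacPhases(onset=2, peak=2, end_sys=6, n_frames=8)
        delta, stab, fallback = rotational_angle_change(t, phases)
        assert delta == pytest.approx(60.0)
        assert stab == 3
        assert not fallback

    def test_constant_angle_zero_change(self):
        t = self._trace([2, 3, 4, 5], [45.0] * 4)
        phases = CardiacPhases(onset=2, peak=2, end_sys=5, n_frames=8)
        delta, _, fallback = rotational_angle_change(t, phases)
        assert delta == 0.0
        assert not fallback

    def test_sign_flips_with_reversed_rotation(self):
        phases = CardiacPhases(onset=2, peak=2, end_sys=6, n_frames=8)
        fwd = self._trace([2, 3, 4, 5, 6], [0.0, 30.0, 30.0, 60.0, 90.0])
        rev = self._trace([2, 3, 4, 5, 6], [0.0, -30.0, -30.0, -60.0, -90.0])
        d1, _, _ = rotational_angle_change(fwd, phases)
        d2, _, _ = rotational_angle_change(rev, phases)
        assert d1 == -d2 != 0

    def test_no_stabilisation_falls_back_with_flag(self):
        t = self._trace([2, 3, 4, 5, 6], [0.0, 20.0, 60.0, 100.0, 140.0])
        phases = CardiacPhases(onset=2, peak=2, end_sys=6, n_frames=8)
        delta, stab, fallback = rotational_angle_change(t, phases)
        assert fallback
        assert stab == 3
        assert delta == pytest.approx(120.0)

    def test_fully_gated_window_raises(self):
        t = self._trace([2, 3, 4, 5], [0.0, 10.0, 20.0, 30.0], fd=[5.0] * 4)
        phases = CardiacPhases(onset=2, peak=2, end_sys=5, n_frames=8)
        with pytest.raises(ValueError, match="gate"):
            rotational_angle_change(t, phases)

    def test_gated_frames_excluded_from_search(self):
        # the gated 500-degree outlier would break stabilisation if included
        fd = [30.0, 5.0, 30.0, 30.0, 30.0, 30.0]
        t = self._trace(
            [2, 3, 4, 5, 6, 7], [30.0, 500.0, 30.0, 30.0, 30.0, 80.0], fd=fd
        )
        phases = CardiacPhases(onset=2, peak=2, end_sys=7, n_frames=9)
        delta, stab, fallback = rotational_angle_change(t, phases)
        assert stab == 4
        assert delta == pytest.approx(50.0)
        assert not fallback


class TestPhantomRecovery:
    def test_programmed_rotation_recovered(self):
        angles = np.full(20, 30.0)
        for k in range(20):
            if k > 4:
                angles[k] = 30.0 + 60.0 * min((k - 4) / 3.0, 1.0)
        params = PhantomParams(
            jet_offset_frac=0.25, jet_angle_deg=angles, noise_sd_cm_s=0.0
        )
        vel, masks = render_phantom(params, with_noise=False)
        from aortaflow import quantify_case

        rec = quantify_case(vel, masks)
        gt = ground_truth_indices(params)
        assert gt.delta_ra_deg == pytest.approx(60.0, abs=2.0)
        assert rec.delta_ra_deg == pytest.approx(gt.delta_ra_deg, abs=5.0)

    def test_offset_jet_fd_recovery(self, eccentric_phantom, eccentric_ground_truth):
        from aortaflow import quantify_case

        vel, masks = eccentric_phantom
        rec = quantify_case(vel, masks)
        assert rec.fds_avg_pct == pytest.approx(
            eccentric_ground_truth.fds_avg_pct, abs=0.5
        )
        assert rec.fds_avg_pct == pytest.approx(25.0, abs=3.0)
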