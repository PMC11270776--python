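"""Color-Doppler pipeline: segmentation, decoding, calibration, averaging."""

import numpy as np
import pytest

from aortaflow import cd, synthetic
from aortaflow.core import CrossSectionField, VesselContour
from aortaflow.errors import TrackingLostError
from aortaflow.segmentation import star_kalman_track


def disk_stack(n_frames, radius, size=96, center=None, noise=0.0, seed=0):
    """Anti-aliased bright disk on dark background."""
    rng = np.random.default_rng(seed)
    cy, cx = center or (size // 2, size // 2)
    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.hypot(yy - cy, xx - cx)
    im = np.clip(radius - rr + 0.5, 0.0, 1.0)
    stack = np.repeat(im[None], n_frames, axis=0)
    if noise:
        stack = stack + noise * rng.standard_normal(stack.shape)
    return stack


class TestStarKalman:
    def test_noiseless_disk_radius_within_one_pixel(self):
        contour = star_kalman_track(disk_stack(5, 20.0), (48, 48))
        assert np.all(np.abs(contour.radii - 20.0) < 1.0)

    @pytest.mark.parametrize("radius", [10.0, 15.0, 25.0])
    def test_area_error_below_five_percent(self, radius):
        contour = star_kalman_track(disk_stack(3, radius), (48, 48))
        mask = contour.mask(0, (96, 96))
        assert abs(mask.sum() - np.pi * radius**2) / (np.pi * radius**2) < 0.05

    def test_kalman_variance_not_above_raw_detections(self):
        stack = disk_stack(40, 20.0, noise=0.08, seed=3)
        contour, raw = star_kalman_track(stack, (48, 48), return_raw=True)
        # compare per-ray temporal variance, after the filter settles
        kalman_var = np.nanvar(contour.radii[10:], axis=0).mean()
        raw_var = np.nanvar(raw[10:], axis=0).mean()
        assert kalman_var <= raw_var

    def test_missing_edge_falls_back_to_prediction(self):
        stack = disk_stack(3, 20.0)
        # remove the edge along the +x ray in the last frame
        stack[2, 44:52, 48:] = 1.0
        contour = star_kalman_track(stack, (48, 48))
        ray0 = int(np.argmin(np.abs(contour.angles - 0.0)))
        assert contour.radii[2, ray0] == pytest.approx(contour.radii[1, ray0])

    def test_constant_image_loses_tracking(self):
        with pytest.raises(TrackingLostError):
            star_kalman_track(np.full((3, 64, 64), 0.5), (32, 32))

    def test_offcenter_seed_recenters(self):
        contour = star_kalman_track(disk_stack(8, 20.0), (42, 53))
        assert np.linalg.norm(contour.centers[-1] - (48, 48)) < 2.0


class TestContourSmoothing:
    def _contour(self, radii):
        n_frames, n_rays = radii.shape
        return VesselContour(centers=np.full((n_frames, 2), 48.0),
                             radii=radii,
                             angles=np.arange(n_rays) * 2 * np.pi / n_rays)

    def test_constant_radii_unchanged(self):
        c = self._contour(np.full((5, 8), 12.0))
        out = cd.smooth_contour_over_frames(c, sigma_frames=2.0)
        np.testing.assert_allclose(out.radii, 12.0)

    def test_infinite_sigma_gives_global_mean(self):
        c = self._contour(np.tile([[9.0], [10.0], [11.0]], (1, 8)))
        out = cd.smooth_contour_over_frames(c, sigma_frames=np.inf)
        np.testing.assert_allclose(out.radii, 10.0)

    def test_temporal_variance_never_increases(self, rng):
        c = self._contour(10 + rng.standard_normal((20, 8)))
        out = cd.smooth_contour_over_frames(c, sigma_frames=1.5)
        assert np.all(out.radii.var(axis=0) <= c.radii.var(axis=0) + 1e-12)

    def test_mean_radius_unit_conversion(self):
        c = self._contour(np.full((4, 8), 40.0))
        assert cd.mean_radius(c, 0.25e-3) == pytest.approx(10e-3)

    def test_empty_contour_rejected(self):
        with pytest.raises(ValueError):
            VesselContour(centers=np.zeros((0, 2)), radii=np.zeros((0, 8)),
                          angles=np.arange(8) * np.pi / 4)


class TestDecodeCalibrate:
    def test_noiseless_decode_matches_truth_within_half_quantum(self, truth_factory):
        truth = truth_factory(kind="parabolic", seed=11)
        seq = synthetic.make_cd_sequence(truth, pixel_spacing=truth.radius / 30)
        center = (seq.frames.shape[1] // 2,) * 2
        contour = cd.star_kalman_segment(seq, center)
        fields = cd.decode_colors(seq, contour)
        q = seq.color_scale.quantum
        for f, tf in zip(fields[:4], seq.truth_fields[:4]):
            check = f.valid & np.isfinite(tf)
            assert np.max(np.abs(f.v[check] - tf[check])) <= 0.5 * q + 1e-12

    def test_dropped_frame_filled_temporally(self, truth_factory):
        truth = truth_factory(kind="parabolic", seed=11)
        vpeak = truth.mean_velocity_peak
        seq = synthetic.make_cd_sequence(truth, dropout_threshold=0.08 * vpeak,
                                         n_cycles=1)
        empty = [i for i, fr in enumerate(seq.frames)
                 if np.all(fr == seq.background_color)]
        assert empty, "expected at least one fully dropped diastolic frame"
        center = (seq.frames.shape[1] // 2,) * 2
        contour = cd.star_kalman_segment(seq, center, coast_on_loss=True)
        fields = cd.decode_colors(seq, contour)
        f = fields[empty[0]]
        assert not f.valid.any()
        assert np.isfinite(f.v[f.mask]).all()

    def test_calibration_scale_and_shape(self, truth_factory, generic_pulse):
        truth = truth_factory(kind="parabolic")
        seq = synthetic.make_cd_sequence(truth, n_cycles=1)
        fields = [CrossSectionField(v=np.nan_to_num(tf) * 0.5,
                                    mask=np.isfinite(tf),
                                    pixel_spacing=seq.pixel_spacing)
                  for tf in seq.truth_fields]
        out, scale = cd.calibrate_to_absolute(fields, seq.timestamps,
                                              generic_pulse)
        # the CD-side cycle mean comes from ~15 frame samples, so the
        # factor matches 2 only to quadrature accuracy
        assert scale == pytest.approx(2.0, rel=2e-3)
        for a, b in zip(out, fields):
            np.testing.assert_array_equal(a.v, b.v * scale)

    def test_identity_calibration(self, truth_factory, generic_pulse):
        truth = truth_factory(kind="parabolic")
        seq = synthetic.make_cd_sequence(truth, n_cycles=1)
        fields = [CrossSectionField(v=np.nan_to_num(tf),
                                    mask=np.isfinite(tf),
                                    pixel_spacing=seq.pixel_spacing)
                  for tf in seq.truth_fields]
        _, scale = cd.calibrate_to_absolute(fields, seq.timestamps,
                                            generic_pulse)
        assert scale == pytest.approx(1.0, rel=2e-3)

    def test_end_to_end_with_dropout(self, truth_factory, generic_pulse):
        """Calibrated mean-velocity trace recovers truth under diastolic
        dropout at 10% of the peak velocity (error relative to peak)."""
        truth = truth_factory(kind="womersley", seed=3)
        vpeak = truth.mean_velocity_peak
        seq = synthetic.make_cd_sequence(truth, pixel_spacing=truth.radius / 40,
                                         dropout_threshold=0.1 * vpeak,
                                         n_cycles=3)
        center = (seq.frames.shape[1] // 2,) * 2
        contour = cd.smooth_contour_over_frames(
            cd.star_kalman_segment(seq, center, coast_on_loss=True))
        fields = cd.decode_colors(seq, contour)
        fields, _ = cd.calibrate_to_absolute(fields, seq.timestamps,
                                             generic_pulse)
        v_rec = np.array([f.mean_velocity() for f in fields])
        v_true = generic_pulse.q_at(seq.timestamps) / (np.pi * truth.radius**2)
        nrmse_peak = np.sqrt(np.mean((v_rec - v_true) ** 2)) / vpeak
        assert nrmse_peak < 0.10


class TestCycleAverage:
    def _fields(self, seq):
        return [CrossSectionField(v=np.nan_to_num(tf), mask=np.isfinite(tf),
                                  pixel_spacing=seq.pixel_spacing)
                for tf in seq.truth_fields]

    def test_two_cycles_average_to_one(self, generic_pulse):
        # two cycles whose frames sit at identical phases, away from bin
        # edges: averaging reproduces the single-cycle fields exactly
        period = generic_pulse.period
        n_per_cycle = 16
        timestamps = np.arange(2 * n_per_cycle) * period / n_per_cycle
        phases = np.mod(timestamps, period)
        yy, xx = np.mgrid[0:21, 0:21]
        mask = np.hypot(yy - 10, xx - 10) <= 8
        fields = [CrossSectionField(
            v=np.where(mask, float(generic_pulse.q_at(p)) * 1e3, 0.0),
            mask=mask, pixel_spacing=1e-3) for p in phases]
        out, _ = cd.cycle_average_fields(fields, timestamps, period)
        assert len(out) == n_per_cycle
        for i, f in enumerate(out):
            np.testing.assert_allclose(f.v, fields[i].v, atol=1e-9)

    def test_single_cycle_identity_and_full_bins(self, truth_factory,
                                                 generic_pulse):
        truth = truth_factory(kind="parabolic")
        seq = synthetic.make_cd_sequence(truth, n_cycles=1)
        fields = self._fields(seq)
        out, phases = cd.cycle_average_fields(fields, seq.timestamps,
                                              generic_pulse.period)
        assert len(out) == len(fields)
        assert np.all(np.diff(phases) > 0)
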