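"""Cross-sectional velocity extraction from color-Doppler frames.

The vessel is segmented over all frames with the star-Kalman tracker
(seeded by a manual point in one frame), the contour is smoothed by a
Gaussian-weighted average over frames, per-pixel relative velocities are
decoded by matching each in-contour pixel's color to the color scale,
missing pixels (diastolic dropout) are interpolated spatially then
temporally, and the relative velocities are converted to absolute ones by
matching the cycle-mean flow of the pulsed-wave Doppler pulse.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import griddata

from .core import CDFrameSequence, ColorScale, CrossSectionField, FlowPulse, VesselContour
from .errors import CalibrationError, NoCycleError, UndecodableFrameError
from .segmentation import star_kalman_track

__all__ = [
    "star_kalman_segment",
    "smooth_contour_over_frames",
    "mean_radius",
    "decode_colors",
    "calibrate_to_absolute",
    "cycle_average_fields",
    "extract_velocity_fields",
]


def signal_image(seq: CDFrameSequence) -> np.ndarray:
    """Scalar signal-presence image per frame: color distance to background."""
    return np.linalg.norm(seq.frames - seq.background_color, axis=-1)


def star_kalman_segment(seq: CDFrameSequence, init_center, n_rays: int = 32,
                        init_frame: int | str = "auto",
                        coast_on_loss: bool = False, **kwargs) -> VesselContour:
    """Segment the vessel over all frames from a seed point.

    ``init_frame="auto"`` starts tracking at the frame with the most
    Doppler signal (systole) and tracks forward and backward from there,
    mirroring a manual selection on a well-perfused frame.
    """
    signal = signal_image(seq)
    if init_frame == "auto":
        init_frame = int(np.argmax(signal.sum(axis=(1, 2))))
    if init_frame == 0:
        return star_kalman_track(signal, init_center, n_rays,
                                 coast_on_loss=coast_on_loss, **kwargs)
    fwd = star_kalman_track(signal[init_frame:], init_center, n_rays,
                            coast_on_loss=coast_on_loss, **kwargs)
    bwd = star_kalman_track(signal[init_frame::-1], init_center, n_rays,
                            coast_on_loss=coast_on_loss, **kwargs)
    centers = np.concatenate([bwd.centers[:0:-1], fwd.centers])
    radii = np.concatenate([bwd.radii[:0:-1], fwd.radii])
    return VesselContour(centers=centers, radii=radii, angles=fwd.angles)


def smooth_contour_over_frames(contour: VesselContour,
                               sigma_frames: float = np.inf) -> VesselContour:
    """Gaussian-weighted average of each ray's radius sequence over frames.

    ``sigma_frames=inf`` replaces every frame by the all-frame mean radius
    per ray (a rigid average contour).
    """
    if contour.n_frames < 2:
        return contour
    n = contour.n_frames
    if np.isinf(sigma_frames):
        radii = np.tile(contour.radii.mean(axis=0), (n, 1))
        centers = np.tile(contour.centers.mean(axis=0), (n, 1))
    else:
        f = np.arange(n)
        wmat = np.exp(-0.5 * ((f[:, None] - f[None, :]) / max(sigma_frames, 1e-9)) ** 2)
        wmat /= wmat.sum(axis=1, keepdims=True)
        radii = wmat @ contour.radii
        centers = wmat @ contour.centers
    return VesselContour(centers=centers, radii=radii, angles=contour.angles.copy())


def mean_radius(contour: VesselContour, pixel_spacing: float) -> float:
    """Average radius over frames and rays, in metres."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    return float(contour.radii.mean()) * pixel_spacing


def _fill_spatial(v: np.ndarray, known: np.ndarray, mask: np.ndarray,
                  wall_points: np.ndarray | None = None) -> np.ndarray:
    """2D linear interpolation of missing in-mask pixels from decoded ones.

    ``wall_points`` (m, 2) adds zero-velocity anchors on the vessel wall
    (no-slip), so dropout regions near the rim interpolate towards zero
    instead of extrapolating interior values outwards.
    """
    out = v.copy()
    missing = mask & ~known
    if not missing.any() or not known.any():
        return out
    pts = np.argwhere(known).astype(float)
    vals = v[known]
    if wall_points is not None and wall_points.size:
        pts = np.vstack([pts, wall_points])
        vals = np.concatenate([vals, np.zeros(wall_points.shape[0])])
    tgt = np.argwhere(missing)
    filled = griddata(pts, vals, tgt, method="linear")
    bad = np.isnan(filled)
    if bad.any():  # outside the convex hull of anchor points
        filled[bad] = griddata(pts, vals, tgt[bad], method="nearest")
    out[missing] = filled
    return out


def _wall_points(contour: VesselContour, frame: int, oversample: int = 4) -> np.ndarray:
    """(m, 2) row/col coordinates of the contour boundary for one frame."""
    ang = np.linspace(0.0, 2.0 * np.pi, oversample * contour.angles.size,
                      endpoint=False)
    ang_c = np.concatenate([contour.angles, [contour.angles[0] + 2 * np.pi]])
    rad_c = np.concatenate([contour.radii[frame], [contour.radii[frame, 0]]])
    r = np.interp(ang, ang_c, rad_c)
    cy, cx = contour.centers[frame]
    return np.column_stack([cy + r * np.sin(ang), cx + r * np.cos(ang)])


def decode_colors(seq: CDFrameSequence, contour: VesselContour,
                  match_tolerance: float | None = None) -> list[CrossSectionField]:
    """Decode per-pixel relative velocities by color-scale matching.

    Each in-contour pixel gets the velocity of the nearest color-scale
    entry if the Euclidean color distance is within ``match_tolerance``
    (default: half the scale's minimum inter-entry distance); other
    in-contour pixels are missing and filled by 2D linear interpolation,
    and frames with no decoded pixel at all are filled per-pixel by linear
    interpolation over time.  The validity mask records decoded (True)
    versus interpolated (False) pixels.
    """
    scale = seq.color_scale
    if match_tolerance is None:
        match_tolerance = 0.5 * scale.min_color_separation()
    n_frames = seq.frames.shape[0]
    shape = seq.frames.shape[1:3]

    v_stack = np.zeros((n_frames,) + shape)
    known_stack = np.zeros((n_frames,) + shape, dtype=bool)
    masks = [contour.mask(f, shape) for f in range(n_frames)]
    for f in range(n_frames):
        pix = seq.frames[f][masks[f]]  # (m, 3)
        d = np.linalg.norm(pix[:, None, :] - scale.colors[None, :, :], axis=2)
        nearest = np.argmin(d, axis=1)
        ok = d[np.arange(pix.shape[0]), nearest] <= match_tolerance
        vals = np.where(ok, scale.velocities[nearest], 0.0)
        v = np.zeros(shape)
        known = np.zeros(shape, dtype=bool)
        v[masks[f]] = vals
        known[masks[f]] = ok
        v_stack[f] = v
        known_stack[f] = known

    decoded_frames = np.flatnonzero(known_stack.any(axis=(1, 2)))
    if decoded_frames.size == 0:
        raise UndecodableFrameError("no frame decodes any pixel")

    thr = float(seq.dropout_threshold)

    def _bound_fills(v, known, mask):
        # undecoded in-lumen pixels are censored at the wall-filter level:
        # their true |v| is below the threshold, so bound the fill there
        if thr > 0:
            filled = mask & ~known
            v = np.where(filled, np.clip(v, -thr, thr), v)
        return v

    spatial = {g: _bound_fills(_fill_spatial(v_stack[g], known_stack[g], masks[g],
                                             _wall_points(contour, g)),
                               known_stack[g], masks[g])
               for g in decoded_frames}
    fields = []
    for f in range(n_frames):
        if known_stack[f].any():
            v = spatial[f]
        else:
            # temporal fill from the nearest frames that decoded pixels
            v = np.empty(shape)
            stack = np.stack([spatial[g] for g in decoded_frames])
            for (r, c) in np.argwhere(masks[f]):
                v[r, c] = np.interp(f, decoded_frames, stack[:, r, c])
            v = _bound_fills(v, known_stack[f], masks[f])
        v = np.where(masks[f], v, 0.0)
        fields.append(CrossSectionField(v=v, mask=masks[f],
                                        pixel_spacing=seq.pixel_spacing,
                                        valid=known_stack[f]))
    return fields


def calibrate_to_absolute(fields: list[CrossSectionField], timestamps: np.ndarray,
                          pwd_flow: FlowPulse,
                          statistic: str = "mean") -> tuple[list[CrossSectionField], float]:
    """Scale relative CD velocities to absolute ones via the PWD flow.

    A single global factor s* matches the cycle-mean (default) or peak
    CD-derived flow to the PWD flow; returns the scaled fields and s*.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps[-1] - timestamps[0] < pwd_flow.period * (1 - 1.0 / timestamps.size):
        raise ValueError("timestamps must span at least one cardiac cycle")
    cd_flow = np.array([f.flow() for f in fields])
    if statistic == "mean":
        # cycle-mean of the CD flow by periodic trapezoid over the cycle
        # phase (the frames are not phase-locked to the heartbeat, so a
        # plain frame average is biased at coarse CD frame rates)
        phase = np.sort(np.mod(timestamps - timestamps[0], pwd_flow.period))
        order = np.argsort(np.mod(timestamps - timestamps[0], pwd_flow.period))
        qp = cd_flow[order]
        phase_c = np.concatenate([phase, [phase[0] + pwd_flow.period]])
        qp_c = np.concatenate([qp, [qp[0]]])
        ref = pwd_flow.mean()
        got = float(np.trapezoid(qp_c, phase_c) / pwd_flow.period)
    elif statistic == "peak":
        ref, got = float(np.max(pwd_flow.q)), float(np.max(cd_flow))
    else:
        raise ValueError("statistic must be 'mean' or 'peak'")
    if got == 0:
        raise CalibrationError("CD-derived flow statistic is zero")
    s = ref / got
    scaled = [CrossSectionField(v=f.v * s, mask=f.mask.copy(),
                                pixel_spacing=f.pixel_spacing,
                                valid=f.valid.copy()) for f in fields]
    return scaled, s


def cycle_average_fields(fields: list[CrossSectionField], timestamps: np.ndarray,
                         period: float) -> tuple[list[CrossSectionField], np.ndarray]:
    """Group frames by cycle phase and average point-wise per phase bin.

    The number of phase bins matches the frame rate over one period, so
    every bin receives at least one frame for uniform timestamps.
    Returns (per-phase fields, mean member phase time per bin).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps[-1] - timestamps[0] < period * (1 - 2.0 / timestamps.size):
        raise NoCycleError("need at least one full cycle of frames")
    dt = float(np.median(np.diff(timestamps)))
    n_bins = max(int(np.ceil(period / dt - 1e-9)), 1)
    phase = np.mod(timestamps - timestamps[0], period) / period
    # the epsilon keeps frames that sit exactly on a bin edge (frame grid
    # commensurate with the cycle) from splitting on floating-point error
    bins = np.floor(phase * n_bins + 1e-7).astype(int) % n_bins
    out, centers = [], []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if members.size == 0:
            continue
        v = np.mean([fields[i].v for i in members], axis=0)
        mask = fields[members[0]].mask
        valid = np.logical_and.reduce([fields[i].valid for i in members])
        out.append(CrossSectionField(v=np.where(mask, v, 0.0), mask=mask.copy(),
                                     pixel_spacing=fields[members[0]].pixel_spacing,
                                     valid=valid))
        centers.append(float(np.mean(phase[members])) * period)
    return out, np.asarray(centers)


def extract_velocity_fields(seq: CDFrameSequence, init_center, pwd_flow: FlowPulse,
                            n_rays: int = 32, sigma_frames: float = np.inf,
                            dropout_expected: bool = True):
    """Full CD pipeline: segment, smooth, decode, calibrate, cycle-average."""
    contour = star_kalman_segment(seq, init_center, n_rays,
                                  coast_on_loss=dropout_expected)
    contour = smooth_contour_over_frames(contour, sigma_frames)
    fields = decode_colors(seq, contour)
    fields, scale = calibrate_to_absolute(fields, seq.timestamps, pwd_flow)
    averaged, phase_times = cycle_average_fields(fields, seq.timestamps,
                                                 pwd_flow.period)
    return averaged, phase_times, contour, scale
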