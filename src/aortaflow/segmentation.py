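"""Star-Kalman vessel-contour tracking.

From a seed point inside the lumen, the boundary is located along N
uniformly spaced radial rays ("star") as the strongest outward intensity
drop within a gated window, and each ray's radius is tracked across frames
by a scalar Kalman filter with a constant-radius process model.  The
center is updated each frame to the centroid of the detected boundary
points, so the contour stays closed and star-shaped by construction.

The tracker expects images that are bright inside the vessel and darker
outside (color-Doppler signal presence, or the complement of an FFE
magnitude image).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .core import VesselContour
from .errors import TrackingLostError

__all__ = ["star_kalman_track"]

_RAY_STEP = 0.5  # px sampling step along each ray


def _ray_profiles(image: np.ndarray, center: np.ndarray, angles: np.ndarray,
                  r_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear intensity samples along every ray; returns (radii, profiles)."""
    radii = np.arange(0.0, r_max, _RAY_STEP)
    rows = center[0] + radii[None, :] * np.sin(angles)[:, None]
    cols = center[1] + radii[None, :] * np.cos(angles)[:, None]
    prof = map_coordinates(image, [rows.ravel(), cols.ravel()], order=1,
                           mode="nearest").reshape(rows.shape)
    return radii, prof


def _edge_along_ray(radii: np.ndarray, profile: np.ndarray,
                    lo: float, hi: float, min_strength: float) -> float | None:
    """Sub-pixel radius of the strongest outward intensity drop in [lo, hi]."""
    grad = -np.gradient(profile, _RAY_STEP)
    window = (radii >= lo) & (radii <= hi)
    if not window.any():
        return None
    idx = np.flatnonzero(window)
    k = idx[np.argmax(grad[idx])]
    if grad[k] <= min_strength:
        return None
    # parabolic refinement around the gradient peak
    if 0 < k < radii.size - 1:
        denom = grad[k - 1] - 2.0 * grad[k] + grad[k + 1]
        if denom < 0:
            k_frac = 0.5 * (grad[k - 1] - grad[k + 1]) / denom
            return float(radii[k] + np.clip(k_frac, -1.0, 1.0) * _RAY_STEP)
    return float(radii[k])


def star_kalman_track(images, init_center, n_rays: int = 32,
                      gate: float = 5.0, process_var: float = 0.1,
                      meas_var: float = 1.0, edge_fraction: float = 0.1,
                      coast_on_loss: bool = False,
                      return_raw: bool = False):
    """Track a star-shaped contour through a stack of 2D images.

    Parameters
    ----------
    images : (n_frames, H, W) array
        Bright-inside intensity images.
    init_center : (row, col)
        Seed point inside the vessel in the first frame.
    gate : float
        Half-width (px) of the search window around the Kalman prediction.
    edge_fraction : float
        Minimum edge strength as a fraction of the frame intensity range.
    coast_on_loss : bool
        If a frame loses the edge on more than half its rays, hold the
        Kalman prediction for that frame instead of raising
        :class:`~aortaflow.errors.TrackingLostError`.
    return_raw : bool
        Also return the raw per-frame edge detections (NaN where missing).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ValueError("images must be a (n_frames, H, W) stack")
    if n_rays < 8:
        raise ValueError("n_rays must be >= 8")
    center = np.asarray(init_center, dtype=float)
    h, w = images.shape[1:]
    if not (0 <= center[0] < h and 0 <= center[1] < w):
        raise ValueError("init_center must lie inside the image")
    angles = np.arange(n_rays) * (2.0 * np.pi / n_rays)
    r_max = min(center[0], center[1], h - 1 - center[0], w - 1 - center[1])
    if r_max < 3:
        raise ValueError("init_center too close to the image border")

    state = np.full(n_rays, np.nan)
    var = np.full(n_rays, meas_var)
    centers = np.zeros((images.shape[0], 2))
    radii_out = np.zeros((images.shape[0], n_rays))
    raw = np.full((images.shape[0], n_rays), np.nan)

    for f in range(images.shape[0]):
        im = images[f]
        min_strength = edge_fraction * (im.max() - im.min()) + 1e-12
        rad, prof = _ray_profiles(im, center, angles, r_max)
        missing = 0
        for i in range(n_rays):
            if np.isnan(state[i]):
                lo, hi = 1.0, rad[-1]
            else:
                var[i] += process_var
                lo, hi = state[i] - gate, state[i] + gate
            z = _edge_along_ray(rad, prof[i], lo, hi, min_strength)
            raw[f, i] = np.nan if z is None else z
            if z is None:
                missing += 1
                continue
            if np.isnan(state[i]):
                state[i], var[i] = z, meas_var
            else:
                k_gain = var[i] / (var[i] + meas_var)
                state[i] += k_gain * (z - state[i])
                var[i] *= 1.0 - k_gain

        if missing > 0.5 * n_rays or np.isnan(state).any():
            if not coast_on_loss or np.isnan(state).any():
                raise TrackingLostError(
                    f"frame {f}: no edge on {missing}/{n_rays} rays")
        else:
            # damped recentering to the boundary-point centroid
            offs = np.column_stack([state * np.sin(angles), state * np.cos(angles)])
            center = center + 0.5 * offs.mean(axis=0)

        radii_out[f] = state
        centers[f] = center

    contour = VesselContour(centers=centers, radii=radii_out, angles=angles)
    return (contour, raw) if return_raw else contour
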