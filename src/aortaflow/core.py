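"""Core data containers shared by all modalities.

Units are SI throughout: seconds, metres, m/s, m^3/s, Pa.  The central
exchange object is :class:`FlowPulse`, a single-cycle volumetric flow
waveform; every modality reduces to one, and all downstream analysis
(characterization, generic profiles, hemodynamics) starts from one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlowPulse",
    "VelocityTrace",
    "PWDSpectrogram",
    "ColorScale",
    "CDFrameSequence",
    "QFlowSeries",
    "VesselContour",
    "CrossSectionField",
    "align_to_reference",
]


@dataclass
class FlowPulse:
    """One-cycle volumetric flow waveform Q(t).

    ``times`` start at 0 and stay below ``period``; the waveform is
    periodic with period ``period`` (seconds).  ``q`` is in m^3/s.
    """

    times: np.ndarray
    q: np.ndarray
    period: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.times.shape != self.q.shape:
            raise ValueError("times and q must have the same length")
        if self.times.ndim != 1 or self.times.size < 4:
            raise ValueError("a flow pulse needs at least 4 samples")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.times[0] != 0 or self.times[-1] > self.period + 1e-12:
            raise ValueError("times must start at 0 and stay within one period")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("flow values must be finite")

    @property
    def heart_rate(self) -> float:
        """Heart rate in beats per minute."""
        return 60.0 / self.period

    def q_at(self, t) -> np.ndarray:
        """Periodic linear interpolation of Q at arbitrary times."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period)
        tt = np.concatenate([self.times, [self.times[0] + self.period]])
        qq = np.concatenate([self.q, [self.q[0]]])
        return np.interp(phase, tt, qq)

    def mean(self) -> float:
        """Cycle-mean flow (periodic trapezoid)."""
        tt = np.concatenate([self.times, [self.times[0] + self.period]])
        qq = np.concatenate([self.q, [self.q[0]]])
        return float(np.trapezoid(qq, tt) / self.period)

    def resample(self, n: int) -> "FlowPulse":
        """Resample onto a uniform n-point grid over one period."""
        t = np.arange(n) * (self.period / n)
        return FlowPulse(times=t, q=self.q_at(t), period=self.period)

    def scaled(self, factor: float) -> "FlowPulse":
        return FlowPulse(times=self.times.copy(), q=self.q * factor, period=self.period)

    def rotated(self, t0: float) -> "FlowPulse":
        """Cyclically rotate so that the sample at phase ``t0`` becomes t=0."""
        n = self.times.size
        t = np.arange(n) * (self.period / n)
        return FlowPulse(times=t, q=self.q_at(t + t0), period=self.period)


@dataclass
class VelocityTrace:
    """Mean cross-sectional velocity v(t) in m/s (Q = v * pi * r^2)."""

    times: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.times.shape != self.v.shape:
            raise ValueError("times and v must have the same length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PWDSpectrogram:
    """Pulsed-wave Doppler spectrogram: intensity over (velocity bin, time)."""

    times: np.ndarray          # (n_times,), s, strictly increasing
    v_bin_centers: np.ndarray  # (n_bins,), m/s, strictly monotone
    intensity: np.ndarray      # (n_bins, n_times), >= 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.v_bin_centers = np.asarray(self.v_bin_centers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.v_bin_centers.size, self.times.size):
            raise ValueError("intensity must be (n_bins, n_times)")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        d = np.diff(self.v_bin_centers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("velocity bins must be strictly monotone")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if not np.any(self.intensity.sum(axis=0) > 0):
            raise ValueError("spectrogram has no column with positive intensity")


@dataclass
class ColorScale:
    """Ordered (color, velocity) pairs; velocities strictly monotone.

    Stored explicitly so decoding never depends on a named colormap.
    """

    colors: np.ndarray      # (n, 3) in [0, 1]
    velocities: np.ndarray  # (n,) m/s

    def __post_init__(self):
        self.colors = np.asarray(self.colors, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.colors.shape != (self.velocities.size, 3):
            raise ValueError("colors must be (n, 3)")
        if self.velocities.size < 16:
            raise ValueError("a color scale needs at least 16 entries")
        if not np.all(np.diff(self.velocities) > 0):
            raise ValueError("scale velocities must be strictly increasing")

    @property
    def quantum(self) -> float:
        """Largest velocity step between adjacent scale entries."""
        return float(np.max(np.diff(self.velocities)))

    def min_color_separation(self) -> float:
        from scipy.spatial.distance import pdist

        return float(np.min(pdist(self.colors)))

    def encode(self, v: np.ndarray) -> np.ndarray:
        """Index of the nearest scale entry for each velocity."""
        v = np.asarray(v, dtype=float)
        idx = np.searchsorted(self.velocities, v)
        idx = np.clip(idx, 1, self.velocities.size - 1)
        left = self.velocities[idx - 1]
        right = self.velocities[idx]
        idx = np.where(np.abs(v - left) <= np.abs(right - v), idx - 1, idx)
        return idx

    @classmethod
    def symmetric(cls, vmax: float, n_levels: int = 64) -> "ColorScale":
        """Two-branch scale: blue family for reverse, red family for forward."""
        if n_levels < 16 or n_levels % 2:
            raise ValueError("n_levels must be even and >= 16")
        if vmax <= 0:
            raise ValueError("vmax must be positive")
        velocities = np.linspace(-vmax, vmax, n_levels)
        colors = np.zeros((n_levels, 3))
        mag = np.abs(velocities) / vmax
        neg = velocities < 0
        colors[neg, 2] = 1.0
        colors[neg, 1] = mag[neg]
        colors[~neg, 0] = 1.0
        colors[~neg, 1] = mag[~neg]
        return cls(colors=colors, velocities=velocities)


@dataclass
class CDFrameSequence:
    """Color-Doppler frame stack with its calibration metadata.

    ``frames`` are RGB images (n_frames, H, W, 3); pixels matching
    ``background_color`` carry no Doppler signal.  For synthetic data the
    generating velocity grids are kept in ``truth_fields`` (n_frames, H, W)
    with NaN outside the lumen.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_spacing: float
    color_scale: ColorScale
    background_color: np.ndarray = field(default_factory=lambda: np.zeros(3))
    truth_fields: np.ndarray | None = None
    #: wall-filter/write-priority level: in-lumen pixels with |v| below this
    #: carry no color (0 = none); known scanner setting, used to bound fills
    dropout_threshold: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.background_color = np.asarray(self.background_color, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[3] != 3:
            raise ValueError("frames must be (n_frames, H, W, 3)")
        if self.frames.shape[0] != self.timestamps.size:
            raise ValueError("one timestamp per frame required")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass
class QFlowSeries:
    """Paired FFE magnitude / PCA phase images over one cardiac cycle.

    ``pca`` stores the signed phase fraction in [-1, 1]; velocity is
    phase fraction times ``venc``.
    """

    ffe: np.ndarray   # (n_frames, H, W) magnitude
    pca: np.ndarray   # (n_frames, H, W) phase fraction
    venc: float       # m/s
    pixel_spacing: float  # m
    period: float     # s

    def __post_init__(self):
        self.ffe = np.asarray(self.ffe, dtype=float)
        self.pca = np.asarray(self.pca, dtype=float)
        if self.ffe.shape != self.pca.shape or self.ffe.ndim != 3:
            raise ValueError("ffe and pca must be matching (n_frames, H, W) stacks")
        if self.ffe.shape[0] < 8:
            raise ValueError("need at least 8 frames over the cycle")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.pixel_spacing <= 0 or self.period <= 0:
            raise ValueError("pixel_spacing and period must be positive")

    @property
    def n_frames(self) -> int:
        return self.ffe.shape[0]


@dataclass
class VesselContour:
    """Star-shaped contour per frame: a center plus one radius per ray."""

    centers: np.ndarray  # (n_frames, 2) as (row, col) pixel coords
    radii: np.ndarray    # (n_frames, n_rays) pixels
    angles: np.ndarray   # (n_rays,) radians, uniformly spaced

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.radii.ndim != 2 or self.radii.shape[0] != self.centers.shape[0]:
            raise ValueError("radii must be (n_frames, n_rays)")
        if self.radii.shape[1] != self.angles.size:
            raise ValueError("one angle per ray required")
        if self.radii.size == 0:
            raise ValueError("empty contour")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    @property
    def n_frames(self) -> int:
        return self.radii.shape[0]

    def mask(self, frame: int, shape: tuple[int, int]) -> np.ndarray:
        """Boolean lumen mask for one frame on an image of given shape."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        cy, cx = self.centers[frame]
        dy = rr - cy
        dx = cc - cx
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        # periodic interpolation of radius versus angle
        ang = np.concatenate([self.angles, [self.angles[0] + 2 * np.pi]])
        rad = np.concatenate([self.radii[frame], [self.radii[frame, 0]]])
        r_at = np.interp(theta, ang, rad)
        return np.hypot(dy, dx) <= r_at


@dataclass
class CrossSectionField:
    """Gridded through-plane velocity over the lumen.

    ``valid`` marks pixels decoded directly from data; interpolated fills
    are inside the mask but not valid.
    """

    v: np.ndarray             # (H, W) m/s, 0 outside mask
    mask: np.ndarray          # (H, W) bool lumen mask
    pixel_spacing: float      # m
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.v.shape != self.mask.shape:
            raise ValueError("v and mask shapes must match")
        if self.valid is None:
            self.valid = self.mask.copy()
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not np.all(np.isfinite(self.v[self.mask])):
            raise ValueError("velocities inside the mask must be finite")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def area(self) -> float:
        """Lumen area in m^2."""
        return float(self.mask.sum()) * self.pixel_spacing**2

    def mean_velocity(self) -> float:
        if not self.mask.any():
            raise ValueError("empty mask")
        return float(self.v[self.mask].mean())

    def flow(self) -> float:
        """Volumetric flow: sum of v times pixel area over the mask."""
        return float(self.v[self.mask].sum()) * self.pixel_spacing**2


def align_to_reference(pulse: FlowPulse, reference: FlowPulse, n: int = 512) -> FlowPulse:
    """Cyclically rotate ``pulse`` to best match ``reference``.

    The rotation maximizes the circular cross-correlation of the two
    waveforms on a common phase grid; used before waveform comparisons
    because the two cycles' trigger points (systolic foot within the
    late-diastolic zero-flow plateau) are arbitrary.
    """
    phase = np.arange(n) / n
    a = pulse.q_at(phase * pulse.period)
    b = reference.q_at(phase * reference.period)
    # corr[s] = sum_j b[j] * a[j + s]; best s advances `pulse` onto `reference`
    corr = np.fft.irfft(np.conj(np.fft.rfft(b)) * np.fft.rfft(a), n)
    shift = int(np.argmax(corr))
    # parabolic sub-sample refinement of the correlation peak
    c0, c1, c2 = corr[(shift - 1) % n], corr[shift], corr[(shift + 1) % n]
    denom = c0 - 2 * c1 + c2
    frac = 0.5 * (c0 - c2) / denom if denom < 0 else 0.0
    t0 = (shift + float(np.clip(frac, -1, 1))) / n * pulse.period
    q = pulse.q_at(phase * pulse.period + t0)
    return FlowPulse(times=phase * reference.period, q=q, period=reference.period)
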