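"""Ground-truthed synthetic inputs for every pipeline stage.

Emulates the three acquisition modalities at the statistical level of the
study conditions:

* pulsed-wave Doppler: a time-velocity intensity spectrogram whose per-column
  ridge is a Gaussian around the true mean velocity, with spectral broadening,
  an additive noise floor, and per-cycle period jitter (frame rates of tens
  of Hz);
* color Doppler: indexed-color frames of a circular lumen with an explicit
  (color, velocity) scale and diastolic signal dropout below a velocity
  threshold (frame rates ~7-23 Hz, ~0.2 mm pixels);
* Q-flow MRI: paired FFE-like magnitude (dark lumen on bright background)
  and PCA-like signed phase-fraction images with VENC encoding
  (~30 frames/cycle, ~1 mm pixels).

No ultrasound physics (beamforming, speckle) and no scanner file formats
are modelled.  All randomness flows from explicit seeds; identical inputs
reproduce identical outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CDFrameSequence, ColorScale, FlowPulse, PWDSpectrogram, QFlowSeries
from . import profiles as _profiles
from .waveforms import triphasic_pulse

__all__ = [
    "TruthRecord",
    "make_triphasic_pulse",
    "make_pwd_spectrogram",
    "make_cd_sequence",
    "make_qflow_series",
]

PROFILE_KINDS = ("womersley", "parabolic", "plug", "power_law")


@dataclass
class TruthRecord:
    """Ground truth shared by the synthetic generators.

    ``noise_level`` is dimensionless: the amplitude of additive disturbances
    relative to the signal scale of each modality (spectrogram ridge peak for
    PWD, peak velocity for CD pixel noise).
    """

    flow_pulse: FlowPulse
    radius: float
    profile_kind: str = "womersley"
    seed: int = 0
    noise_level: float = 0.0
    power_exponent: float = 9.0
    n_harmonics: int = 16
    _womersley: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.flow_pulse.period <= 0:
            raise ValueError("flow pulse period must be positive")
        if self.profile_kind not in PROFILE_KINDS:
            raise ValueError(f"profile_kind must be one of {PROFILE_KINDS}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @property
    def mean_velocity_peak(self) -> float:
        """Peak of the mean cross-sectional velocity |Q|/(pi r^2)."""
        return float(np.max(np.abs(self.flow_pulse.q))) / (np.pi * self.radius**2)

    def mean_velocity(self, t) -> np.ndarray:
        """True mean cross-sectional velocity v(t) = Q(t)/(pi r^2)."""
        return self.flow_pulse.q_at(t) / (np.pi * self.radius**2)

    def velocity(self, radial_fraction, t) -> np.ndarray:
        """True through-plane velocity at radial fractions and times."""
        if self.profile_kind == "womersley":
            if self._womersley is None:
                object.__setattr__(self, "_womersley", _profiles.fit_womersley(
                    self.flow_pulse, self.radius, n_harmonics=self.n_harmonics))
            return _profiles.evaluate_womersley(self._womersley, radial_fraction, t)
        shape = _profiles.radial_shape(self.profile_kind, radial_fraction,
                                       self.power_exponent)
        return self.mean_velocity(t) * shape


def make_triphasic_pulse(peak_flow: float, reverse_fraction: float,
                         heart_rate: float, n_samples: int = 200,
                         seed: int = 0) -> FlowPulse:
    """Triphasic one-cycle flow pulse (see :mod:`aortaflow.waveforms`).

    ``seed`` is accepted for interface uniformity with the other
    generators; the template itself is deterministic.
    """
    del seed
    return triphasic_pulse(peak_flow, reverse_fraction, heart_rate, n_samples)


def _cycle_phases(times: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Phase fraction in [0, 1) of each time under jittered cycle periods."""
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0,
                  periods.size - 1)
    return (times - starts[idx]) / periods[idx]


def make_pwd_spectrogram(truth: TruthRecord, frame_rate: float = 50.0,
                         v_bins: int = 256, broadening_sd: float = 0.01,
                         n_cycles: int = 4, cycle_jitter_sd: float = 0.0,
                         v_range: tuple[float, float] | None = None) -> PWDSpectrogram:
    """Synthetic PWD spectrogram of ``n_cycles`` heartbeats.

    Each time column is a Gaussian ridge (sd ``broadening_sd``, m/s) centred
    on the true mean velocity, plus a uniform noise floor of amplitude
    ``truth.noise_level`` relative to the unit ridge peak.  The velocity
    axis spans the true range with >= 20% margin so the ridge never
    aliases; passing an explicit ``v_range`` that would clip the ridge
    raises ``ValueError``.
    """
    if frame_rate < 10:
        raise ValueError("frame_rate must be >= 10 Hz")
    if v_bins < 32:
        raise ValueError("v_bins must be >= 32")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if broadening_sd < 0 or cycle_jitter_sd < 0:
        raise ValueError("broadening_sd and cycle_jitter_sd must be >= 0")

    rng = np.random.default_rng(truth.seed)
    period = truth.flow_pulse.period
    periods = period + cycle_jitter_sd * rng.standard_normal(n_cycles)
    periods = np.clip(periods, 0.5 * period, 1.5 * period)
    total = float(np.sum(periods))
    times = np.arange(0.0, total, 1.0 / frame_rate)
    phases = _cycle_phases(times, periods)
    v_true = truth.mean_velocity(phases * period)

    v_lo, v_hi = float(np.min(v_true)), float(np.max(v_true))
    span = max(v_hi - v_lo, 1e-9)
    margin = max(0.2 * span, 3.0 * broadening_sd)
    if v_range is None:
        v_range = (v_lo - margin, v_hi + margin)
    elif v_range[0] > v_lo - 3.0 * broadening_sd or v_range[1] < v_hi + 3.0 * broadening_sd:
        raise ValueError("requested velocity axis would clip the spectral ridge")
    v_centers = np.linspace(v_range[0], v_range[1], v_bins)
    bin_width = v_centers[1] - v_centers[0]
    sd = max(broadening_sd, 0.25 * bin_width)  # keep the ridge resolvable

    ridge = np.exp(-0.5 * ((v_centers[:, None] - v_true[None, :]) / sd) ** 2)
    intensity = ridge + truth.noise_level * rng.random(ridge.shape)
    return PWDSpectrogram(times=times, v_bin_centers=v_centers, intensity=intensity)


def _disk_grid(radius: float, pixel_spacing: float, margin: float = 1.3):
    half = int(np.ceil(radius * margin / pixel_spacing))
    coords = (np.arange(2 * half + 1) - half) * pixel_spacing
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(yy, xx)
    return rr, rr <= radius


def make_cd_sequence(truth: TruthRecord, frame_rate: float = 15.0,
                     pixel_spacing: float = 0.2e-3,
                     color_scale: ColorScale | None = None,
                     dropout_threshold: float = 0.0,
                     n_cycles: int = 1) -> CDFrameSequence:
    """Synthetic color-Doppler frame sequence of a circular lumen.

    Pixel velocities follow the truth profile at each frame time, perturbed
    by Gaussian noise of sd ``truth.noise_level`` x peak velocity, then
    encoded by the nearest color-scale level.  Pixels with |v| below
    ``dropout_threshold`` are rendered as background, emulating diastolic
    signal loss.  The generating velocity grids are stored in
    ``truth_fields`` (NaN outside the lumen).
    """
    if dropout_threshold < 0:
        raise ValueError("dropout_threshold must be >= 0")
    rng = np.random.default_rng(truth.seed + 1)
    period = truth.flow_pulse.period
    times = np.arange(0.0, n_cycles * period - 1e-9, 1.0 / frame_rate)
    rr, mask = _disk_grid(truth.radius, pixel_spacing)
    s = np.clip(rr / truth.radius, 0.0, 1.0)

    fields = np.full((times.size,) + rr.shape, np.nan)
    for i, t in enumerate(times):
        v = np.asarray(truth.velocity(s, float(np.mod(t, period))), dtype=float)
        fields[i][mask] = v[mask]

    vmax_true = float(np.nanmax(np.abs(fields)))
    if color_scale is None:
        color_scale = ColorScale.symmetric(1.2 * max(vmax_true, 1e-6), 64)
    if (color_scale.velocities[0] > -vmax_true - 1e-12
            or color_scale.velocities[-1] < vmax_true - 1e-12):
        raise ValueError("color scale does not span the true velocity range")

    noise_sd = truth.noise_level * truth.mean_velocity_peak
    background = np.zeros(3)
    frames = np.zeros((times.size,) + rr.shape + (3,))
    for i in range(times.size):
        v = fields[i].copy()
        if noise_sd > 0:
            v[mask] += noise_sd * rng.standard_normal(int(mask.sum()))
        idx = color_scale.encode(np.nan_to_num(v))
        rgb = color_scale.colors[idx]
        visible = mask & (np.abs(np.nan_to_num(v)) >= dropout_threshold)
        frames[i] = np.where(visible[..., None], rgb, background[None, None, :])

    return CDFrameSequence(frames=frames, timestamps=times,
                           pixel_spacing=pixel_spacing, color_scale=color_scale,
                           background_color=background, truth_fields=fields,
                           dropout_threshold=dropout_threshold)


def make_qflow_series(truth: TruthRecord, n_frames: int = 30,
                      pixel_spacing: float = 1.0e-3,
                      venc: float | None = None, noise_sd: float = 0.0,
                      seed: int | None = None,
                      allow_aliasing: bool = False) -> QFlowSeries:
    """Synthetic Q-flow MRI series: FFE magnitude + PCA phase fraction.

    Phase encodes v/VENC directly in [-1, 1]; with ``allow_aliasing`` values
    outside that interval wrap around, mirroring VENC semantics.  The FFE
    lumen is dark on a bright background with an anti-aliased rim so the
    wall is sub-pixel localizable.
    """
    if n_frames < 8:
        raise ValueError("n_frames must be >= 8")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    period = truth.flow_pulse.period
    times = np.arange(n_frames) / n_frames * period
    rr, mask = _disk_grid(truth.radius, pixel_spacing)
    s = np.clip(rr / truth.radius, 0.0, 1.0)

    vmax_true = 0.0
    v_stack = np.zeros((n_frames,) + rr.shape)
    for i, t in enumerate(times):
        v = np.asarray(truth.velocity(s, float(t)), dtype=float)
        v = np.where(mask, v, 0.0)
        v_stack[i] = v
        vmax_true = max(vmax_true, float(np.max(np.abs(v))))

    if venc is None:
        venc = 1.2 * max(vmax_true, 1e-6)
    if venc <= 0:
        raise ValueError("venc must be positive")
    if not allow_aliasing and venc < vmax_true - 1e-12:
        raise ValueError("venc below the peak velocity would alias; "
                         "pass allow_aliasing=True to request it")

    pca = (v_stack + noise_sd * rng.standard_normal(v_stack.shape)) / venc
    if allow_aliasing:
        pca = np.mod(pca + 1.0, 2.0) - 1.0

    # anti-aliased dark disk: rim coverage fraction in [0, 1]
    coverage = np.clip((truth.radius - rr) / pixel_spacing + 0.5, 0.0, 1.0)
    ffe_frame = 1.0 - 0.8 * coverage
    ffe = np.repeat(ffe_frame[None], n_frames, axis=0)
    if truth.noise_level > 0:
        ffe = ffe + 0.05 * truth.noise_level * rng.standard_normal(ffe.shape)

    return QFlowSeries(ffe=ffe, pca=pca, venc=float(venc),
                       pixel_spacing=pixel_spacing, period=period)
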