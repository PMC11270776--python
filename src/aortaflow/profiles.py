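"""Generic cross-sectional velocity profiles.

Given a volumetric flow pulse Q(t) and a vessel radius R, this module
constructs the four generic axisymmetric profiles used as alternatives to
a measured velocity field:

* **plug** (flat):      u = Q / (pi R^2)
* **parabolic**:        u = 2 Q / (pi R^2) * (1 - s^2),  s = y/R
* **power law** (n):    u = Q / (pi R^2) * (n+2)/n * (1 - s^n)
* **Womersley**:        harmonic decomposition of Q(t) with the analytic
  oscillatory pipe-flow solution per harmonic.

All profiles integrate to Q(t) exactly (Womersley up to the truncated
harmonic series).  The Womersley solution for harmonic k with complex flow
amplitude Q_k uses the Bessel-function kernel

    u_k(s, t) = Re{ Q_k / (pi R^2) * [1 - J0(L s)/J0(L)] / D * e^{i k w t} },

with L = i^{3/2} alpha_k, alpha_k = R sqrt(k w rho / mu) the Womersley
number, and D = 1 - 2 J1(L) / (L J0(L)) the normalization making the
cross-sectional mean of the kernel equal one.  The steady component is
assigned the parabolic (Poiseuille) shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .core import CrossSectionField, FlowPulse
from .waveforms import triphasic_pulse

__all__ = [
    "WomersleyModel",
    "fit_womersley",
    "evaluate_womersley",
    "profile_from_flow",
    "radial_shape",
    "generic_flow_pulse",
    "BLOOD_DENSITY",
    "BLOOD_VISCOSITY",
]

BLOOD_DENSITY = 1060.0    # kg/m^3
BLOOD_VISCOSITY = 0.004   # Pa s (Newtonian reference value)


@dataclass
class WomersleyModel:
    """Harmonic decomposition of a flow pulse plus fluid constants.

    ``coeffs[k-1]`` is the complex amplitude of harmonic k, such that
    Q(t) = q_mean + sum_k Re{coeffs[k-1] e^{i k omega t}}.
    """

    radius: float
    density: float
    viscosity: float
    period: float
    q_mean: float
    coeffs: np.ndarray  # (n_harmonics,) complex

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.size

    def alpha(self, k: int = 1) -> float:
        """Womersley number of harmonic k: R sqrt(k omega rho / mu)."""
        return self.radius * np.sqrt(k * self.omega * self.density / self.viscosity)

    def reconstruct(self, t) -> np.ndarray:
        """Flow waveform implied by the stored harmonics."""
        t = np.asarray(t, dtype=float)
        q = np.full(t.shape, self.q_mean)
        for k in range(1, self.n_harmonics + 1):
            q = q + np.real(self.coeffs[k - 1] * np.exp(1j * k * self.omega * t))
        return q

    def wall_shear_stress(self, t) -> np.ndarray:
        """Signed wall shear stress tau_w(t) = -mu du/dy at y=R (Pa).

        Positive for forward flow; steady part is the Poiseuille value
        4 mu Q_mean / (pi R^3).
        """
        t = np.asarray(t, dtype=float)
        mu, r = self.viscosity, self.radius
        tau = np.full(t.shape, 4.0 * mu * self.q_mean / (np.pi * r**3))
        for k in range(1, self.n_harmonics + 1):
            lam = 1j**1.5 * self.alpha(k)
            d = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
            # du/dy at y=R of the normalized kernel: (lam/R) J1(lam)/(J0(lam) D)
            grad = (lam / r) * jv(1, lam) / (jv(0, lam) * d)
            amp = -mu * self.coeffs[k - 1] / (np.pi * r**2) * grad
            tau = tau + np.real(amp * np.exp(1j * k * self.omega * t))
        return tau


def fit_womersley(pulse: FlowPulse, radius: float,
                  density: float = BLOOD_DENSITY,
                  viscosity: float = BLOOD_VISCOSITY,
                  n_harmonics: int = 10) -> WomersleyModel:
    """Discrete Fourier decomposition of a flow pulse into mean + harmonics."""
    if density <= 0 or viscosity <= 0:
        raise ValueError("density and viscosity must be positive")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    dt = np.diff(pulse.times)
    uniform = np.allclose(dt, dt[0], rtol=1e-9) \
        and np.isclose(pulse.times[-1] + dt[0], pulse.period, rtol=1e-9)
    if uniform and pulse.q.size >= 4 * n_harmonics:
        q = pulse.q  # exact DFT on the native uniform grid
    else:
        q = pulse.resample(max(256, 8 * n_harmonics)).q
    n = q.size
    qhat = np.fft.fft(q) / n
    coeffs = 2.0 * qhat[1 : n_harmonics + 1]
    return WomersleyModel(radius=radius, density=density, viscosity=viscosity,
                          period=pulse.period, q_mean=float(qhat[0].real),
                          coeffs=coeffs)


def evaluate_womersley(model: WomersleyModel, radial_fraction, t) -> np.ndarray:
    """Axial velocity u(y/R, t) of the Womersley model (m/s).

    ``radial_fraction`` and ``t`` broadcast against each other; the no-slip
    wall gives u(1, t) = 0 for all t.
    """
    s = np.asarray(radial_fraction, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("radial_fraction must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    area = np.pi * model.radius**2
    u = 2.0 * model.q_mean / area * (1.0 - s**2) * np.ones_like(t)
    for k in range(1, model.n_harmonics + 1):
        lam = 1j**1.5 * model.alpha(k)
        d = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
        kernel = (1.0 - jv(0, lam * s) / jv(0, lam)) / d
        u = u + np.real(model.coeffs[k - 1] / area * kernel
                        * np.exp(1j * k * model.omega * t))
    return u


def radial_shape(kind: str, s, exponent: float = 2.0) -> np.ndarray:
    """Normalized radial profile shape (cross-sectional mean = 1)."""
    s = np.asarray(s, dtype=float)
    if kind == "plug":
        return np.ones_like(s)
    if kind == "parabolic":
        return 2.0 * (1.0 - s**2)
    if kind == "power_law":
        if exponent <= 0:
            raise ValueError("power-law exponent must be positive")
        return (exponent + 2.0) / exponent * (1.0 - s**exponent)
    raise ValueError(f"unknown profile kind: {kind!r}")


def profile_from_flow(kind: str, pulse: FlowPulse, radius: float, t: float,
                      pixel_spacing: float | None = None,
                      exponent: float = 2.0,
                      margin: float = 1.1) -> CrossSectionField:
    """Generic velocity field over a circular cross-section at time ``t``.

    ``kind`` is one of ``plug``, ``parabolic``, ``power_law``; the field
    integrates to Q(t) exactly (up to pixelization of the disk).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if pixel_spacing is None:
        pixel_spacing = radius / 24.0
    q_t = float(pulse.q_at(t))
    half = int(np.ceil(radius * margin / pixel_spacing))
    coords = (np.arange(2 * half + 1) - half) * pixel_spacing
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(yy, xx)
    mask = rr <= radius
    s = np.clip(rr / radius, 0.0, 1.0)
    u = np.zeros_like(rr)
    u[mask] = q_t / (np.pi * radius**2) * radial_shape(kind, s[mask], exponent)
    return CrossSectionField(v=u, mask=mask, pixel_spacing=pixel_spacing)


def generic_flow_pulse() -> FlowPulse:
    """Packaged generic abdominal-aortic flow pulse.

    Triphasic template pulse with a maximum flow of 5 L/min and a heart
    rate of 63.5 beats/min (the population-mean inlet conditions used when
    no patient-specific Doppler acquisition is available).
    """
    peak = 5.0 / 60000.0  # 5 L/min in m^3/s
    return triphasic_pulse(peak_flow=peak, reverse_fraction=0.25,
                           heart_rate=63.5, n_samples=200)
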