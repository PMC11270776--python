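"""Desk-scale wall-shear-stress and outlet-pressure surrogates.

Instead of a 3D finite-volume solve, wall shear stress is evaluated
analytically for a straight tube from the Womersley model, and the
standard cycle metrics are computed from the WSS time series:

    TAWSS = (1/T) int |WSS| dt
    OSI   = 1/2 (1 - |(1/T) int WSS dt| / ((1/T) int |WSS| dt))

OSI lies in [0, 0.5]: 0 where the WSS never changes sign, 0.5 where its
time mean vanishes.  The outlet is a 3-element Windkessel (characteristic
impedance Zc, peripheral resistance Rp, compliance C to a distal
reference pressure P_out):

    P(t) = Zc Q(t) + Pc(t),    C dPc/dt = Q(t) - (Pc - P_out)/Rp

integrated with classical RK4 over several cycles; metrics use the last
cycle, after the transient.  Blood shear-thinning is described by the
Carreau law; the Womersley surrogate itself uses the Newtonian reference
viscosity, since the analytic solution requires it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FlowPulse
from .errors import ConvergenceError
from .profiles import WomersleyModel

__all__ = [
    "CarreauParams", "WindkesselParams", "WSSRecord", "HemodynamicMaps",
    "carreau_viscosity", "womersley_wss", "wss_metrics",
    "windkessel_pressure", "fit_windkessel", "MMHG_PA",
]

MMHG_PA = 133.322  # 1 mmHg in Pa


@dataclass
class CarreauParams:
    """Carreau shear-thinning parameters (literature blood values)."""

    mu0: float = 0.056       # Pa s, zero-shear viscosity
    mu_inf: float = 0.00345  # Pa s, infinite-shear viscosity
    lam: float = 3.313       # s, relaxation time
    n: float = 0.3568        # power index

    def __post_init__(self):
        if not self.mu0 >= self.mu_inf > 0:
            raise ValueError("need mu0 >= mu_inf > 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class WindkesselParams:
    """3-element Windkessel: Zc, Rp in Pa s/m^3, C in m^3/Pa, P_out in Pa."""

    zc: float
    rp: float
    c: float
    p_out: float = 0.0

    def __post_init__(self):
        if self.zc <= 0 or self.rp <= 0 or self.c <= 0:
            raise ValueError("Zc, Rp and C must be positive")


@dataclass
class WSSRecord:
    """Signed wall shear stress over one period, per location.

    ``wss`` has shape (n_times,) or (n_locations, n_times).
    """

    times: np.ndarray
    wss: np.ndarray
    period: float
    locations: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.wss = np.atleast_2d(np.asarray(self.wss, dtype=float))
        if self.wss.shape[1] != self.times.size:
            raise ValueError("wss must have one column per time sample")
        if not np.all(np.isfinite(self.wss)):
            raise ValueError("wss values must be finite")
        if self.period <= 0:
            raise ValueError("period must be positive")


@dataclass
class HemodynamicMaps:
    """Per-location systolic WSS, TAWSS and OSI."""

    systolic_wss: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray


def carreau_viscosity(shear_rate, p: CarreauParams | None = None) -> np.ndarray:
    """Carreau viscosity mu(gamma) = mu_inf + (mu0-mu_inf)[1+(lam g)^2]^((n-1)/2)."""
    if p is None:
        p = CarreauParams()
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear_rate must be >= 0")
    return p.mu_inf + (p.mu0 - p.mu_inf) * (1.0 + (p.lam * g) ** 2) ** ((p.n - 1.0) / 2.0)


def womersley_wss(model: WomersleyModel, t) -> np.ndarray:
    """Signed wall shear stress of the Womersley model at times ``t`` (Pa)."""
    return model.wall_shear_stress(t)


def wss_metrics(rec: WSSRecord, systolic_time: float) -> HemodynamicMaps:
    """Systolic WSS, TAWSS and OSI per location (trapezoidal in time)."""
    if not 0 <= systolic_time <= rec.period:
        raise ValueError("systolic_time must lie within the period")
    t = rec.times
    sys_wss = np.array([np.interp(systolic_time, t, row) for row in rec.wss])
    mean_wss = np.trapezoid(rec.wss, t, axis=1) / rec.period
    tawss = np.trapezoid(np.abs(rec.wss), t, axis=1) / rec.period
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = 0.5 * (1.0 - np.abs(mean_wss) / tawss)
    osi = np.where(tawss == 0.0, 0.0, osi)
    osi = np.clip(osi, 0.0, 0.5)
    return HemodynamicMaps(systolic_wss=sys_wss, tawss=tawss, osi=osi)


def windkessel_pressure(pulse: FlowPulse, p: WindkesselParams,
                        n_cycles: int = 2, steps_per_cycle: int = 400
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the 3-element Windkessel over ``n_cycles``; return the
    last cycle as (times, pressure) with times starting at 0.

    Classical RK4 at >= 200 steps per cycle; the initial capacitor
    pressure is P_out, and the leading cycles absorb the transient.
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2 (the first cycles are transient)")
    steps_per_cycle = max(steps_per_cycle, 200)
    T = pulse.period
    h = T / steps_per_cycle

    def dpc(t, pc):
        return (pulse.q_at(t) - (pc - p.p_out) / p.rp) / p.c

    pc = p.p_out
    n_total = n_cycles * steps_per_cycle
    t_grid = np.arange(n_total + 1) * h
    pc_hist = np.empty(n_total + 1)
    pc_hist[0] = pc
    for i in range(n_total):
        t = t_grid[i]
        k1 = dpc(t, pc)
        k2 = dpc(t + h / 2, pc + h / 2 * k1)
        k3 = dpc(t + h / 2, pc + h / 2 * k2)
        k4 = dpc(t + h, pc + h * k3)
        pc += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        pc_hist[i + 1] = pc

    pressure = p.zc * pulse.q_at(t_grid) + pc_hist
    last = slice(n_total - steps_per_cycle, n_total + 1)
    return t_grid[last] - t_grid[last][0], pressure[last]


def fit_windkessel(pulse: FlowPulse, target_sys: float, target_dia: float,
                   init: WindkesselParams, tol: float = 100.0,
                   max_iter: int = 50, n_cycles: int = 6) -> WindkesselParams:
    """Iteratively scale the Windkessel parameters to match a target
    systolic/diastolic pressure pair.

    Fixed-point scheme: per iteration the total resistance Zc+Rp (at the
    init's Zc/Rp ratio) is corrected through the steady-state identity
    mean P = P_out + (Zc+Rp) Q_mean to remove the mid-pressure error
    (sys+dia)/2, and the compliance is scaled by the achieved/target
    pulse-pressure ratio.  Each evaluation simulates long enough for the
    RC transient to settle.  Returns ``init`` unchanged if it already
    meets both targets within ``tol`` (Pa); raises
    :class:`ConvergenceError` carrying the last iterate otherwise.
    """
    if not target_sys > target_dia > 0:
        raise ValueError("need target_sys > target_dia > 0")
    target_pp = target_sys - target_dia
    q_mean = pulse.mean()
    if q_mean <= 0:
        raise ValueError("cycle-mean flow must be positive to set a mean pressure")
    zc_frac = init.zc / (init.zc + init.rp)

    def evaluate(p: WindkesselParams):
        settle = int(np.ceil(6.0 * p.rp * p.c / pulse.period)) + 2
        cycles = min(max(n_cycles, settle), 80)
        _, pressure = windkessel_pressure(pulse, p, n_cycles=cycles)
        return float(pressure.max()), float(pressure.min())

    params = init
    for _ in range(max_iter + 1):
        sys_p, dia_p = evaluate(params)
        if abs(sys_p - target_sys) <= tol and abs(dia_p - target_dia) <= tol:
            return params
        mid_err = 0.5 * ((target_sys + target_dia) - (sys_p + dia_p))
        r_total = params.zc + params.rp + mid_err / q_mean
        r_total = max(r_total, 0.1 * (params.zc + params.rp))
        c_new = params.c * max(sys_p - dia_p, 1e-12) / target_pp
        params = WindkesselParams(zc=zc_frac * r_total,
                                  rp=(1 - zc_frac) * r_total,
                                  c=c_new, p_out=params.p_out)
    raise ConvergenceError("Windkessel fit did not converge", last_iterate=params)
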