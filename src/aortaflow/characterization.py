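"""Scalar characterization of a one-cycle flow pulse.

Thirteen descriptors quantify the waveform: the flow extrema and mean,
their ratio, heart rate, stroke volume, the systolic duration and its
fraction of the cycle, and the phase volumes (systolic forward SF,
reversal RF, total forward FF, total backward BF) with their ratios
SF/RF and FF/BF.  Phases are delimited by zero-crossings: systole runs
from the cycle start (the systolic foot) to the first down-crossing, the
reversal phase from there to the next up-crossing or the cycle end.
A pulse without a second (up-) zero-crossing therefore degenerates to
SF = FF, RF = BF and SRratio = FBratio exactly; a pulse without any
reverse flow has no down-crossing, so its systolic time must be supplied
manually and the reverse-flow descriptors are reported as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FlowPulse
from .errors import MissingSystolicTimeError

__all__ = ["FlowParameters", "zero_crossings", "compute_flow_parameters",
           "parameter_differences", "rotate_to_systolic_foot"]

_FINE_N = 2048

PARAMETER_NAMES = (
    "q_max", "q_min", "q_mean", "max_min_ratio", "heart_rate",
    "stroke_volume", "systolic_time", "systolic_ratio",
    "sf", "rf", "ff", "bf", "sr_ratio", "fb_ratio",
)


@dataclass
class FlowParameters:
    """Flow-pulse descriptors (SI units; volumes m^3, times s, rate 1/min)."""

    q_max: float
    q_min: float
    q_mean: float
    max_min_ratio: float
    heart_rate: float
    stroke_volume: float
    systolic_time: float
    systolic_ratio: float
    sf: float
    rf: float
    ff: float
    bf: float
    sr_ratio: float
    fb_ratio: float
    triphasic: bool = False
    second_zero_crossing: bool = False
    negative_flow_present: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


def zero_crossings(pulse: FlowPulse) -> list[tuple[float, str]]:
    """Interior zero-crossing times with direction ('down' = + to -).

    Crossing times are refined to sub-sample precision by linear
    interpolation between samples of opposite sign; runs of exactly-zero
    samples between opposite signs yield one crossing at the first zero
    sample.
    """
    t, q = pulse.times, pulse.q
    nz = np.flatnonzero(q != 0.0)
    crossings: list[tuple[float, str]] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if np.sign(q[a]) == np.sign(q[b]):
            continue
        direction = "down" if q[a] > 0 else "up"
        if b == a + 1:
            tc = t[a] + (t[b] - t[a]) * q[a] / (q[a] - q[b])
        else:
            tc = t[a + 1]  # first exactly-zero sample in the run
        crossings.append((float(tc), direction))
    return crossings


def rotate_to_systolic_foot(pulse: FlowPulse, n: int = _FINE_N) -> FlowPulse:
    """Cyclically rotate so t=0 is the systolic foot.

    The foot is the minimum within 0.3 period before the global maximum;
    ties (a zero-flow diastolic plateau) resolve to the last occurrence,
    i.e. the point where the systolic upstroke actually starts.
    """
    fine = pulse.resample(n)
    m = int(np.argmax(fine.q))
    window = int(round(0.3 * n))
    idx = (m - window + np.arange(window)) % n
    vals = fine.q[idx]
    pos = window - 1 - int(np.argmin(vals[::-1]))
    # systole cannot start in reverse flow: advance to the up-crossing
    while vals[pos] < 0.0 and pos < window - 1:
        pos += 1
    foot = idx[pos]
    return fine.rotated(foot / n * pulse.period)


def compute_flow_parameters(pulse: FlowPulse,
                            manual_systolic_time: float | None = None,
                            rotate: bool = True) -> FlowParameters:
    """Compute the 13 flow descriptors plus shape flags.

    The pulse is first rotated so the cycle starts at the systolic foot;
    integration is trapezoidal on a fine uniform resampling of the cycle.
    """
    work = rotate_to_systolic_foot(pulse) if rotate else pulse.resample(_FINE_N)
    T = work.period
    t = np.concatenate([work.times, [T]])
    q = np.concatenate([work.q, [work.q[0]]])

    q_max = float(np.max(q))
    q_min = float(np.min(q))
    q_mean = float(np.trapezoid(q, t) / T)
    sv = float(np.trapezoid(q, t))
    ff = float(np.trapezoid(np.maximum(q, 0.0), t))
    bf = float(abs(np.trapezoid(np.minimum(q, 0.0), t)))
    negative = q_min < 0.0

    crossings = zero_crossings(FlowPulse(times=work.times, q=work.q, period=T))
    downs = [tc for tc, d in crossings if d == "down"]
    ups = [tc for tc, d in crossings if d == "up"]

    if negative and downs:
        e = downs[0]
        t_up = next((tu for tu in ups if tu > e), T)
        second = t_up < T
        sf = float(np.trapezoid(np.maximum(q, 0.0) * (t <= e), t))
        seg = (t >= e) & (t <= t_up)
        rf = float(abs(np.trapezoid(np.where(seg, q, 0.0), t)))
        max_min_ratio = q_max / abs(q_min)
        sr_ratio = sf / rf if rf > 0 else np.nan
        fb_ratio = ff / bf if bf > 0 else np.nan
        triphasic = (len(crossings) == 2 and second
                     and crossings[0][1] == "down" and crossings[1][1] == "up"
                     and float(np.max(q[t >= t_up])) > 0.0)
    else:
        if manual_systolic_time is None:
            raise MissingSystolicTimeError(
                "pulse has no reverse flow; supply manual_systolic_time")
        e = float(manual_systolic_time)
        second = False
        triphasic = False
        sf = float(np.trapezoid(np.maximum(q, 0.0) * (t <= e), t))
        rf = np.nan
        max_min_ratio = np.nan
        sr_ratio = np.nan
        fb_ratio = np.nan

    return FlowParameters(
        q_max=q_max, q_min=q_min, q_mean=q_mean, max_min_ratio=max_min_ratio,
        heart_rate=60.0 / T, stroke_volume=sv, systolic_time=e,
        systolic_ratio=e / T, sf=sf, rf=rf, ff=ff, bf=bf,
        sr_ratio=sr_ratio, fb_ratio=fb_ratio, triphasic=bool(triphasic),
        second_zero_crossing=bool(second), negative_flow_present=bool(negative))


def parameter_differences(test: FlowParameters, reference: FlowParameters,
                          absolute: bool = False) -> dict[str, float]:
    """Percentual differences 100 (test - ref)/ref per parameter.

    NaN in either operand propagates; a zero reference yields NaN with a
    warning.  ``absolute=True`` returns absolute percentual differences.
    """
    out: dict[str, float] = {}
    for name in PARAMETER_NAMES:
        a, b = getattr(test, name), getattr(reference, name)
        if np.isnan(a) or np.isnan(b):
            out[name] = np.nan
        elif b == 0:
            warnings.warn(f"reference parameter {name} is zero; difference undefined")
            out[name] = np.nan
        else:
            d = 100.0 * (a - b) / b
            out[name] = abs(d) if absolute else d
    return out
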