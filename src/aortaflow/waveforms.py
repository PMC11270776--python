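"""Closed-form triphasic flow-pulse template.

The abdominal-aortic flow pulse is triphasic: a dominant systolic forward
lobe, an early-diastolic reversal, and a small late-diastolic forward
lobe.  The template is a sum of three raised-cosine lobes with fixed
relative timings (systole over 0-35% of the cycle, reversal over 35-60%,
late forward over 60-80%, zero flow afterwards).  Lobe boundaries touch
zero exactly, so a pulse with any reversal has exactly two interior
sign changes.
"""

from __future__ import annotations

import numpy as np

from .core import FlowPulse

# (start, width) of each lobe as fractions of the period
SYSTOLIC_LOBE = (0.0, 0.35)
REVERSAL_LOBE = (0.35, 0.25)
LATE_LOBE = (0.60, 0.20)
LATE_LOBE_FRACTION = 0.12  # late forward peak relative to systolic peak


def _raised_cosine(phase: np.ndarray, start: float, width: float) -> np.ndarray:
    """Unit-amplitude raised-cosine bump supported on [start, start+width]."""
    x = (phase - start) / width
    lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
    return np.where((x >= 0.0) & (x <= 1.0), lobe, 0.0)


def triphasic_shape(phase: np.ndarray, reverse_fraction: float,
                    late_fraction: float = LATE_LOBE_FRACTION) -> np.ndarray:
    """Normalized triphasic waveform (peak = 1) at cycle phases in [0, 1)."""
    phase = np.mod(np.asarray(phase, dtype=float), 1.0)
    q = _raised_cosine(phase, *SYSTOLIC_LOBE)
    q = q - reverse_fraction * _raised_cosine(phase, *REVERSAL_LOBE)
    q = q + late_fraction * _raised_cosine(phase, *LATE_LOBE)
    return q


def triphasic_pulse(peak_flow: float, reverse_fraction: float, heart_rate: float,
                    n_samples: int = 200) -> FlowPulse:
    """Sampled triphasic pulse with peak ``peak_flow`` (m^3/s) and the given
    heart rate (beats/min)."""
    if peak_flow <= 0:
        raise ValueError("peak_flow must be positive")
    if not 0.0 <= reverse_fraction < 1.0:
        raise ValueError("reverse_fraction must be in [0, 1)")
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    if n_samples < 32:
        raise ValueError("n_samples too small to resolve three lobes")
    period = 60.0 / heart_rate
    phase = np.arange(n_samples) / n_samples
    q = peak_flow * triphasic_shape(phase, reverse_fraction)
    return FlowPulse(times=phase * period, q=q, period=period)
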