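"""Comparison statistics between a test and a reference field.

Two statistics quantify how a test quantity (ultrasound-derived or
generic) deviates from the reference (MRI):

* point-wise percentual difference, normalized by the *mean* of the
  reference over the support (not the local value):
      dp_i = (test_i - ref_i) / mean(ref) * 100%
* normalized root-mean-square error:
      nRMSE = sqrt(mean_i (ref_i - test_i)^2) / mean(ref) * 100%

For axially resolved surface quantities the most proximal part of the
domain, one diameter from the inlet, can be excluded; the normalizing
reference mean is then computed over the same included points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptySupportError

__all__ = ["FieldPair", "percentual_pointwise_diff", "nrmse"]


@dataclass
class FieldPair:
    """Test and reference values on a common support.

    ``axial`` (m, distance from the inlet plane, 0 at the inlet) and
    ``diameter`` (m) are only needed for the proximal-exclusion rule.
    """

    test: np.ndarray
    reference: np.ndarray
    axial: np.ndarray | None = None
    diameter: float | None = None

    def __post_init__(self):
        self.test = np.ravel(np.asarray(self.test, dtype=float))
        self.reference = np.ravel(np.asarray(self.reference, dtype=float))
        if self.test.shape != self.reference.shape:
            raise ValueError("test and reference must have equal lengths")
        if self.axial is not None:
            self.axial = np.ravel(np.asarray(self.axial, dtype=float))
            if self.axial.shape != self.test.shape:
                raise ValueError("axial coordinates must match the field length")


def percentual_pointwise_diff(pair: FieldPair) -> np.ndarray:
    """Per-point percentual difference relative to the reference mean."""
    ref_mean = pair.reference.mean()
    if ref_mean == 0:
        raise ValueError("reference mean is zero; normalization undefined")
    return (pair.test - pair.reference) / ref_mean * 100.0


def nrmse(pair: FieldPair, exclude_proximal: bool = False) -> float:
    """Normalized RMSE in percent, optionally excluding the proximal
    one-diameter region (requires ``axial`` and ``diameter``)."""
    keep = np.ones(pair.test.size, dtype=bool)
    if exclude_proximal:
        if pair.axial is None or pair.diameter is None:
            raise ValueError("proximal exclusion needs axial coordinates and a diameter")
        keep = pair.axial >= pair.diameter
    if not keep.any():
        raise EmptySupportError("all points excluded from the nRMSE support")
    ref = pair.reference[keep]
    test = pair.test[keep]
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise ValueError("reference mean is zero; normalization undefined")
    return float(np.sqrt(np.mean((ref - test) ** 2)) / ref_mean * 100.0)
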