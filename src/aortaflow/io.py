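"""Reading and writing the package's on-disk formats.

Waveforms travel as plain CSV (``time_s``, ``flow_m3s`` or ``v_ms``) with
the period in a ``# key=value`` comment line; image stacks travel as a
NumPy ``.npz`` container with a JSON sidecar holding the axis calibration
(time origin/step, velocity-bin edges, pixel spacing, VENC, color scale),
so nothing depends on scanner file formats or named colormaps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CDFrameSequence, ColorScale, FlowPulse, PWDSpectrogram, QFlowSeries, VelocityTrace

__all__ = [
    "save_flow_pulse", "load_flow_pulse",
    "save_velocity_trace", "load_velocity_trace",
    "save_spectrogram", "load_spectrogram",
    "save_cd_sequence", "load_cd_sequence",
    "save_qflow_series", "load_qflow_series",
]


def _read_header_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
    return meta


def save_flow_pulse(pulse: FlowPulse, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# period_s={pulse.period!r}\n")
        pd.DataFrame({"time_s": pulse.times, "flow_m3s": pulse.q}).to_csv(fh, index=False)


def load_flow_pulse(path) -> FlowPulse:
    path = Path(path)
    meta = _read_header_meta(path)
    df = pd.read_csv(path, comment="#")
    return FlowPulse(times=df["time_s"].to_numpy(), q=df["flow_m3s"].to_numpy(),
                     period=meta["period_s"])


def save_velocity_trace(trace: VelocityTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "v_ms": trace.v}).to_csv(path, index=False)


def load_velocity_trace(path) -> VelocityTrace:
    df = pd.read_csv(path, comment="#")
    return VelocityTrace(times=df["time_s"].to_numpy(), v=df["v_ms"].to_numpy())


def _save_with_sidecar(path: Path, arrays: dict, meta: dict) -> None:
    np.savez(path, **arrays)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def _load_sidecar(path: Path) -> dict:
    return json.loads(path.with_suffix(path.suffix + ".json").read_text())


def save_spectrogram(spec: PWDSpectrogram, path) -> None:
    path = Path(path)
    _save_with_sidecar(path,
                       {"intensity": spec.intensity},
                       {"time_origin_s": float(spec.times[0]),
                        "time_step_s": float(np.median(np.diff(spec.times))),
                        "n_times": int(spec.times.size),
                        "v_bin_centers_ms": spec.v_bin_centers.tolist()})


def load_spectrogram(path) -> PWDSpectrogram:
    path = Path(path)
    meta = _load_sidecar(path)
    with np.load(path) as data:
        intensity = data["intensity"]
    times = meta["time_origin_s"] + meta["time_step_s"] * np.arange(meta["n_times"])
    return PWDSpectrogram(times=times, v_bin_centers=np.asarray(meta["v_bin_centers_ms"]),
                          intensity=intensity)


def save_cd_sequence(seq: CDFrameSequence, path) -> None:
    path = Path(path)
    arrays = {"frames": seq.frames}
    if seq.truth_fields is not None:
        arrays["truth_fields"] = seq.truth_fields
    _save_with_sidecar(path, arrays,
                       {"timestamps_s": seq.timestamps.tolist(),
                        "pixel_spacing_m": seq.pixel_spacing,
                        "background_color": seq.background_color.tolist(),
                        "scale_colors": seq.color_scale.colors.tolist(),
                        "scale_velocities_ms": seq.color_scale.velocities.tolist()})


def load_cd_sequence(path) -> CDFrameSequence:
    path = Path(path)
    meta = _load_sidecar(path)
    with np.load(path) as data:
        frames = data["frames"]
        truth = data["truth_fields"] if "truth_fields" in data.files else None
    scale = ColorScale(colors=np.asarray(meta["scale_colors"]),
                       velocities=np.asarray(meta["scale_velocities_ms"]))
    return CDFrameSequence(frames=frames, timestamps=np.asarray(meta["timestamps_s"]),
                           pixel_spacing=meta["pixel_spacing_m"], color_scale=scale,
                           background_color=np.asarray(meta["background_color"]),
                           truth_fields=truth)


def save_qflow_series(series: QFlowSeries, path) -> None:
    path = Path(path)
    _save_with_sidecar(path, {"ffe": series.ffe, "pca": series.pca},
                       {"venc_ms": series.venc,
                        "pixel_spacing_m": series.pixel_spacing,
                        "period_s": series.period})


def load_qflow_series(path) -> QFlowSeries:
    path = Path(path)
    meta = _load_sidecar(path)
    with np.load(path) as data:
        ffe, pca = data["ffe"], data["pca"]
    return QFlowSeries(ffe=ffe, pca=pca, venc=meta["venc_ms"],
                       pixel_spacing=meta["pixel_spacing_m"], period=meta["period_s"])
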