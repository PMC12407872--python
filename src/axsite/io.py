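"""Reading and writing the package's on-disk formats.

Sessions are delimited tables (``time_s``, ``fluor``, ``mux``, ``trig``);
images and volumes are multi-page TIFFs with a JSON sidecar holding the
pixel/voxel calibration, channel names, and (for synthetic data) the ground
truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from axsite.synthetic_data import LabeledField2D, LabeledVolume3D, PhotometryRecording

__all__ = [
    "write_session",
    "read_session",
    "write_volume",
    "read_volume",
    "write_field",
    "read_field",
]


def write_session(path: str | Path, rec: PhotometryRecording) -> None:
    df = pd.DataFrame(
        {"time_s": rec.time_s, "fluor": rec.fluor, "mux": rec.mux, "trig": rec.trig}
    )
    df.to_csv(path, sep="\t", index=False)


def read_session(path: str | Path, sample_rate_hz: float | None = None) -> PhotometryRecording:
    df = pd.read_csv(path, sep="\t")
    required = {"time_s", "fluor", "mux", "trig"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"session table missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if sample_rate_hz is None:
        if t.size < 2:
            raise ValueError("cannot infer sample rate from fewer than 2 samples")
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return PhotometryRecording(
        sample_rate_hz=sample_rate_hz,
        time_s=t,
        fluor=df["fluor"].to_numpy(dtype=float),
        mux=df["mux"].to_numpy(dtype=float),
        trig=df["trig"].to_numpy(dtype=float),
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, vol: LabeledVolume3D) -> None:
    path = Path(path)
    names = list(vol.channels)
    stack = np.stack([vol.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"channels": names, "voxel_size_um": list(vol.voxel_size_um)})
    )


def read_volume(path: str | Path) -> LabeledVolume3D:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stack = tifffile.imread(path)
    channels = {n: stack[i].astype(float) for i, n in enumerate(meta["channels"])}
    return LabeledVolume3D(channels=channels, voxel_size_um=tuple(meta["voxel_size_um"]))


def write_field(path: str | Path, field: LabeledField2D) -> None:
    path = Path(path)
    names = list(field.channels)
    stack = np.stack([field.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"channels": names, "pixel_size_um": field.pixel_size_um})
    )


def read_field(path: str | Path) -> LabeledField2D:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stack = tifffile.imread(path)
    channels = {n: stack[i].astype(float) for i, n in enumerate(meta["channels"])}
    return LabeledField2D(channels=channels, pixel_size_um=float(meta["pixel_size_um"]))
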