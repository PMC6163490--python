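"""File interchange: TIFF images and volumes, CSV shift tables, JSON sidecars.

Complex fields persist as paired-page 32-bit float TIFF (page 0 = real
part, page 1 = imaginary part) with a JSON sidecar carrying pitch,
wavelength and plane position.  Volumes are multi-page TIFF z-stacks with
a JSON sidecar for the z grid and provenance.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .deconv import Volume3D
from .psr import LowResStack
from .wave import ComplexField2D

__all__ = [
    "save_complex_field",
    "load_complex_field",
    "save_volume",
    "load_volume",
    "save_image",
    "load_image",
    "save_stack",
    "load_stack",
    "sha256_of",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_complex_field(field: ComplexField2D, path: str | Path) -> Path:
    path = Path(path)
    pages = np.stack([field.data.real, field.data.imag]).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "kind": "complex_field",
        "pitch_um": field.pitch,
        "wavelength_um": field.wavelength,
        "z_position_um": field.z_position,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_complex_field(path: str | Path) -> ComplexField2D:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise ValueError(f"{path} is not a paired-page complex TIFF (shape {pages.shape})")
    meta = json.loads(_sidecar(path).read_text())
    data = pages[0].astype(np.float64) + 1j * pages[1].astype(np.float64)
    return ComplexField2D(
        data=data,
        pitch=meta["pitch_um"],
        wavelength=meta["wavelength_um"],
        z_position=meta.get("z_position_um", 0.0),
    )


def save_volume(volume: Volume3D, path: str | Path, extra_meta: dict | None = None) -> Path:
    path = Path(path)
    if volume.mode == "complex":
        pages = np.concatenate([volume.data.real, volume.data.imag]).astype(np.float32)
    else:
        pages = volume.data.astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "kind": "volume3d",
        "mode": volume.mode,
        "pitch_xy_um": volume.pitch_xy,
        "z_values_um": [float(z) for z in volume.z_values],
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    pages = tifffile.imread(path).astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())
    z = np.asarray(meta["z_values_um"], dtype=np.float64)
    if meta["mode"] == "complex":
        nz = len(z)
        data = pages[:nz] + 1j * pages[nz:]
    else:
        data = pages
    return Volume3D(data=data, pitch_xy=meta["pitch_xy_um"], z_values=z, mode=meta["mode"])


def save_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def load_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def save_stack(stack: LowResStack, directory: str | Path, prefix: str = "frame") -> Path:
    """Write a low-resolution stack as TIFF frames plus a shifts CSV.

    The CSV columns are ``frame, dx_um, dy_um``; returns the CSV path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (frame, (dx, dy)) in enumerate(zip(stack.frames, stack.shifts)):
        name = f"{prefix}_{i:03d}.tiff"
        save_image(frame, directory / name)
        rows.append((name, dx, dy))
    csv_path = directory / "shifts.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "dx_um", "dy_um"])
        writer.writerows(rows)
    meta = {"kind": "lowres_stack", "pitch_um": stack.pitch, "height_id": stack.height_id}
    (directory / "stack.json").write_text(json.dumps(meta, indent=2))
    return csv_path


def load_stack(directory: str | Path) -> LowResStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    frames, shifts = [], []
    with open(directory / "shifts.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            frames.append(load_image(directory / row["frame"]))
            shifts.append((float(row["dx_um"]), float(row["dy_um"])))
    return LowResStack(
        frames=frames, shifts=shifts, pitch=meta["pitch_um"], height_id=meta["height_id"]
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
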