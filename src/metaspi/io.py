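"""Serialization helpers: HDF5 array containers, image and CSV export."""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .modulation import MeasurementSet, SamplingPlan, patterns_for
from .optics import ComplexField, TransferFunction

__all__ = [
    "save_field",
    "load_field",
    "save_transfer",
    "load_transfer",
    "write_image_16bit",
    "measurements_to_csv",
    "patterns_to_tiff",
]


def save_field(path: str | Path, fld: ComplexField) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=fld.values)
        d.attrs["pixel_pitch"] = fld.pixel_pitch
        d.attrs["axes"] = "y,x (pixels)"


def load_field(path: str | Path) -> ComplexField:
    with h5py.File(path, "r") as f:
        d = f["values"]
        return ComplexField(values=d[...], pixel_pitch=float(d.attrs.get("pixel_pitch", 1.0)))


def save_transfer(path: str | Path, h: TransferFunction) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=h.values)
        d.attrs["mode"] = h.mode
        d.attrs["quantized"] = h.quantized
        d.attrs["axes"] = "fy,fx (cycles/grid, centered)"
        f.create_dataset("fx", data=h.fx)
        f.create_dataset("fy", data=h.fy)


def load_transfer(path: str | Path) -> TransferFunction:
    with h5py.File(path, "r") as f:
        d = f["values"]
        return TransferFunction(
            values=d[...],
            mode=str(d.attrs["mode"]),
            quantized=bool(d.attrs["quantized"]),
            fx=f["fx"][...],
            fy=f["fy"][...],
        )


def write_image_16bit(path: str | Path, image: np.ndarray, data_range: float | None = None) -> None:
    """Write a real image as 16-bit PNG/TIFF, scaled to the given data range."""
    image = np.asarray(image, dtype=np.float64)
    if data_range is None:
        data_range = max(float(image.max()), 1e-12)
    scaled = np.clip(image / data_range, 0.0, 1.0)
    iio.imwrite(Path(path), (scaled * 65535.0 + 0.5).astype(np.uint16))


def measurements_to_csv(path: str | Path, m: MeasurementSet) -> None:
    """One row per bucket value with its pattern index metadata."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["pattern_number", "index", "phase_step", "value"])
        k = m.plan.patterns_per_coefficient
        steps = {
            "fourier": ["0", "2pi/3", "4pi/3"],
            "hadamard": ["+1", "-1"],
            "random": [""],
        }[m.plan.kind]
        for j, v in enumerate(m.values):
            coeff = m.plan.coefficient_order[j // k]
            w.writerow([j, ";".join(map(str, coeff)), steps[j % k], repr(float(v))])


def patterns_to_tiff(path: str | Path, plan: SamplingPlan, limit: int | None = None) -> int:
    """Export a plan's patterns as a TIFF stack; returns the number written."""
    stack = []
    for i, p in enumerate(patterns_for(plan)):
        if limit is not None and i >= limit:
            break
        stack.append((np.clip(p.values, 0, 1) * 65535.0 + 0.5).astype(np.uint16))
    iio.imwrite(Path(path), np.stack(stack), extension=".tiff")
    return len(stack)
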