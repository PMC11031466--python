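"""NIfTI and sidecar I/O for dynamic series, maps and masks.

Series are stored as 4D NIfTI-1 in (x, y, z, t) axis order with the voxel
size in the affine and the sampling interval both in the header (pixdim)
and in a JSON sidecar next to the image; maps and masks are 3D NIfTI with
the same spatial geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DynamicSeries

__all__ = ["save_series", "load_series", "save_map", "load_map",
           "write_sidecar", "read_sidecar"]


def _affine(voxel_size_mm) -> np.ndarray:
    # data axes are (t, z, y, x); NIfTI wants (x, y, z[, t])
    dz, dy, dx = voxel_size_mm
    return np.diag([dx, dy, dz, 1.0])


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def save_series(series: DynamicSeries, path, meta: dict | None = None) -> None:
    """Write a 4D series as NIfTI plus a JSON sidecar (dt, metadata)."""
    img = nib.Nifti1Image(series.data.transpose(3, 2, 1, 0).astype(np.float32),
                          _affine(series.voxel_size_mm))
    img.header["pixdim"][4] = series.dt
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    side = {"sampling_interval_s": series.dt,
            "voxel_size_mm": list(series.voxel_size_mm)}
    side.update(series.meta)
    if meta:
        side.update(meta)
    write_sidecar(_sidecar_path(path), side)


def load_series(path) -> DynamicSeries:
    """Read a 4D NIfTI series written by :func:`save_series`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    zooms = img.header.get_zooms()
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = read_sidecar(sidecar)
    dt = float(meta.get("sampling_interval_s") or zooms[3])
    if dt <= 0:
        raise ValueError(f"{path}: no positive sampling interval recorded")
    voxel = tuple(float(v) for v in (zooms[2], zooms[1], zooms[0]))
    extra = {k: v for k, v in meta.items()
             if k not in ("sampling_interval_s", "voxel_size_mm")}
    return DynamicSeries(data.transpose(3, 2, 1, 0).astype(float), dt, voxel,
                         meta=extra)


def save_map(volume: np.ndarray, voxel_size_mm, path) -> None:
    """Write a 3D map or mask (z, y, x) as NIfTI."""
    arr = volume.astype(np.float32) if volume.dtype != bool else volume.astype(np.uint8)
    img = nib.Nifti1Image(arr.transpose(2, 1, 0), _affine(voxel_size_mm)[:4, :4])
    nib.save(img, str(path))


def load_map(path) -> np.ndarray:
    """Read a 3D NIfTI map back into (z, y, x) order."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got shape {data.shape}")
    return data.transpose(2, 1, 0)


def write_sidecar(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
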