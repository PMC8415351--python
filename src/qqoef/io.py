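"""NIfTI / CSV / sidecar I/O.

Volumes are written as NIfTI with a shared diagonal affine built from the
voxel size; echo times live in a JSON sidecar (not the NIfTI header).
All volumes of one dataset must share the same affine — a mismatch is an
error, never a silent resample.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .forward import EchoSeries

__all__ = [
    "affine_from_voxel_size",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_echo_series",
    "load_echo_series",
    "write_json",
    "read_json",
]


def affine_from_voxel_size(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


def save_volume(path: str | Path, data: np.ndarray, voxel_size_mm: float,
                dtype=np.float32) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype),
                          affine_from_voxel_size(voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path,
                expect_affine: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    aff = img.affine
    if expect_affine is not None and not np.allclose(aff, expect_affine, atol=1e-6):
        raise ValueError(f"{path}: affine mismatch (registration is out of scope)")
    return np.asarray(img.get_fdata()), aff


def save_mask(path: str | Path, mask: np.ndarray, voxel_size_mm: float) -> Path:
    return save_volume(path, np.asarray(mask, dtype=np.uint8), voxel_size_mm,
                       dtype=np.uint8)


def load_mask(path: str | Path, expect_affine: np.ndarray | None = None) -> np.ndarray:
    data, _ = load_volume(path, expect_affine)
    return data > 0.5


def save_echo_series(path: str | Path, echoes: EchoSeries,
                     voxel_size_mm: float) -> Path:
    """4-D NIfTI (x, y, z, echo) plus a JSON sidecar of echo times (s)."""
    path = Path(path)
    save_volume(path, echoes.magnitudes, voxel_size_mm)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii or .nii.gz
    sidecar = Path(str(sidecar) + "_echoes.json")
    write_json(sidecar, {"echo_times_s": [float(t) for t in echoes.echo_times]})
    return path


def load_echo_series(path: str | Path,
                     expect_affine: np.ndarray | None = None) -> EchoSeries:
    path = Path(path)
    data, _ = load_volume(path, expect_affine)
    sidecar = path.with_suffix("").with_suffix("")
    sidecar = Path(str(sidecar) + "_echoes.json")
    meta = read_json(sidecar)
    return EchoSeries(echo_times=np.asarray(meta["echo_times_s"]), magnitudes=data)


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
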