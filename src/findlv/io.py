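"""Reading and writing datasets and detection reports.

Supported image formats: NIfTI-1 (a single 4D file or an ordered series
of 3D files, via nibabel) and MetaImage 3D series (.mha / .mhd+raw, via
SimpleITK). Format scale factors (slope/intercept) are applied at read
time so in-memory values are Hounsfield units. Detection results are
serialized as JSON with stable key order; ``detected_phase`` is null for
a legitimate no-detection.
"""

from __future__ import annotations

import glob as _glob
import json
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np

from . import __version__
from .core import (
    Dataset4D,
    DetectionParams,
    DetectionResult,
    InvalidInputError,
    PhaseHistogram,
    Volume3D,
)

__all__ = ["read_dataset", "write_dataset", "write_result", "read_result"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def _read_volume3d(path: Path) -> Volume3D:
    if _is_nifti(path):
        img = nib.load(str(path))
        data = img.get_fdata(dtype=np.float64)  # applies scl slope/intercept
        if data.ndim != 3:
            raise InvalidInputError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return Volume3D(data, spacing)
    if path.suffix.lower() in _META_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        if arr.ndim != 3:
            raise InvalidInputError(f"{path}: expected a 3D volume, got ndim={arr.ndim}")
        return Volume3D(np.transpose(arr, (2, 1, 0)).astype(np.float64), tuple(img.GetSpacing()))
    raise InvalidInputError(f"{path}: unsupported image format")


def read_dataset(spec: str | Path | Iterable[str | Path]) -> Dataset4D:
    """Load a 4D dataset.

    ``spec`` may be: a single 4D NIfTI file (phases in stored
    4th-dimension order); a glob pattern or directory of 3D files, taken
    in lexicographic filename order; or an explicit ordered list of 3D
    file paths (the manifest order is used verbatim).
    """
    if isinstance(spec, (str, Path)):
        path = Path(spec)
        if path.is_dir():
            files = sorted(p for p in path.iterdir() if _is_nifti(p) or p.suffix.lower() in _META_SUFFIXES)
            return _read_series(files)
        if path.exists():
            if _is_nifti(path):
                img = nib.load(str(path))
                if img.ndim == 4:
                    return _read_4d_nifti(path)
            return _read_series([path])
        files = sorted(Path(p) for p in _glob.glob(str(spec)))
        if not files:
            raise FileNotFoundError(f"no files match {spec!r}")
        return _read_series(files)
    return _read_series([Path(p) for p in spec])


def _read_4d_nifti(path: Path) -> Dataset4D:
    img = nib.load(str(path))
    data = img.get_fdata(dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    phases = [Volume3D(data[..., k], spacing) for k in range(data.shape[3])]
    return Dataset4D(phases)


def _read_series(files: list[Path]) -> Dataset4D:
    for f in files:
        if not f.exists():
            raise IOError(f"cannot read {f}: file does not exist")
    vols = [_read_volume3d(f) for f in files]
    if len(vols) < 2:
        raise InvalidInputError(f"a 4D dataset needs >= 2 phases, got {len(vols)} file(s)")
    return Dataset4D(vols)


def write_dataset(dataset: Dataset4D, path: str | Path) -> Path:
    """Write a dataset as a single 4D NIfTI file (phase = 4th dimension)."""
    path = Path(path)
    arr = np.moveaxis(dataset.as_array(), 0, -1)  # (nx, ny, nz, P)
    affine = np.diag(list(dataset.spacing) + [1.0])
    img = nib.Nifti1Image(arr.astype(np.float64), affine)
    img.header.set_zooms(tuple(dataset.spacing) + (1.0,))
    nib.save(img, str(path))
    return path


def write_result(result: DetectionResult, path: str | Path) -> Path:
    """Serialize a detection result to JSON with stable key order.

    The histogram is written with string keys "1".."P", zero bins
    included; ``detected_phase`` is null for no-detection.
    """
    path = Path(path)
    payload = {
        "tool": "findlv",
        "version": __version__,
        "detected_phase": result.detected_phase,
        "histogram": {str(p): result.histogram.counts[p] for p in sorted(result.histogram.counts)},
        "eligible_voxels": result.eligible_voxels,
        "shrink_factor": result.shrink_factor,
        "params": result.params.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_result(path: str | Path) -> DetectionResult:
    """Parse a JSON detection report back into a DetectionResult."""
    d = json.loads(Path(path).read_text())
    return DetectionResult(
        detected_phase=d["detected_phase"],
        histogram=PhaseHistogram({int(k): v for k, v in d["histogram"].items()}),
        eligible_voxels=d["eligible_voxels"],
        shrink_factor=d["shrink_factor"],
        params=DetectionParams.from_dict(d["params"]),
    )
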