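"""Integer-factor mean-pooling ("bin shrink") and matrix-size mapping.

The first step of the detection pipeline downsamples every phase by one
integer factor, identical for all three axes. Each output voxel is the
arithmetic mean of its block of input voxels, so attenuation statistics
are preserved while the voxel count drops by factor^3. The factor is set
indirectly through the desired *matrix size* — the number of voxels in
x after shrinking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidParameterError, Volume3D

__all__ = ["ShrinkSpec", "compute_shrink_factor", "bin_shrink"]


@dataclass(frozen=True)
class ShrinkSpec:
    """One integer shrink factor, applied to all three axes."""

    factor: int

    def __post_init__(self) -> None:
        if int(self.factor) != self.factor or self.factor < 1:
            raise InvalidParameterError(f"shrink factor must be a positive integer, got {self.factor}")
        object.__setattr__(self, "factor", int(self.factor))


def compute_shrink_factor(input_extent_x: int, matrix_size: int) -> int:
    """Map an input x-extent and a requested matrix size to a shrink factor.

    ``factor = max(1, floor(input_extent_x / matrix_size))`` — e.g. a
    512-voxel image shrunk to matrix size 128 uses factor 4. The filter
    never up-samples: a matrix size larger than the input clamps to 1.
    """
    if int(input_extent_x) != input_extent_x or input_extent_x < 1:
        raise InvalidParameterError(f"input_extent_x must be a positive integer, got {input_extent_x}")
    if int(matrix_size) != matrix_size or matrix_size < 1:
        raise InvalidParameterError(f"matrix_size must be a positive integer, got {matrix_size}")
    return max(1, int(input_extent_x) // int(matrix_size))


def _bin_shrink_array(values: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Mean-pool a 3D array by per-axis integer factors.

    Boundary bins may be partial; they average over the voxels actually
    present. Non-finite voxels are excluded from the mean; a bin whose
    voxels are all non-finite yields NaN (ineligible downstream).
    Accumulation is in float64 regardless of input width.
    """
    vals = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(vals)
    sums = np.where(finite, vals, 0.0)
    counts = finite.astype(np.float64)
    for ax, f in enumerate(factors):
        if f > 1:
            starts = np.arange(0, vals.shape[ax], f)
            sums = np.add.reduceat(sums, starts, axis=ax)
            counts = np.add.reduceat(counts, starts, axis=ax)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)
    return out


def bin_shrink(volume: Volume3D, spec: ShrinkSpec | int) -> Volume3D:
    """Shrink a volume by an integer factor via block means.

    Output extent per axis is ``ceil(n / factor)``; output spacing is the
    input spacing times the factor. Factor 1 returns an exact copy.
    The operation is purely functional: the result is independent of any
    execution partitioning and reproducible run-to-run.
    """
    if isinstance(spec, int):
        spec = ShrinkSpec(spec)
    f = spec.factor
    if f == 1:
        return Volume3D(volume.values.copy(), volume.spacing)
    out = _bin_shrink_array(volume.values, (f, f, f))
    new_spacing = tuple(s * f for s in volume.spacing)
    return Volume3D(out, new_spacing)  # type: ignore[arg-type]
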