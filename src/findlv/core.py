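"""Core domain types for 4D cardiac CT phase detection.

Conventions used throughout the package:

* Attenuation values are calibrated Hounsfield units (HU). Any on-disk
  scaling (slope/intercept) is applied at read time, before detection.
* Phase numbers are **1-based** in every reported or serialized output,
  matching radiological convention ("the 10th phase"); internal array
  indices are 0-based.
* All phases of a dataset share one voxel grid (extents and spacing);
  resampling between mismatched grids is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Volume3D",
    "Dataset4D",
    "DetectionParams",
    "PhaseHistogram",
    "DetectionResult",
    "InvalidParameterError",
    "InvalidInputError",
    "GridMismatchError",
]


class InvalidParameterError(ValueError):
    """An algorithm parameter violates its contract."""


class InvalidInputError(ValueError):
    """An input dataset violates its contract."""


class GridMismatchError(InvalidInputError):
    """Phases of a 4D dataset do not share one voxel grid."""


@dataclass
class Volume3D:
    """A 3D scalar grid of attenuation values in Hounsfield units.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Attenuation in HU. Stored as float64. Non-finite voxels are
        permitted (they are ineligible for detection and are excluded
        from shrink means).
    spacing : tuple of float
        Millimetres per voxel along (x, y, z); all positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidInputError(
                f"volume must be 3D, got ndim={self.values.ndim}"
            )
        if any(n < 1 for n in self.values.shape):
            raise InvalidInputError(f"extents must be >= 1, got {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def extents(self) -> tuple[int, int, int]:
        """Voxel counts (nx, ny, nz)."""
        return self.values.shape  # type: ignore[return-value]


@dataclass
class Dataset4D:
    """An ordered sequence of co-registered 3D volumes, one per cardiac phase.

    Index order is acquisition order; the first list element is phase 1.
    Optional ``acquisition_times`` (seconds, strictly increasing) are
    carried for provenance only — the detection algorithm trusts the
    supplied ordering and never re-sorts by time stamp.
    """

    phases: list[Volume3D]
    acquisition_times: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.phases) < 2:
            raise InvalidInputError(
                f"a 4D dataset needs >= 2 phases, got {len(self.phases)}"
            )
        ref = self.phases[0]
        for i, ph in enumerate(self.phases[1:], start=2):
            if ph.extents != ref.extents or ph.spacing != ref.spacing:
                raise GridMismatchError(
                    f"phase {i} grid {ph.extents}/{ph.spacing} differs from "
                    f"phase 1 grid {ref.extents}/{ref.spacing}"
                )
        if self.acquisition_times is not None:
            t = [float(x) for x in self.acquisition_times]
            if len(t) != len(self.phases):
                raise InvalidInputError("acquisition_times length must equal phase count")
            if any(b <= a for a, b in zip(t, t[1:])):
                raise InvalidInputError("acquisition_times must be strictly increasing")
            self.acquisition_times = t

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def extents(self) -> tuple[int, int, int]:
        return self.phases[0].extents

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.phases[0].spacing

    def as_array(self) -> np.ndarray:
        """Stack phases into a (P, nx, ny, nz) float64 array."""
        return np.stack([p.values for p in self.phases], axis=0)


IncreaseMode = Literal["relative", "absolute"]


@dataclass
class DetectionParams:
    """Thresholds and sizing for the phase-detection algorithm.

    Attributes
    ----------
    hu_lower, hu_upper : float
        Closed eligibility window on the *first-phase* attenuation,
        default [30, 150] HU — the range of unenhanced blood, so that
        only chambers still free of contrast agent at acquisition start
        (notably the LV) are considered.
    increase_mode : {"relative", "absolute"}
        How the required attenuation increase is expressed.
    increase_value : float
        Relative mode: dimensionless fraction; a voxel's temporal maximum
        must reach first * (1 + increase_value). Absolute mode: HU; the
        maximum must reach first + increase_value. Default relative 1.0
        (maximum at least twice the baseline), reflecting that first-pass
        LV enhancement multiplies baseline blood attenuation severalfold.
    matrix_size : int
        Target voxel count in x after shrinking; sets the integer shrink
        factor. Default 16, the size with the best reader agreement.
    """

    hu_lower: float = 30.0
    hu_upper: float = 150.0
    increase_mode: IncreaseMode = "relative"
    increase_value: float = 1.0
    matrix_size: int = 16

    def __post_init__(self) -> None:
        if not self.hu_lower < self.hu_upper:
            raise InvalidParameterError(
                f"hu_lower must be < hu_upper, got [{self.hu_lower}, {self.hu_upper}]"
            )
        if self.increase_mode not in ("relative", "absolute"):
            raise InvalidParameterError(f"unknown increase_mode {self.increase_mode!r}")
        if not self.increase_value > 0:
            raise InvalidParameterError("increase_value must be > 0")
        if int(self.matrix_size) != self.matrix_size or self.matrix_size < 1:
            raise InvalidParameterError("matrix_size must be a positive integer")
        self.matrix_size = int(self.matrix_size)

    def to_dict(self) -> dict:
        return {
            "hu_lower": self.hu_lower,
            "hu_upper": self.hu_upper,
            "increase_mode": self.increase_mode,
            "increase_value": self.increase_value,
            "matrix_size": self.matrix_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**d)


@dataclass
class PhaseHistogram:
    """Per-phase voxel vote counts — one bin per phase, 1-based keys.

    ``counts[p]`` is the number of eligible voxels whose temporal maximum
    occurs at phase ``p``. Bins exist for every phase of the dataset,
    including empty ones.
    """

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise InvalidInputError("histogram needs at least one bin")
        keys = sorted(self.counts)
        if keys != list(range(1, len(keys) + 1)):
            raise InvalidInputError(
                f"histogram bins must be exactly 1..P, got {keys}"
            )
        cleaned = {}
        for k in keys:
            c = self.counts[k]
            if int(c) != c or c < 0:
                raise InvalidInputError(f"bin {k} count must be a non-negative integer")
            cleaned[k] = int(c)
        self.counts = cleaned

    @property
    def n_phases(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        """Counts as an int array indexed 0..P-1 (phase p at index p-1)."""
        return np.array([self.counts[p] for p in range(1, self.n_phases + 1)], dtype=np.int64)


@dataclass
class DetectionResult:
    """Outcome of a phase-detection run.

    ``detected_phase`` is the 1-based winning bin, or ``None`` when no
    voxel satisfied both conditions (all bins zero). No-detection is a
    legitimate outcome, not an error.
    """

    detected_phase: int | None
    histogram: PhaseHistogram
    eligible_voxels: int
    shrink_factor: int
    params: DetectionParams = field(default_factory=DetectionParams)

    def __post_init__(self) -> None:
        if self.eligible_voxels != self.histogram.total:
            raise InvalidInputError(
                "eligible_voxels must equal the histogram total "
                f"({self.eligible_voxels} != {self.histogram.total})"
            )
        if self.shrink_factor < 1:
            raise InvalidParameterError("shrink_factor must be >= 1")
        counts = self.histogram.as_array()
        if self.detected_phase is None:
            if counts.any():
                raise InvalidInputError("detected_phase is None but histogram is non-zero")
        else:
            expected = int(np.argmax(counts)) + 1  # argmax -> earliest on ties
            if not counts.any() or self.detected_phase != expected:
                raise InvalidInputError(
                    f"detected_phase {self.detected_phase} is not the earliest "
                    f"maximal bin ({expected})"
                )
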