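"""The findLV phase-detection algorithm.

Detects, in a 4D cardiac CT dataset, the phase with high contrast in the
left ventricle (LV) and low contrast in the right ventricle (RV), using
the first-pass dynamics of the contrast bolus: the agent enhances the RV
first and — after lung transit — the LV, so LV attenuation rises with
phase number while RV enhancement washes out.

Four main steps:

1. shrink every phase by one integer factor (block means);
2. per voxel of the shrunken grid, record the maximum attenuation over
   all phases and the phase at which it occurs;
3. a voxel *votes* iff its first-phase value lies in the HU eligibility
   window (unenhanced blood, default [30, 150] HU) and its maximum shows
   the required increase over the first phase; the vote goes to the bin
   of its argmax phase in the phase histogram;
4. the phase with the most votes wins (earliest phase on ties); an
   all-zero histogram is an explicit no-detection.

Because acquisition starts with contrast already high in the RV, RV
voxels exceed the eligibility window in the first phase and do not vote;
the algorithm does not separately verify that the RV is unenhanced at
the detected phase.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .core import (
    Dataset4D,
    DetectionParams,
    DetectionResult,
    InvalidInputError,
    PhaseHistogram,
    Volume3D,
)
from .shrink import ShrinkSpec, bin_shrink, compute_shrink_factor

_logger = logging.getLogger("findlv")

__all__ = [
    "TemporalExtremum",
    "temporal_extremum",
    "build_phase_histogram",
    "select_phase",
    "detect_phase",
]


@dataclass
class TemporalExtremum:
    """Per-voxel temporal maximum and its 1-based phase of occurrence.

    ``max_values`` and ``argmax_phases`` share the (shrunken) grid shape;
    ``argmax_phases`` entries are in 1..P, earliest phase on exact ties.
    """

    max_values: np.ndarray
    argmax_phases: np.ndarray
    n_phases: int

    def __post_init__(self) -> None:
        if self.max_values.shape != self.argmax_phases.shape:
            raise InvalidInputError("max_values and argmax_phases must share a shape")


def temporal_extremum(shrunken: Dataset4D) -> TemporalExtremum:
    """Per-voxel maximum over phases and the phase where it occurs.

    Ties in the maximum are broken toward the earliest phase, which pins
    the result deterministically (one-voxel histogram margins do occur in
    practice, so tie rules matter).
    """
    stack = shrunken.as_array()  # (P, nx, ny, nz)
    max_values = np.max(stack, axis=0)
    # np.argmax returns the first occurrence -> earliest phase on ties
    argmax_phases = np.argmax(stack, axis=0).astype(np.int64) + 1
    return TemporalExtremum(max_values, argmax_phases, shrunken.n_phases)


def _vote_mask(
    extremum: TemporalExtremum, first_phase: Volume3D, params: DetectionParams
) -> np.ndarray:
    first = first_phase.values
    if first.shape != extremum.max_values.shape:
        raise InvalidInputError(
            f"first-phase grid {first.shape} does not match extremum grid "
            f"{extremum.max_values.shape}"
        )
    # NaN first-phase or max values compare False -> ineligible, as intended
    with np.errstate(invalid="ignore"):
        eligible = (first >= params.hu_lower) & (first <= params.hu_upper)
        if params.increase_mode == "relative":
            increased = extremum.max_values >= first * (1.0 + params.increase_value)
        else:
            increased = extremum.max_values >= first + params.increase_value
    return eligible & increased


def build_phase_histogram(
    extremum: TemporalExtremum, first_phase: Volume3D, params: DetectionParams
) -> PhaseHistogram:
    """Histogram the argmax phases of all voxels passing both conditions.

    A voxel votes iff (a) its first-phase attenuation lies in the closed
    window [hu_lower, hu_upper] and (b) its temporal maximum shows the
    required increase: relative mode ``max >= first * (1 + v)``, absolute
    mode ``max >= first + v``. Comparisons are inclusive ("at least",
    "between"). Bins exist for every phase, empty ones included.
    """
    mask = _vote_mask(extremum, first_phase, params)
    votes = np.bincount(
        extremum.argmax_phases[mask], minlength=extremum.n_phases + 1
    )
    return PhaseHistogram({p: int(votes[p]) for p in range(1, extremum.n_phases + 1)})


def select_phase(histogram: PhaseHistogram) -> int | None:
    """The bin with the most votes, earliest on ties; None if all zero."""
    counts = histogram.as_array()
    if not counts.any():
        return None
    return int(np.argmax(counts)) + 1


def detect_phase(dataset: Dataset4D, params: DetectionParams | None = None) -> DetectionResult:
    """Run the full detection pipeline on a 4D dataset.

    shrink -> temporal extremum -> histogram vote -> phase selection.
    The shrink factor is derived from the dataset's x-extent and
    ``params.matrix_size`` and never up-samples.
    """
    if params is None:
        params = DetectionParams()
    factor = compute_shrink_factor(dataset.extents[0], params.matrix_size)
    spec = ShrinkSpec(factor)
    t0 = time.perf_counter()
    shrunk = Dataset4D(
        [bin_shrink(ph, spec) for ph in dataset.phases],
        acquisition_times=dataset.acquisition_times,
    )
    t1 = time.perf_counter()
    extremum = temporal_extremum(shrunk)
    t2 = time.perf_counter()
    histogram = build_phase_histogram(extremum, shrunk.phases[0], params)
    t3 = time.perf_counter()
    detected = select_phase(histogram)
    t4 = time.perf_counter()
    _logger.info(
        "detect_phase timings (s): shrink=%.4f voxel_loop=%.4f "
        "array_analysis=%.4f histogram_loop=%.4f",
        t1 - t0, t2 - t1, t3 - t2, t4 - t3,
    )
    return DetectionResult(
        detected_phase=detected,
        histogram=histogram,
        eligible_voxels=histogram.total,
        shrink_factor=factor,
        params=params,
    )
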