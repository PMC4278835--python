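"""Independent brute-force reference implementations used as test oracles.

Deliberately written as naive nested loops, sharing no code with the
package, so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_bin_shrink(values: np.ndarray, f: int) -> np.ndarray:
    """Triple-loop block mean; partial boundary bins average present voxels."""
    nx, ny, nz = values.shape
    ox, oy, oz = math.ceil(nx / f), math.ceil(ny / f), math.ceil(nz / f)
    out = np.empty((ox, oy, oz), dtype=np.float64)
    for i in range(ox):
        for j in range(oy):
            for k in range(oz):
                block = values[i * f:(i + 1) * f, j * f:(j + 1) * f, k * f:(k + 1) * f]
                finite = block[np.isfinite(block)]
                out[i, j, k] = finite.mean() if finite.size else np.nan
    return out


def brute_force_temporal_extremum(stack: np.ndarray):
    """Per-voxel scan over phases; earliest phase wins exact ties."""
    P, nx, ny, nz = stack.shape
    max_values = np.empty((nx, ny, nz))
    argmax_phases = np.empty((nx, ny, nz), dtype=np.int64)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                best, best_p = stack[0, i, j, k], 1
                for p in range(1, P):
                    if stack[p, i, j, k] > best:
                        best, best_p = stack[p, i, j, k], p + 1
                max_values[i, j, k] = best
                argmax_phases[i, j, k] = best_p
    return max_values, argmax_phases


def reference_detect(stack: np.ndarray, hu_lower: float, hu_upper: float,
                     increase_mode: str, increase_value: float,
                     matrix_size: int):
    """End-to-end nested-loop re-statement of the detection pipeline.

    Takes the raw (P, nx, ny, nz) stack; returns (detected_phase_or_None,
    counts array indexed by phase-1, shrink_factor).
    """
    P = stack.shape[0]
    f = max(1, stack.shape[1] // matrix_size)
    shrunk = np.stack([brute_force_bin_shrink(stack[p], f) for p in range(P)])
    max_values, argmax_phases = brute_force_temporal_extremum(shrunk)
    counts = np.zeros(P, dtype=np.int64)
    nx, ny, nz = shrunk.shape[1:]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                first = shrunk[0, i, j, k]
                if not (hu_lower <= first <= hu_upper):
                    continue
                m = max_values[i, j, k]
                if increase_mode == "relative":
                    ok = m >= first * (1.0 + increase_value)
                else:
                    ok = m >= first + increase_value
                if ok:
                    counts[argmax_phases[i, j, k] - 1] += 1
    detected = int(np.argmax(counts)) + 1 if counts.any() else None
    return detected, counts, f
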