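"""Synthetic 4D cardiac first-pass contrast phantom.

Emulates the acquisition protocol of a dynamic whole-heart CT perfusion
study: one volume per RR-interval during a dynamic window, followed by a
few late single acquisitions, ~14-26 phases in total. The scan begins
with contrast already high in the right ventricle (RV); RV enhancement
washes out while left-ventricle (LV) enhancement rises to a later peak.

Chamber enhancement follows a gamma-variate bolus curve — the standard
first-pass model — added to a blood baseline inside two ellipsoidal
chambers, surrounded by a static myocardial shell, soft-tissue
background and low-attenuation lung slabs. Additive Gaussian noise is
drawn from a seeded generator, so identical parameters give
byte-identical datasets. The ground truth (the phase at which the
sampled LV curve peaks) is returned alongside the dataset, making every
other module testable without patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import Dataset4D, InvalidParameterError, Volume3D

__all__ = [
    "GammaVariateParams",
    "EllipsoidGeometry",
    "PhantomParams",
    "PhantomTruth",
    "gamma_variate",
    "generate_phantom",
    "save_phantom",
]


@dataclass(frozen=True)
class GammaVariateParams:
    """Gamma-variate bolus curve, normalized so its maximum is ``amplitude``.

    ``t0`` is the arrival time (s); the curve is zero before it. ``alpha``
    (shape) and ``beta`` (scale, s) set rise and washout; the peak falls
    at ``t0 + alpha * beta``. ``amplitude`` is the peak HU enhancement.
    """

    t0: float
    alpha: float
    beta: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidParameterError("alpha must be > 0")
        if not self.beta > 0:
            raise InvalidParameterError("beta must be > 0")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")


def gamma_variate(t: float | np.ndarray, p: GammaVariateParams) -> np.ndarray:
    """Evaluate the normalized gamma-variate enhancement at time(s) ``t``.

    ``0`` for ``t <= t0``; otherwise
    ``amplitude * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)``,
    whose analytic maximum ``amplitude`` occurs at ``t = t0 + alpha*beta``.
    """
    t = np.asarray(t, dtype=np.float64)
    dt = t - p.t0
    with np.errstate(invalid="ignore", divide="ignore"):
        shaped = np.where(
            dt > 0,
            p.amplitude
            * np.power(np.clip(dt, 0, None) / (p.alpha * p.beta), p.alpha)
            * np.exp(p.alpha - np.clip(dt, 0, None) / p.beta),
            0.0,
        )
    return shaped


@dataclass(frozen=True)
class EllipsoidGeometry:
    """Axis-aligned ellipsoid: centre and semi-axes in voxel units."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise InvalidParameterError("semi-axes must be positive")

    def mask(self, extents: tuple[int, int, int]) -> np.ndarray:
        gx, gy, gz = np.ogrid[: extents[0], : extents[1], : extents[2]]
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return (
            ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2
        ) <= 1.0

    def inside(self, extents: tuple[int, int, int]) -> bool:
        return all(
            c - a >= 0 and c + a <= n - 1
            for c, a, n in zip(self.center, self.semi_axes, extents)
        )


# Curve timings are tied to the default 0.8 s RR-interval: the LV peak at
# t0 + alpha*beta = 7.2 s samples exactly at phase 10; the RV curve
# arrives before acquisition start (t0 < 0) and has largely washed out by
# the LV peak.
_DEFAULT_RV_CURVE = GammaVariateParams(t0=-2.0, alpha=3.0, beta=1.2, amplitude=400.0)
_DEFAULT_LV_CURVE = GammaVariateParams(t0=2.0, alpha=3.0, beta=(7.2 - 2.0) / 3.0, amplitude=300.0)


@dataclass
class PhantomParams:
    """Phantom geometry, protocol, tissue constants and noise.

    ``n_phases`` is the total phase count: the dynamic window contributes
    ``n_phases - len(late_phase_offsets)`` acquisitions, one per
    ``rr_interval``; the late phases follow at the given offsets (s)
    after the last dynamic acquisition. ``rv_arrival_delay`` shifts the
    RV bolus arrival later (s); the default 0 reproduces the clinical
    protocol where contrast is already high in the RV at scan start, a
    positive value emulates an acquisition that begins before RV
    arrival (a known misdetection risk).
    """

    extents: tuple[int, int, int] = (64, 64, 48)
    n_phases: int = 20
    rr_interval: float = 0.8
    late_phase_offsets: tuple[float, ...] = (10.0, 20.0, 35.0)
    lv_geometry: EllipsoidGeometry = field(
        default_factory=lambda: EllipsoidGeometry((22.0, 32.0, 24.0), (10.0, 12.0, 14.0))
    )
    rv_geometry: EllipsoidGeometry = field(
        default_factory=lambda: EllipsoidGeometry((45.0, 32.0, 24.0), (9.0, 11.0, 13.0))
    )
    myocardium_thickness: float = 3.0
    lung_margin: int = 8
    myocardium_hu: float = 50.0
    blood_baseline_hu: float = 40.0
    lung_hu: float = -800.0
    background_hu: float = 50.0
    rv_curve: GammaVariateParams = field(default_factory=lambda: _DEFAULT_RV_CURVE)
    lv_curve: GammaVariateParams = field(default_factory=lambda: _DEFAULT_LV_CURVE)
    rv_arrival_delay: float = 0.0
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise InvalidParameterError("n_phases must be >= 2")
        if self.n_phases <= len(self.late_phase_offsets):
            raise InvalidParameterError("n_phases must exceed the number of late phases")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.rr_interval <= 0:
            raise InvalidParameterError("rr_interval must be > 0")
        offs = tuple(float(o) for o in self.late_phase_offsets)
        if any(b <= a for a, b in zip(offs, offs[1:])) or any(o <= 0 for o in offs):
            raise InvalidParameterError("late_phase_offsets must be positive and increasing")
        for name, geo in (("lv", self.lv_geometry), ("rv", self.rv_geometry)):
            if not geo.inside(self.extents):
                raise InvalidParameterError(f"{name} ellipsoid extends outside the grid")
        if (self.lv_geometry.mask(self.extents) & self.rv_geometry.mask(self.extents)).any():
            raise InvalidParameterError("LV and RV ellipsoids overlap")

    def phase_times(self) -> np.ndarray:
        """Acquisition time stamps (s): dynamic window then late phases."""
        n_dyn = self.n_phases - len(self.late_phase_offsets)
        dyn = np.arange(n_dyn) * self.rr_interval
        late = dyn[-1] + np.asarray(self.late_phase_offsets, dtype=np.float64)
        return np.concatenate([dyn, late])

    def effective_rv_curve(self) -> GammaVariateParams:
        return replace(self.rv_curve, t0=self.rv_curve.t0 + self.rv_arrival_delay)


@dataclass
class PhantomTruth:
    """Ground truth recorded at generation time.

    Peak phases are 1-based argmaxes of the *sampled* (noiseless) chamber
    curves; ``lv_hu`` / ``rv_hu`` are the per-phase chamber attenuations
    (baseline plus enhancement).
    """

    lv_peak_phase: int
    rv_peak_phase: int
    lv_hu: list[float]
    rv_hu: list[float]
    phase_times: list[float]

    def to_dict(self) -> dict:
        return {
            "lv_peak_phase": self.lv_peak_phase,
            "rv_peak_phase": self.rv_peak_phase,
            "lv_hu": self.lv_hu,
            "rv_hu": self.rv_hu,
            "phase_times": self.phase_times,
        }


def generate_phantom(params: PhantomParams | None = None) -> tuple[Dataset4D, PhantomTruth]:
    """Generate a seeded 4D phantom and its ground truth.

    Each phase volume is soft-tissue background with lung slabs at both
    x-edges, a static myocardial shell around the LV, and the two blood
    pools at ``blood_baseline_hu`` plus their bolus curves sampled at the
    phase time. Zero-mean Gaussian noise (``noise_sigma`` HU) is added
    from ``numpy.random.default_rng(seed)``.
    """
    if params is None:
        params = PhantomParams()
    times = params.phase_times()
    rv_curve = params.effective_rv_curve()
    lv_enh = gamma_variate(times, params.lv_curve)
    rv_enh = gamma_variate(times, rv_curve)
    lv_hu = params.blood_baseline_hu + lv_enh
    rv_hu = params.blood_baseline_hu + rv_enh

    nx, ny, nz = params.extents
    lv_mask = params.lv_geometry.mask(params.extents)
    rv_mask = params.rv_geometry.mask(params.extents)
    myo = EllipsoidGeometry(
        params.lv_geometry.center,
        tuple(a + params.myocardium_thickness for a in params.lv_geometry.semi_axes),
    )
    myo_mask = myo.mask(params.extents) & ~lv_mask & ~rv_mask
    lung_mask = np.zeros(params.extents, dtype=bool)
    if params.lung_margin > 0:
        lung_mask[: params.lung_margin, :, :] = True
        lung_mask[nx - params.lung_margin :, :, :] = True
    lung_mask &= ~(lv_mask | rv_mask | myo_mask)

    base = np.full(params.extents, params.background_hu, dtype=np.float64)
    base[lung_mask] = params.lung_hu
    base[myo_mask] = params.myocardium_hu

    rng = np.random.default_rng(params.seed)
    phases = []
    for k in range(params.n_phases):
        vol = base.copy()
        vol[lv_mask] = lv_hu[k]
        vol[rv_mask] = rv_hu[k]
        if params.noise_sigma > 0:
            vol += rng.normal(0.0, params.noise_sigma, size=params.extents)
        phases.append(Volume3D(vol))

    truth = PhantomTruth(
        lv_peak_phase=int(np.argmax(lv_hu)) + 1,
        rv_peak_phase=int(np.argmax(rv_hu)) + 1,
        lv_hu=[float(v) for v in lv_hu],
        rv_hu=[float(v) for v in rv_hu],
        phase_times=[float(t) for t in times],
    )
    return Dataset4D(phases, acquisition_times=list(times)), truth


def save_phantom(
    dataset: Dataset4D, truth: PhantomTruth, params: PhantomParams, path: str | Path
) -> Path:
    """Write the phantom as a 4D NIfTI plus a JSON ground-truth sidecar.

    Returns the sidecar path (``<stem>.truth.json`` next to the image).
    """
    from .io import write_dataset

    path = Path(path)
    write_dataset(dataset, path)
    sidecar = path.with_name(path.name.removesuffix(".nii.gz").removesuffix(".nii") + ".truth.json")
    payload = {
        "truth": truth.to_dict(),
        "params": {
            "extents": list(params.extents),
            "n_phases": params.n_phases,
            "rr_interval": params.rr_interval,
            "late_phase_offsets": list(params.late_phase_offsets),
            "noise_sigma": params.noise_sigma,
            "seed": params.seed,
        },
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return sidecar
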