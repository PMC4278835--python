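"""Agreement statistics for phase detection against reader references.

A case's reference is the (possibly multi-element) set of phases that
both human readers accepted; the detector agrees when its phase lies in
that set, and a failure to detect any phase counts as disagreement.
Agreement ratios get exact Clopper-Pearson binomial confidence intervals
(built from inverse cumulative-beta quantiles, hence asymmetric near 0
and 1); per-case detection durations get normal-approximation intervals;
pairwise timing comparisons across matrix sizes use paired t tests at a
Bonferroni-corrected significance level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .core import InvalidInputError, InvalidParameterError

__all__ = [
    "CaseOutcome",
    "AgreementSummary",
    "agreement",
    "clopper_pearson_ci",
    "mean_ci_normal",
    "bonferroni_alpha",
    "format_percent",
    "load_manifest",
    "pairwise_timing_tests",
]


@dataclass(frozen=True)
class CaseOutcome:
    """One case: the detected phase (or None) and the acceptable set."""

    case_id: str
    detected_phase: int | None
    reference_phases: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_phases", frozenset(int(p) for p in self.reference_phases))
        if not self.reference_phases:
            raise InvalidInputError(f"case {self.case_id}: reference phase set is empty")

    @property
    def success(self) -> bool:
        return self.detected_phase is not None and self.detected_phase in self.reference_phases


@dataclass
class AgreementSummary:
    """Successes ``x`` out of ``n`` cases, ratio, optional CI bounds."""

    x: int
    n: int
    ratio: float
    ci: tuple[float, float] | None = None
    level: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise InvalidInputError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")
        if self.ci is not None:
            lo, hi = self.ci
            if not (0.0 <= lo <= self.ratio <= hi <= 1.0):
                raise InvalidInputError(f"CI ({lo}, {hi}) inconsistent with ratio {self.ratio}")


def agreement(outcomes: list[CaseOutcome], level: float | None = 0.95) -> AgreementSummary:
    """Fraction of cases whose detected phase lies in the reference set.

    Every case counts toward the denominator; a no-detection is a
    failure. ``level=None`` skips the confidence interval.
    """
    if not outcomes:
        raise InvalidInputError("agreement over an empty case list is undefined")
    x = sum(o.success for o in outcomes)
    n = len(outcomes)
    ci = clopper_pearson_ci(x, n, level) if level is not None else None
    return AgreementSummary(x=x, n=n, ratio=x / n, ci=ci, level=level)


def clopper_pearson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI from inverse-beta quantiles.

    lower = Beta^{-1}(alpha/2; x, n-x+1) (0 when x = 0),
    upper = Beta^{-1}(1-alpha/2; x+1, n-x) (1 when x = n),
    with alpha = 1 - level. The interval is asymmetric in general and
    conservative: coverage is at least the nominal level.
    """
    if int(n) != n or n < 1:
        raise InvalidParameterError(f"n must be a positive integer, got {n}")
    if int(x) != x or not 0 <= x <= n:
        raise InvalidParameterError(f"x must be an integer in [0, {n}], got {x}")
    if not 0.0 < level < 1.0:
        raise InvalidParameterError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lower, upper


def mean_ci_normal(samples: list[float] | np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a symmetric normal-approximation CI: mean +/- z * sd/sqrt(n)."""
    arr = np.asarray(samples, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidInputError("mean_ci_normal needs at least 2 samples")
    if not 0.0 < level < 1.0:
        raise InvalidParameterError(f"level must be in (0, 1), got {level}")
    mean = float(arr.mean())
    half = float(stats.norm.ppf(0.5 + level / 2.0) * arr.std(ddof=1) / np.sqrt(arr.size))
    return mean, mean - half, mean + half


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha/m for m comparisons."""
    if int(m) != m or m < 1:
        raise InvalidParameterError(f"m must be a positive integer, got {m}")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / m


def format_percent(ratio: float) -> int:
    """Whole-percent display rounding, half away from zero (55.17% -> 55)."""
    return int(Decimal(ratio * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def pairwise_timing_tests(
    durations_by_size: dict[int, list[float]], alpha: float = 0.05
) -> list[dict]:
    """Two-sided paired t tests of per-case durations between matrix sizes.

    All ``C(k, 2)`` pairs are tested; each entry reports the p-value and
    whether it falls below the Bonferroni-corrected threshold
    ``alpha / C(k, 2)``.
    """
    sizes = sorted(durations_by_size)
    pairs = list(combinations(sizes, 2))
    if not pairs:
        return []
    threshold = bonferroni_alpha(alpha, len(pairs))
    out = []
    for a, b in pairs:
        da = np.asarray(durations_by_size[a], dtype=np.float64)
        db = np.asarray(durations_by_size[b], dtype=np.float64)
        if da.shape != db.shape:
            raise InvalidInputError(f"paired test needs equal case counts for sizes {a} and {b}")
        t, p = stats.ttest_rel(da, db)
        out.append(
            {
                "sizes": [a, b],
                "t": float(t),
                "p": float(p),
                "significant": bool(p < threshold),
                "threshold": threshold,
            }
        )
    return out


def load_manifest(path: str | Path) -> list[dict]:
    """Read a case manifest: JSON list or delimited text.

    JSON: ``[{"case_id": ..., "path": ..., "reference_phases": [...]}]``.
    Delimited text (TSV/CSV): columns ``case_id``, ``path``,
    ``reference_phases`` with the phase list comma- or
    semicolon-separated within the field.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        entries = json.loads(text)
    else:
        sep = "\t" if "\t" in text.splitlines()[0] else ","
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = [h.strip() for h in lines[0].split(sep)]
        entries = []
        for ln in lines[1:]:
            fields = [f.strip() for f in ln.split(sep)]
            row = dict(zip(header, fields))
            row["reference_phases"] = [
                int(p) for p in row["reference_phases"].replace(";", ",").split(",") if p
            ]
            entries.append(row)
    for e in entries:
        if not {"case_id", "path", "reference_phases"} <= e.keys():
            raise InvalidInputError(f"manifest entry missing required keys: {e}")
        e["reference_phases"] = [int(p) for p in e["reference_phases"]]
    return entries
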