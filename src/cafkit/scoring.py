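"""Quantitative immunohistochemistry scoring primitives.

Implements the tumor-level IHC quantifications used throughout the
package: the H-score (percent of stained cells weighted by staining
intensity 0-3, hence a value in [0, 300]), marker dichotomization at the
cohort median, a three-category FAP stratification, immune-cell densities
per mm^2, CD31 vessel fraction normalized on stromal content, and a
semi-quantitative adiposity score.

Counts, stained-area percentages and intensity histograms are *inputs*
here; no cell detection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "IntensityHistogram",
    "HScore",
    "FieldMeasurement",
    "compute_h_score",
    "dichotomize_by_median",
    "stratify_3cat",
    "cell_density",
    "vessel_fraction",
    "adiposity_score",
]

#: Default immune-field area in mm^2 (x10 magnification field).
DEFAULT_FIELD_AREA_MM2 = 1.65

#: Default CD31 field area in mm^2. The source protocol prints an
#: implausible "1596 mm^2"; interpreted as 1.596 mm^2 and configurable.
DEFAULT_CD31_FIELD_AREA_MM2 = 1.596


@dataclass(frozen=True)
class IntensityHistogram:
    """Percent of scored cells at each staining intensity 0..3.

    Percents must be nonnegative and sum to 100. The degenerate
    single-intensity convention (all mass at one intensity) is the
    histogram ``{i: 100}``.
    """

    pct_at_intensity: Mapping[int, float]

    def __post_init__(self) -> None:
        pcts = dict(self.pct_at_intensity)
        if not set(pcts).issubset({0, 1, 2, 3}):
            raise ValueError(f"intensities must be in 0..3, got {sorted(pcts)}")
        vals = np.array([pcts.get(i, 0.0) for i in range(4)], dtype=float)
        if np.any(vals < 0):
            raise ValueError("percentages must be nonnegative")
        if abs(vals.sum() - 100.0) > 1e-9:
            raise ValueError(f"percentages must sum to 100, got {vals.sum()!r}")
        object.__setattr__(self, "pct_at_intensity", pcts)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pct_at_intensity.get(i, 0.0) for i in range(4)], dtype=float
        )


@dataclass(frozen=True)
class HScore:
    """An H-score value, bounded to [0, 300]."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 300.0:
            raise ValueError(f"H-score must lie in [0, 300], got {self.value}")

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class FieldMeasurement:
    """One microscope field: area and per-compartment quantities."""

    field_area: float  # mm^2
    count: int | None = None
    stained_area_pct: float | None = None
    stroma_percent: float | None = None
    compartment: str = "stromal"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.field_area <= 0:
            raise ValueError("field area must be positive")
        for name in ("stained_area_pct", "stroma_percent"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


def compute_h_score(hist: IntensityHistogram) -> HScore:
    """H-score = sum_i i * pct_at_intensity[i].

    The all-unstained histogram gives 0 and the all-intensity-3
    histogram gives 300; the score is linear in the histogram.
    """
    weights = np.arange(4, dtype=float)
    return HScore(float(weights @ hist.as_array()))


def _as_values(values: Iterable) -> np.ndarray:
    arr = np.asarray([float(v) for v in values], dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return arr


def dichotomize_by_median(values: Sequence) -> tuple[list[str], float]:
    """Label each value ``"low"`` (strictly below the median) or ``"high"``.

    The median is the linear-interpolation 50% quantile. When all values
    are equal every label is ``"high"`` (nothing is strictly below).

    Returns ``(labels, threshold)``.
    """
    arr = _as_values(values)
    if arr.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    med = float(np.quantile(arr, 0.5))
    labels = ["low" if v < med else "high" for v in arr]
    return labels, med


def stratify_3cat(
    values: Sequence, t1: float = 47.0, t2: float = 95.0
) -> list[str]:
    """Three-category stratification: low (<=t1), intermediate (t1,t2], high (>t2).

    Defaults reproduce the FAP H-score strata (low <= 47, intermediate
    47-95, high > 95).
    """
    if not t1 < t2:
        raise ValueError(f"thresholds must satisfy t1 < t2, got {t1} >= {t2}")
    arr = _as_values(values)
    out = []
    for v in arr:
        if v <= t1:
            out.append("low")
        elif v <= t2:
            out.append("intermediate")
        else:
            out.append("high")
    return out


def cell_density(total_count: float, fields: Sequence[FieldMeasurement]) -> float:
    """Cells per mm^2: total count divided by the summed field area."""
    if len(fields) == 0:
        raise ValueError("at least one field is required")
    if total_count < 0:
        raise ValueError("count must be nonnegative")
    area = float(sum(f.field_area for f in fields))
    if area <= 0:
        raise ValueError("total field area must be positive")
    return float(total_count) / area


def vessel_fraction(fields: Sequence[tuple[float, float]]) -> float:
    """Mean CD31+ area percent normalized by the stromal proportion.

    Each field is ``(cd31_area_pct, stroma_pct)``; the per-field value is
    ``cd31_area_pct / (stroma_pct / 100)`` and the mean over fields is
    returned. A field with zero stroma is rejected by index, since its
    normalized value is undefined.
    """
    if len(fields) == 0:
        raise ValueError("at least one field is required")
    vals = []
    for i, (cd31, stroma) in enumerate(fields):
        if not 0.0 <= cd31 <= 100.0:
            raise ValueError(f"field {i}: CD31 area percent out of [0, 100]")
        if not 0.0 <= stroma <= 100.0:
            raise ValueError(f"field {i}: stroma percent out of [0, 100]")
        if stroma == 0:
            raise ValueError(f"field {i}: stroma percent is zero")
        vals.append(cd31 / (stroma / 100.0))
    return float(np.mean(vals))


def adiposity_score(adipose_surface_pct: float) -> int:
    """Semi-quantitative adiposity of the stroma.

    0 for < 1% adipose surface, 1 for [1, 10], 2 for (10, 30], 3 above
    30%. The bins are half-open and exhaustive on [0, 100].
    """
    p = float(adipose_surface_pct)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"adipose surface percent must lie in [0, 100], got {p}")
    if p < 1.0:
        return 0
    if p <= 10.0:
        return 1
    if p <= 30.0:
        return 2
    return 3
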