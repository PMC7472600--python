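"""Calibration-curve quantitation of GC-FAME peak tables.

The chromatographic stages upstream (membrane isolation, lipid extraction,
transesterification, peak integration) are out of scope: input here is an
already-integrated peak-area table per sample plus a table of calibration
standards per fatty acid.  Quantitation proceeds in three steps:

1. an ordinary-least-squares straight line ``area = slope * conc + intercept``
   per fatty acid (:func:`fit_calibration`);
2. inversion of the line to back-calculate micrograms/mL per peak
   (:func:`quantify_peaks`);
3. closure of the ten cluster quantities to relative percentages summing to
   100 (:func:`relative_percentages`).

A coverage check records the fraction of total chromatogram area carried by
the cluster (healthy profiles sit above ~97%); failing samples are flagged
on the profile, never dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import registry as _registry
from .errors import (
    EmptyProfileError,
    InconsistentAreasError,
    InsufficientStandardsError,
    NonMonotoneCalibrationError,
    UncalibratedPeakError,
)
from .registry import FattyAcidDef

logger = logging.getLogger(__name__)

#: r-squared below which a calibration is logged as poor (not fatal).
R2_WARN_THRESHOLD = 0.995

#: Default minimum cluster share of total chromatogram area.
COVERAGE_THRESHOLD = 0.97


@dataclass(frozen=True)
class StandardPoint:
    """One calibration-standard injection: known concentration, measured area."""

    fa_code: str
    concentration_ug_ml: float
    area: float

    def __post_init__(self):
        if self.concentration_ug_ml <= 0:
            raise InsufficientStandardsError(
                f"{self.fa_code}: standard concentration must be positive"
            )
        if self.area <= 0:
            raise InsufficientStandardsError(
                f"{self.fa_code}: standard area must be positive"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    fa_code: str
    slope: float          # area units per (ug/mL)
    intercept: float      # area units
    r_squared: float
    n_points: int

    def quantity(self, area: float) -> float:
        """Back-calculate ug/mL from a peak area (may be negative; see caller)."""
        return (area - self.intercept) / self.slope


@dataclass(frozen=True)
class PeakTable:
    """Integrated peak areas for one sample.

    ``rows`` maps a cluster code (or ``"other"`` for pooled non-cluster area)
    to a non-negative area.  Run metadata (column, oven program, ...) rides
    along untouched.
    """

    sample_id: str
    rows: tuple[tuple[str, float], ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for code, area in self.rows:
            if area < 0:
                raise InconsistentAreasError(
                    f"{self.sample_id}: negative area for {code}"
                )
            if code != "other":
                if code in seen:
                    raise InconsistentAreasError(
                        f"{self.sample_id}: duplicate peak row for {code}"
                    )
                seen.add(code)

    def area_of(self, code: str) -> float | None:
        for c, a in self.rows:
            if c == code:
                return a
        return None


@dataclass(frozen=True)
class CompositionProfile:
    """One sample's quantified cluster composition.

    ``percent`` closes to 100 over the cluster; ``coverage_fraction`` is the
    cluster share of total chromatogram area (1.0 when no 'other' area was
    reported).
    """

    sample_id: str
    quantity_ug_ml: Mapping[str, float]
    percent: Mapping[str, float]
    coverage_fraction: float = 1.0
    coverage_pass: bool = True

    def percent_vector(self, registry: Sequence[FattyAcidDef] | None = None) -> np.ndarray:
        codes = _registry.cluster_codes(registry)
        return np.array([self.percent[c] for c in codes], dtype=float)


def fit_calibration(
    points: Sequence[StandardPoint], *, force_zero_intercept: bool = False
) -> CalibrationCurve:
    """Fit the straight-line detector response for one fatty acid.

    Requires at least 3 points on at least 2 distinct concentration levels.
    ``r_squared`` is the squared sample correlation between fitted and
    observed areas.  A non-positive fitted slope means the detector response
    is not usable for inversion and raises
    :class:`NonMonotoneCalibrationError`.
    """
    if len(points) < 3:
        raise InsufficientStandardsError(
            f"insufficient standards: need >= 3 points, got {len(points)}"
        )
    codes = {p.fa_code for p in points}
    if len(codes) != 1:
        raise InsufficientStandardsError(
            f"insufficient standards: mixed fa_codes {sorted(codes)}"
        )
    (code,) = codes
    x = np.array([p.concentration_ug_ml for p in points], dtype=float)
    y = np.array([p.area for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise InsufficientStandardsError(
            f"insufficient standards: need >= 2 distinct concentrations for {code}"
        )
    if force_zero_intercept:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        fitted = slope * x
        r = np.corrcoef(fitted, y)[0, 1] if np.std(fitted) > 0 else 0.0
        r2 = float(r * r)
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    if slope <= 0:
        raise NonMonotoneCalibrationError(
            f"non-monotone calibration for {code}: slope {slope:.4g}"
        )
    if r2 < R2_WARN_THRESHOLD:
        logger.warning(
            "calibration for %s has r^2 = %.4f (< %.3f)", code, r2, R2_WARN_THRESHOLD
        )
    return CalibrationCurve(code, slope, intercept, min(r2, 1.0), len(points))


def quantify_peaks(
    table: PeakTable,
    curves: Mapping[str, CalibrationCurve],
    registry: Sequence[FattyAcidDef] | None = None,
) -> dict[str, float]:
    """Back-calculate ug/mL for every cluster fatty acid in one sample.

    Quantities are ``(area - intercept) / slope``, clipped at zero (with a
    logged warning) when the area falls below the curve intercept.  A cluster
    peak missing from the table is treated as quantity zero with a warning; a
    cluster peak *present* without a curve is an error.
    """
    codes = _registry.cluster_codes(registry)
    out: dict[str, float] = {}
    for code in codes:
        area = table.area_of(code)
        if area is None:
            logger.warning(
                "%s: cluster peak %s absent from table; quantity set to 0",
                table.sample_id,
                code,
            )
            out[code] = 0.0
            continue
        curve = curves.get(code)
        if curve is None:
            raise UncalibratedPeakError(
                f"uncalibrated peak: {code} in sample {table.sample_id}"
            )
        q = curve.quantity(area)
        if q < 0:
            logger.warning(
                "%s: area %.4g below intercept for %s; quantity clipped to 0",
                table.sample_id,
                area,
                code,
            )
            q = 0.0
        out[code] = q
    return out


def relative_percentages(
    quantities: Mapping[str, float],
    registry: Sequence[FattyAcidDef] | None = None,
) -> dict[str, float]:
    """Close the cluster quantities to percentages summing to 100."""
    codes = _registry.cluster_codes(registry)
    total = math.fsum(quantities.get(c, 0.0) for c in codes)
    if total <= 0:
        raise EmptyProfileError("empty profile: all cluster quantities are zero")
    return {c: 100.0 * quantities.get(c, 0.0) / total for c in codes}


def coverage_check(
    cluster_area_sum: float,
    total_area_sum: float,
    threshold: float = COVERAGE_THRESHOLD,
) -> tuple[float, bool]:
    """Cluster share of total chromatogram area and whether it meets ``threshold``."""
    if cluster_area_sum <= 0:
        raise InconsistentAreasError("inconsistent areas: cluster area must be > 0")
    if total_area_sum < cluster_area_sum:
        raise InconsistentAreasError(
            "inconsistent areas: total area below cluster area"
        )
    fraction = cluster_area_sum / total_area_sum
    return fraction, fraction >= threshold


def profile_from_peaks(
    table: PeakTable,
    curves: Mapping[str, CalibrationCurve],
    registry: Sequence[FattyAcidDef] | None = None,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> CompositionProfile:
    """Full quantitation of one sample: quantities, closed percentages, coverage."""
    codes = set(_registry.cluster_codes(registry))
    quantities = quantify_peaks(table, curves, registry)
    percent = relative_percentages(quantities, registry)
    cluster_area = math.fsum(a for c, a in table.rows if c in codes)
    total_area = math.fsum(a for _, a in table.rows)
    fraction, ok = coverage_check(cluster_area, total_area, coverage_threshold)
    if not ok:
        logger.warning(
            "%s: cluster coverage %.4f below %.2f (flagged, retained)",
            table.sample_id,
            fraction,
            coverage_threshold,
        )
    return CompositionProfile(table.sample_id, quantities, percent, fraction, ok)
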