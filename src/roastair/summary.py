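"""Replicate summaries of SERs, storage-age trends, and particle-size statistics.

SER replicates are summarized on the arithmetic scale (mean, SD, CV) since
they are approximately normal across roasting replicates; particle Feret
diameters are summarized geometrically (GM, GSD) since particle-size
distributions are lognormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "SERGroup",
    "SERSummary",
    "ParticleSample",
    "GeometricSummary",
    "StorageTrend",
    "summarize_sers",
    "storage_trend",
    "geometric_summary",
    "feret_diameter",
]


@dataclass(frozen=True)
class SERGroup:
    """Replicate SERs for one (analyte, roast level, physical form) cell."""

    analyte: str
    roast_level: str
    physical_form: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise InvalidParameterError("SER group needs at least one value")
        if any(v < 0 for v in self.values):
            raise InvalidParameterError("SERs must be >= 0")


@dataclass(frozen=True)
class SERSummary:
    mean: float
    sd: float | None
    cv_percent: float | None
    minimum: float
    maximum: float
    n: int


@dataclass(frozen=True)
class ParticleSample:
    """Feret-diameter sample (cm) for one physical form."""

    physical_form: str
    diameters: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameters):
            raise InvalidParameterError("diameters must be > 0")


@dataclass(frozen=True)
class GeometricSummary:
    gm: float
    gsd: float | None
    minimum: float
    maximum: float
    n: int


@dataclass(frozen=True)
class StorageTrend:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n: int


def summarize_sers(group: SERGroup) -> SERSummary:
    """Arithmetic mean, sample SD (n-1), CV% and extremes of a replicate group.

    With a single replicate SD and CV are undefined (None).  A zero mean with
    positive spread makes the CV undefined and is rejected.
    """
    x = np.asarray(group.values, dtype=float)
    n = x.size
    mean = float(x.mean())
    if n == 1:
        return SERSummary(mean, None, None, float(x.min()), float(x.max()), 1)
    sd = float(x.std(ddof=1))
    if mean == 0.0 and sd > 0.0:
        raise InvalidParameterError("CV undefined: zero mean with nonzero spread")
    cv = 0.0 if sd == 0.0 else 100.0 * sd / mean
    return SERSummary(mean, sd, cv, float(x.min()), float(x.max()), n)


def storage_trend(records) -> StorageTrend:
    """Ordinary least squares of SER on storage day with a 95% CI on the slope.

    ``records`` is a sequence of (day, ser) pairs or a DataFrame with
    ``day``/``ser`` columns.  The CI uses the t distribution with n-2
    degrees of freedom; an exact linear fit has zero CI width.
    """
    if hasattr(records, "columns"):
        day = np.asarray(records["day"], dtype=float)
        ser = np.asarray(records["ser"], dtype=float)
    else:
        arr = np.asarray(list(records), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidParameterError("records must be (day, ser) pairs")
        day, ser = arr[:, 0], arr[:, 1]
    n = day.size
    if n < 3:
        raise InsufficientDataError("storage trend needs >= 3 records")
    if np.unique(day).size < 2:
        raise InvalidParameterError("storage days have no spread; slope undefined")
    fit = stats.linregress(day, ser)
    tcrit = stats.t.ppf(0.975, df=n - 2)
    half = tcrit * fit.stderr
    return StorageTrend(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci_low=float(fit.slope - half),
        slope_ci_high=float(fit.slope + half),
        n=n,
    )


def geometric_summary(sample: ParticleSample) -> GeometricSummary:
    """GM = exp(mean ln d), GSD = exp(SD ln d) (n-1 denominator), extremes."""
    d = np.asarray(sample.diameters, dtype=float)
    if d.size == 0:
        raise InsufficientDataError("empty particle sample")
    logs = np.log(d)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if d.size >= 2 else None
    return GeometricSummary(gm, gsd, float(d.min()), float(d.max()), int(d.size))


def _directional_width(pts: np.ndarray, angle_rad: float) -> float:
    u = np.array([math.cos(angle_rad), math.sin(angle_rad)])
    proj = pts @ u
    return float(proj.max() - proj.min())


def _max_pairwise_distance(pts: np.ndarray) -> float:
    # Exact rotating-caliper-equivalent answer: the maximum Feret diameter
    # equals the largest pairwise distance among convex-hull vertices.
    if len(pts) >= 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear/degenerate input: brute-force all points
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def feret_diameter(outline, direction="max") -> float:
    """Caliper width of a 2-D point set.

    For a numeric ``direction`` (degrees), the width of the projection onto
    that direction.  For ``"max"``, the maximum caliper width over all
    directions, computed exactly as the largest pairwise distance between
    convex-hull vertices (a 1-degree angle scan provides the bracket that
    this exact value always dominates).
    """
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InvalidParameterError("outline must contain >= 2 points in 2-D")
    if direction == "max":
        return _max_pairwise_distance(pts)
    angle = math.radians(float(direction))
    return _directional_width(pts, angle)
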