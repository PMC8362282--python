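"""Disc and nucleus cross-section geometry.

The transverse cross-section of an intervertebral disc is represented by a
closed polygon (:class:`Contour`) in millimetres.  The coordinate convention
is fixed package-wide: the x-axis is anteroposterior and increases
*posteriorly*, the y-axis points left-right, and the mid-sagittal line is the
horizontal line through the disc centroid.

Two dimensionless indicators summarise where the nucleus pulposus sits inside
the annulus fibrosus:

* ``P1`` — ratio of the mean anterior annulus width D1 to the mean posterior
  annulus width D2, both measured along the mid-sagittal line.  ``P1 > 1``
  means the nucleus sits posterior of the disc centre.
* ``P2`` — nucleus cross-sectional area as a fraction of the disc area.

The module measures (D1, D2) and areas from contours, aggregates measurement
records into (P1, P2), and solves the inverse problem: placing a nucleus
contour inside a given disc contour so that it realises prescribed ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely import contains_properly
from shapely.geometry import LineString, Polygon

from .exceptions import ContainmentError, GeometryError, InfeasiblePlacementError

__all__ = [
    "Contour",
    "MeasurementRecord",
    "RatioPair",
    "measure_edge_distances",
    "measure_areas",
    "compute_ratios",
    "place_nucleus",
    "read_contour_csv",
    "write_contour_csv",
    "read_measurement_csv",
    "write_measurement_csv",
    "records_to_frame",
]

_AREA_TOL = 1e-12

MEASUREMENT_COLUMNS = [
    "subject_id",
    "observer_id",
    "d1_mm",
    "d2_mm",
    "disc_area_mm2",
    "nucleus_area_mm2",
    "pfirrmann_grade",
]


@dataclass(frozen=True)
class Contour:
    """Closed 2D polygon (mm) bounding a disc or nucleus cross-section.

    Vertices are stored as an ``(n, 2)`` array and implicitly joined
    last-to-first.  The polygon must be simple (non-self-intersecting) with
    nonzero area; vertex orientation is irrelevant.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError(f"contour points must be (n, 2), got {pts.shape}")
        # drop an explicit closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise GeometryError("a contour needs at least 3 distinct vertices")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        poly = Polygon(pts)
        if not poly.is_valid:
            raise GeometryError("contour polygon is self-intersecting or invalid")
        if poly.area <= _AREA_TOL:
            raise GeometryError("contour has (near-)zero area")

    @cached_property
    def polygon(self) -> Polygon:
        """The shapely polygon backing this contour."""
        return Polygon(self.points)

    @property
    def area(self) -> float:
        """Enclosed area (mm^2), positive for either vertex orientation."""
        return self.polygon.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    @classmethod
    def ellipse(
        cls,
        semi_axis_ap: float,
        semi_axis_lat: float,
        n_vertices: int = 256,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "Contour":
        """Elliptical contour with AP semi-axis along x, lateral along y."""
        if semi_axis_ap <= 0 or semi_axis_lat <= 0:
            raise GeometryError("semi-axes must be positive")
        t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        pts = np.column_stack(
            [center[0] + semi_axis_ap * np.cos(t), center[1] + semi_axis_lat * np.sin(t)]
        )
        return cls(pts)

    @classmethod
    def circle(
        cls, radius: float, n_vertices: int = 256, center: tuple[float, float] = (0.0, 0.0)
    ) -> "Contour":
        return cls.ellipse(radius, radius, n_vertices=n_vertices, center=center)

    def scaled(self, factor: float, origin: tuple[float, float] | None = None) -> "Contour":
        """Similarity-scale about ``origin`` (default: own centroid)."""
        if factor <= 0:
            raise GeometryError("scale factor must be positive")
        ox, oy = origin if origin is not None else self.centroid
        o = np.array([ox, oy])
        return Contour(o + factor * (self.points - o))

    def translated(self, dx: float, dy: float = 0.0) -> "Contour":
        return Contour(self.points + np.array([dx, dy]))


@dataclass(frozen=True)
class MeasurementRecord:
    """One observer's measurements of one subject's disc."""

    subject_id: str
    observer_id: str
    d1_mm: float
    d2_mm: float
    disc_area_mm2: float
    nucleus_area_mm2: float
    pfirrmann_grade: int

    def __post_init__(self) -> None:
        if self.d1_mm <= 0 or self.d2_mm <= 0:
            raise ValueError("D1 and D2 must be positive")
        if not 0 < self.nucleus_area_mm2 < self.disc_area_mm2:
            raise ValueError("need 0 < nucleus area < disc area")
        if self.pfirrmann_grade not in {1, 2, 3, 4, 5}:
            raise ValueError("Pfirrmann grade must be an integer in 1..5")


@dataclass(frozen=True)
class RatioPair:
    """The derived indicators P1 (position ratio) and P2 (area fraction).

    Values are stored at full precision; rounding to two decimals (P1) and a
    whole percent (P2) happens only at report time via the properties below.
    """

    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.p1 <= 0:
            raise ValueError("P1 must be positive")
        if not 0 < self.p2 < 1:
            raise ValueError("P2 must lie in (0, 1)")

    @property
    def p1_report(self) -> float:
        """P1 rounded to two decimals, as printed in reports."""
        return round(self.p1, 2)

    @property
    def p2_percent(self) -> int:
        """P2 as a whole percent, as printed in reports."""
        return int(round(self.p2 * 100.0))


def _midline_span(contour: Contour, y: float) -> tuple[float, float]:
    """Extent [x_min, x_max] of the contour along the horizontal line at y."""
    minx, miny, maxx, maxy = contour.polygon.bounds
    if not (miny < y < maxy):
        raise GeometryError("mid-sagittal line misses the contour")
    line = LineString([(minx - 1.0, y), (maxx + 1.0, y)])
    inter = contour.polygon.intersection(line)
    if inter.is_empty or inter.length <= 0:
        raise GeometryError("mid-sagittal line misses the contour interior")
    b = inter.bounds
    return (b[0], b[2])


def _require_containment(disc: Contour, nucleus: Contour) -> None:
    if not contains_properly(disc.polygon, nucleus.polygon):
        raise ContainmentError("nucleus contour is not strictly inside the disc contour")


def measure_edge_distances(disc: Contour, nucleus: Contour) -> tuple[float, float]:
    """Anterior (D1) and posterior (D2) annulus widths along the mid-sagittal line.

    The mid-sagittal line is the horizontal through the *disc* centroid.
    D1 is the distance from the anterior disc boundary to the anterior
    nucleus boundary; D2 is the posterior analogue.  Anterior is the -x
    direction.

    Raises
    ------
    ContainmentError
        If the nucleus is not strictly inside the disc.
    GeometryError
        If the mid-sagittal line misses the nucleus.
    """
    _require_containment(disc, nucleus)
    _, yc = disc.centroid
    d_lo, d_hi = _midline_span(disc, yc)
    n_lo, n_hi = _midline_span(nucleus, yc)
    d1 = n_lo - d_lo
    d2 = d_hi - n_hi
    if d1 <= 0 or d2 <= 0:
        raise GeometryError("nucleus touches or crosses the annulus on the mid-sagittal line")
    return (d1, d2)


def measure_areas(disc: Contour, nucleus: Contour) -> tuple[float, float]:
    """Cross-sectional areas (disc, nucleus) in mm^2 by the shoelace formula."""
    return (disc.area, nucleus.area)


def compute_ratios(records: Iterable[MeasurementRecord] | pd.DataFrame) -> RatioPair:
    """Aggregate measurement records into the (P1, P2) indicator pair.

    P1 is the ratio of the *mean* D1 to the *mean* D2 across records (a ratio
    of means, not a mean of per-record ratios), and P2 likewise the ratio of
    mean nucleus area to mean disc area.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(list(records))
    if len(frame) == 0:
        raise ValueError("compute_ratios needs at least one measurement record")
    if (frame["d2_mm"] <= 0).any() or (frame["d1_mm"] <= 0).any():
        raise ValueError("all D1/D2 values must be positive")
    p1 = frame["d1_mm"].mean() / frame["d2_mm"].mean()
    p2 = frame["nucleus_area_mm2"].mean() / frame["disc_area_mm2"].mean()
    return RatioPair(p1=float(p1), p2=float(p2))


def _placement_offset(disc: Contour, scaled: Contour, p1: float, yc: float) -> float:
    """AP offset making the measured D1/D2 of the translated nucleus equal p1.

    For contours whose mid-sagittal intersection is a single interval the
    offset has the closed form below; a bracketed root solve covers the rest.
    """
    d_lo, d_hi = _midline_span(disc, yc)
    n_lo, n_hi = _midline_span(scaled, yc)
    delta = (p1 * (d_hi - n_hi) + d_lo - n_lo) / (1.0 + p1)

    def ratio_residual(dx: float) -> float:
        s_lo, s_hi = _midline_span(scaled.translated(dx), yc)
        d1 = s_lo - d_lo
        d2 = d_hi - s_hi
        if d1 <= 0 or d2 <= 0:
            raise InfeasiblePlacementError(
                f"offset {dx:.4g} mm pushes the nucleus across the annulus boundary"
            )
        return d1 / d2 - p1

    # The closed form is exact unless the midline crosses a concavity; verify
    # and fall back to a root solve in that case.
    if abs(ratio_residual(delta)) > 1e-9 * p1:
        lo = d_lo - n_lo + 1e-9
        hi = d_hi - n_hi - 1e-9
        delta = brentq(ratio_residual, lo, hi, xtol=1e-12)
    return delta


def place_nucleus(disc: Contour, p1: float, p2: float) -> Contour:
    """Construct a nucleus contour inside ``disc`` realising (p1, p2).

    The disc contour is similarity-scaled about its centroid by sqrt(p2) —
    so the area fraction is exactly p2 — then translated along the
    anteroposterior axis by the unique offset that makes the measured D1/D2
    ratio equal p1.  Measuring the result recovers (p1, p2) to machine
    precision for convex discs.

    Raises
    ------
    InfeasiblePlacementError
        If the requested p1 pushes part of the nucleus outside the disc.
    """
    if not 0 < p2 < 1:
        raise ValueError("P2 must lie in (0, 1)")
    if p1 <= 0:
        raise ValueError("P1 must be positive")
    cx, cy = disc.centroid
    scaled = disc.scaled(np.sqrt(p2), origin=(cx, cy))
    delta = _placement_offset(disc, scaled, p1, cy)
    nucleus = scaled.translated(delta)
    if not contains_properly(disc.polygon, nucleus.polygon):
        raise InfeasiblePlacementError(
            f"P1={p1:.4g}, P2={p2:.4g} places part of the nucleus outside the disc"
        )
    return nucleus


# ---------------------------------------------------------------------------
# CSV interfaces


def read_contour_csv(path: str | Path) -> Contour:
    """Read an ordered-vertex contour from CSV with columns x_mm, y_mm."""
    frame = pd.read_csv(path)
    missing = {"x_mm", "y_mm"} - set(frame.columns)
    if missing:
        raise ValueError(f"contour CSV {path} lacks columns {sorted(missing)}")
    return Contour(frame[["x_mm", "y_mm"]].to_numpy(dtype=float))


def write_contour_csv(contour: Contour, path: str | Path) -> None:
    pd.DataFrame(contour.points, columns=["x_mm", "y_mm"]).to_csv(path, index=False)


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "observer_id": r.observer_id,
                "d1_mm": r.d1_mm,
                "d2_mm": r.d2_mm,
                "disc_area_mm2": r.disc_area_mm2,
                "nucleus_area_mm2": r.nucleus_area_mm2,
                "pfirrmann_grade": r.pfirrmann_grade,
            }
            for r in records
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def read_measurement_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"measurement CSV {path} lacks columns {sorted(missing)}")
    return frame[MEASUREMENT_COLUMNS]


def write_measurement_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame[MEASUREMENT_COLUMNS].to_csv(path, index=False)
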