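"""Contour data model and plaque/necrotic-core morphometry.

A cross-section is a set of nested closed contours (lumen, intima, media,
adventitia outer borders) plus one or two necrotic-core (NC) polygons lying in
the intima ring.  All morphometric quantities are defined from the perspective
of the lumen center: cap thickness (capT), intima-media thickness (IMT) and NC
thickness (NCt) are measured radially along rays cast from the lumen centroid,
and the NC angle is the angular span of the NC front side as seen from that
point.

Coordinates are 2D Cartesian in millimetres; contours are stored
counter-clockwise; angles are radians, counter-clockwise from the +x axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .errors import InvalidGeometryError

# Intersections closer than this along a ray are merged (vertex grazing).
_MERGE_TOL = 1e-9

COMPONENTS = ("lumen", "intima", "media", "adventitia", "nc")

SITE_NAMES = ("minus_sidecap", "midcap", "plus_sidecap")
# Fractions of the NC angular span at which the three measurement rays sit.
SITE_FRACTIONS = {"minus_sidecap": 0.25, "midcap": 0.50, "plus_sidecap": 0.75}


def _as_vertex_array(vertices: Iterable) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidGeometryError(f"vertices must be (N, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidGeometryError("non-finite vertex coordinates")
    # Drop an explicit closing vertex if present.
    if arr.shape[0] > 1 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    return arr


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise polygons."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Simple closed polygon belonging to one plaque component.

    Vertices are normalized to counter-clockwise order on construction.
    """

    vertices: np.ndarray
    component: str = "nc"

    def __post_init__(self):
        arr = _as_vertex_array(self.vertices)
        if arr.shape[0] < 3:
            raise InvalidGeometryError("contour needs at least 3 vertices")
        if self.component not in COMPONENTS:
            raise InvalidGeometryError(f"unknown component {self.component!r}")
        if signed_area(arr) < 0:
            arr = arr[::-1].copy()
        if signed_area(arr) <= 0:
            raise InvalidGeometryError("contour has non-positive area")
        object.__setattr__(self, "vertices", arr)
        poly = Polygon(arr)
        if not poly.is_valid:
            raise InvalidGeometryError("contour is self-intersecting")
        object.__setattr__(self, "_poly", poly)

    @property
    def polygon(self) -> Polygon:
        return self._poly  # type: ignore[attr-defined]

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


@dataclass(frozen=True)
class CrossSection:
    """One plaque slice: nested wall contours, NC polygons and cluster IDs."""

    section_id: str
    artery_id: str
    patient_id: str
    lumen: Contour
    intima_outer: Contour
    media_outer: Contour
    adventitia_outer: Contour
    ncs: tuple[Contour, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "ncs", tuple(self.ncs))
        if not 0 <= len(self.ncs) <= 2:
            raise InvalidGeometryError("a cross-section carries 0-2 NCs")
        rings = [self.lumen, self.intima_outer, self.media_outer, self.adventitia_outer]
        for inner, outer in zip(rings[:-1], rings[1:]):
            if not outer.polygon.contains(inner.polygon):
                raise InvalidGeometryError(
                    f"{inner.component} contour not strictly inside {outer.component}"
                )
        intima_ring = self.intima_outer.polygon.difference(self.lumen.polygon)
        for i, nc in enumerate(self.ncs):
            if not intima_ring.contains(nc.polygon):
                raise InvalidGeometryError(f"NC {i} not inside the intima ring")
        for i in range(len(self.ncs)):
            for j in range(i + 1, len(self.ncs)):
                if self.ncs[i].polygon.intersects(self.ncs[j].polygon):
                    raise InvalidGeometryError("NC polygons overlap")


@dataclass(frozen=True)
class SiteMeasurement:
    """Radial thickness measurements along one site ray."""

    site: str
    capT: float  # lumen boundary -> NC front, mm
    IMT: float  # lumen boundary -> media outer border, mm
    NCt: float  # NC front -> NC back, mm (0 when the back is absent)
    rNCt: float  # NCt / IMT
    ray_angle: float  # rad, CCW from +x about the lumen center


@dataclass(frozen=True)
class PlaqueFeatures:
    """Morphometric summary of one NC in one cross-section."""

    min_cap_thickness: float
    nc_angle: float  # rad
    sites: tuple[SiteMeasurement, SiteMeasurement, SiteMeasurement]
    lumen_center: np.ndarray
    span: tuple[float, float] = (0.0, 0.0)  # unwrapped (start, end) ray angles
    section_id: str = ""
    artery_id: str = ""
    patient_id: str = ""
    nc_index: int = 0

    def site(self, name: str) -> SiteMeasurement:
        for s in self.sites:
            if s.site == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------

def ray_polygon_hits(
    origin: np.ndarray, angle: float, vertices: np.ndarray
) -> np.ndarray:
    """All positive ray-parameter distances where the ray meets the polygon.

    Returns sorted distances (mm) of the ray ``origin + t*(cos a, sin a)``
    against every polygon edge; hits closer than 1 nm are merged.
    """
    o = np.asarray(origin, dtype=float)
    d = np.array([math.cos(angle), math.sin(angle)])
    p1 = vertices
    p2 = np.roll(vertices, -1, axis=0)
    e = p2 - p1  # (N, 2)
    w = o - p1
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 1] * e[:, 0] - w[:, 0] * e[:, 1]) / denom
        s = (d[0] * w[:, 1] - d[1] * w[:, 0]) / denom
    # Tolerant bounds on the edge parameter: a ray passing exactly through a
    # shared vertex must not slip between the two adjacent edges.
    mask = (
        (np.abs(denom) > 1e-14)
        & (s >= -1e-12)
        & (s < 1.0 + 1e-12)
        & (t > _MERGE_TOL)
    )
    hits = np.sort(t[mask])
    if hits.size > 1:
        keep = np.concatenate([[True], np.diff(hits) > _MERGE_TOL])
        hits = hits[keep]
    return hits


def ray_first_hit(
    origin: np.ndarray, angle: float, contour: Contour
) -> tuple[np.ndarray | None, float | None, np.ndarray]:
    """First boundary intersection of a ray with a contour.

    Returns ``(point, distance, all_distances)``; point and distance are None
    on a miss (the miss is a signal, not an error).
    """
    hits = ray_polygon_hits(np.asarray(origin, float), angle, contour.vertices)
    if hits.size == 0:
        return None, None, hits
    d = np.array([math.cos(angle), math.sin(angle)])
    return np.asarray(origin, float) + hits[0] * d, float(hits[0]), hits


def lumen_center(cs: CrossSection) -> np.ndarray:
    """Lumen center := area centroid of the lumen polygon."""
    if cs.lumen.area <= 0:
        raise InvalidGeometryError("degenerate lumen")
    return cs.lumen.centroid()


# ---------------------------------------------------------------------------
# NC front side
# ---------------------------------------------------------------------------

def _unwrap_about(angles: np.ndarray, ref: float) -> np.ndarray:
    """Map angles into (ref - pi, ref + pi]."""
    return ref + np.mod(angles - ref + math.pi, 2 * math.pi) - math.pi


def nc_front_side(
    cs: CrossSection, nc: Contour
) -> tuple[np.ndarray, tuple[float, float]]:
    """Lumen-visible front polyline of an NC and its angular span.

    Casts a ray from the lumen center through every NC vertex and keeps the
    vertex only if it is the first intersection of that ray with the NC
    boundary — exactly how a light-based catheter sees the core.  Retained
    vertices are returned ordered by ray angle together with the unwrapped
    (start, end) span defining the NC angle.
    """
    center = lumen_center(cs)
    verts = nc.vertices
    rel = verts - center
    radii = np.hypot(rel[:, 0], rel[:, 1])
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    # Unwrap about the NC centroid direction so spans crossing the +/-pi cut
    # stay contiguous.
    c = nc.centroid() - center
    ref = math.atan2(c[1], c[0])
    angles = _unwrap_about(angles, ref)

    keep = np.zeros(len(verts), dtype=bool)
    for i in range(len(verts)):
        hits = ray_polygon_hits(center, angles[i], verts)
        if hits.size == 0:
            continue
        keep[i] = radii[i] <= hits[0] + 1e-7
    if keep.sum() < 3:
        raise InvalidGeometryError("fewer than 3 front-side vertices retained")

    order = np.argsort(angles[keep], kind="stable")
    front = verts[keep][order]
    ang = angles[keep][order]
    # Ties at identical angles: keep the smaller radius.
    uniq_front, uniq_ang = [], []
    for p, a, r in zip(front, ang, radii[keep][order]):
        if uniq_ang and abs(a - uniq_ang[-1]) < 1e-12:
            prev = uniq_front[-1] - center
            if r < math.hypot(prev[0], prev[1]):
                uniq_front[-1] = p
        else:
            uniq_front.append(p)
            uniq_ang.append(a)
    front = np.asarray(uniq_front)
    return front, (float(uniq_ang[0]), float(uniq_ang[-1]))


def nc_angle_deg(span: tuple[float, float]) -> float:
    return math.degrees(span[1] - span[0])


# ---------------------------------------------------------------------------
# Site measurements
# ---------------------------------------------------------------------------

def _front_hit(center: np.ndarray, angle: float, front: np.ndarray) -> float:
    """Radial distance from center to an open front polyline along a ray."""
    d = np.array([math.cos(angle), math.sin(angle)])
    far = center + 1e3 * d
    ray = LineString([center, far])
    inter = ray.intersection(LineString(front))
    if inter.is_empty:
        raise InvalidGeometryError("site ray misses the NC front polyline")
    pts = []
    if inter.geom_type == "Point":
        pts = [inter]
    else:
        for g in getattr(inter, "geoms", []):
            if g.geom_type == "Point":
                pts.append(g)
            else:  # collinear overlap: use its nearest endpoint
                pts.extend(Point(c) for c in g.coords)
    return min(p.distance(Point(center)) for p in pts)


def site_measurements(
    cs: CrossSection,
    nc: Contour | None = None,
    front: np.ndarray | None = None,
    span: tuple[float, float] | None = None,
) -> tuple[SiteMeasurement, SiteMeasurement, SiteMeasurement]:
    """capT / IMT / NCt / rNCt at the three site rays (25 %, 50 %, 75 % of
    the NC angle).

    Pass the closed ``nc`` contour for ground-truth geometry (NCt measured
    front-to-back along the ray) or a front-only polyline for reconstructed
    inputs, where the backside is absent and NCt is reported as 0.
    """
    if nc is None and front is None:
        raise ValueError("provide a closed NC contour or a front polyline")
    center = lumen_center(cs)
    if front is None:
        front, span = nc_front_side(cs, nc)
    elif span is None:
        rel = front - center
        a = np.arctan2(rel[:, 1], rel[:, 0])
        a = _unwrap_about(a, float(np.median(a)))
        span = (float(a.min()), float(a.max()))

    start, end = span
    out = []
    for name in SITE_NAMES:
        theta = start + SITE_FRACTIONS[name] * (end - start)
        _, r_lum, _ = ray_first_hit(center, theta, cs.lumen)
        _, r_med, _ = ray_first_hit(center, theta, cs.media_outer)
        if r_lum is None or r_med is None:
            raise InvalidGeometryError("site ray misses lumen or media contour")
        if nc is not None:
            hits = ray_polygon_hits(center, theta, nc.vertices)
            if hits.size == 0:
                raise InvalidGeometryError("site ray misses the NC")
            r_front = float(hits[0])
            nct = float(hits[-1] - hits[0]) if hits.size > 1 else 0.0
        else:
            r_front = _front_hit(center, theta, front)
            nct = 0.0
        capt = r_front - r_lum
        imt = r_med - r_lum
        if capt <= 0 or imt <= 0:
            raise InvalidGeometryError("non-positive capT or IMT at a site ray")
        out.append(
            SiteMeasurement(
                site=name,
                capT=capt,
                IMT=imt,
                NCt=nct,
                rNCt=nct / imt,
                ray_angle=theta,
            )
        )
    return tuple(out)  # type: ignore[return-value]


def min_cap_thickness(
    cs: CrossSection,
    nc: Contour | None = None,
    front: np.ndarray | None = None,
    span: tuple[float, float] | None = None,
    step_deg: float = 0.25,
) -> tuple[float, np.ndarray]:
    """Minimum radial lumen-to-NC-front distance over the NC angular span.

    The span is sampled densely (default 0.25 deg) rather than only at vertex
    angles.  Returns the thickness and the NC-front point where it occurs.
    """
    center = lumen_center(cs)
    if front is None:
        front, span = nc_front_side(cs, nc)
    elif span is None:
        rel = front - center
        a = _unwrap_about(np.arctan2(rel[:, 1], rel[:, 0]), 0.0)
        span = (float(a.min()), float(a.max()))
    start, end = span
    n = max(3, int(math.ceil((end - start) / math.radians(step_deg))) + 1)
    thetas = np.linspace(start, end, n)
    front_line = LineString(front) if nc is None else None
    best, best_pt = math.inf, None
    for theta in thetas:
        _, r_lum, _ = ray_first_hit(center, theta, cs.lumen)
        if r_lum is None:
            continue
        if nc is not None:
            hits = ray_polygon_hits(center, theta, nc.vertices)
            if hits.size == 0:
                continue
            r_front = float(hits[0])
        else:
            d = np.array([math.cos(theta), math.sin(theta)])
            inter = LineString([center, center + 1e3 * d]).intersection(front_line)
            if inter.is_empty:
                continue
            r_front = Point(center).distance(inter)
        t = r_front - r_lum
        if t < best:
            best = t
            best_pt = center + r_front * np.array([math.cos(theta), math.sin(theta)])
    if best_pt is None:
        raise InvalidGeometryError("no ray in the span hits both lumen and NC front")
    return float(best), best_pt


def characterize(cs: CrossSection) -> list[PlaqueFeatures]:
    """Full morphometry of every NC in a cross-section."""
    out = []
    for i, nc in enumerate(cs.ncs):
        front, span = nc_front_side(cs, nc)
        sites = site_measurements(cs, nc=nc)
        mct, _ = min_cap_thickness(cs, nc=nc)
        out.append(
            PlaqueFeatures(
                min_cap_thickness=mct,
                nc_angle=span[1] - span[0],
                sites=sites,
                lumen_center=lumen_center(cs),
                span=span,
                section_id=cs.section_id,
                artery_id=cs.artery_id,
                patient_id=cs.patient_id,
                nc_index=i,
            )
        )
    return out
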