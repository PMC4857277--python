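"""Backside reconstruction of a necrotic core from its visible front.

Given the lumen-visible NC front polyline, the method:

1. converts relative NC thickness estimates (rNCt, either group medians or a
   plaque-specific regression prediction) to absolute thicknesses at the
   three site rays and places back points behind the front,
2. attaches a circular arc to each NC edge (NCs have rounded edges); the arc
   center comes from a two-circle construction anchored at the edge vertex,
   the arc radius scales with the NC angle (0.14 mm per radian) and its
   angular extent is 30 degrees,
3. closes the backside with a polynomial forced through the two arc free
   ends and the three back points, and
4. clips any part of the closed NC protruding past the intima, leaving a
   thin clearance layer (10 um) so the NC never touches the media.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .errors import ReconstructionError
from .gee import GEECoefficients, predict_rnct
from .geometry import (
    Contour,
    CrossSection,
    PlaqueFeatures,
    SiteMeasurement,
    lumen_center,
    ray_first_hit,
    site_measurements,
)


@dataclass(frozen=True)
class ReconstructionParams:
    arc_angle_deg: float = 30.0  # angular extent of each edge arc
    arc_radius_coeff: float = 0.14  # mm of arc radius per rad of NC angle
    media_clearance_mm: float = 0.010  # gap kept between NC and media
    closure_degree: int = 4
    circle1_radius_mm: float | None = None  # None -> use the final arc radius
    arc_points: int = 16
    backside_points: int = 80

    def __post_init__(self):
        if self.arc_angle_deg <= 0 or self.arc_radius_coeff <= 0:
            raise ReconstructionError("arc parameters must be positive")
        if self.media_clearance_mm < 0:
            raise ReconstructionError("media clearance must be non-negative")


@dataclass(frozen=True)
class GroupAverages:
    """Cohort median rNCt at midcap and (pooled) sidecap positions."""

    rnct_mid: float = 0.40
    rnct_side: float = 0.35

    def __post_init__(self):
        if not (0 < self.rnct_mid < 1 and 0 < self.rnct_side < 1):
            raise ReconstructionError("group-average rNCt must lie in (0, 1)")


@dataclass(frozen=True)
class ReconstructionResult:
    nc_polygon: Contour
    method: str
    rnct_used: tuple[float, float]  # (mid, side-average) actually applied
    clipped_to_media: bool
    params: ReconstructionParams
    flags: tuple[str, ...] = ()


def group_average_rnct(features: list[PlaqueFeatures]) -> GroupAverages:
    """Median midcap rNCt and median of the pooled +/- sidecap rNCt."""
    if not features:
        raise ReconstructionError("no features to average")
    mids = [f.site("midcap").rNCt for f in features]
    sides = [f.site(s).rNCt for f in features
             for s in ("minus_sidecap", "plus_sidecap")]
    return GroupAverages(rnct_mid=float(np.median(mids)),
                         rnct_side=float(np.median(sides)))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def back_points(
    center: np.ndarray,
    sites: tuple[SiteMeasurement, ...],
    rnct: tuple[float, float],
    lumen_radii: dict[str, float],
) -> dict[str, np.ndarray]:
    """Back point per site ray: front hit + rNCt x IMT radially outward."""
    rnct_mid, rnct_side = rnct
    out = {}
    for s in sites:
        rn = rnct_mid if s.site == "midcap" else rnct_side
        r_back = lumen_radii[s.site] + s.capT + rn * s.IMT
        d = np.array([math.cos(s.ray_angle), math.sin(s.ray_angle)])
        out[s.site] = center + r_back * d
    return out


def _circle_circle_intersections(c1, r1, c2, r2):
    d = float(np.hypot(*(c2 - c1)))
    if d > r1 + r2 or d < abs(r1 - r2) or d == 0:
        return []
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h2 = r1**2 - a**2
    if h2 < 0:
        return []
    h = math.sqrt(max(h2, 0.0))
    u = (c2 - c1) / d
    m = c1 + a * u
    n = np.array([-u[1], u[0]])
    return [m + h * n, m - h * n]


def edge_arc(
    front: np.ndarray,
    which: str,
    nc_angle: float,
    cs: CrossSection,
    params: ReconstructionParams,
) -> tuple[np.ndarray, bool]:
    """Rounded-edge arc attached to one end of the front polyline.

    Implements the two-circle construction: circle 1 sits at the NC edge
    vertex; its intersection with the cap (front polyline extended toward the
    lumen along the edge ray) centers circle 2; of the two circle-circle
    intersections the one most distant from the lumen centers the final arc.
    Returns the arc polyline starting at the edge vertex, plus a flag marking
    the quarter-arc fallback.
    """
    center = lumen_center(cs)
    r3 = params.arc_radius_coeff * nc_angle
    r1 = params.circle1_radius_mm if params.circle1_radius_mm is not None else r3
    E = front[0] if which == "left" else front[-1]
    ang_E = math.atan2(E[1] - center[1], E[0] - center[0])
    u_rad = np.array([math.cos(ang_E), math.sin(ang_E)])
    _, r_lum, _ = ray_first_hit(center, ang_E, cs.lumen)
    cap_len = float(np.hypot(*(E - center))) - (r_lum or 0.0)

    P = None
    if r_lum is not None and r1 < cap_len:
        # Intersection of circle 1 with the cap extension toward the lumen.
        P = E - r1 * u_rad
    else:
        # Circle 1 crosses the lumen along the edge ray; intersect it with the
        # front polyline instead.
        circle = Point(E).buffer(r1, quad_segs=64).exterior
        inter = circle.intersection(LineString(front))
        pts = []
        if not inter.is_empty:
            geoms = inter.geoms if hasattr(inter, "geoms") else [inter]
            pts = [np.array([g.x, g.y]) for g in geoms if g.geom_type == "Point"]
        if pts:
            P = min(pts, key=lambda p: np.hypot(*(p - E)))

    fallback = False
    C = None
    if P is not None:
        cands = _circle_circle_intersections(E, r1, P, r1)
        if cands:
            lum_poly = cs.lumen.polygon
            dists = [lum_poly.exterior.distance(Point(c)) for c in cands]
            if abs(dists[0] - dists[1]) > 1e-9:
                C = cands[int(np.argmax(dists))]
            else:
                # Exact tie (concentric geometry): take the candidate farther
                # from the middle of the NC front, i.e. beyond the edge.
                midf = front[len(front) // 2]
                C = max(cands, key=lambda c: np.hypot(*(c - midf)))
    if C is None:
        # Documented fallback: quarter-arc centered at the edge vertex.
        fallback = True
        C = E

    if fallback:
        # Arc of radius r3 centered at E, from the radial direction outward.
        start_ang = ang_E
        extent = math.pi / 2
        sweep_candidates = [extent, -extent]
        arcs = []
        for sw in sweep_candidates:
            t = np.linspace(0, sw, params.arc_points)
            pts = np.column_stack(
                [E[0] + r3 * np.cos(start_ang + t), E[1] + r3 * np.sin(start_ang + t)]
            )
            arcs.append(pts)
        # Pick the sweep that ends farther from the NC front midline.
        midf = front[len(front) // 2]
        arc = max(arcs, key=lambda a: np.hypot(*(a[-1] - midf)))
        arc[0] = E  # attach exactly
        return arc, fallback

    # Start point: projection of the edge vertex onto the final circle
    # (coincides with E when circle-1 radius equals the arc radius).
    v = E - C
    nv = float(np.hypot(*v))
    S = C + r3 * v / nv if nv > 0 else E + r3 * u_rad
    start_ang = math.atan2(S[1] - C[1], S[0] - C[0])
    extent = math.radians(params.arc_angle_deg)
    best = None
    for sw in (extent, -extent):
        t = np.linspace(0.0, sw, params.arc_points)
        pts = np.column_stack(
            [C[0] + r3 * np.cos(start_ang + t), C[1] + r3 * np.sin(start_ang + t)]
        )
        end_r = float(np.hypot(*(pts[-1] - center)))
        if best is None or end_r > best[0]:
            best = (end_r, pts)
    arc = best[1]
    arc[0] = E  # exact attachment to the front end
    return arc, fallback


def close_backside(
    front: np.ndarray,
    arc_left: np.ndarray,
    arc_right: np.ndarray,
    back_pts: dict[str, np.ndarray],
    params: ReconstructionParams,
) -> Polygon:
    """Close the NC with a polynomial through arc free ends and back points.

    The polynomial lives in a local frame whose abscissa is the chord between
    the two arc free ends; degree 4 interpolates the five conditions exactly.
    If the resulting polygon self-intersects the degree drops to 2
    (least-squares through the back points, exact at the arc ends).
    """
    L = arc_left[-1]
    R = arc_right[-1]
    interior = [back_pts["minus_sidecap"], back_pts["midcap"], back_pts["plus_sidecap"]]
    chord = R - L
    clen = float(np.hypot(*chord))
    if clen < 1e-9:
        raise ReconstructionError("degenerate backside chord")
    ex = chord / clen
    ey = np.array([-ex[1], ex[0]])

    def to_local(p):
        q = p - L
        return np.array([q @ ex, q @ ey])

    pts5 = np.array([to_local(p) for p in [L] + interior + [R]])
    order = np.argsort(pts5[:, 0])
    xs, ys = pts5[order, 0], pts5[order, 1]
    if np.min(np.diff(xs)) < 1e-9:
        raise ReconstructionError("back points collapse along the backside chord")

    def sample(coeff_fn):
        xg = np.linspace(0.0, clen, params.backside_points)
        yg = coeff_fn(xg)
        pts = L + np.outer(xg, ex) + np.outer(yg, ey)
        return pts

    def assemble(back_curve):
        # Orient the sampled backside from R to L.
        if np.hypot(*(back_curve[0] - R)) > np.hypot(*(back_curve[-1] - R)):
            back_curve = back_curve[::-1]
        ring = np.vstack([front, arc_right[1:], back_curve[1:-1], arc_left[::-1][:-1]])
        # Weld near-duplicate consecutive points.
        keep = np.concatenate(
            [[True], np.hypot(*np.diff(ring, axis=0).T) > 1e-9]
        )
        return Polygon(ring[keep])

    coeffs = np.polyfit(xs, ys, deg=min(params.closure_degree, len(xs) - 1))
    poly = assemble(sample(np.poly1d(coeffs)))
    if poly.is_valid and poly.area > 0:
        return poly

    # Fallback: quadratic exact at the chord ends, least squares elsewhere.
    yL, yR = pts5[order][0, 1], pts5[order][-1, 1]
    lin = lambda x: yL + (yR - yL) * x / clen  # noqa: E731
    xi, yi = xs[1:-1], ys[1:-1]
    basis = (xi - xs[0]) * (xi - xs[-1])
    denom = float(basis @ basis)
    c = float(basis @ (yi - lin(xi))) / denom if denom > 0 else 0.0
    poly = assemble(sample(lambda x: lin(x) + c * (x - xs[0]) * (x - xs[-1])))
    if poly.is_valid and poly.area > 0:
        return poly
    raise ReconstructionError("backside closure self-intersects at all degrees")


def clip_media(
    nc_poly: Polygon,
    intima_outer: Contour,
    clearance_mm: float = 0.010,
) -> tuple[Polygon, bool]:
    """Remove NC area outside the intima, keeping a thin clearance layer."""
    region = intima_outer.polygon.buffer(-clearance_mm)
    if region.contains(nc_poly):
        return nc_poly, False
    clipped = nc_poly.intersection(region)
    if clipped.is_empty:
        raise ReconstructionError("NC entirely outside the intima after clipping")
    if clipped.geom_type == "MultiPolygon":
        clipped = max(clipped.geoms, key=lambda g: g.area)
    if clipped.area <= 0:
        raise ReconstructionError("clipped NC has zero area")
    return clipped, True


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _resolve_rnct(
    method: str,
    source,
    sites: tuple[SiteMeasurement, ...],
    nc_angle: float,
) -> tuple[float, float, float]:
    """(rnct_mid, rnct_minus, rnct_plus) for the chosen estimation method."""
    by = {s.site: s for s in sites}
    if method == "group_average":
        ga: GroupAverages = source
        return ga.rnct_mid, ga.rnct_side, ga.rnct_side
    if method == "plaque_specific":
        coeffs: dict[str, GEECoefficients] = source
        mid = by["midcap"]
        rm = predict_rnct(coeffs["midcap"], nc_angle, mid.IMT * 1e3, mid.capT * 1e3)
        out = []
        for name in ("minus_sidecap", "plus_sidecap"):
            s = by[name]
            out.append(
                predict_rnct(coeffs["sidecap"], nc_angle, s.IMT * 1e3, s.capT * 1e3)
            )
        return rm, out[0], out[1]
    if method == "oracle":
        rm, rs = source  # true (mid, side) values injected by the caller
        return rm, rs, rs
    raise ReconstructionError(f"unknown reconstruction method {method!r}")


def reconstruct(
    cs: CrossSection,
    front: np.ndarray,
    span: tuple[float, float],
    method: str,
    source,
    params: ReconstructionParams | None = None,
) -> ReconstructionResult:
    """Full backside reconstruction for one NC front polyline.

    ``source`` is a :class:`GroupAverages` for the group-average method, a
    dict of site -> :class:`GEECoefficients` for the plaque-specific method,
    or a true (mid, side) rNCt pair for the oracle mode used in validation.
    """
    params = params or ReconstructionParams()
    center = lumen_center(cs)
    nc_angle = span[1] - span[0]
    sites = site_measurements(cs, front=front, span=span)

    rm, rminus, rplus = _resolve_rnct(method, source, sites, nc_angle)
    lumen_radii = {}
    for s in sites:
        _, r_lum, _ = ray_first_hit(center, s.ray_angle, cs.lumen)
        lumen_radii[s.site] = r_lum
    bp = back_points(center, sites, (rm, 0.0), lumen_radii)
    # Re-place side points with their own values (sides may differ under the
    # plaque-specific method).
    by = {s.site: s for s in sites}
    for name, rn in (("minus_sidecap", rminus), ("plus_sidecap", rplus)):
        s = by[name]
        d = np.array([math.cos(s.ray_angle), math.sin(s.ray_angle)])
        bp[name] = center + (lumen_radii[name] + s.capT + rn * s.IMT) * d

    flags = []
    arc_l, fb_l = edge_arc(front, "left", nc_angle, cs, params)
    arc_r, fb_r = edge_arc(front, "right", nc_angle, cs, params)
    if fb_l:
        flags.append("arc_fallback_left")
    if fb_r:
        flags.append("arc_fallback_right")

    poly = close_backside(front, arc_l, arc_r, bp, params)
    poly, clipped = clip_media(poly, cs.intima_outer, params.media_clearance_mm)
    if poly.intersection(cs.lumen.polygon).area > 0:
        poly = poly.difference(cs.lumen.polygon)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        flags.append("clipped_to_lumen")

    contour = Contour(np.asarray(poly.exterior.coords)[:-1], "nc")
    return ReconstructionResult(
        nc_polygon=contour,
        method=method,
        rnct_used=(rm, 0.5 * (rminus + rplus)),
        clipped_to_media=clipped,
        params=params,
        flags=tuple(flags),
    )
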