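"""Geometry agreement scores and peak-stress location shift taxonomy.

The similarity index is the Dice-type overlap of the ground-truth and
reconstructed NC polygons, SI = 2|A_GT ∩ A_rec| / (|A_GT| + |A_rec|); the
area mismatch is |A_rec − A_GT| / A_GT in percent (normalized by ground
truth, hence asymmetric by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .errors import InvalidGeometryError
from .geometry import Contour, CrossSection, lumen_center

#: Default distance below which two peak-stress locations count as the same
#: spot (surrogate for the visual-inspection call; configurable).
COLOCALIZATION_THRESHOLD_MM = 0.050


@dataclass(frozen=True)
class GeometryScore:
    si: float
    delta_a_pct: float
    a_gt: float
    a_rec: float
    overlap: float


@dataclass(frozen=True)
class PCSShift:
    distance: float  # mm
    category: str  # colocalized | side_to_side | same_side | lumen_nc_translocation


def _poly(obj) -> Polygon:
    if isinstance(obj, Contour):
        return obj.polygon
    if isinstance(obj, Polygon):
        return obj
    return Polygon(np.asarray(obj, dtype=float))


def similarity_index(gt, rec) -> GeometryScore:
    """Dice overlap and relative area mismatch of two NC polygons."""
    g, r = _poly(gt), _poly(rec)
    a_gt, a_rec = g.area, r.area
    if a_gt + a_rec <= 0:
        raise InvalidGeometryError("zero total area")
    overlap = g.intersection(r).area
    si = 2.0 * overlap / (a_gt + a_rec)
    delta = abs(a_rec - a_gt) / a_gt * 100.0 if a_gt > 0 else math.inf
    return GeometryScore(si=float(si), delta_a_pct=float(delta),
                         a_gt=float(a_gt), a_rec=float(a_rec),
                         overlap=float(overlap))


def classify_pcs_shift(
    loc_gt,
    loc_rec,
    cs: CrossSection,
    nc: Contour,
    span: tuple[float, float],
    threshold_mm: float = COLOCALIZATION_THRESHOLD_MM,
) -> PCSShift:
    """Classify how a reconstructed-geometry peak stress moved.

    Categories: below ``threshold_mm`` -> colocalized; on opposite angular
    sides of the midcap ray -> side_to_side; same angular side but radially
    translocated between the lumen border and the NC front ->
    lumen_nc_translocation; otherwise same_side.
    """
    p_gt = np.asarray(loc_gt, dtype=float)
    p_rec = np.asarray(loc_rec, dtype=float)
    dist = float(np.hypot(*(p_rec - p_gt)))
    if dist <= threshold_mm:
        return PCSShift(distance=dist, category="colocalized")

    center = lumen_center(cs)
    mid = 0.5 * (span[0] + span[1])

    def angular_offset(p):
        v = p - center
        a = math.atan2(v[1], v[0])
        return (a - mid + math.pi) % (2 * math.pi) - math.pi

    off_gt, off_rec = angular_offset(p_gt), angular_offset(p_rec)
    half = 0.5 * (span[1] - span[0]) + math.radians(15.0)
    if abs(off_gt) > half or abs(off_rec) > half:
        raise InvalidGeometryError("peak location outside the cap+shoulder span")

    if off_gt * off_rec < 0:
        return PCSShift(distance=dist, category="side_to_side")

    # Radial position: near the lumen border vs near the NC front border.
    from .geometry import ray_first_hit, ray_polygon_hits  # local import, no cycle

    def radial_class(p, off):
        # Nearer the lumen border or nearer the NC front border at its angle?
        theta = mid + off
        _, r_lum, _ = ray_first_hit(center, theta, cs.lumen)
        hits = ray_polygon_hits(center, theta, nc.vertices)
        v = p - center
        r = math.hypot(v[0], v[1])
        if r_lum is None or hits.size == 0:
            return "lumen"
        return "lumen" if abs(r - r_lum) <= abs(r - hits[0]) else "nc_front"

    c_gt = radial_class(p_gt, off_gt)
    c_rec = radial_class(p_rec, off_rec)
    if {c_gt, c_rec} == {"lumen", "nc_front"}:
        return PCSShift(distance=dist, category="lumen_nc_translocation")
    return PCSShift(distance=dist, category="same_side")
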