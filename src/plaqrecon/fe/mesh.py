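"""Structured polar meshing of plaque cross-sections.

All contours of a cross-section are star-shaped about the lumen centroid, so
the domain is meshed as a structured polar grid: a set of angular columns,
each split radially into bands (cap intima, NC, intima behind the NC,
media+adventitia, buffer).  Within the angular span of an NC the band borders
follow the NC front/back by ray casting; outside, the NC band collapses to
zero thickness and its nodes merge, which keeps the triangulation conforming
across the NC edges without constrained Delaunay machinery.

The cap band always carries ``n_cap_layers`` (>= 7) element layers across the
cap, so the resolution rule at the thinnest cap holds by construction.
Quadratic (6-node) triangles are generated by default: they behave far
better than linear triangles at near-incompressibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import FEError
from ..geometry import Contour, CrossSection, lumen_center, ray_polygon_hits
from .materials import DEFAULT_MATERIALS, MaterialSpec

BAND_NAMES = ("cap", "nc", "behind", "media", "buffer")
BAND_MATERIAL = {
    "cap": "intima",
    "behind": "intima",
    "nc": "nc",
    "media": "media_adventitia",
    "buffer": "buffer",
}

# Radial floors (mm) preventing sliver element rows where an NC pinches out
# or is clipped close to the media.
_NC_FLOOR = 0.02
_BEHIND_FLOOR = 0.03
_CAP_FLOOR = 0.02


@dataclass(frozen=True)
class MeshParams:
    n_cap_layers: int = 7
    n_nc_layers: int = 4
    n_behind_layers: int = 3
    n_media_layers: int = 4
    n_buffer_layers: int = 3
    fine_deg: float = 3.0  # angular step near the NC span(s)
    coarse_deg: float = 6.0  # elsewhere (buffer included; it is soft)
    shoulder_margin_deg: float = 25.0  # fine zone extends this far past spans
    buffer_thickness_frac: float = 0.5  # of the mean adventitia radius
    quadratic: bool = True

    def refined(self, factor: float = 2.0) -> "MeshParams":
        """Uniformly refined copy (for mesh-convergence checks)."""
        f = float(factor)
        return replace(
            self,
            n_cap_layers=int(round(self.n_cap_layers * f)),
            n_nc_layers=int(round(self.n_nc_layers * f)),
            n_behind_layers=int(round(self.n_behind_layers * f)),
            n_media_layers=int(round(self.n_media_layers * f)),
            n_buffer_layers=int(round(self.n_buffer_layers * f)),
            fine_deg=self.fine_deg / f,
            coarse_deg=self.coarse_deg / f,
        )


@dataclass
class FEModel:
    """Meshed cross-section ready for the solver."""

    nodes: np.ndarray  # (N, 2) reference coordinates, mm
    elements: np.ndarray  # (ne, 3) or (ne, 6) connectivity
    band: np.ndarray  # (ne,) index into BAND_NAMES
    elem_angle: np.ndarray  # (ne,) column mid-angle about the lumen center
    C10: np.ndarray  # (ne,) kPa
    K: np.ndarray  # (ne,) kPa bulk modulus
    lumen_edges: np.ndarray  # (nedge, 2 or 3) node ids on the pressurized border
    fixed_nodes: np.ndarray  # node ids with both dofs constrained
    center: np.ndarray  # lumen center used for the polar construction
    spans: list  # list of (start, end) NC angular spans
    materials: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def band_name(self, e: int) -> str:
        return BAND_NAMES[self.band[e]]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements[:, :3]].mean(axis=1)

    def with_nodes(self, nodes: np.ndarray) -> "FEModel":
        out = FEModel(**{**self.__dict__})
        out.nodes = np.asarray(nodes, dtype=float).copy()
        return out


def _ray_radius(center, theta, contour: Contour) -> float:
    hits = ray_polygon_hits(center, theta, contour.vertices)
    if hits.size == 0:
        raise FEError(f"mesh ray at angle {theta:.4f} misses {contour.component}")
    return float(hits[0])


def _in_span(theta: float, span: tuple[float, float]) -> bool:
    start, end = span
    width = end - start
    off = (theta - start) % (2 * math.pi)
    return 0.0 < off < width


def _angular_grid(spans, fine, coarse, margin) -> np.ndarray:
    """Non-uniform angle grid, finer near NC spans, snapped to span ends."""
    two_pi = 2 * math.pi
    fine_zones = [((s - margin) % two_pi, (e + margin) % two_pi) for s, e in spans]

    def is_fine(theta):
        return any(_in_span(theta, z) or theta == z[0] for z in fine_zones)

    angles = [0.0]
    while angles[-1] < two_pi:
        step = fine if is_fine(angles[-1] % two_pi) else coarse
        angles.append(angles[-1] + step)
    grid = np.array(angles[:-1]) % two_pi
    grid = np.unique(np.round(grid, 12))
    # Snap the nearest grid angle to each exact span endpoint.
    for s, e in spans:
        for target in (s % two_pi, e % two_pi):
            i = int(np.argmin(np.abs(np.angle(np.exp(1j * (grid - target))))))
            grid[i] = target
    grid = np.sort(grid % two_pi)
    # Merge near-duplicate columns left over from snapping.
    keep = np.concatenate([[True], np.diff(grid) > 1e-6])
    return grid[keep]


def _nc_span(center, nc: Contour) -> tuple[float, float]:
    rel = nc.vertices - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    c = nc.centroid() - center
    ref = math.atan2(c[1], c[0])
    ang = ref + np.mod(ang - ref + math.pi, 2 * math.pi) - math.pi
    return float(ang.min()), float(ang.max())


def build_model(
    cs: CrossSection,
    nc_polygons: list[Contour] | None = None,
    materials: dict[str, MaterialSpec] | None = None,
    buffer_thickness: float | None = None,
    params: MeshParams | None = None,
) -> FEModel:
    """Mesh a cross-section (with the given NC polygons) into a solver model.

    ``nc_polygons`` defaults to the section's own NCs; pass a reconstructed
    polygon list to mesh a reconstructed-geometry variant, or ``[]`` for a
    no-NC wall model.  The outer boundary of the soft buffer ring is fully
    constrained; the lumen border is marked for pressure loading.
    """
    params = params or MeshParams()
    materials = materials or DEFAULT_MATERIALS
    ncs = list(cs.ncs) if nc_polygons is None else list(nc_polygons)
    if len(ncs) > 2:
        raise FEError("at most two NCs are supported")
    center = lumen_center(cs)

    spans = [_nc_span(center, nc) for nc in ncs]
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            zi, zj = spans[i], spans[j]
            if _in_span(zi[0], zj) or _in_span(zj[0], zi):
                raise FEError("angularly overlapping NCs are not supported")

    grid = _angular_grid(
        spans,
        math.radians(params.fine_deg),
        math.radians(params.coarse_deg),
        math.radians(params.shoulder_margin_deg),
    )

    n_cap, n_nc = params.n_cap_layers, params.n_nc_layers
    n_beh, n_med, n_buf = (
        params.n_behind_layers,
        params.n_media_layers,
        params.n_buffer_layers,
    )
    if n_cap < 7:
        raise FEError("at least 7 element layers are required across the cap")
    band_of_row = (
        [0] * n_cap + [1] * n_nc + [2] * n_beh + [3] * n_med + [4] * n_buf
    )
    M = len(band_of_row)

    # Mean adventitia radius for the buffer thickness.
    probe = np.linspace(0, 2 * math.pi, 32, endpoint=False)
    r_adv_mean = float(
        np.mean([_ray_radius(center, t, cs.adventitia_outer) for t in probe])
    )
    t_buf = (
        buffer_thickness
        if buffer_thickness is not None
        else params.buffer_thickness_frac * r_adv_mean
    )

    # Per-column radial node positions.
    J = len(grid)
    col_radii = np.empty((J, M + 1))
    cap_frac = n_cap / (n_cap + n_beh)
    for j, theta in enumerate(grid):
        r_lum = _ray_radius(center, theta, cs.lumen)
        r_int = _ray_radius(center, theta, cs.intima_outer)
        r_adv = _ray_radius(center, theta, cs.adventitia_outer)
        r_buf = r_adv + t_buf
        r_ncf = r_ncb = None
        for nc, span in zip(ncs, spans):
            if _in_span(theta, span):
                hits = ray_polygon_hits(center, theta, nc.vertices)
                if hits.size >= 2:
                    r_ncf, r_ncb = float(hits[0]), float(hits[-1])
                break
        if r_ncf is None or r_ncb - r_ncf < _NC_FLOOR:
            r_c = r_lum + cap_frac * (r_int - r_lum)
            r_ncf = r_ncb = r_c
        else:
            r_ncf = max(r_ncf, r_lum + _CAP_FLOOR)
            r_ncb = min(max(r_ncb, r_ncf + _NC_FLOOR), r_int - _BEHIND_FLOOR)
            if r_ncb <= r_ncf:
                r_c = r_lum + cap_frac * (r_int - r_lum)
                r_ncf = r_ncb = r_c
        col_radii[j] = np.concatenate(
            [
                np.linspace(r_lum, r_ncf, n_cap + 1),
                np.linspace(r_ncf, r_ncb, n_nc + 1)[1:],
                np.linspace(r_ncb, r_int, n_beh + 1)[1:],
                np.linspace(r_int, r_adv, n_med + 1)[1:],
                np.linspace(r_adv, r_buf, n_buf + 1)[1:],
            ]
        )

    # Node numbering with merging of collapsed (equal-radius) column nodes.
    node_id = np.empty((J, M + 1), dtype=int)
    coords: list[tuple[float, float]] = []
    for j, theta in enumerate(grid):
        ct, st = math.cos(theta), math.sin(theta)
        prev_r = None
        for k in range(M + 1):
            r = col_radii[j, k]
            if prev_r is not None and r - prev_r < 1e-12:
                node_id[j, k] = node_id[j, k - 1]
            else:
                node_id[j, k] = len(coords)
                coords.append((center[0] + r * ct, center[1] + r * st))
            prev_r = r
    nodes = np.asarray(coords)

    tris, band, eang = [], [], []
    for j in range(J):
        j2 = (j + 1) % J
        theta_mid = grid[j] + 0.5 * ((grid[j2] - grid[j]) % (2 * math.pi))
        for k in range(M):
            a, b = node_id[j, k], node_id[j2, k]
            c, d = node_id[j2, k + 1], node_id[j, k + 1]
            for tri in ((a, c, b), (a, d, c)):  # CCW winding
                if len(set(tri)) < 3:
                    continue
                p = nodes[list(tri)]
                area = 0.5 * (
                    (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
                    - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1])
                )
                if area <= 1e-10:
                    continue
                tris.append(tri)
                band.append(band_of_row[k])
                eang.append(theta_mid % (2 * math.pi))
    elements = np.asarray(tris, dtype=int)
    band = np.asarray(band, dtype=int)
    eang = np.asarray(eang)

    lumen_ring = [(node_id[j, 0], node_id[(j + 1) % J, 0]) for j in range(J)]
    fixed = np.unique(node_id[:, M])

    if params.quadratic:
        elements, edge_mid = _to_quadratic(nodes, elements)
        nodes = edge_mid.pop("nodes")
        lumen_edges = np.array(
            [(a, b, edge_mid[(min(a, b), max(a, b))]) for a, b in lumen_ring]
        )
        outer_mids = [
            edge_mid.get((min(node_id[j, M], node_id[(j + 1) % J, M]),
                          max(node_id[j, M], node_id[(j + 1) % J, M])))
            for j in range(J)
        ]
        fixed = np.unique(
            np.concatenate([fixed, [m for m in outer_mids if m is not None]])
        )
    else:
        lumen_edges = np.asarray(lumen_ring)

    c10 = np.empty(len(elements))
    bulk = np.empty(len(elements))
    for bi, name in enumerate(BAND_NAMES):
        mat = materials[BAND_MATERIAL[name]]
        sel = band == bi
        c10[sel] = mat.C10
        bulk[sel] = mat.bulk_modulus

    spans_norm = [(s % (2 * math.pi), (s % (2 * math.pi)) + (e - s)) for s, e in spans]
    return FEModel(
        nodes=nodes,
        elements=elements,
        band=band,
        elem_angle=eang,
        C10=c10,
        K=bulk,
        lumen_edges=lumen_edges,
        fixed_nodes=fixed,
        center=center,
        spans=spans_norm,
        materials=dict(materials),
    )


def _to_quadratic(nodes: np.ndarray, tris: np.ndarray):
    """Add midside nodes: (ne,3) -> (ne,6) with local order (1,2,3,12,23,31)."""
    coords = list(map(tuple, nodes))
    edge_mid: dict = {}
    out = np.empty((len(tris), 6), dtype=int)
    for e, (a, b, c) in enumerate(tris):
        out[e, :3] = (a, b, c)
        for s, (i, j) in enumerate(((a, b), (b, c), (c, a))):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                edge_mid[key] = len(coords)
                coords.append(
                    (
                        0.5 * (nodes[i, 0] + nodes[j, 0]),
                        0.5 * (nodes[i, 1] + nodes[j, 1]),
                    )
                )
            out[e, 3 + s] = edge_mid[key]
    edge_mid["nodes"] = np.asarray(coords)
    return out, edge_mid


def ring_model(
    ri: float,
    ro: float,
    material: MaterialSpec,
    n_theta: int = 64,
    n_r: int = 8,
    quadratic: bool = True,
) -> FEModel:
    """Homogeneous annulus, inner border pressurized, outer border free.

    Verification fixture for the thick-walled-cylinder closed form; the
    caller pins rigid-body modes (see :func:`pin_rigid_body`).
    """
    thetas = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
    radii = np.linspace(ri, ro, n_r + 1)
    node_id = np.arange(n_theta * (n_r + 1)).reshape(n_theta, n_r + 1)
    nodes = np.array(
        [
            (r * math.cos(t), r * math.sin(t))
            for t in thetas
            for r in radii
        ]
    )
    tris, eang = [], []
    for j in range(n_theta):
        j2 = (j + 1) % n_theta
        for k in range(n_r):
            a, b = node_id[j, k], node_id[j2, k]
            c, d = node_id[j2, k + 1], node_id[j, k + 1]
            tris.append((a, c, b))
            tris.append((a, d, c))
            mid = thetas[j] + math.pi / n_theta
            eang.extend([mid % (2 * math.pi)] * 2)
    elements = np.asarray(tris)
    lumen_ring = [(node_id[j, 0], node_id[(j + 1) % n_theta, 0]) for j in range(n_theta)]
    if quadratic:
        elements, edge_mid = _to_quadratic(nodes, elements)
        nodes = edge_mid.pop("nodes")
        lumen_edges = np.array(
            [(a, b, edge_mid[(min(a, b), max(a, b))]) for a, b in lumen_ring]
        )
    else:
        lumen_edges = np.asarray(lumen_ring)
    ne = len(elements)
    return FEModel(
        nodes=nodes,
        elements=elements,
        band=np.zeros(ne, dtype=int),
        elem_angle=np.asarray(eang),
        C10=np.full(ne, material.C10),
        K=np.full(ne, material.bulk_modulus),
        lumen_edges=lumen_edges,
        fixed_nodes=np.array([], dtype=int),
        center=np.zeros(2),
        spans=[],
        materials={"all": material},
    )


def pin_rigid_body(model: FEModel) -> np.ndarray:
    """Fixed-dof list suppressing the 3 rigid-body modes of a free ring.

    Picks the outer-border nodes nearest the +x and -x axes: both dofs on the
    first, the y dof on the second (3-2-1 style minimal constraints).
    """
    r = np.hypot(model.nodes[:, 0] - model.center[0], model.nodes[:, 1] - model.center[1])
    outer = np.flatnonzero(r > 0.999 * r.max())
    ang = np.arctan2(model.nodes[outer, 1], model.nodes[outer, 0])
    n1 = outer[np.argmin(np.abs(ang))]
    n2 = outer[np.argmin(np.abs(np.abs(ang) - math.pi))]
    return np.array([2 * n1, 2 * n1 + 1, 2 * n2 + 1])
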