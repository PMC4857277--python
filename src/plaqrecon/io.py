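"""Reading and writing the package's exchange formats.

Contours travel as long-form CSV (one row per vertex) or GeoJSON feature
collections; derived features and scores as CSV tables; fitted coefficients
as JSON (see :mod:`plaqrecon.gee`); solved stress fields as legacy-ASCII VTK
unstructured grids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError
from .geometry import Contour, CrossSection, PlaqueFeatures

CSV_COLUMNS = [
    "section_id",
    "patient_id",
    "artery_id",
    "component",
    "ring_index",
    "vertex_index",
    "x_mm",
    "y_mm",
]

_RING_COMPONENTS = ("lumen", "intima", "media", "adventitia")


def cross_sections_to_frame(sections: list[CrossSection]) -> pd.DataFrame:
    rows = []
    for cs in sections:
        items = [
            (cs.lumen, "lumen", 0),
            (cs.intima_outer, "intima", 0),
            (cs.media_outer, "media", 0),
            (cs.adventitia_outer, "adventitia", 0),
        ] + [(nc, "nc", i) for i, nc in enumerate(cs.ncs)]
        for contour, comp, ring in items:
            for vi, (x, y) in enumerate(contour.vertices):
                rows.append(
                    (cs.section_id, cs.patient_id, cs.artery_id, comp, ring, vi, x, y)
                )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_contours_csv(sections: list[CrossSection], path) -> None:
    cross_sections_to_frame(sections).to_csv(path, index=False)


def read_contours_csv(path) -> list[CrossSection]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidGeometryError(f"contour CSV lacks columns {sorted(missing)}")
    return _frame_to_sections(df)


def _frame_to_sections(df: pd.DataFrame) -> list[CrossSection]:
    sections = []
    for sid, g in df.groupby("section_id", sort=False):
        parts = {}
        ncs = []
        for (comp, ring), gg in g.groupby(["component", "ring_index"], sort=False):
            gg = gg.sort_values("vertex_index")
            contour = Contour(gg[["x_mm", "y_mm"]].to_numpy(), comp)
            if comp == "nc":
                ncs.append((ring, contour))
            else:
                parts[comp] = contour
        for comp in _RING_COMPONENTS:
            if comp not in parts:
                raise InvalidGeometryError(f"section {sid} lacks a {comp} contour")
        ncs = [c for _, c in sorted(ncs)]
        sections.append(
            CrossSection(
                section_id=str(sid),
                patient_id=str(g["patient_id"].iloc[0]),
                artery_id=str(g["artery_id"].iloc[0]),
                lumen=parts["lumen"],
                intima_outer=parts["intima"],
                media_outer=parts["media"],
                adventitia_outer=parts["adventitia"],
                ncs=tuple(ncs),
            )
        )
    return sections


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def write_contours_geojson(sections: list[CrossSection], path) -> None:
    features = []
    for cs in sections:
        items = [
            (cs.lumen, "lumen"),
            (cs.intima_outer, "intima"),
            (cs.media_outer, "media"),
            (cs.adventitia_outer, "adventitia"),
        ] + [(nc, "nc") for nc in cs.ncs]
        for contour, comp in items:
            ring = contour.vertices.tolist()
            ring.append(ring[0])
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "section_id": cs.section_id,
                        "patient_id": cs.patient_id,
                        "artery_id": cs.artery_id,
                        "component": comp,
                    },
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_contours_geojson(path) -> list[CrossSection]:
    with open(path) as fh:
        collection = json.load(fh)
    rows = []
    for feat in collection["features"]:
        props = feat["properties"]
        ring = feat["geometry"]["coordinates"][0]
        comp = props["component"]
        for vi, (x, y) in enumerate(ring[:-1]):
            rows.append(
                (
                    props["section_id"],
                    props["patient_id"],
                    props["artery_id"],
                    comp,
                    props.get("ring_index", 0),
                    vi,
                    x,
                    y,
                )
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    # Distinguish multiple NCs of one section by order of appearance.
    fixed = []
    for sid, g in df.groupby("section_id", sort=False):
        nc_break = g[(g.component == "nc") & (g.vertex_index == 0)].index
        for ring, start in enumerate(nc_break):
            end = nc_break[ring + 1] if ring + 1 < len(nc_break) else g.index[-1] + 1
            df.loc[start:end - 1, "ring_index"] = np.where(
                df.loc[start:end - 1, "component"] == "nc", ring, 0
            )
    return _frame_to_sections(df)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def features_to_frame(features: list[PlaqueFeatures]) -> pd.DataFrame:
    rows = []
    for f in features:
        row = {
            "section_id": f.section_id,
            "artery_id": f.artery_id,
            "patient_id": f.patient_id,
            "nc_index": f.nc_index,
            "min_capT_mm": f.min_cap_thickness,
            "nc_angle_deg": np.degrees(f.nc_angle),
        }
        for s in f.sites:
            tag = {"midcap": "mid", "minus_sidecap": "mside", "plus_sidecap": "pside"}[
                s.site
            ]
            row.update(
                {
                    f"capT_{tag}_mm": s.capT,
                    f"IMT_{tag}_mm": s.IMT,
                    f"NCt_{tag}_mm": s.NCt,
                    f"rNCt_{tag}": s.rNCt,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def gee_table_from_features(features: list[PlaqueFeatures], site: str) -> pd.DataFrame:
    """Regression table (rnct, covariates, cluster id) for one site relation.

    The two sidecap measurements of an NC enter as separate rows sharing the
    artery cluster; midcap gives one row per NC.
    """
    names = ["midcap"] if site == "midcap" else ["minus_sidecap", "plus_sidecap"]
    rows = []
    for f in features:
        for name in names:
            s = f.site(name)
            rows.append(
                {
                    "rnct": s.rNCt,
                    "nc_angle_rad": f.nc_angle,
                    "imt_um": s.IMT * 1e3,
                    "capt_um": s.capT * 1e3,
                    "artery_id": f.artery_id,
                    "section_id": f.section_id,
                    "nc_index": f.nc_index,
                    "site": name,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------

def write_vtk(path, model, field=None) -> None:
    """Legacy-ASCII VTK unstructured grid (triangles as linear cells)."""
    tris = model.elements[:, :3]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nplaqrecon field\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {model.n_nodes} float\n")
        for x, y in model.nodes:
            fh.write(f"{x:.6e} {y:.6e} 0.0\n")
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for a, b, c in tris:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("\n".join(["5"] * len(tris)) + "\n")
        fh.write(f"CELL_DATA {len(tris)}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(b)) for b in model.band) + "\n")
        if field is not None:
            fh.write("SCALARS von_mises_kpa float 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.6e}" for v in field.von_mises) + "\n")
            fh.write(f"POINT_DATA {model.n_nodes}\nVECTORS displacement float\n")
            for ux, uy in field.displacements:
                fh.write(f"{ux:.6e} {uy:.6e} 0.0\n")
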