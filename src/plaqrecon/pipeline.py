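"""End-to-end experiment: ground truth -> backside removal -> reconstruction
-> geometry scores -> stress -> peak-cap-stress comparison.

For every NC the pipeline measures the ground-truth morphometry, removes the
backside, reconstructs it with the group-average and plaque-specific methods
(plus an oracle variant fed the true rNCt, for validation), scores geometric
agreement, and compares peak cap stresses between the ground-truth and
reconstructed geometries under prestressed systolic loading.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import io as pio
from .errors import PlaqreconError
from .fe import (
    DEFAULT_MATERIALS,
    MMHG_TO_KPA,
    MeshParams,
    build_model,
    peak_cap_stress,
    prestress_backward_incremental,
    solve_pressurized,
)
from .gee import TABLE_COEFFICIENTS, fit_gee
from .geometry import CrossSection, characterize, nc_front_side
from .metrics import classify_pcs_shift, similarity_index
from .reconstruction import (
    GroupAverages,
    ReconstructionParams,
    group_average_rnct,
    reconstruct,
)
from .synthetic import PopulationSpec, sample_population

log = logging.getLogger("plaqrecon")

METHOD_TAGS = {"group_average": "ga", "plaque_specific": "ps", "oracle": "or"}


@dataclass
class RunConfig:
    population: PopulationSpec | None = None
    contours_path: str | None = None
    methods: tuple = ("group_average", "plaque_specific", "oracle")
    gee_source: str = "refit"  # "refit" on the input cohort or "packaged"
    recon_params: ReconstructionParams = field(default_factory=ReconstructionParams)
    mesh_params: MeshParams = field(default_factory=MeshParams)
    materials: dict = field(default_factory=lambda: dict(DEFAULT_MATERIALS))
    compute_stress: bool = True
    prestress: bool = True
    p_prestress_mmhg: float = 100.0
    p_sys_mmhg: float = 140.0
    shoulder_deg: float = 15.0
    stratify_kpa: float = 300.0  # boundary value goes to the high group
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.population is None) == (self.contours_path is None):
            raise PlaqreconError(
                "configure exactly one input source (population or contours_path)"
            )

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(asdict_safe(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def asdict_safe(cfg: RunConfig) -> dict:
    out = {}
    for k, v in cfg.__dict__.items():
        if k == "out_dir":  # output location must not change provenance
            continue
        try:
            json.dumps(v)
            out[k] = v
        except TypeError:
            out[k] = repr(v)
    return out


def _loo_group_averages(features, exclude) -> GroupAverages:
    """Group medians excluding the target NC (no self-information)."""
    rest = [f for f in features if (f.section_id, f.nc_index) != exclude]
    return group_average_rnct(rest if rest else features)


def _solve_geometry(cs, ncs, cfg: RunConfig):
    model = build_model(cs, nc_polygons=ncs, materials=cfg.materials,
                        params=cfg.mesh_params)
    prestressed = False
    u0 = None
    if cfg.prestress and cfg.p_prestress_mmhg > 0:
        model, info = prestress_backward_incremental(
            model, cfg.p_prestress_mmhg * MMHG_TO_KPA
        )
        prestressed = True
        u_p0 = info.get("u_at_p0")
        u0 = None if u_p0 is None else np.asarray(u_p0).ravel()
    p_sys = cfg.p_sys_mmhg * MMHG_TO_KPA
    fld = None
    if u0 is not None:
        try:  # warm start from the prestress state; fall back to a full ramp
            fld = solve_pressurized(model, p_sys, u0=u0, n_steps=2)
        except PlaqreconError:
            fld = None
    if fld is None:
        fld = solve_pressurized(model, p_sys)
    return model, fld, prestressed


def run_pipeline(config: RunConfig):
    """Execute the full experiment; returns (records, summary, failures)."""
    t_start = time.time()
    if config.population is not None:
        sections, truth = sample_population(config.population)
    else:
        path = str(config.contours_path)
        if path.endswith(".json") or path.endswith(".geojson"):
            sections = pio.read_contours_geojson(path)
        else:
            sections = pio.read_contours_csv(path)
        truth = None

    features = [f for cs in sections for f in characterize(cs)]
    feat_df = pio.features_to_frame(features)

    if config.gee_source == "packaged":
        coeffs = dict(TABLE_COEFFICIENTS)
        averages_global = GroupAverages()
    else:
        coeffs = {
            site: fit_gee(pio.gee_table_from_features(features, site), site=site)
            for site in ("midcap", "sidecap")
        }
        averages_global = group_average_rnct(features)

    cfg_hash = config.config_hash()
    records, failures = [], []
    feat_by_key = {(f.section_id, f.nc_index): f for f in features}
    gt_cache: dict = {}  # ground-truth solve shared by both NCs of a section
    for cs in sections:
        for nc_index, nc in enumerate(cs.ncs):
            key = (cs.section_id, nc_index)
            f = feat_by_key[key]
            try:
                rec = _process_nc(cs, nc, nc_index, f, features, coeffs,
                                  averages_global, config, gt_cache)
            except PlaqreconError as exc:
                log.warning("section %s nc %d failed: %s", cs.section_id,
                            nc_index, exc)
                failures.append(
                    {"section_id": cs.section_id, "nc_index": nc_index,
                     "error": str(exc)}
                )
                continue
            rec.update(
                {"section_id": cs.section_id, "artery_id": cs.artery_id,
                 "nc_index": nc_index, "config_hash": cfg_hash,
                 "seed": config.seed}
            )
            records.append(rec)

    records = pd.DataFrame(records)
    summary = summarize(records, stratify_kpa=config.stratify_kpa)
    summary["n_sections"] = len(sections)
    summary["n_failures"] = len(failures)
    summary["elapsed_s"] = round(time.time() - t_start, 1)
    summary["config_hash"] = cfg_hash
    summary["seed"] = config.seed

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        feat_df.to_csv(out / "features.csv", index=False)
        records.to_csv(out / "scores.csv", index=False)
        pd.DataFrame(failures).to_csv(out / "failures.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        with open(out / "coeffs.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in coeffs.items()}, fh, indent=2)
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)
            pio.write_contours_csv(sections, out / "contours.csv")
    return records, summary, failures


def _process_nc(cs, nc, nc_index, f, features, coeffs, averages_global, config,
                gt_cache=None):
    front, span = nc_front_side(cs, nc)
    rec = {}
    reconstructions = {}
    for method in config.methods:
        if method == "group_average":
            if config.gee_source == "packaged":
                source = averages_global
            else:
                source = _loo_group_averages(features, (cs.section_id, nc_index))
        elif method == "plaque_specific":
            source = coeffs
        elif method == "oracle":
            rs = 0.5 * (f.site("minus_sidecap").rNCt + f.site("plus_sidecap").rNCt)
            source = (f.site("midcap").rNCt, rs)
        else:
            raise PlaqreconError(f"unknown method {method}")
        r = reconstruct(cs, front, span, method, source, config.recon_params)
        reconstructions[method] = r
        tag = METHOD_TAGS[method]
        score = similarity_index(nc, r.nc_polygon)
        rec[f"si_{tag}"] = score.si
        rec[f"da_{tag}_pct"] = score.delta_a_pct
        rec[f"area_gt_mm2"] = score.a_gt
        rec[f"area_{tag}_mm2"] = score.a_rec
        rec[f"clipped_{tag}"] = r.clipped_to_media
        rec[f"flags_{tag}"] = "|".join(r.flags)

    if config.compute_stress:
        if gt_cache is not None and cs.section_id in gt_cache:
            gt_model, gt_fld, prestressed = gt_cache[cs.section_id]
        else:
            gt_model, gt_fld, prestressed = _solve_geometry(cs, list(cs.ncs),
                                                            config)
            if gt_cache is not None:
                gt_cache[cs.section_id] = (gt_model, gt_fld, prestressed)
        gt_res = peak_cap_stress(gt_fld, gt_model,
                                 shoulder_deg=config.shoulder_deg, span=span)
        rec["pcs_gt_kpa"] = gt_res.pcs
        rec["pcs_gt_region"] = gt_res.region
        rec["prestressed"] = prestressed
        for method, r in reconstructions.items():
            tag = METHOD_TAGS[method]
            variant = list(cs.ncs)
            variant[nc_index] = r.nc_polygon
            v_model, v_fld, _ = _solve_geometry(cs, variant, config)
            res = peak_cap_stress(v_fld, v_model,
                                  shoulder_deg=config.shoulder_deg, span=span)
            rec[f"pcs_{tag}_kpa"] = res.pcs
            rec[f"pcs_{tag}_diff_pct"] = (
                abs(res.pcs - gt_res.pcs) / gt_res.pcs * 100.0
            )
            shift = classify_pcs_shift(gt_res.location, res.location, cs, nc, span)
            rec[f"pcs_{tag}_shift_mm"] = shift.distance
            rec[f"pcs_{tag}_shift_category"] = shift.category
    return rec


def _med_iqr(x) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return {"median": math.nan, "q25": math.nan, "q75": math.nan, "n": 0}
    return {
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
        "n": int(len(x)),
    }


def summarize(records: pd.DataFrame, stratify_kpa: float = 300.0) -> dict:
    """Cohort summary: score medians, PCS regression and stratified errors."""
    out: dict = {"n_records": int(len(records))}
    if len(records) == 0:
        return out
    for tag in ("ga", "ps", "or"):
        if f"si_{tag}" in records:
            out[f"si_{tag}"] = _med_iqr(records[f"si_{tag}"])
            out[f"da_{tag}_pct"] = _med_iqr(records[f"da_{tag}_pct"])
    if "pcs_gt_kpa" in records:
        out["pcs_gt_kpa"] = _med_iqr(records["pcs_gt_kpa"])
        gt = records["pcs_gt_kpa"].to_numpy(float)
        high = gt >= stratify_kpa  # boundary value belongs to the high group
        for tag in ("ga", "ps", "or"):
            col = f"pcs_{tag}_kpa"
            if col not in records:
                continue
            rec = records[col].to_numpy(float)
            ok = np.isfinite(gt) & np.isfinite(rec)
            out[col] = _med_iqr(rec)
            out[f"pcs_{tag}_diff_pct"] = _med_iqr(records[f"pcs_{tag}_diff_pct"])
            if ok.sum() >= 3 and np.std(gt[ok]) > 0:
                fit = sstats.linregress(gt[ok], rec[ok])
                out[f"pcs_{tag}_regression"] = {
                    "slope": float(fit.slope),
                    "intercept": float(fit.intercept),
                    "r_squared": float(fit.rvalue**2),
                }
            for name, sel in (("low", ~high), ("high", high)):
                d = records.loc[ok & sel, f"pcs_{tag}_diff_pct"]
                out[f"pcs_{tag}_diff_pct_{name}"] = _med_iqr(d)
            cats = records[f"pcs_{tag}_shift_category"].value_counts().to_dict() \
                if f"pcs_{tag}_shift_category" in records else {}
            out[f"pcs_{tag}_shift_counts"] = {k: int(v) for k, v in cats.items()}
    return out
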