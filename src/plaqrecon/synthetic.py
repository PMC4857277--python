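"""Synthetic plaque cross-sections emulating the study cohort geometry.

The generator builds star-shaped (about the lumen centroid) vessel-wall rings
in polar form and inserts one or two necrotic cores as annular bands whose cap
thickness, NC thickness and wall thickness follow configurable angular
profiles.  Population sampling draws per-section features from log-normal
marginals calibrated to cohort medians and interquartile ranges (right-skewed
thickness data), with a shared per-artery latent effect producing
within-artery correlation, so that clustered-regression machinery downstream
has realistic input.

The relative NC thickness (rNCt) of a sampled plaque is generated from the
packaged linear relation between rNCt and (NC angle, IMT, capT) plus
cluster-correlated noise, so that plaque-specific estimation has a true signal
to recover, and the cohort rNCt medians land at their configured targets
(0.40 midcap / 0.35 sidecap by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import SpecError
from .geometry import Contour, CrossSection, PlaqueFeatures
from .gee import TABLE_COEFFICIENTS, predict_rnct

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# Idealized single plaques
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NCSpec:
    """One necrotic core: angular placement and thickness profiles (mm/rad)."""

    mid_angle: float = math.pi / 2  # direction of the NC center from lumen center
    nc_angle: float = math.radians(54.0)  # angular span of the front side
    capt: tuple[float, float] = (0.30, 0.31)  # (midcap, sidecap) cap thickness
    nct: tuple[float, float] = (0.42, 0.36)  # (midcap, sidecap) NC thickness
    imt: tuple[float, float] = (1.05, 1.03)  # wall thickness at mid/side rays
    min_capt: float | None = None  # optional localized cap thinning
    notch_frac: float = 0.72  # notch position, fraction of the half-span
    notch_sign: int = 1

    def __post_init__(self):
        if not math.radians(10) < self.nc_angle < math.radians(170):
            raise SpecError("nc_angle must lie in (10 deg, 170 deg)")
        if min(self.capt) <= 0 or min(self.nct) < 0 or min(self.imt) <= 0:
            raise SpecError("thickness profiles must be positive")


@dataclass(frozen=True)
class PlaqueSpec:
    """Deterministic idealized cross-section specification (mm, rad)."""

    lumen_radius: float = 1.5
    lumen_ellipticity: float = 0.0  # 0 = circle; 0.1 -> 10 % axis imbalance
    far_imt: float = 0.35  # wall thickness away from any plaque
    media_thickness: float = 0.20
    adventitia_thickness: float = 0.30
    ncs: tuple[NCSpec, ...] = (NCSpec(),)
    vertex_density: int = 512  # vertices per full wall contour
    section_id: str = "S0"
    artery_id: str = "A0"
    patient_id: str = "P0"

    def __post_init__(self):
        if self.lumen_radius <= 0:
            raise SpecError("lumen_radius must be positive")
        if not 1 <= len(self.ncs) <= 2:
            raise SpecError("1 or 2 NCs per section")


def _wrap_delta(theta, mid):
    return np.mod(theta - mid + math.pi, TWO_PI) - math.pi


def _capt_profile(nc: NCSpec, delta: np.ndarray) -> np.ndarray:
    quarter = nc.nc_angle / 4.0
    c2 = (nc.capt[1] - nc.capt[0]) / quarter**2
    capt = nc.capt[0] + c2 * delta**2
    if nc.min_capt is not None and nc.min_capt < capt.min() + nc.capt[0]:
        dn = nc.notch_sign * nc.notch_frac * nc.nc_angle / 2.0
        base_at_notch = nc.capt[0] + c2 * dn**2
        depth = base_at_notch - nc.min_capt
        if depth > 0:
            sigma = nc.nc_angle / 40.0
            capt = capt - depth * np.exp(-0.5 * ((delta - dn) / sigma) ** 2)
    return capt


def _nct_profile(nc: NCSpec, delta: np.ndarray) -> np.ndarray:
    # Monotone shape-preserving interpolation through the mid (0), side (0.5)
    # and edge (1 -> zero thickness) knots of the normalized half-span, so the
    # band pinches closed at the edges without overshoot.
    u = np.abs(delta) / (nc.nc_angle / 2.0)
    interp = PchipInterpolator([0.0, 0.5, 1.0], [nc.nct[0], nc.nct[1], 0.0])
    out = np.where(u <= 1.0, interp(np.clip(u, 0, 1)), 0.0)
    return np.maximum(out, 0.0)


_IMT_TAPER = 0.6  # rad over which a plaque's wall thickening decays


def _imt_profile(spec: PlaqueSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Wall thickness vs angle: thick over each NC, baseline elsewhere.

    Within an NC span the profile interpolates the configured mid/side IMT
    (monotone, exact at the site rays); beyond the span edge it tapers with a
    half-cosine to the far-wall baseline over a fixed angular window, so one
    plaque's thickening never reaches the opposite wall.
    """
    interps = []
    for nc in spec.ncs:
        half = nc.nc_angle / 2.0
        quarter = nc.nc_angle / 4.0
        shape = PchipInterpolator(
            [0.0, quarter, half], [nc.imt[0], nc.imt[1], nc.imt[1]]
        )
        interps.append((nc, half, shape))

    def f(theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        imt = np.full(theta.shape, spec.far_imt)
        for nc, half, shape in interps:
            d = np.abs(_wrap_delta(theta, nc.mid_angle))
            inside = d <= half
            imt_in = shape(np.clip(d, 0, half))
            bump_in = np.where(inside, imt_in - spec.far_imt, 0.0)
            in_taper = (d > half) & (d < half + _IMT_TAPER)
            edge_amp = nc.imt[1] - spec.far_imt
            taper = edge_amp * 0.5 * (
                1.0 + np.cos(np.pi * (d - half) / _IMT_TAPER)
            )
            imt = imt + np.where(inside, bump_in, np.where(in_taper, taper, 0.0))
        return imt

    return f


def _lumen_radius_fn(spec: PlaqueSpec) -> Callable[[np.ndarray], np.ndarray]:
    a = spec.lumen_radius * (1.0 + spec.lumen_ellipticity)
    b = spec.lumen_radius / (1.0 + spec.lumen_ellipticity)

    def f(theta: np.ndarray) -> np.ndarray:
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    return f


def make_idealized(spec: PlaqueSpec) -> CrossSection:
    """Deterministic idealized cross-section from a :class:`PlaqueSpec`.

    The lumen is a (possibly elliptical) ring centered at the origin; wall
    rings follow the angular IMT profile measured from the lumen boundary;
    each NC is an annular band between the cap and the configured NC
    thickness, pinching closed at the edges of its angular span.
    """
    n = max(64, int(spec.vertex_density))
    theta = np.linspace(0.0, TWO_PI, n, endpoint=False)
    r_lum_fn = _lumen_radius_fn(spec)
    imt_fn = _imt_profile(spec)

    r_lum = r_lum_fn(theta)
    imt = imt_fn(theta)
    r_media = r_lum + imt
    r_intima = r_media - spec.media_thickness
    r_adv = r_media + spec.adventitia_thickness

    def ring(radii, component):
        pts = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
        return Contour(pts, component)

    ncs = []
    for nc in spec.ncs:
        half = nc.nc_angle / 2.0
        m = max(33, int(round(spec.vertex_density * nc.nc_angle / TWO_PI)) | 1)
        d = np.linspace(-half, half, m)
        th = nc.mid_angle + d
        rl = r_lum_fn(th)
        capt = _capt_profile(nc, d)
        nct = _nct_profile(nc, d)
        inner_wall = imt_fn(th) - spec.media_thickness
        if np.any(capt + nct > inner_wall - 0.01):
            raise SpecError("NC (capT + NCt) exceeds the local intima thickness")
        if np.any(capt <= 0.01):
            raise SpecError("cap thickness profile collapses to zero")
        r_front = rl + capt
        r_back = r_front + nct
        front = np.column_stack([r_front * np.cos(th), r_front * np.sin(th)])
        keep = nct > 1e-6
        back = np.column_stack([r_back * np.cos(th), r_back * np.sin(th)])[keep]
        poly = np.vstack([front, back[::-1]])
        ncs.append(Contour(poly, "nc"))

    return CrossSection(
        section_id=spec.section_id,
        artery_id=spec.artery_id,
        patient_id=spec.patient_id,
        lumen=ring(r_lum, "lumen"),
        intima_outer=ring(r_intima, "intima"),
        media_outer=ring(r_media, "media"),
        adventitia_outer=ring(r_adv, "adventitia"),
        ncs=tuple(ncs),
    )


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

def _lognorm_sigma(q25: float, q75: float) -> float:
    """Log-scale SD of a log-normal from its quartiles."""
    return math.log(q75 / q25) / (2.0 * 0.674489750196082)


#: Cohort calibration: (median, q25, q75) of each geometric feature.
COHORT_TARGETS = {
    "nc_angle_deg": (54.0, 35.0, 75.0),
    "capt_mid_mm": (0.30, 0.13, 0.53),
    "capt_side_mm": (0.31, 0.16, 0.54),
    "imt_mid_mm": (1.05, 0.89, 1.29),
    "imt_side_mm": (1.03, 0.84, 1.24),
    "min_capt_mm": (0.20, 0.09, 0.40),
    "rnct_mid": (0.40, math.nan, math.nan),
    "rnct_side": (0.35, math.nan, math.nan),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling plan for a synthetic cohort (defaults emulate the study)."""

    n_patients: int = 7
    arteries_per_patient: int = 2
    sections_per_artery: int = 4
    n_sections: int | None = None  # optional cap on total sections
    targets: dict = field(default_factory=lambda: dict(COHORT_TARGETS))
    within_artery_rho: float = 0.3
    two_nc_probability: float = 21.0 / 52.0
    rnct_noise_sd: float = 0.12
    lumen_radius_median: float = 1.5
    seed: int = 0


def _draw_lognormal(rng, median, sigma, latent, rho):
    z = math.sqrt(rho) * latent + math.sqrt(1 - rho) * rng.standard_normal()
    return median * math.exp(sigma * z)


_MEDIA_TH = 0.20


def _draw_nc_features(rng, pop: PopulationSpec, latent_cov: float,
                      latent_resp: float, primary_angle: float,
                      second: bool) -> dict:
    """Raw feature draw for one NC (rNCt calibration applied later)."""
    t = pop.targets
    rho = pop.within_artery_rho
    sig = {k: _lognorm_sigma(v[1], v[2]) for k, v in t.items()
           if not math.isnan(v[1])}

    angle_deg = _draw_lognormal(rng, t["nc_angle_deg"][0], sig["nc_angle_deg"],
                                latent_cov, rho)
    angle = math.radians(min(max(angle_deg, 12.0), 130.0))

    capt_mid = _draw_lognormal(rng, t["capt_mid_mm"][0], sig["capt_mid_mm"],
                               latent_cov, rho)
    capt_side = capt_mid * (t["capt_side_mm"][0] / t["capt_mid_mm"][0]) \
        * math.exp(0.08 * rng.standard_normal())
    imt_mid = _draw_lognormal(rng, t["imt_mid_mm"][0], sig["imt_mid_mm"],
                              latent_cov, rho)
    imt_mid = max(imt_mid, 0.60)  # lower tail truncated for feasibility
    imt_side = imt_mid * (t["imt_side_mm"][0] / t["imt_mid_mm"][0]) \
        * math.exp(0.05 * rng.standard_normal())
    imt_side = min(max(imt_side, 0.55), imt_mid)

    # Cluster-correlated rNCt noise, independent of the covariate latent
    # (errors stay exogenous); the linear-relation mean is evaluated after
    # cap calibration.
    eps_nc = rng.standard_normal()

    def noise():
        return (math.sqrt(rho) * latent_resp
                + math.sqrt(1 - rho)
                * (0.7 * eps_nc + 0.714 * rng.standard_normal()))

    ratio = 0.20 / 0.30 * math.exp(0.374 * rng.standard_normal())
    if second:
        mid_angle = primary_angle + math.pi + rng.uniform(-0.5, 0.5)
    else:
        mid_angle = primary_angle
    return {
        "mid_angle": mid_angle % TWO_PI,
        "angle": angle,
        "capt_mid": capt_mid,
        "capt_side": capt_side,
        "imt_mid": imt_mid,
        "imt_side": imt_side,
        "eps_mid": noise(),
        "eps_side": noise(),
        "min_capt_ratio": min(ratio, 0.95),
        "notch_frac": rng.uniform(0.62, 0.85),
        "notch_sign": int(rng.choice([-1, 1])),
    }


def _rnct_feasible(rnct, imt, capt):
    hi = 0.9 * (imt - _MEDIA_TH - capt) / imt
    return float(np.clip(rnct, 0.05, min(0.85, hi)))


def _bisect_monotone(fn, target, lo, hi, iters=60):
    """Solve fn(x) = target for a nondecreasing fn on [lo, hi]."""
    if fn(lo) > target or fn(hi) < target:
        return None
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _calibrate_cohort(all_nc: list[dict], pop: PopulationSpec) -> tuple[float, float]:
    """In-place cohort calibration: cap scale, then rNCt offsets.

    Feasibility clamps truncate the upper tails of the drawn features, which
    would drag the cohort medians below their configured targets; a
    multiplicative cap-thickness rescale and additive rNCt offsets (solved by
    bisection on the post-clamp medians) restore them.
    """
    t = pop.targets

    def capt_med(s):
        return float(np.median(
            [min(s * d["capt_mid"], 0.55 * (d["imt_mid"] - _MEDIA_TH))
             for d in all_nc]
        ))

    s_capt = _bisect_monotone(capt_med, t["capt_mid_mm"][0], 0.5, 3.0) or 1.0
    for d in all_nc:
        d["capt_mid"] = min(s_capt * d["capt_mid"],
                            0.55 * (d["imt_mid"] - _MEDIA_TH))
        d["capt_side"] = min(s_capt * d["capt_side"],
                             0.55 * (d["imt_side"] - _MEDIA_TH))
        for site, key in (("midcap", "mid"), ("sidecap", "side")):
            mu = predict_rnct(
                TABLE_COEFFICIENTS[site], d["angle"],
                d[f"imt_{key}"] * 1000.0, d[f"capt_{key}"] * 1000.0,
                clamp=False,
            )
            d[f"raw_rnct_{key}"] = mu + pop.rnct_noise_sd * d[f"eps_{key}"]

    def ratio_med(s):
        return float(np.median(
            [min(d["capt_mid"], d["capt_side"]) * min(s * d["min_capt_ratio"], 0.95)
             for d in all_nc]
        ))

    s_ratio = _bisect_monotone(ratio_med, t["min_capt_mm"][0], 0.3, 2.0) or 1.0
    for d in all_nc:
        d["min_capt_ratio"] = min(s_ratio * d["min_capt_ratio"], 0.95)

    def rnct_med(key):
        def med(off):
            return float(np.median(
                [_rnct_feasible(d[f"raw_rnct_{key}"] + off,
                                d[f"imt_{key}"], d[f"capt_{key}"])
                 for d in all_nc]
            ))
        return med

    off_mid = _bisect_monotone(rnct_med("mid"), t["rnct_mid"][0], -0.5, 0.5)
    off_side = _bisect_monotone(rnct_med("side"), t["rnct_side"][0], -0.5, 0.5)
    return (0.0 if off_mid is None else off_mid,
            0.0 if off_side is None else off_side)


def _nc_spec_from_features(d: dict, off_mid: float, off_side: float) -> NCSpec:
    rnct_mid = _rnct_feasible(d["raw_rnct_mid"] + off_mid,
                              d["imt_mid"], d["capt_mid"])
    rnct_side = _rnct_feasible(d["raw_rnct_side"] + off_side,
                               d["imt_side"], d["capt_side"])
    return NCSpec(
        mid_angle=d["mid_angle"],
        nc_angle=d["angle"],
        capt=(d["capt_mid"], d["capt_side"]),
        nct=(rnct_mid * d["imt_mid"], rnct_side * d["imt_side"]),
        imt=(d["imt_mid"], d["imt_side"]),
        min_capt=min(d["capt_mid"], d["capt_side"]) * d["min_capt_ratio"],
        notch_frac=d["notch_frac"],
        notch_sign=d["notch_sign"],
    )


def _fit_nc_thickness(spec: PlaqueSpec) -> PlaqueSpec:
    """Scale NC thickness profiles down where they would pierce the media.

    The site-level feasibility clamp cannot see the full angular profiles
    (the cap profile extrapolates beyond the sidecap ray); this numeric pass
    guarantees the constructed band fits inside the intima with margin,
    keeping the section buildable instead of dropping it.
    """
    imt_fn = _imt_profile(spec)
    new_ncs = []
    for nc in spec.ncs:
        half = nc.nc_angle / 2.0
        d = np.linspace(-half, half, 101)
        th = nc.mid_angle + d
        inner = imt_fn(th) - spec.media_thickness
        capt = _capt_profile(nc, d)
        nct = _nct_profile(nc, d)
        room = inner - 0.02 - capt
        mask = nct > 1e-3
        if not np.any(mask) or np.min(room[mask]) <= 0.01:
            continue  # cap itself (not the NC) violates: drop this NC
        s = min(1.0, float(np.min(room[mask] / nct[mask])))
        if s < 1.0:
            nc = replace(nc, nct=(s * nc.nct[0], s * nc.nct[1]))
        new_ncs.append(nc)
    if not new_ncs:
        return spec
    return replace(spec, ncs=tuple(new_ncs))


def _truth_row(spec: PlaqueSpec, nc: NCSpec, idx: int) -> dict:
    return {
        "section_id": spec.section_id,
        "artery_id": spec.artery_id,
        "patient_id": spec.patient_id,
        "nc_index": idx,
        "nc_angle_rad": nc.nc_angle,
        "capt_mid_mm": nc.capt[0],
        "capt_side_mm": nc.capt[1],
        "imt_mid_mm": nc.imt[0],
        "imt_side_mm": nc.imt[1],
        "nct_mid_mm": nc.nct[0],
        "nct_side_mm": nc.nct[1],
        "rnct_mid": nc.nct[0] / nc.imt[0],
        "rnct_side": nc.nct[1] / nc.imt[1],
        "min_capt_mm": nc.min_capt,
    }


def sample_population(
    pop: PopulationSpec,
) -> tuple[list[CrossSection], pd.DataFrame]:
    """Reproducible synthetic cohort plus a table of generating parameters.

    Returns the cross-sections and a truth DataFrame with one row per NC
    holding the exact generating feature values (the oracle for recovery and
    reconstruction tests).
    """
    rng = np.random.default_rng(pop.seed)
    limit = pop.n_sections if pop.n_sections is not None else math.inf

    # Phase 1: draw all per-section features.
    drawn = []  # (section meta, [nc feature dicts], lumen_r, ellipticity)
    total = 0
    for p in range(pop.n_patients):
        for a in range(pop.arteries_per_patient):
            latent_cov = rng.standard_normal()
            latent_resp = rng.standard_normal()
            artery = f"P{p}A{a}"
            for s in range(pop.sections_per_artery):
                if total >= limit:
                    break
                total += 1
                primary_angle = rng.uniform(0, TWO_PI)
                ncs = [_draw_nc_features(rng, pop, latent_cov, latent_resp,
                                         primary_angle, False)]
                if rng.uniform() < pop.two_nc_probability:
                    ncs.append(_draw_nc_features(rng, pop, latent_cov,
                                                 latent_resp, primary_angle,
                                                 True))
                lumen_r = pop.lumen_radius_median * math.exp(
                    0.15 * rng.standard_normal()
                )
                meta = (f"{artery}S{s}", artery, f"P{p}")
                drawn.append((meta, ncs, lumen_r, rng.uniform(0.0, 0.12)))

    # Phase 2: calibrate cap scale and rNCt offsets so cohort medians hit
    # the targets despite feasibility clamping and skewed covariates.
    all_nc = [d for _, ncs, _, _ in drawn for d in ncs]
    off_mid, off_side = _calibrate_cohort(all_nc, pop)

    # Phase 3: build geometries.
    sections: list[CrossSection] = []
    truth_rows: list[dict] = []
    for (sid, artery, patient), nc_feats, lumen_r, ell in drawn:
        ncs = [_nc_spec_from_features(d, off_mid, off_side) for d in nc_feats]
        spec = PlaqueSpec(
            lumen_radius=lumen_r,
            lumen_ellipticity=ell,
            far_imt=max(0.30, 0.35 * ncs[0].imt[0] / 1.05),
            ncs=tuple(ncs),
            vertex_density=512,
            section_id=sid,
            artery_id=artery,
            patient_id=patient,
        )
        spec = _fit_nc_thickness(spec)
        try:
            cs = make_idealized(spec)
        except SpecError:
            # Rare infeasible draw: fall back to a tamer single NC.
            spec = replace(spec, ncs=(spec.ncs[0],))
            try:
                cs = make_idealized(spec)
            except SpecError:
                continue
        sections.append(cs)
        for i, nc in enumerate(spec.ncs):
            truth_rows.append(_truth_row(spec, nc, i))
    truth = pd.DataFrame(truth_rows)
    truth.attrs["seed"] = pop.seed
    truth.attrs["rnct_offsets"] = (off_mid, off_side)
    return sections, truth


# ---------------------------------------------------------------------------
# GEE simulation
# ---------------------------------------------------------------------------

def simulate_gee_dataset(
    coeffs,
    residual_sd: float,
    pop: PopulationSpec,
    site: str = "midcap",
    rho: float | None = None,
) -> pd.DataFrame:
    """Covariate table with rNCt responses drawn from a known linear relation.

    Covariates follow the population marginals (without building polygons);
    the response is the linear predictor plus exchangeable cluster-correlated
    Gaussian noise with total SD ``residual_sd`` and within-artery correlation
    ``rho`` (defaults to the population value).  Generating coefficients are
    recorded in ``DataFrame.attrs['truth']`` for recovery tests.
    """
    rng = np.random.default_rng(pop.seed)
    rho = pop.within_artery_rho if rho is None else rho
    t = pop.targets
    key = "mid" if site == "midcap" else "side"
    sig_angle = _lognorm_sigma(*t["nc_angle_deg"][1:])
    sig_imt = _lognorm_sigma(*t[f"imt_{key}_mm"][1:])
    sig_capt = _lognorm_sigma(*t[f"capt_{key}_mm"][1:])

    rows = []
    n_arteries = pop.n_patients * pop.arteries_per_patient
    for a in range(n_arteries):
        b = rng.standard_normal()  # covariate clustering latent
        b_resp = rng.standard_normal()  # response clustering latent (separate:
        # correlated errors must stay exogenous to the covariates)
        for s in range(pop.sections_per_artery):
            angle = math.radians(
                min(_draw_lognormal(rng, t["nc_angle_deg"][0], sig_angle, b, rho), 150)
            )
            imt = max(_draw_lognormal(rng, t[f"imt_{key}_mm"][0], sig_imt,
                                      b, rho), 0.60) * 1e3
            capt = _draw_lognormal(rng, t[f"capt_{key}_mm"][0], sig_capt,
                                   b, rho) * 1e3
            # Same feasibility truncation as the geometric sampler: the cap
            # must leave room for the NC inside the intima.
            capt = min(capt, 0.55 * (imt - _MEDIA_TH * 1e3))
            mu = predict_rnct(coeffs, angle, imt, capt, clamp=False)
            eps = residual_sd * (
                math.sqrt(rho) * b_resp
                + math.sqrt(1 - rho) * rng.standard_normal()
            )
            rows.append(
                {
                    "rnct": mu + eps,
                    "nc_angle_rad": angle,
                    "imt_um": imt,
                    "capt_um": capt,
                    "artery_id": f"A{a}",
                    "site": site,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "beta0": coeffs.beta0,
        "beta_angle": coeffs.beta_angle,
        "beta_imt": coeffs.beta_imt,
        "beta_capt": coeffs.beta_capt,
        "residual_sd": residual_sd,
        "rho": rho,
        "seed": pop.seed,
    }
    return df
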