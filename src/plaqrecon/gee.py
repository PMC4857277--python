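"""Plaque-specific rNCt estimation via generalized estimating equations.

The relative NC thickness at a site is modeled linearly in the NC angle
(rad), the intima-media thickness (um) and the cap thickness (um):

    rNCt_i = beta0_i + beta_angle_i * angle + beta_IMT_i * IMT + beta_capT_i * capT

with ``i`` the midcap or (pooled +/-) sidecap relation.  Cross-sections from
one artery are correlated, so the model is fitted as a Gaussian identity-link
GEE with an exchangeable working correlation over artery clusters and a
robust (sandwich, Liang-Zeger) covariance for the coefficients.

The packaged default coefficients reproduce the published fit; they are
stored on the natural scale (the conventional presentation multiplies them by
1000).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PlaqreconError

PARAM_NAMES = ("beta0", "beta_angle", "beta_imt", "beta_capt")

#: Clamping band for out-of-range predictions (artifact policy).
CLAMP_LO, CLAMP_HI = 0.01, 0.95


@dataclass(frozen=True)
class GEECoefficients:
    """Fitted (or packaged) site-specific coefficients on the natural scale."""

    site: str  # "midcap" or "sidecap"
    beta0: float
    beta_angle: float  # per rad
    beta_imt: float  # per um
    beta_capt: float  # per um
    covariance: np.ndarray = field(
        default_factory=lambda: np.full((4, 4), np.nan)
    )
    r_squared: float = math.nan
    n_obs: int = 0
    n_clusters: int = 0

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (4, 4):
            raise PlaqreconError("covariance must be 4x4")
        object.__setattr__(self, "covariance", cov)

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_angle, self.beta_imt, self.beta_capt])

    def scaled_by_1000(self) -> np.ndarray:
        """Coefficients in the conventional x1000 presentation."""
        return self.betas * 1000.0

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "betas": self.betas.tolist(),
            "covariance": self.covariance.tolist(),
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GEECoefficients":
        b = d["betas"]
        return cls(
            site=d["site"],
            beta0=b[0],
            beta_angle=b[1],
            beta_imt=b[2],
            beta_capt=b[3],
            covariance=np.asarray(d["covariance"]),
            r_squared=d.get("r_squared", math.nan),
            n_obs=d.get("n_obs", 0),
            n_clusters=d.get("n_clusters", 0),
        )


def _packaged(site, b0, ba, bi, bc, se0, sea, sei, sec, r2):
    # Published values are x1000; store natural scale.  Robust SEs enter the
    # covariance diagonal (off-diagonals unpublished -> zero).
    cov = np.diag(np.array([se0, sea, sei, sec]) ** 2) / 1000.0**2
    return GEECoefficients(
        site=site,
        beta0=b0 / 1000.0,
        beta_angle=ba / 1000.0,
        beta_imt=bi / 1000.0,
        beta_capt=bc / 1000.0,
        covariance=cov,
        r_squared=r2,
        n_obs=73,
        n_clusters=13,
    )


#: Packaged published coefficients (x1000 presentation de-scaled).
TABLE_COEFFICIENTS = {
    "midcap": _packaged("midcap", 187.0, 63.3, 0.29, -0.51,
                        55.4, 26.6, 0.07, 0.08, 0.47),
    "sidecap": _packaged("sidecap", 175.0, 130.0, 0.18, -0.42,
                         46.4, 19.8, 0.05, 0.06, 0.44),
}


def predict_rnct(
    coeffs: GEECoefficients,
    nc_angle_rad: float,
    imt_um: float,
    capt_um: float,
    clamp: bool = True,
) -> float:
    """Evaluate the linear predictor; optionally clamp into (0, 1).

    Angle in radians, IMT and capT in micrometres.  Predictions outside the
    physical range are clamped to [0.01, 0.95] when ``clamp`` is set (the
    caller can inspect the raw value with ``clamp=False``).
    """
    val = (
        coeffs.beta0
        + coeffs.beta_angle * nc_angle_rad
        + coeffs.beta_imt * imt_um
        + coeffs.beta_capt * capt_um
    )
    if clamp:
        return float(np.clip(val, CLAMP_LO, CLAMP_HI))
    return float(val)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame):
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["nc_angle_rad"].to_numpy(float),
            table["imt_um"].to_numpy(float),
            table["capt_um"].to_numpy(float),
        ]
    )
    y = table["rnct"].to_numpy(float)
    clusters = table["artery_id"].to_numpy()
    return X, y, clusters


def fit_gee(
    table: pd.DataFrame,
    site: str = "midcap",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GEECoefficients:
    """Gaussian identity-link GEE with exchangeable working correlation.

    ``table`` needs columns rnct, nc_angle_rad, imt_um, capt_um, artery_id.
    Iterates coefficient/correlation updates until the relative coefficient
    change falls below ``tol``; the coefficient covariance is the
    cluster-robust sandwich estimator, and r^2 is the squared Pearson
    correlation of fitted vs observed rNCt.
    """
    X, y, clusters = _design(table)
    n, p = X.shape
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise PlaqreconError("GEE needs at least 2 clusters")
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        corr = np.corrcoef(X[:, 1:].T)
        raise PlaqreconError(
            "singular design matrix; covariate correlations:\n" + str(corr)
        )
    idx = [np.flatnonzero(clusters == lab) for lab in labels]

    beta = np.linalg.lstsq(X, y, rcond=None)[0]  # OLS start
    alpha = 0.0
    trace = []
    for it in range(max_iter):
        resid = y - X @ beta
        phi = float(resid @ resid) / max(n - p, 1)
        # Exchangeable correlation from within-cluster residual products.
        num, pairs = 0.0, 0
        for ii in idx:
            r = resid[ii]
            ni = len(r)
            if ni > 1:
                num += (r.sum() ** 2 - (r**2).sum()) / 2.0
                pairs += ni * (ni - 1) // 2
        alpha = 0.0 if pairs <= p else float(np.clip(num / phi / (pairs - p), -0.2, 0.99))

        A = np.zeros((p, p))
        b = np.zeros(p)
        for ii in idx:
            ni = len(ii)
            Ri = np.full((ni, ni), alpha) + (1 - alpha) * np.eye(ni)
            Wi = np.linalg.inv(Ri) / phi
            Xi = X[ii]
            A += Xi.T @ Wi @ Xi
            b += Xi.T @ Wi @ y[ii]
        new_beta = np.linalg.solve(A, b)
        delta = np.max(np.abs(new_beta - beta) / np.maximum(np.abs(new_beta), 1e-12))
        trace.append(delta)
        beta = new_beta
        if delta < tol:
            break
    else:
        raise PlaqreconError(f"GEE did not converge; relative-change trace: {trace}")

    # Bias-corrected (Mancl-DeRouen) sandwich covariance: cluster residuals
    # are inflated by (I - H_i)^-1, which keeps coverage honest when a
    # heavy-tailed covariate gives single clusters high leverage.
    resid = y - X @ beta
    phi = float(resid @ resid) / max(n - p, 1)
    B = np.zeros((p, p))
    parts = []
    for ii in idx:
        ni = len(ii)
        Ri = np.full((ni, ni), alpha) + (1 - alpha) * np.eye(ni)
        Wi = np.linalg.inv(Ri) / phi
        Xi = X[ii]
        parts.append((Xi, Wi, resid[ii]))
        B += Xi.T @ Wi @ Xi
    Binv = np.linalg.inv(B)
    M = np.zeros((p, p))
    for Xi, Wi, ei in parts:
        Hi = Xi @ Binv @ Xi.T @ Wi
        ei_adj = np.linalg.solve(np.eye(len(ei)) - Hi, ei)
        g = Xi.T @ Wi @ ei_adj
        M += np.outer(g, g)
    cov = Binv @ M @ Binv

    fitted = X @ beta
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    return GEECoefficients(
        site=site,
        beta0=beta[0],
        beta_angle=beta[1],
        beta_imt=beta[2],
        beta_capt=beta[3],
        covariance=cov,
        r_squared=r2,
        n_obs=n,
        n_clusters=len(labels),
    )


def wald_tests(coeffs: GEECoefficients) -> pd.DataFrame:
    """Per-coefficient robust z statistics and two-sided normal p values."""
    se = np.sqrt(np.diag(coeffs.covariance))
    betas = coeffs.betas
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, betas / se, np.inf * np.sign(betas))
    z = np.where(betas == 0.0, 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"parameter": PARAM_NAMES, "beta": betas, "se": se,
                         "z": z, "p": p})


def save_coefficients(coeffs: GEECoefficients, path) -> None:
    with open(path, "w") as fh:
        json.dump(coeffs.to_dict(), fh, indent=2)


def load_coefficients(path) -> GEECoefficients:
    with open(path) as fh:
        return GEECoefficients.from_dict(json.load(fh))
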