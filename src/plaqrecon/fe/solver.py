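"""Nearly-incompressible neo-Hookean plane-strain solver.

Total-Lagrangian formulation on (quadratic) triangles with strain energy

    W = C10 (I1_bar - 3) + (K / 2) (J - 1)^2,   I1_bar = J^(-2/3) I1,

plane strain (F33 = 1), follower pressure on the lumen border, Newton
iterations with load stepping and adaptive substepping.  The consistent
material tangent is obtained by central differencing of the first
Piola-Kirchhoff stress (the unsymmetric follower-load stiffness is omitted;
with the small load increments used here Newton still contracts quickly).

The Cauchy stress is reported per element (quadrature average) as the full
3D tensor implied by plane strain, including the out-of-plane component, and
the von Mises stress is computed from that full tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..errors import FEError
from .mesh import FEModel

# 3-point quadrature on the reference triangle (weights sum to 1/2).
_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW = np.array([1 / 6, 1 / 6, 1 / 6])

# 3-point Gauss on [-1, 1] for the pressurized quadratic edges.
_EQ = np.array([-math.sqrt(3 / 5), 0.0, math.sqrt(3 / 5)])
_EW = np.array([5 / 9, 8 / 9, 5 / 9])


def _tri6_dN(xi: float, eta: float) -> np.ndarray:
    l1, l2, l3 = 1 - xi - eta, xi, eta
    d1, d2, d3 = np.array([-1.0, -1.0]), np.array([1.0, 0.0]), np.array([0.0, 1.0])
    return np.array(
        [
            (4 * l1 - 1) * d1,
            (4 * l2 - 1) * d2,
            (4 * l3 - 1) * d3,
            4 * (l2 * d1 + l1 * d2),
            4 * (l3 * d2 + l2 * d3),
            4 * (l1 * d3 + l3 * d1),
        ]
    )


def _tri3_dN(xi: float, eta: float) -> np.ndarray:
    return np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])


@dataclass
class StressField:
    displacements: np.ndarray  # (N, 2) mm
    cauchy: np.ndarray  # (ne, 4): sxx, syy, sxy, szz (kPa)
    von_mises: np.ndarray  # (ne,) kPa
    pressure: float  # kPa


@dataclass(frozen=True)
class PCSResult:
    pcs: float  # kPa
    location: np.ndarray  # element centroid, reference coordinates (mm)
    region: str  # "cap" or "shoulder"
    element: int = -1


class _Assembler:
    """Precomputed element operators for one mesh."""

    def __init__(self, model: FEModel):
        self.model = model
        elems = model.elements
        self.nn = elems.shape[1]
        dN_fn = _tri6_dN if self.nn == 6 else _tri3_dN
        qp = _QP if self.nn == 6 else np.array([[1 / 3, 1 / 3]])
        qw = _QW if self.nn == 6 else np.array([0.5])
        self.dN = np.stack([dN_fn(x, e) for x, e in qp])  # (q, a, 2)
        self.qw = qw
        X = model.nodes[elems]  # (ne, a, 2)
        # Jacobian dX/dxi per (e, q): J[i, j] = sum_a dN[q,a,j] X[e,a,i]
        Jac = np.einsum("qaj,eai->eqij", self.dN, X)
        detJ = Jac[..., 0, 0] * Jac[..., 1, 1] - Jac[..., 0, 1] * Jac[..., 1, 0]
        if np.any(detJ <= 0):
            raise FEError("non-positive element Jacobian in reference mesh")
        inv = np.empty_like(Jac)
        inv[..., 0, 0] = Jac[..., 1, 1]
        inv[..., 1, 1] = Jac[..., 0, 0]
        inv[..., 0, 1] = -Jac[..., 0, 1]
        inv[..., 1, 0] = -Jac[..., 1, 0]
        inv /= detJ[..., None, None]
        # G[e,q,a,i] = dN_a/dX_i
        self.G = np.einsum("qaj,eqji->eqai", self.dN, inv)
        self.wdet = self.qw[None, :] * detJ  # (ne, q)
        self.C10 = model.C10[:, None]
        self.K = model.K[:, None]

        ndof_e = 2 * self.nn
        dofs = (2 * elems[:, :, None] + np.arange(2)[None, None, :]).reshape(
            len(elems), ndof_e
        )
        self.rows = np.repeat(dofs, ndof_e, axis=1).ravel()
        self.cols = np.tile(dofs, (1, ndof_e)).ravel()
        self.dofs = dofs
        self.ndof = 2 * model.n_nodes

    # -- kinematics ---------------------------------------------------------
    def deformation(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 2)[self.model.elements]  # (ne, a, 2)
        gradu = np.einsum("eai,eqaj->eqij", ue, self.G)
        F = gradu.copy()
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        return F

    def piola(self, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(P_2x2, P33) of the plane-strain neo-Hookean energy."""
        J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        if np.any(J <= 0):
            raise FEError("element inversion (det F <= 0)")
        I1 = np.einsum("...ij,...ij->...", F, F) + 1.0
        Jm23 = J ** (-2.0 / 3.0)
        FinvT = np.empty_like(F)
        FinvT[..., 0, 0] = F[..., 1, 1]
        FinvT[..., 1, 1] = F[..., 0, 0]
        FinvT[..., 0, 1] = -F[..., 1, 0]
        FinvT[..., 1, 0] = -F[..., 0, 1]
        FinvT /= J[..., None, None]
        C10 = self.C10
        K = self.K
        iso = 2.0 * C10[..., None, None] * Jm23[..., None, None] * (
            F - (I1 / 3.0)[..., None, None] * FinvT
        )
        vol = (K * (J - 1.0) * J)[..., None, None] * FinvT
        P = iso + vol
        P33 = C10 * Jm23 * (2.0 - 2.0 * I1 / 3.0) + K * (J - 1.0) * J
        return P, P33

    def internal_force(self, F: np.ndarray) -> np.ndarray:
        P, _ = self.piola(F)
        fe = np.einsum("eq,eqij,eqaj->eai", self.wdet, P, self.G)
        f = np.zeros(self.ndof)
        np.add.at(f, self.dofs.reshape(len(fe), -1),
                  fe.reshape(len(fe), -1))
        return f

    def tangent(self, F: np.ndarray) -> sp.csr_matrix:
        h = 1e-7
        A = np.empty(F.shape[:2] + (2, 2, 2, 2))
        for k in range(2):
            for l in range(2):
                Fp = F.copy()
                Fp[..., k, l] += h
                Pp, _ = self.piola(Fp)
                Fm = F.copy()
                Fm[..., k, l] -= h
                Pm, _ = self.piola(Fm)
                A[..., k, l] = (Pp - Pm) / (2 * h)  # A[e,q,i,j,k,l]
        # K[(a,i),(b,k)] = sum_q w |J| G[a,j] dP_ij/dF_kl G[b,l]
        Ke = np.einsum("eq,eqaj,eqijkl,eqbl->eaibk", self.wdet, self.G,
                       A, self.G, optimize=True)
        vals = Ke.reshape(len(Ke), -1).ravel()
        Kmat = sp.coo_matrix((vals, (self.rows, self.cols)),
                             shape=(self.ndof, self.ndof))
        return Kmat.tocsr()

    # -- follower pressure --------------------------------------------------
    def external_force(self, u: np.ndarray, p: float) -> np.ndarray:
        f = np.zeros(self.ndof)
        if p == 0.0 or len(self.model.lumen_edges) == 0:
            return f
        edges = self.model.lumen_edges
        x = self.model.nodes + u.reshape(-1, 2)
        if edges.shape[1] == 3:
            xe = x[edges]  # (m, 3, 2): start, end, mid
            for xi, w in zip(_EQ, _EW):
                N = np.array([xi * (xi - 1) / 2, xi * (xi + 1) / 2, 1 - xi * xi])
                dN = np.array([xi - 0.5, xi + 0.5, -2 * xi])
                t = np.einsum("a,mai->mi", dN, xe)
                nrm = np.column_stack([t[:, 1], -t[:, 0]])  # outward from lumen
                fa = p * w * N[None, :, None] * nrm[:, None, :]
                np.add.at(f, (2 * edges[..., None] + np.arange(2)).reshape(-1),
                          fa.reshape(-1))
        else:
            xe = x[edges]
            t = xe[:, 1] - xe[:, 0]
            nrm = np.column_stack([t[:, 1], -t[:, 0]])
            fa = 0.5 * p * np.repeat(nrm[:, None, :], 2, axis=1)
            np.add.at(f, (2 * edges[..., None] + np.arange(2)).reshape(-1),
                      fa.reshape(-1))
        return f


def _free_dofs(model: FEModel, extra_fixed=None) -> np.ndarray:
    fixed = set()
    for n in model.fixed_nodes:
        fixed.add(2 * int(n))
        fixed.add(2 * int(n) + 1)
    for d in extra_fixed if extra_fixed is not None else []:
        fixed.add(int(d))
    return np.setdiff1d(np.arange(2 * model.n_nodes), np.fromiter(fixed, int))


def solve_pressurized(
    model: FEModel,
    p_kpa: float,
    u0: np.ndarray | None = None,
    extra_fixed_dofs=None,
    n_steps: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 25,
    max_halvings: int = 8,
) -> StressField:
    """Static equilibrium under lumen pressure ``p_kpa``.

    Load is ramped in increments (adaptively halved on Newton failure or
    element inversion); within each increment Newton iterates until the
    residual drops below ``tol`` relative to the external load.
    """
    asm = _Assembler(model)
    free = _free_dofs(model, extra_fixed_dofs)
    if len(free) == 2 * model.n_nodes and len(model.lumen_edges):
        raise FEError("model has no constraints; pin rigid-body modes")
    u = np.zeros(2 * model.n_nodes) if u0 is None else u0.copy()

    if n_steps is None:
        n_steps = max(1, int(math.ceil(abs(p_kpa) / 5.0)))
    p_done = 0.0
    dp = p_kpa / n_steps if n_steps else 0.0
    halvings = 0
    while p_done < p_kpa - 1e-12 or (p_kpa == 0.0 and p_done == 0.0):
        if p_kpa == 0.0:
            break
        p_try = min(p_done + dp, p_kpa)
        u_save = u.copy()
        try:
            u = _newton(asm, free, u, p_try, tol, max_iter)
        except FEError:
            halvings += 1
            if halvings > max_halvings:
                raise FEError(
                    f"Newton failed; last converged load {p_done:.3f} kPa"
                )
            dp *= 0.5
            u = u_save
            continue
        p_done = p_try

    F = asm.deformation(u)
    P, P33 = asm.piola(F)
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    # Cauchy sigma = (1/J) P F^T per quadrature point, then element average.
    sig = np.einsum("eqij,eqkj->eqik", P, F) / J[..., None, None]
    sxx = sig[..., 0, 0].mean(axis=1)
    syy = sig[..., 1, 1].mean(axis=1)
    sxy = (0.5 * (sig[..., 0, 1] + sig[..., 1, 0])).mean(axis=1)
    szz = (P33 / J).mean(axis=1)
    cauchy = np.column_stack([sxx, syy, sxy, szz])
    vm = _von_mises(cauchy)
    return StressField(
        displacements=u.reshape(-1, 2), cauchy=cauchy, von_mises=vm,
        pressure=p_kpa,
    )


def _residual_norm(asm, free, u, p):
    F = asm.deformation(u)
    fint = asm.internal_force(F)
    fext = asm.external_force(u, p)
    R = fint - fext
    return F, R, float(np.linalg.norm(R[free])), float(np.linalg.norm(fext[free]))


def _newton(asm, free, u, p, tol, max_iter):
    ref = 1e-12
    lu = None
    rn_prev = math.inf
    F, R, rn, fe_n = _residual_norm(asm, free, u, p)
    for it in range(max_iter):
        ref = max(ref, fe_n)
        if rn <= tol * ref:
            return u
        # Refactorize only while convergence is not yet contracting well;
        # the reused factorization still drives the true residual down.
        if lu is None or rn > 0.2 * rn_prev:
            K = asm.tangent(F)
            lu = spla.splu(K[free][:, free].tocsc())
        du = lu.solve(-R[free])
        if not np.all(np.isfinite(du)):
            raise FEError("singular tangent")
        rn_prev = rn
        # Backtracking line search: reject steps that invert elements or
        # grow the residual.
        alpha = 1.0
        accepted = False
        for _ in range(6):
            u_try = u.copy()
            u_try[free] += alpha * du
            try:
                F_t, R_t, rn_t, fe_t = _residual_norm(asm, free, u_try, p)
            except FEError:
                alpha *= 0.5
                continue
            if rn_t < rn or rn_t <= tol * max(ref, fe_t):
                u, F, R, rn, fe_n = u_try, F_t, R_t, rn_t, fe_t
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            raise FEError("line search failed (stalled Newton step)")
    raise FEError(f"Newton did not converge in {max_iter} iterations")


def _von_mises(cauchy: np.ndarray) -> np.ndarray:
    sxx, syy, sxy, szz = cauchy.T
    return np.sqrt(
        0.5
        * (
            (sxx - syy) ** 2
            + (syy - szz) ** 2
            + (szz - sxx) ** 2
            + 6.0 * sxy**2
        )
    )


# ---------------------------------------------------------------------------
# Prestress
# ---------------------------------------------------------------------------

def prestress_backward_incremental(
    model: FEModel,
    p0_kpa: float,
    tol_mm: float = 1e-3,
    max_outer: int = 50,
    relax: float = 1.0,
    **solve_kw,
) -> tuple[FEModel, dict]:
    """Unloaded configuration whose pressurization recovers the imaged one.

    Fixed-point iteration on the estimated unloaded node set X: pressurize X
    to ``p0_kpa``, compare the deformed nodes with the imaged nodes x*, and
    update X <- X - relax * (x(X) - x*) until the maximum mismatch falls
    below ``tol_mm`` (default 1 um).  On three consecutive error increases
    the iteration restarts once with under-relaxation 0.5.
    """
    x_star = model.nodes.copy()
    if p0_kpa == 0.0:
        return model, {"iterations": 0, "error_mm": 0.0, "converged": True}

    X = x_star.copy()
    X_good = None  # last X whose pressurization succeeded
    errs: list[float] = []
    u_ws = None
    alpha = relax
    it = 0
    backoffs = 0
    while it < max_outer:
        m = model.with_nodes(X)
        field = None
        if u_ws is not None:
            # Warm start: the previous outer iterate is an excellent initial
            # guess; try a cheap single load step (no halving retries)
            # before re-ramping from zero.
            try:
                field = solve_pressurized(m, p0_kpa, u0=u_ws, n_steps=1,
                                          max_iter=10, max_halvings=0,
                                          **solve_kw)
            except FEError:
                field = None
        if field is None:
            try:
                field = solve_pressurized(m, p0_kpa, **solve_kw)
            except FEError:
                # The current estimate is mechanically worse than the imaged
                # geometry; back off toward the last solvable estimate with
                # a damped update.
                if X_good is None or backoffs >= 12:
                    raise
                backoffs += 1
                alpha = max(0.5 * alpha, 0.05)
                X = 0.5 * (X + X_good)
                continue
        it += 1
        X_good = X.copy()
        u_ws = field.displacements.ravel()
        x = X + field.displacements
        err = float(np.max(np.hypot(*(x - x_star).T)))
        if err < tol_mm:
            return model.with_nodes(X), {
                "iterations": it, "error_mm": err, "converged": True,
                "relax": alpha, "u_at_p0": field.displacements.copy(),
            }
        # Growing mismatch: damp the fixed-point update instead of diverging.
        if errs and err > errs[-1]:
            alpha = max(0.5 * alpha, 0.05)
            if alpha <= 0.05 and err > 3.0 * min(errs):
                raise FEError(
                    f"backward-incremental prestress diverged "
                    f"(error {err:.2e} mm after {it} iterations)"
                )
        errs.append(err)
        X = X - alpha * (x - x_star)
    raise FEError(
        f"backward-incremental prestress did not reach {tol_mm} mm in "
        f"{max_outer} iterations (last error {errs[-1]:.2e} mm)"
    )


# ---------------------------------------------------------------------------
# Peak cap stress
# ---------------------------------------------------------------------------

def peak_cap_stress(
    field: StressField,
    model: FEModel,
    shoulder_deg: float = 15.0,
    span: tuple[float, float] | None = None,
) -> PCSResult:
    """Maximum von Mises stress over the cap and its 15-degree shoulders.

    The cap is the intima in front of the NC (within the NC angular span);
    the shoulders are the intima within ``shoulder_deg`` beyond either end of
    the span.  Locations are reported in the reference (imaged) frame.
    """
    spans = [span] if span is not None else model.spans
    if not spans:
        raise FEError("model has no NC span; peak cap stress undefined")
    sh = math.radians(shoulder_deg)
    two_pi = 2 * math.pi
    cap_mask = np.zeros(len(field.von_mises), dtype=bool)
    shoulder_mask = np.zeros_like(cap_mask)
    is_cap_band = model.band == 0
    is_intima = (model.band == 0) | (model.band == 2)
    for s, e in spans:
        width = e - s
        off = (model.elem_angle - s) % two_pi
        inside = off <= width
        cap_mask |= is_cap_band & inside
        shoulder_off = ((off > width) & (off <= width + sh)) | (off >= two_pi - sh)
        shoulder_mask |= is_intima & shoulder_off
    cand = cap_mask | shoulder_mask
    if not np.any(cand):
        raise FEError("empty cap+shoulder element set")
    idx = np.flatnonzero(cand)
    best = idx[np.argmax(field.von_mises[idx])]
    region = "cap" if cap_mask[best] else "shoulder"
    centroid = model.nodes[model.elements[best, :3]].mean(axis=0)
    return PCSResult(
        pcs=float(field.von_mises[best]),
        location=centroid,
        region=region,
        element=int(best),
    )
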