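"""Total-Lagrangian FEM core: element kernels, assembly, Newton solver.

Elements
--------
* 6-node linear wedge (prism), full 3×2 Gauss integration, Saint-Venant–
  Kirchhoff material (second Piola–Kirchhoff stress linear in the
  Green–Lagrange strain), isotropic per layer.
* 3-node membrane, plane-stress Saint-Venant–Kirchhoff, one-point
  integration, no bending resistance.  A small diagonal regularization is
  added to the tangent (never to the residual) so the singular
  transverse modes of an unstressed membrane do not stall the first Newton
  steps; equilibrium is unaffected.

Loads
-----
Internal pressure is a follower load on the (current) inner surface with
its consistent, unsymmetric load stiffness.  Rigid-sphere contact uses a
node-to-surface penalty with consistent tangent.

Units: µm / µN / MPa (1 µN/µm = 1 N/m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = ["FEMSystem", "RigidSphere", "NewtonError", "newton_solve"]

_SQ3 = 1.0 / np.sqrt(3.0)


class NewtonError(RuntimeError):
    """Raised when the Newton loop fails to converge."""

    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


def _wedge_shape_gradients():
    """dN/dξ at the 6 Gauss points of the reference wedge: (gp, node, 3)."""
    tri_pts = [(1 / 6, 1 / 6), (2 / 3, 1 / 6), (1 / 6, 2 / 3)]
    out = []
    for zeta in (-_SQ3, _SQ3):
        for (r, s) in tri_pts:
            t = 1.0 - r - s
            m, p = (1 - zeta) / 2, (1 + zeta) / 2
            dN = np.array(
                [
                    [-m, -m, -t / 2],
                    [m, 0.0, -r / 2],
                    [0.0, m, -s / 2],
                    [-p, -p, t / 2],
                    [p, 0.0, r / 2],
                    [0.0, p, s / 2],
                ]
            )
            out.append(dN)
    return np.array(out)  # (6, 6, 3)


_WEDGE_DN = _wedge_shape_gradients()
_WEDGE_W = np.full(6, 1.0 / 6.0)  # triangle weight 1/6 × ζ-weight 1


def _lame(E, nu):
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    return lam, mu


def _skew(v):
    """Batch skew-symmetric matrices: v (..., 3) -> (..., 3, 3)."""
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


@dataclass
class RigidSphere:
    """Displacement-controlled rigid spherical indenter.

    The penalty force is C¹-smoothed: quadratic in the penetration over the
    first ``smoothing`` µm, linear beyond — grazing nodes then enter contact
    without tangent discontinuities that make the active set chatter.
    """

    center: np.ndarray      # current center position, µm
    radius: float           # µm
    axis: np.ndarray        # outward unit axis of indentation
    candidates: np.ndarray  # node ids that may contact
    penalty: float = 1000.0  # contact pressure per penetration, MPa/µm
    smoothing: float = 0.02  # µm
    areas: np.ndarray | None = None  # tributary area per candidate (µm²)


class FEMSystem:
    """Assembled mechanical system on a :class:`ShellMesh`."""

    def __init__(self, mesh, materials: dict, membrane_stabilization: float = 1e-4):
        self.mesh = mesh
        self.n_dof = 3 * mesh.n_nodes
        self.materials = dict(materials)
        self.membrane_stabilization = membrane_stabilization

        # --- wedge precomputation -----------------------------------------
        self.wedges = mesh.wedges
        ne = len(self.wedges)
        if ne:
            X = mesh.nodes[self.wedges]                       # (ne, 6, 3)
            J = np.einsum("gal,eak->egkl", _WEDGE_DN, X)      # (ne, gp, 3, 3)
            detJ = np.linalg.det(J)
            if np.any(detJ <= 0):
                raise ValueError("inverted wedge element in reference mesh")
            invJ = np.linalg.inv(J)
            self.wG = np.einsum("gal,eglk->egak", _WEDGE_DN, invJ)  # dN/dX
            self.wWeight = detJ * _WEDGE_W[None, :]
            lam = np.empty(ne)
            mu = np.empty(ne)
            for name, (E, nu) in self.materials.items():
                m = mesh.layer_id == name
                lam[m], mu[m] = _lame(E, nu)
            self.wLam = lam[:, None]
            self.wMu = mu[:, None]
            dofs = (3 * self.wedges[:, :, None] + np.arange(3)).reshape(ne, 18)
            self.wRows = np.repeat(dofs, 18, axis=1).ravel()
            self.wCols = np.tile(dofs, (1, 18)).ravel()
            self.wDofs = dofs
        # --- membrane precomputation --------------------------------------
        self.membranes = mesh.membranes
        nm = len(self.membranes)
        if nm:
            E, nu = self.materials["membrane"]
            t = mesh.thickness["membrane"]
            Xm = mesh.nodes[self.membranes]                   # (nm, 3, 3)
            e1 = Xm[:, 1] - Xm[:, 0]
            e2full = Xm[:, 2] - Xm[:, 0]
            nrm = np.cross(e1, e2full)
            area = 0.5 * np.linalg.norm(nrm, axis=1)
            b1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
            nh = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
            b2 = np.cross(nh, b1)
            # reference 2D coordinates and constant shape gradients
            x2 = np.einsum("ei,ei->e", e1, b1)
            x3 = np.einsum("ei,ei->e", e2full, b1)
            y3 = np.einsum("ei,ei->e", e2full, b2)
            G2 = np.empty((nm, 3, 2))
            G2[:, 1, 0] = y3 / (x2 * y3)
            G2[:, 1, 1] = -x3 / (x2 * y3)
            G2[:, 2, 0] = 0.0
            G2[:, 2, 1] = 1.0 / y3
            G2[:, 0] = -G2[:, 1] - G2[:, 2]
            self.mG = G2
            self.mWeight = (area * t)[:, None]
            self.mLamPS = E * nu / (1 - nu**2)
            self.mMu = E / (2 * (1 + nu))
            dofs = (3 * self.membranes[:, :, None] + np.arange(3)).reshape(nm, 9)
            self.mRows = np.repeat(dofs, 9, axis=1).ravel()
            self.mCols = np.tile(dofs, (1, 9)).ravel()
            self.mDofs = dofs
        # --- pressure faces ------------------------------------------------
        self.pfaces = mesh.pressure_faces
        nf = len(self.pfaces)
        if nf:
            dofs = (3 * self.pfaces[:, :, None] + np.arange(3)).reshape(nf, 9)
            self.pRows = np.repeat(dofs, 9, axis=1).ravel()
            self.pCols = np.tile(dofs, (1, 9)).ravel()
            self.pDofs = dofs

        # --- constraints ---------------------------------------------------
        self.fixed_dofs = np.zeros(self.n_dof, dtype=bool)
        for n in mesh.unused_nodes:
            self.fixed_dofs[3 * n:3 * n + 3] = True
        self.free = np.nonzero(~self.fixed_dofs)[0]

    # -- constraint management ---------------------------------------------

    def fix_dofs(self, dof_ids):
        self.fixed_dofs[np.asarray(dof_ids, dtype=int)] = True
        self.free = np.nonzero(~self.fixed_dofs)[0]

    def fix_nodes(self, node_ids):
        ids = np.asarray(node_ids, dtype=int)
        self.fix_dofs((3 * ids[:, None] + np.arange(3)).ravel())

    # -- element kernels ----------------------------------------------------

    def _wedge_forces(self, u, want_tangent):
        ue = u.reshape(-1, 3)[self.wedges]                      # (ne, 6, 3)
        F = np.einsum("egak,eai->egik", self.wG, ue)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        C = np.einsum("egki,egkj->egij", F, F)
        Egl = 0.5 * (C - np.eye(3))
        trE = np.trace(Egl, axis1=-2, axis2=-1)
        lam = self.wLam[:, :, None, None]
        mu = self.wMu[:, :, None, None]
        S = 2.0 * mu * Egl
        S[..., 0, 0] += (lam * trE[..., None, None])[..., 0, 0]
        S[..., 1, 1] += (lam * trE[..., None, None])[..., 0, 0]
        S[..., 2, 2] += (lam * trE[..., None, None])[..., 0, 0]
        P = np.einsum("egik,egkj->egij", F, S)
        w = self.wWeight
        fint = np.einsum("eg,egaJ,egiJ->eai", w, self.wG, P)
        if not want_tangent:
            return fint, S, F, None
        B = np.einsum("egik,egjk->egij", F, F)
        eye = np.eye(3)
        # A_iJjL = δ_ij S_JL + λ F_iJ F_jL + μ B_ij δ_JL + μ F_iL F_jJ
        A = (
            np.einsum("ij,egJL->egiJjL", eye, S, optimize=True)
            + lam[..., None, None] * np.einsum("egiJ,egjL->egiJjL", F, F, optimize=True)
            + mu[..., None, None] * np.einsum("egij,JL->egiJjL", B, eye, optimize=True)
            + mu[..., None, None] * np.einsum("egiL,egjJ->egiJjL", F, F, optimize=True)
        )
        T = np.einsum("eg,egaJ,egiJjL->egaijL", w, self.wG, A, optimize=True)
        Ke = np.einsum("egaijL,egbL->eaibj", T, self.wG, optimize=True).reshape(-1, 324)
        return fint, S, F, Ke

    def _membrane_forces(self, u, want_tangent):
        ue = u.reshape(-1, 3)[self.membranes]                   # (nm, 3, 3)
        xe = self.mesh.nodes[self.membranes] + ue
        F = np.einsum("eaJ,eai->eiJ", self.mG, xe)              # (nm, 3, 2)
        C = np.einsum("ekI,ekJ->eIJ", F, F)
        Egl = 0.5 * (C - np.eye(2))
        trE = np.trace(Egl, axis1=-2, axis2=-1)
        S = 2.0 * self.mMu * Egl
        S[..., 0, 0] += self.mLamPS * trE
        S[..., 1, 1] += self.mLamPS * trE
        P = np.einsum("eiK,eKJ->eiJ", F, S)
        fint = self.mWeight[..., None] * np.einsum("eaJ,eiJ->eai", self.mG, P)
        if not want_tangent:
            return fint, None
        B = np.einsum("eiK,ejK->eij", F, F)
        eye2 = np.eye(2)
        eye3 = np.eye(3)
        A = (
            np.einsum("ij,eJL->eiJjL", eye3, S)
            + self.mLamPS * np.einsum("eiJ,ejL->eiJjL", F, F)
            + self.mMu * np.einsum("eij,JL->eiJjL", B, eye2)
            + self.mMu * np.einsum("eiL,ejJ->eiJjL", F, F)
        )
        Ke = self.mWeight[:, 0, None] * np.einsum(
            "eaJ,eiJjL,ebL->eaibj", self.mG, A, self.mG, optimize=True
        ).reshape(-1, 81)
        return fint, Ke

    def _pressure_forces(self, u, pressure, want_tangent):
        x = (self.mesh.nodes + u.reshape(-1, 3))[self.pfaces]   # (nf, 3, 3)
        e1 = x[:, 1] - x[:, 0]
        e2 = x[:, 2] - x[:, 0]
        nvec = np.cross(e1, e2)
        fnode = (pressure / 6.0) * nvec                         # same for 3 nodes
        fext = np.repeat(fnode[:, None, :], 3, axis=1)
        if not want_tangent:
            return fext, None
        J1 = _skew(e2) - _skew(e1)
        J2 = -_skew(e2)
        J3 = _skew(e1)
        Kf = np.empty((len(self.pfaces), 3, 3, 3, 3))
        for a in range(3):
            Kf[:, a, :, 0, :] = (pressure / 6.0) * J1
            Kf[:, a, :, 1, :] = (pressure / 6.0) * J2
            Kf[:, a, :, 2, :] = (pressure / 6.0) * J3
        return fext, Kf.reshape(-1, 81)

    def _contact_forces(self, u, contact: RigidSphere, want_tangent):
        ids = contact.candidates
        x = self.mesh.nodes[ids] + u.reshape(-1, 3)[ids]
        d = np.linalg.norm(x - contact.center, axis=1)
        pen = contact.radius - d
        active = pen > 0
        f = np.zeros(self.n_dof)
        blocks, adof = None, None
        if np.any(active):
            ai = ids[active]
            xa = x[active]
            da = d[active]
            pa = pen[active]
            ua = (xa - contact.center) / da[:, None]
            eps = contact.smoothing
            # area-weighted penalty: constant contact pressure per unit
            # penetration, so the law is mesh-independent
            k = contact.penalty * (
                contact.areas[active] if contact.areas is not None else 1.0
            )
            small = pa < eps
            g = np.where(small, k * pa**2 / (2 * eps), k * (pa - eps / 2))
            gp = np.where(small, k * pa / eps, k)
            fa = g[:, None] * ua
            dof = (3 * ai[:, None] + np.arange(3))
            np.add.at(f, dof.ravel(), fa.ravel())
            if want_tangent:
                eye = np.eye(3)
                uu = np.einsum("ni,nj->nij", ua, ua)
                Jc = (-gp[:, None, None] * uu
                      + (g / da)[:, None, None] * (eye - uu))
                blocks = -Jc  # external force: enters jacobian negated
                adof = dof
        return f, blocks, adof

    # -- global assembly -----------------------------------------------------

    def assemble(self, u, pressure=0.0, contact: RigidSphere | None = None,
                 want_tangent=True):
        """Residual r = f_int − f_ext and (optionally) the tangent."""
        f_int = np.zeros(self.n_dof)
        f_ext = np.zeros(self.n_dof)
        vals, rows, cols = [], [], []

        if len(self.wedges):
            fw, _, _, Kw = self._wedge_forces(u, want_tangent)
            np.add.at(f_int, self.wDofs.ravel(),
                      fw.reshape(len(self.wedges), 18).ravel())
            if want_tangent:
                vals.append(Kw.ravel())
                rows.append(self.wRows)
                cols.append(self.wCols)
        if len(self.membranes):
            fm, Km = self._membrane_forces(u, want_tangent)
            np.add.at(f_int, self.mDofs.ravel(),
                      fm.reshape(len(self.membranes), 9).ravel())
            if want_tangent:
                vals.append(Km.ravel())
                rows.append(self.mRows)
                cols.append(self.mCols)
        if pressure != 0.0 and len(self.pfaces):
            fp, Kp = self._pressure_forces(u, pressure, want_tangent)
            np.add.at(f_ext, self.pDofs.ravel(),
                      fp.reshape(len(self.pfaces), 9).ravel())
            if want_tangent:
                vals.append(-Kp.ravel())  # jacobian of −f_ext
                rows.append(self.pRows)
                cols.append(self.pCols)
        contact_force = np.zeros(self.n_dof)
        if contact is not None:
            fc, blocks, adof = self._contact_forces(u, contact, want_tangent)
            contact_force = fc
            f_ext += fc
            if want_tangent and blocks is not None:
                vals.append(blocks.ravel())
                rows.append(np.repeat(adof, 3, axis=1).ravel())
                cols.append(np.tile(adof, (1, 3)).ravel())

        r = f_int - f_ext
        K = None
        if want_tangent:
            if len(self.membranes) and self.membrane_stabilization > 0:
                diag = np.arange(self.n_dof)
                vals.append(np.full(self.n_dof, self.membrane_stabilization))
                rows.append(diag)
                cols.append(diag)
            K = sparse.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.n_dof, self.n_dof),
            ).tocsr()
        return r, K, f_ext, contact_force

    def cauchy_stress(self, u):
        """Per-wedge Cauchy stress tensor averaged over Gauss points (MPa)."""
        if not len(self.wedges):
            return np.empty((0, 3, 3))
        _, S, F, _ = self._wedge_forces(u, want_tangent=False)
        J = np.linalg.det(F)
        sig = np.einsum("egik,egkl,egjl->egij", F, S, F) / J[..., None, None]
        return sig.mean(axis=1)


def newton_solve(system: FEMSystem, u, pressure=0.0, contact=None,
                 tol=1e-6, max_iter=14):
    """Newton iteration to equilibrium at fixed load; returns (u, history).

    Convergence: ‖r‖ on free dofs below ``tol`` times the external force
    norm (with an absolute floor for unloaded states).
    """
    free = system.free
    history = []
    u = u.copy()
    for it in range(max_iter):
        r, K, f_ext, _ = system.assemble(u, pressure, contact)
        ref = max(np.linalg.norm(f_ext[free]), 1e-8)
        rn = np.linalg.norm(r[free])
        history.append(rn / ref)
        if rn <= tol * ref:
            return u, history
        if not np.isfinite(rn) or (it > 3 and rn / ref > 1e6):
            raise NewtonError("Newton diverged", history)
        Kff = K[free][:, free].tocsc()
        try:
            du = splu(Kff, permc_spec="MMD_AT_PLUS_A",
                      options={"SymmetricMode": True}).solve(-r[free])
        except RuntimeError as exc:  # singular factorization
            raise NewtonError(f"linear solve failed: {exc}", history) from exc
        # backtracking line search on the residual norm
        step = 1.0
        for _ in range(6):
            u_try = u.copy()
            u_try[free] += step * du
            r_try, _, f_try, _ = system.assemble(
                u_try, pressure, contact, want_tangent=False
            )
            if np.linalg.norm(r_try[free]) < rn * (1.0 - 1e-4 * step) or step < 0.2:
                break
            step *= 0.5
        u = u_try
    # accept near-converged states, else fail
    r, _, f_ext, _ = system.assemble(u, pressure, contact, want_tangent=False)
    ref = max(np.linalg.norm(f_ext[free]), 1e-8)
    if np.linalg.norm(r[free]) <= 10 * tol * ref:
        history.append(np.linalg.norm(r[free]) / ref)
        return u, history
    raise NewtonError("Newton did not converge", history)
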