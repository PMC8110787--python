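"""High-level indentation simulations of turgid shells.

The workflow mirrors the physical experiment: build the layered shell,
inflate it to the turgor pressure with a follower load on the inner
surface, fix the bottom half of the inflated grain, then advance a rigid
spherical probe into the chosen site under displacement control and record
the force–depth curve.  Apparent stiffness is the local tangent slope of
that curve at a stated depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .mesh import ShellMesh, build_pollen_mesh, build_sphere_mesh
from .system import FEMSystem, NewtonError, RigidSphere, newton_solve

__all__ = [
    "PollenModel",
    "SphereShellModel",
    "FEMState",
    "IndentationSimResult",
    "inflate",
    "indent",
    "apparent_stiffness_at",
    "classify_linearity",
    "reissner_stiffness",
    "run_parameter_sweep",
    "measure_axes",
    "enclosed_volume",
]


@dataclass
class PollenModel:
    """Two-layer turgid pollen-wall model (ellipsoid of revolution).

    Defaults are the lily pollen reference configuration: unpressurized
    axes 128 × 97 µm, intine 1.5 µm, exine 0.5 µm, ν = 0.3, turgor
    0.2 MPa, E_i = 10 MPa, E_e = 20 MPa, with the colpus as a 25°
    half-width band along the major axis where the exine is absent.
    """

    major_axis_0: float = 128.0
    minor_axis_0: float = 97.0
    t_intine: float = 1.5
    t_exine: float = 0.5
    E_i: float = 10.0
    E_e: float = 20.0
    nu: float = 0.3
    P: float = 0.2
    colpus_halfwidth_deg: float = 25.0
    colpus_extent: float = 0.8
    indenter_radius: float = 1.0

    def __post_init__(self) -> None:
        for name in ("major_axis_0", "minor_axis_0", "t_intine", "t_exine"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.P < 0:
            raise ValueError("pressure must be nonnegative")
        if self.E_i <= 0 or self.E_e <= 0:
            raise ValueError("moduli must be positive")

    def materials(self) -> dict:
        return {"intine": (self.E_i, self.nu), "exine": (self.E_e, self.nu)}


@dataclass
class SphereShellModel:
    """Reduced spherical-shell model (solid wedges or membrane)."""

    diameter: float = 100.0
    thickness: float = 0.5
    element_kind: str = "solid_wedge"  # or "membrane"
    E: float = 10.0
    nu: float = 0.3
    P: float = 0.2
    indenter_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.thickness <= 0:
            raise ValueError("geometry must be positive")
        if self.thickness >= 0.2 * self.diameter:
            raise ValueError("thickness must be small compared to the diameter")
        if self.element_kind not in ("solid_wedge", "membrane"):
            raise ValueError("element_kind must be solid_wedge or membrane")

    def materials(self) -> dict:
        key = "membrane" if self.element_kind == "membrane" else "shell"
        return {key: (self.E, self.nu)}


@dataclass
class FEMState:
    """Converged solution snapshot."""

    u: np.ndarray                  # (n_dof,) nodal displacements, µm
    pressure: float                # MPa
    cauchy_stress: np.ndarray      # (n_wedges, 3, 3), MPa
    history: list = field(default_factory=list)  # residual norms per step
    converged: bool = True


@dataclass
class IndentationSimResult:
    """Simulated force–depth curve for one site."""

    site: str
    depth_samples: np.ndarray      # µm, starting at 0
    force_samples: np.ndarray      # µN
    k_apparent: float | None = None
    eval_depth: float | None = None
    linearity_class: str | None = None
    truncated: bool = False
    diagnostics: dict = field(default_factory=dict)


def _mount_constraints(mesh: ShellMesh) -> list[int]:
    """Isostatic 6-dof support that removes rigid modes without reactions.

    The net pressure load on a closed shell vanishes, so a statically
    determinate support carries no force and does not perturb the inflated
    shape: x/y at both poles, y/z at the +x tip.
    """
    m = mesh.mount_nodes
    a, b, c = m["pole_top"], m["pole_bot"], m["tip_px"]
    return [3 * a, 3 * a + 1, 3 * b, 3 * b + 1, 3 * c + 1, 3 * c + 2]


def inflate(
    mesh: ShellMesh,
    model,
    n_steps: int = 20,
    tol: float = 1e-6,
    min_step_fraction: float = 1.0 / 16.0,
) -> FEMState:
    """Pressurize the shell to ``model.P`` with incremental follower loading.

    The load is ramped in ``n_steps`` increments with Newton iteration at
    each level and automatic step halving (down to ``min_step_fraction`` of
    the nominal increment) on divergence.
    """
    system = FEMSystem(mesh, model.materials())
    system.fix_dofs(_mount_constraints(mesh))
    u = np.zeros(system.n_dof)
    history: list = []
    if model.P == 0:
        return FEMState(u, 0.0, system.cauchy_stress(u), history)
    p_now = 0.0
    dp_nominal = model.P / n_steps
    dp = dp_nominal
    while p_now < model.P - 1e-12:
        dp = min(dp, model.P - p_now)
        try:
            u_new, hist = newton_solve(system, u, pressure=p_now + dp, tol=tol)
        except NewtonError as exc:
            if dp <= dp_nominal * min_step_fraction + 1e-15:
                raise NewtonError(
                    f"inflation diverged at P = {p_now + dp:.4g} MPa",
                    history + exc.history,
                ) from exc
            dp *= 0.5
            continue
        u = u_new
        p_now += dp
        history.append((p_now, hist[-1], len(hist)))
        dp = min(dp * 2.0, dp_nominal)
    return FEMState(u, model.P, system.cauchy_stress(u), history)


def measure_axes(mesh: ShellMesh, state: FEMState) -> tuple[float, float]:
    """Deformed tip-to-tip major and minor axes (µm).

    The minor axis is read along ±y (exine-covered on the pollen model) so
    the colpus recess does not enter the measurement.
    """
    x = mesh.nodes + state.u.reshape(-1, 3)
    m = mesh.mount_nodes
    major = float(np.linalg.norm(x[m["tip_px"]] - x[m["tip_mx"]]))
    minor = float(np.linalg.norm(x[m["side_py"]] - x[m["side_my"]]))
    return major, minor


def enclosed_volume(mesh: ShellMesh, state: FEMState | None = None) -> float:
    """Volume enclosed by the (deformed) inner surface, µm³."""
    x = mesh.nodes + (state.u.reshape(-1, 3) if state is not None else 0.0)
    tri = x[mesh.pressure_faces]
    return float(np.abs(np.einsum("ij,ij->i", tri[:, 0],
                                  np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)


def indent(
    mesh: ShellMesh,
    inflated_state: FEMState,
    model,
    site: str,
    max_depth: float,
    n_steps: int = 30,
    tol: float = 1e-6,
    penalty: float = 50000.0,
    smoothing: float = 2e-4,
    contact_radius_factor: float = 10.0,
    min_step_fraction: float = 1.0 / 16.0,
) -> IndentationSimResult:
    """Displacement-controlled rigid-sphere indentation at a named site.

    The bottom half of the shell (reference coordinate below the equatorial
    plane normal to the indentation axis) is held fixed at its inflated
    position.  Depth is the indenter advance past first contact with the
    site apex; the reaction force is the resultant of the contact forces
    projected on the indentation axis.
    """
    if site not in mesh.site_nodes:
        raise ValueError(f"unknown site {site!r}; have {sorted(mesh.site_nodes)}")
    if max_depth < 0:
        raise ValueError("max_depth must be nonnegative")
    axis = np.asarray(mesh.site_axes[site], dtype=float)
    axis = axis / np.linalg.norm(axis)
    site_node = mesh.site_nodes[site]

    system = FEMSystem(mesh, model.materials())
    below = np.nonzero(mesh.nodes @ axis < 0.0)[0]
    if below.size == 0:
        raise ValueError("empty Dirichlet set: no nodes below the equator")
    system.fix_nodes(below)

    u = inflated_state.u.copy()
    x_site = mesh.nodes[site_node] + u.reshape(-1, 3)[site_node]
    ref_site = mesh.nodes[site_node]
    cand = mesh.exposed_nodes[
        np.linalg.norm(mesh.nodes[mesh.exposed_nodes] - ref_site, axis=1)
        <= contact_radius_factor * model.indenter_radius
    ]
    cand_areas = (mesh.vertex_areas[cand % mesh.n_verts]
                  if mesh.vertex_areas.size else None)
    c0 = x_site + model.indenter_radius * axis

    depths = [0.0]
    forces = [0.0]
    history: list = []
    truncated = False
    max_penetration = 0.0
    if max_depth > 0:
        d_nominal = max_depth / n_steps
        d_now, dd = 0.0, d_nominal
        du_prev = np.zeros_like(u)
        dd_prev = 0.0
        while d_now < max_depth - 1e-12:
            dd = min(dd, max_depth - d_now)
            contact = RigidSphere(
                center=c0 - (d_now + dd) * axis,
                radius=model.indenter_radius,
                axis=axis,
                candidates=cand,
                penalty=penalty,
                smoothing=smoothing,
                areas=cand_areas,
            )
            # secant predictor from the previous accepted increment
            u_start = u
            if dd_prev > 0:
                u_start = u + du_prev * (dd / dd_prev)
            try:
                u_new, hist = newton_solve(
                    system, u_start, pressure=inflated_state.pressure,
                    contact=contact, tol=tol,
                )
            except NewtonError:
                if dd <= d_nominal * min_step_fraction + 1e-15:
                    truncated = True
                    break
                dd *= 0.5
                dd_prev = 0.0
                continue
            du_prev = u_new - u
            dd_prev = dd
            u = u_new
            d_now += dd
            _, _, _, fc = system.assemble(
                u, inflated_state.pressure, contact, want_tangent=False
            )
            f_axis = float(-fc.reshape(-1, 3).sum(axis=0) @ axis)
            x_cand = mesh.nodes[cand] + u.reshape(-1, 3)[cand]
            gaps = np.linalg.norm(x_cand - contact.center, axis=1) - contact.radius
            max_penetration = max(max_penetration, float(max(-gaps.min(), 0.0)))
            depths.append(d_now)
            forces.append(f_axis)
            history.append((d_now, hist[-1], len(hist)))
            dd = min(dd * 2.0, d_nominal)
        if not truncated and forces[-1] <= 0 and max_depth > model.indenter_radius:
            raise NewtonError("contact never established within max_depth")

    return IndentationSimResult(
        site=site,
        depth_samples=np.asarray(depths),
        force_samples=np.asarray(forces),
        truncated=truncated,
        diagnostics={
            "history": history,
            "max_penetration_um": max_penetration,
            "penalty": penalty,
            "n_contact_candidates": int(cand.size),
        },
    )


def apparent_stiffness_at(
    result: IndentationSimResult,
    depth: float,
    half_window: float = 0.1,
    mode: str = "tangent",
) -> float:
    """Apparent stiffness (N/m) from the simulated curve at a given depth.

    ``tangent`` (default): central finite difference of force over
    ``depth ± half_window``; ``secant``: F(depth)/depth.
    """
    d, F = result.depth_samples, result.force_samples
    if mode == "secant":
        if not (d[0] <= depth <= d[-1]) or depth <= 0:
            raise ValueError("depth outside sampled range")
        return float(np.interp(depth, d, F) / depth)
    lo, hi = depth - half_window, depth + half_window
    if lo < d[0] or hi > d[-1]:
        raise ValueError(
            f"depth {depth} ± {half_window} µm outside sampled range "
            f"[{d[0]:.3g}, {d[-1]:.3g}]"
        )
    return float((np.interp(hi, d, F) - np.interp(lo, d, F)) / (2 * half_window))


def classify_linearity(
    result: IndentationSimResult,
    fit_range: tuple[float, float] = (0.1, 0.5),
    dead_band: float = 0.01,
) -> str:
    """Sub-/super-linearity of the force curve relative to a small-depth fit.

    A line is fitted over ``fit_range``; the curve is classified by the sign
    of its mean deviation from that line beyond the range midpoint
    (above → superlinear, below → sublinear), with a relative dead band for
    "linear".
    """
    lo, hi = fit_range
    d, F = result.depth_samples, result.force_samples
    if lo < d[0] or hi > d[-1]:
        raise ValueError("fit range outside sampled depths")
    dense = np.linspace(d[0], d[-1], max(200, 4 * len(d)))
    Fd = np.interp(dense, d, F)
    sel_fit = (dense >= lo) & (dense <= hi)
    slope, icpt = np.polyfit(dense[sel_fit], Fd[sel_fit], 1)
    mid = 0.5 * (lo + hi)
    sel = dense > mid
    resid = Fd[sel] - (slope * dense[sel] + icpt)
    scale = np.mean(np.abs(Fd[sel])) + 1e-30
    rel = float(np.mean(resid) / scale)
    if abs(rel) < dead_band:
        return "linear"
    return "superlinear" if rel > 0 else "sublinear"


def reissner_stiffness(E: float, t: float, R: float, nu: float) -> float:
    """Closed-form point-load stiffness of an unpressurized thin spherical
    shell: k = 4 E t² / (R √(3 (1 − ν²))), in N/m for (MPa, µm) inputs."""
    if t <= 0 or R <= 0 or E <= 0:
        raise ValueError("E, t, R must be positive")
    if t / R >= 0.05:
        raise ValueError("thin-shell formula requires t/R < 0.05")
    if not 0 <= nu < 0.5:
        raise ValueError("invalid Poisson ratio")
    return 4.0 * E * t**2 / (R * np.sqrt(3.0 * (1.0 - nu**2)))


_SITE_SETTINGS = {
    # site -> (max_depth, eval_depth) per the study's evaluation depths
    "colpus_center": (1.8, 1.6),
    "antipode": (0.8, 0.6),
}


def run_parameter_sweep(
    P_values,
    E_i_values,
    E_e_values,
    sites=("colpus_center", "antipode"),
    base_model: PollenModel | None = None,
    resolution: int = 3000,
    n_steps_inflate: int = 10,
    n_steps_indent: int = 25,
    mesh: ShellMesh | None = None,
) -> pd.DataFrame:
    """Apparent stiffness over a (P × E_i × E_e) grid at both sites.

    One row per parameter combination and site; diverged runs are recorded
    with NaN stiffness and the failure reason.  Deterministic given mesh and
    solver settings.
    """
    base = base_model if base_model is not None else PollenModel()
    if mesh is None:
        mesh = build_pollen_mesh(base, resolution=resolution)
    rows = []
    for P, E_i, E_e in product(P_values, E_i_values, E_e_values):
        model = PollenModel(
            major_axis_0=base.major_axis_0, minor_axis_0=base.minor_axis_0,
            t_intine=base.t_intine, t_exine=base.t_exine,
            E_i=E_i, E_e=E_e, nu=base.nu, P=P,
            colpus_halfwidth_deg=base.colpus_halfwidth_deg,
            colpus_extent=base.colpus_extent,
            indenter_radius=base.indenter_radius,
        )
        try:
            state = inflate(mesh, model, n_steps=n_steps_inflate)
        except NewtonError as exc:
            for site in sites:
                rows.append({"P_MPa": P, "E_i_MPa": E_i, "E_e_MPa": E_e,
                             "site": site, "k_apparent_Npm": np.nan,
                             "eval_depth_um": np.nan, "reason": str(exc)})
            continue
        for site in sites:
            max_depth, eval_depth = _SITE_SETTINGS[site]
            try:
                res = indent(mesh, state, model, site, max_depth,
                             n_steps=n_steps_indent)
                k = apparent_stiffness_at(res, eval_depth)
                reason = "truncated" if res.truncated else ""
            except (NewtonError, ValueError) as exc:
                k, eval_depth, reason = np.nan, np.nan, str(exc)
            rows.append({"P_MPa": P, "E_i_MPa": E_i, "E_e_MPa": E_e,
                         "site": site, "k_apparent_Npm": k,
                         "eval_depth_um": eval_depth, "reason": reason})
    return pd.DataFrame(rows)
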