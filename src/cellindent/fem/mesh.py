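"""Layered shell meshes on ellipsoids and spheres.

The outer surface is triangulated with a graded vertex density (fine near
the two indentation sites, coarse elsewhere) and extruded inward along the
surface normal into stacked 6-node wedge (prism) layers: an outer exine
layer and an inner intine layer for the pollen model, a single layer for the
sphere model, or no extrusion at all for the membrane variant.  In the
colpus band the exine wedges are omitted, so the exposed surface there is
the (slightly recessed) intine outer face — reproducing the small curvature
difference between colpus and exine regions.

Surface meshing: a deterministic Fibonacci lattice is density-remapped and
relaxed with a few weighted k-means (Lloyd) iterations against a density-
distributed sample cloud; the convex hull of the relaxed unit-sphere points
yields the triangulation, which is then scaled onto the ellipsoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

__all__ = ["ShellMesh", "build_pollen_mesh", "build_sphere_mesh"]

_MESH_SEED = 20210510  # meshes are part of the model definition: fixed seed


# ---------------------------------------------------------------------------
# graded unit-sphere triangulation


def _fibonacci_points(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    u = 1.0 - 2.0 * (i + 0.5) / n          # cos(polar angle), uniform
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(1.0 - u * u, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), u])


def _density(points: np.ndarray, sites: np.ndarray, bumps) -> np.ndarray:
    """Relative vertex density: 1 plus Gaussian bumps around each site.

    ``bumps`` is a sequence of (amplitude, sigma_radians) pairs; two scales
    are used by default — a broad one resolving the indentation dimple and
    a sharp one resolving the probe-sized contact patch.
    """
    rho = np.ones(len(points))
    for s in sites:
        ang = np.arccos(np.clip(points @ s, -1.0, 1.0))
        for amp, sigma in bumps:
            rho += amp * np.exp(-0.5 * (ang / sigma) ** 2)
    return rho


def _graded_sphere_vertices(
    n_vertices: int,
    sites: np.ndarray,
    bumps,
    n_lloyd: int = 6,
) -> np.ndarray:
    """Deterministic graded point set on the unit sphere.

    The density is axisymmetric about the site axis (±z), so the sample
    cloud is drawn exactly by inverse-CDF sampling in u = cos(polar angle)
    with uniform azimuth, then relaxed by weighted Lloyd iterations.
    """
    rng = np.random.default_rng(_MESH_SEED)
    n_samples = max(50 * n_vertices, 40000)
    ug = np.linspace(-1.0, 1.0, 8001)
    phi = np.arccos(np.clip(ug, -1, 1))
    rho = np.ones_like(ug)
    for amp, sigma in bumps:
        rho += amp * np.exp(-0.5 * (phi / sigma) ** 2)          # +z site
        rho += amp * np.exp(-0.5 * ((np.pi - phi) / sigma) ** 2)  # −z site
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (rho[1:] + rho[:-1]))])
    cdf /= cdf[-1]
    u = np.interp(rng.random(n_samples), cdf, ug)
    az = 2 * np.pi * rng.random(n_samples)
    r = np.sqrt(np.maximum(1 - u * u, 0.0))
    cloud = np.column_stack([r * np.cos(az), r * np.sin(az), u])
    idx = rng.choice(n_samples, size=n_vertices, replace=False)
    centers = cloud[idx]
    for _ in range(n_lloyd):
        # assign cloud points to nearest center (chunked to bound memory)
        assign = np.empty(len(cloud), dtype=np.int64)
        for lo in range(0, len(cloud), 20000):
            chunk = cloud[lo:lo + 20000]
            d = chunk @ centers.T  # cosine similarity: larger is closer
            assign[lo:lo + 20000] = d.argmax(axis=1)
        sums = np.zeros_like(centers)
        np.add.at(sums, assign, cloud)
        norms = np.linalg.norm(sums, axis=1)
        ok = norms > 1e-12
        centers[ok] = sums[ok] / norms[ok, None]
    # pin a vertex exactly at each site, at the ±x tips and at ±y (used as
    # isostatic mounting points during inflation and for axis read-out)
    pins = np.vstack(
        [sites, [[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0],
                 [0.0, 1.0, 0.0], [0.0, -1.0, 0.0]]]
    )
    for p in pins:
        centers[np.argmax(centers @ p)] = p
    return centers


# ---------------------------------------------------------------------------
# mesh container


@dataclass
class ShellMesh:
    """Discretized layered shell.

    ``nodes`` holds all node layers stacked: for a wedge mesh with
    ``n_shells`` node layers, global node id ``shell * n_verts + v`` is
    surface vertex ``v`` offset inward; for a membrane mesh there is a
    single layer.
    """

    nodes: np.ndarray                 # (N, 3) reference coordinates, µm
    surf_tris: np.ndarray             # (T, 3) surface triangulation (vertex ids)
    n_verts: int
    wedges: np.ndarray                # (W, 6) node ids; empty for membranes
    layer_id: np.ndarray              # (W,) "intine" | "exine" | "shell"
    membranes: np.ndarray             # (M, 3) node ids; empty for wedge meshes
    pressure_faces: np.ndarray        # (P, 3) node ids, outward oriented
    colpus_mask: np.ndarray           # (T,) bool per surface triangle
    exposed_nodes: np.ndarray         # node ids forming the exposed outer surface
    site_nodes: dict = field(default_factory=dict)
    site_axes: dict = field(default_factory=dict)
    mount_nodes: dict = field(default_factory=dict)
    vertex_areas: np.ndarray = field(default_factory=lambda: np.empty(0))
    unused_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    thickness: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def euler_characteristic(self) -> int:
        v = self.n_verts
        f = len(self.surf_tris)
        edges = set()
        for a, b, c in self.surf_tris:
            for e in ((a, b), (b, c), (c, a)):
                edges.add((min(e), max(e)))
        return v - len(edges) + f


def _orient_outward(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Flip triangles so their normal points away from the origin."""
    p = points[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    centers = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", n, centers) < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _ellipsoid_normals(unit_points: np.ndarray, a: float, b: float) -> np.ndarray:
    """Outward unit normals of the ellipsoid x²/a² + (y²+z²)/b² = 1."""
    n = unit_points / np.array([a, b, b])  # gradient direction
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _vertex_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """One-ring area share per surface vertex (a third of each triangle)."""
    p = points[tris]
    a = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    out = np.zeros(len(points))
    np.add.at(out, tris.ravel(), np.repeat(a / 3.0, 3))
    return out


def _triangulate(resolution: int, sites_unit: np.ndarray, bumps_deg):
    n_vertices = max(resolution // 2 + 2, 40)
    bumps = [(a, np.radians(s)) for a, s in bumps_deg]
    pts = _graded_sphere_vertices(n_vertices, sites_unit, bumps)
    hull = ConvexHull(pts)
    tris = _orient_outward(pts, hull.simplices)
    return pts, tris


DEFAULT_BUMPS = ((15.0, 12.0), (400.0, 3.5))


def build_pollen_mesh(
    model,
    resolution: int = 3000,
    refine_bumps=DEFAULT_BUMPS,
) -> ShellMesh:
    """Two-layer ellipsoidal shell mesh with a colpus band.

    The ellipsoid of revolution about the major (x) axis has unpressurized
    semi-axes taken from ``model``; the colpus is a band of angular
    half-width ``model.colpus_halfwidth_deg`` around the +z direction,
    aligned with the major axis and truncated at ``model.colpus_extent`` of
    the axial length.  Exine wedges are omitted on colpus triangles.
    """
    if resolution < 500:
        raise ValueError("resolution must be at least 500 triangles")
    a = model.major_axis_0 / 2.0
    b = model.minor_axis_0 / 2.0
    if a <= 0 or b <= 0:
        raise ValueError("degenerate axes")
    halfwidth = np.radians(model.colpus_halfwidth_deg)
    if model.colpus_halfwidth_deg * model.colpus_extent / 90.0 >= 1.0:
        raise ValueError("colpus covers half the surface or more")

    sites_unit = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    pts_unit, tris = _triangulate(resolution, sites_unit, refine_bumps)
    surf = pts_unit * np.array([a, b, b])
    normals = _ellipsoid_normals(pts_unit, a, b)
    areas = _vertex_areas(surf, tris)

    # colpus: vertices within the angular band around +z, away from the tips
    beta = np.abs(np.arctan2(pts_unit[:, 1], pts_unit[:, 2]))
    in_band = (beta <= halfwidth) & (pts_unit[:, 2] > 0)
    in_extent = np.abs(pts_unit[:, 0]) <= model.colpus_extent
    vert_colpus = in_band & in_extent
    colpus_mask = vert_colpus[tris].all(axis=1)

    n_verts = len(surf)
    t_e, t_i = model.t_exine, model.t_intine
    shells = [surf, surf - t_e * normals, surf - (t_e + t_i) * normals]
    nodes = np.vstack(shells)

    def gid(shell, verts):
        return shell * n_verts + verts

    wedges, layer = [], []
    for ti, tri in enumerate(tris):
        # wedge node order: bottom (inner) triangle then top (outer) triangle
        wedges.append(np.concatenate([gid(2, tri), gid(1, tri)]))
        layer.append("intine")
        if not colpus_mask[ti]:
            wedges.append(np.concatenate([gid(1, tri), gid(0, tri)]))
            layer.append("exine")
    wedges = np.array(wedges, dtype=np.int64)
    layer = np.array(layer)

    pressure_faces = gid(2, tris)  # inner surface, outward oriented

    # exposed outer surface: shell0 outside the colpus, shell1 on it
    exposed = np.concatenate(
        [gid(0, np.nonzero(~vert_colpus)[0]), gid(1, np.nonzero(vert_colpus)[0])]
    )
    used = np.unique(wedges)
    unused = np.setdiff1d(np.arange(len(nodes)), used)

    i_top = int(np.argmax(pts_unit[:, 2]))     # colpus center vertex
    i_bot = int(np.argmin(pts_unit[:, 2]))     # antipode vertex
    i_px = int(np.argmax(pts_unit[:, 0]))
    i_mx = int(np.argmin(pts_unit[:, 0]))
    i_py = int(np.argmax(pts_unit[:, 1]))
    i_my = int(np.argmin(pts_unit[:, 1]))
    site_nodes = {"colpus_center": int(gid(1, i_top)), "antipode": int(gid(0, i_bot))}
    site_axes = {"colpus_center": np.array([0.0, 0.0, 1.0]),
                 "antipode": np.array([0.0, 0.0, -1.0])}
    # mounting points used for isostatic support during inflation; the top
    # pole uses the intine shell, which exists whether or not the colpus
    # covers the pole
    mount_nodes = {"pole_top": int(gid(1, i_top)), "pole_bot": int(gid(0, i_bot)),
                   "tip_px": int(gid(0, i_px)), "tip_mx": int(gid(0, i_mx)),
                   "side_py": int(gid(0, i_py)), "side_my": int(gid(0, i_my))}

    return ShellMesh(
        nodes=nodes,
        surf_tris=tris,
        n_verts=n_verts,
        wedges=wedges,
        layer_id=layer,
        membranes=np.empty((0, 3), dtype=np.int64),
        pressure_faces=pressure_faces,
        colpus_mask=colpus_mask,
        exposed_nodes=exposed,
        site_nodes=site_nodes,
        site_axes=site_axes,
        mount_nodes=mount_nodes,
        unused_nodes=unused,
        vertex_areas=areas,
        thickness={"intine": t_i, "exine": t_e},
    )


def build_sphere_mesh(
    spec,
    resolution: int = 3000,
    refine_bumps=DEFAULT_BUMPS,
) -> ShellMesh:
    """Single-layer spherical shell mesh (solid wedges or membrane)."""
    if resolution < 500:
        raise ValueError("resolution must be at least 500 triangles")
    R = spec.diameter / 2.0
    t = spec.thickness
    if not (R > 0 and 0 < t < R):
        raise ValueError("invalid sphere geometry")

    sites_unit = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    pts_unit, tris = _triangulate(resolution, sites_unit, refine_bumps)
    surf = pts_unit * R
    n_verts = len(surf)
    areas = _vertex_areas(surf, tris)
    colpus_mask = np.zeros(len(tris), dtype=bool)
    i_top = int(np.argmax(pts_unit[:, 2]))
    i_bot = int(np.argmin(pts_unit[:, 2]))
    i_px = int(np.argmax(pts_unit[:, 0]))
    i_mx = int(np.argmin(pts_unit[:, 0]))
    i_py = int(np.argmax(pts_unit[:, 1]))
    i_my = int(np.argmin(pts_unit[:, 1]))
    site_axes = {"pole": np.array([0.0, 0.0, 1.0]),
                 "antipode": np.array([0.0, 0.0, -1.0])}
    mounts = {"pole_top": i_top, "pole_bot": i_bot, "tip_px": i_px,
              "tip_mx": i_mx, "side_py": i_py, "side_my": i_my}

    if spec.element_kind == "membrane":
        mesh = ShellMesh(
            nodes=surf,
            surf_tris=tris,
            n_verts=n_verts,
            wedges=np.empty((0, 6), dtype=np.int64),
            layer_id=np.empty(0, dtype=object),
            membranes=tris.copy(),
            pressure_faces=tris.copy(),
            colpus_mask=colpus_mask,
            exposed_nodes=np.arange(n_verts),
            site_nodes={"pole": i_top, "antipode": i_bot},
            site_axes=site_axes,
            mount_nodes=mounts,
            vertex_areas=areas,
            thickness={"membrane": t},
        )
        return mesh

    normals = pts_unit  # sphere: outward normal is the unit position
    nodes = np.vstack([surf, surf - t * normals])
    wedges = np.array(
        [np.concatenate([n_verts + tri, tri]) for tri in tris], dtype=np.int64
    )
    layer = np.array(["shell"] * len(wedges))
    return ShellMesh(
        nodes=nodes,
        surf_tris=tris,
        n_verts=n_verts,
        wedges=wedges,
        layer_id=layer,
        membranes=np.empty((0, 3), dtype=np.int64),
        pressure_faces=n_verts + tris,
        colpus_mask=colpus_mask,
        exposed_nodes=np.arange(n_verts),
        site_nodes={"pole": i_top, "antipode": i_bot},
        site_axes=site_axes,
        mount_nodes=mounts,
        vertex_areas=areas,
        thickness={"shell": t},
    )
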