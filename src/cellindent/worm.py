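"""Cylindrical stiffness mapping of a nematode.

Indentation lines are taken along the body axis at successive rotations of
the animal; each site is placed in a cylindrical coordinate system (axial
position ``s`` in µm, angle ``theta`` in degrees).  Because the specimen can
rotate slightly between lines, a per-line angular offset (drift) is
estimated from a tracked surface fiducial and removed before the map is
unfolded onto the (s, θ) rectangle.

The body is idealized as a cylinder: no taper modelling, θ ∈ [0, 360) with
0° defined by the first line's orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import compare_groups, summarize_population

__all__ = [
    "IndentationSite",
    "WormStiffnessMap",
    "assign_coordinates",
    "unfold",
    "band_comparison",
    "detect_bands",
]


@dataclass
class IndentationSite:
    line_index: int
    s: float           # axial position, µm
    theta: float       # angle, degrees in [0, 360)
    k: float           # apparent stiffness, N/m

    def __post_init__(self) -> None:
        self.theta = float(self.theta) % 360.0
        if not self.k > 0:
            raise ValueError("stiffness must be positive")


@dataclass
class WormStiffnessMap:
    """All sites measured on a single nematode."""

    sites: list[IndentationSite]
    band_labels: list[str] | None = None  # "soft" | "stiff" per site
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "line": [s.line_index for s in self.sites],
                "s_um": [s.s for s in self.sites],
                "theta_deg": [s.theta for s in self.sites],
                "k_Npm": [s.k for s in self.sites],
            }
        )
        if self.band_labels is not None:
            df["band"] = self.band_labels
        return df


def assign_coordinates(
    lines: list[list[tuple[float, float]]],
    rotation_angles: list[float],
    fiducials: list[float] | None = None,
    fiducial_reference: float | None = None,
) -> WormStiffnessMap:
    """Place per-line (s, k) measurements into cylindrical coordinates.

    Parameters
    ----------
    lines : list of per-line site lists
        Each site is an ``(s_um, k_Npm)`` pair.
    rotation_angles : declared rotation angle per line (degrees).
    fiducials : optional observed angular position of a tracked surface
        landmark per line.  If given, the per-line drift offset is the
        difference between the observed fiducial angle and its reference
        position (first line's observation by default), and is subtracted.
    """
    if len(lines) != len(rotation_angles):
        raise ValueError("one rotation angle required per line")
    if fiducials is not None and len(fiducials) != len(lines):
        raise ValueError("one fiducial observation required per line")
    if fiducials is None and rotation_angles is None:
        raise ValueError("missing rotation metadata and no fiducials")
    sites: list[IndentationSite] = []
    for li, (line, angle) in enumerate(zip(lines, rotation_angles)):
        drift = 0.0
        if fiducials is not None:
            ref = fiducial_reference if fiducial_reference is not None else fiducials[0]
            # the fiducial co-rotates with the declared angle; any surplus is drift
            surplus = (fiducials[li] - ref) - (angle - rotation_angles[0])
            drift = (surplus + 180.0) % 360.0 - 180.0
        for s, k in line:
            sites.append(IndentationSite(li, s, (angle + drift) % 360.0, k))
    return WormStiffnessMap(sites)


def estimated_drift(map_: WormStiffnessMap, declared: list[float]) -> list[float]:
    """Per-line drift implied by a map relative to declared angles."""
    out = []
    for li, angle in enumerate(declared):
        thetas = [s.theta for s in map_.sites if s.line_index == li]
        d = (np.mean(thetas) - angle + 180.0) % 360.0 - 180.0
        out.append(float(d))
    return out


def unfold(map_: WormStiffnessMap) -> pd.DataFrame:
    """Unfold the cylinder onto a sparse (s × θ) grid.

    Returns a pivoted DataFrame (rows θ, columns s) with NaN holes where no
    indentation was recorded; no interpolation is performed.
    """
    df = map_.to_frame()
    if df["line"].nunique() < 2:
        raise ValueError("unfolding needs at least 2 lines")
    return df.pivot_table(index="theta_deg", columns="s_um", values="k_Npm")


def refold(grid: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`unfold`: back to a long (s, θ, k) table."""
    long = grid.stack().rename("k_Npm").reset_index()
    return long[["s_um", "theta_deg", "k_Npm"]]


def detect_bands(map_: WormStiffnessMap, gap_deg: float = 60.0) -> dict:
    """Cluster stiff-labelled sites into angular bands and report spacing.

    Requires labels on the map (manual or from :func:`two_means_labels`).
    Band centers are circular means of each contiguous angular cluster;
    spacing is the angular distance between adjacent soft/stiff band centers.
    """
    if map_.band_labels is None:
        raise ValueError("map has no band labels")
    centers = {}
    for label in ("soft", "stiff"):
        thetas = sorted(
            {s.theta for s, lab in zip(map_.sites, map_.band_labels) if lab == label}
        )
        if not thetas:
            continue
        clusters: list[list[float]] = [[thetas[0]]]
        for t in thetas[1:]:
            if t - clusters[-1][-1] <= gap_deg:
                clusters[-1].append(t)
            else:
                clusters.append([t])
        # merge wrap-around cluster
        if len(clusters) > 1 and (360.0 - clusters[-1][-1] + clusters[0][0]) <= gap_deg:
            clusters[0] = [t - 360.0 for t in clusters[-1]] + clusters[0]
            clusters.pop()
        centers[label] = sorted(float(np.mean(c)) % 360.0 for c in clusters)
    all_centers = sorted(
        (c, lab) for lab, cs in centers.items() for c in cs
    )
    spacings = []
    for i, (c, _) in enumerate(all_centers):
        nxt = all_centers[(i + 1) % len(all_centers)][0]
        spacings.append((nxt - c) % 360.0)
    return {"band_centers": centers, "adjacent_spacings_deg": spacings}


def two_means_labels(map_: WormStiffnessMap) -> list[str]:
    """Optional 2-means split of stiffness values into soft/stiff labels.

    Lloyd iterations on 1-D data seeded at the min/max; never applied
    silently — callers must opt in.
    """
    k = np.array([s.k for s in map_.sites])
    c = np.array([k.min(), k.max()])
    for _ in range(100):
        assign = np.abs(k[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([k[assign == j].mean() if np.any(assign == j) else c[j] for j in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    return ["soft" if a == 0 else "stiff" for a in assign]


def band_comparison(map_: WormStiffnessMap, labels: list[str] | None = None) -> dict:
    """Soft vs stiff group statistics and a double-sided two-sample test.

    ``labels`` defaults to the map's own band labels; they must partition the
    sites into two nonempty groups.
    """
    labels = labels if labels is not None else map_.band_labels
    if labels is None:
        raise ValueError("no band labels supplied")
    if len(labels) != len(map_.sites):
        raise ValueError("one label per site required")
    k = np.array([s.k for s in map_.sites])
    soft = k[[lab == "soft" for lab in labels]]
    stiff = k[[lab == "stiff" for lab in labels]]
    if soft.size == 0 or stiff.size == 0:
        raise ValueError("labels must produce two nonempty groups")
    labelled = WormStiffnessMap(map_.sites, list(labels))
    return {
        "soft": summarize_population(soft),
        "stiff": summarize_population(stiff),
        "test": compare_groups(soft, stiff),
        "bands": detect_bands(labelled),
    }
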