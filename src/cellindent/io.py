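"""File-format plumbing: delimited curve files, manifests, reports.

Curve files are plain delimited text with columns ``z_um, F_uN`` (one file
per indentation) plus an optional JSON sidecar carrying acquisition
metadata; a batch manifest CSV lists curve files with specimen/region
labels.  Measurement tables and worm maps are CSV; reports are JSON with a
config hash and seed embedded for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import CalibrationRecord, ForceCurve, StiffnessMeasurement
from .worm import IndentationSite, WormStiffnessMap

__all__ = [
    "read_curve",
    "write_curve",
    "read_manifest",
    "read_calibration",
    "write_measurements",
    "read_measurements",
    "read_worm_map",
    "write_worm_map",
    "write_report",
    "config_hash",
]

_META_FIELDS = ("velocity", "approach_distance", "sensor_id", "specimen_id", "region")


def read_curve(path, **overrides) -> ForceCurve:
    """Read one ``z_um, F_uN`` file, merging any JSON sidecar metadata."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if not {"z_um", "F_uN"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns z_um, F_uN")
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        meta.update({k: raw[k] for k in _META_FIELDS if k in raw})
    meta.update(overrides)
    meta.setdefault("curve_id", path.stem)
    return ForceCurve(z=df["z_um"].to_numpy(), F=df["F_uN"].to_numpy(), **meta)


def write_curve(curve: ForceCurve, path) -> None:
    path = Path(path)
    pd.DataFrame({"z_um": curve.z, "F_uN": curve.F}).to_csv(path, index=False)
    meta = {k: getattr(curve, k) for k in _META_FIELDS}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_manifest(path) -> list[ForceCurve]:
    """Read a batch manifest CSV: column ``file`` plus optional metadata
    columns (``specimen_id, region, ...``); paths relative to the manifest."""
    path = Path(path)
    man = pd.read_csv(path)
    if man.empty:
        raise ValueError(f"{path}: empty manifest")
    if "file" not in man.columns:
        raise ValueError(f"{path}: manifest needs a 'file' column")
    curves = []
    for _, row in man.iterrows():
        overrides = {
            k: row[k] for k in _META_FIELDS if k in man.columns and pd.notna(row[k])
        }
        curves.append(read_curve(path.parent / row["file"], **overrides))
    return curves


def read_calibration(path) -> CalibrationRecord:
    raw = json.loads(Path(path).read_text())
    return CalibrationRecord(
        k_system=float(raw["k_system"]),
        source_curve_id=raw.get("source_curve_id", ""),
    )


def write_measurements(measurements: list[StiffnessMeasurement], path) -> None:
    pd.DataFrame([m.as_dict() for m in measurements]).to_csv(path, index=False)


def read_measurements(path) -> list[StiffnessMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            StiffnessMeasurement(
                k=r["k_Npm"],
                k_uncorrected=r.get("k_uncorrected_Npm", np.nan),
                contact_point=r.get("contact_point_um", np.nan),
                fit_window=(r.get("fit_window_lo", np.nan), r.get("fit_window_hi", np.nan)),
                r_squared=r.get("r_squared", np.nan),
                region=r.get("region", ""),
                specimen_id=r.get("specimen_id", ""),
                curve_id=r.get("curve_id", ""),
            )
        )
    return out


def read_worm_map(path) -> WormStiffnessMap:
    """Read a worm map CSV: ``line, s_um, theta_deg, k_Npm`` (+optional band)."""
    df = pd.read_csv(path)
    need = {"line", "s_um", "theta_deg", "k_Npm"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    sites = [
        IndentationSite(int(r["line"]), r["s_um"], r["theta_deg"], r["k_Npm"])
        for _, r in df.iterrows()
    ]
    labels = list(df["band"]) if "band" in df.columns else None
    return WormStiffnessMap(sites, labels)


def write_worm_map(map_: WormStiffnessMap, path) -> None:
    map_.to_frame().to_csv(path, index=False)


def write_surface_off(mesh, path, state=None) -> None:
    """Export the (optionally deformed) outer surface triangulation as OFF.

    OFF is plain text and readable by standard mesh viewers; the surface
    vertices are the first ``n_verts`` nodes of the shell mesh.
    """
    x = mesh.nodes[:mesh.n_verts].copy()
    if state is not None:
        x = x + state.u.reshape(-1, 3)[:mesh.n_verts]
    tris = mesh.surf_tris
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(x)} {len(tris)} 0\n")
        for p in x:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(report: dict, path, config: dict | None = None,
                 seed: int | None = None) -> None:
    """Write a JSON report stamped with the config hash and seed."""
    out = dict(report)
    if config is not None:
        out["config_hash"] = config_hash(config)
    if seed is not None:
        out["seed"] = seed
    Path(path).write_text(json.dumps(out, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
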