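"""End-to-end study workflows.

Two pipelines mirror the two experiments: the pollen workflow takes force
curves (from files or the synthetic generator) through stiffness
extraction, per-grain ratio aggregation and a between-media comparison,
optionally matched against a FEM parameter sweep; the worm workflow builds
the unfolded cylindrical stiffness map and compares soft/stiff bands.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .curves import CalibrationRecord, process_batch
from .stats import compare_groups, normality_test, ratios_from_measurements, summarize_population
from .synth import PopulationSpec, WormGenSpec, gen_pollen_population, gen_worm_map
from .worm import assign_coordinates, band_comparison, unfold

__all__ = ["RunConfig", "run_pollen_workflow", "run_worm_workflow", "select_best_fit"]


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration with a stable hash for provenance."""

    workflow: str                       # pollen | worm | simulate | synth
    out_dir: str = "."
    seed: int = 0
    options: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.workflow not in ("pollen", "worm", "simulate", "synth"):
            raise ValueError(f"unknown workflow {self.workflow!r}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return cio.config_hash(self.as_dict())


def _measurements_for_medium(cfg: RunConfig, medium: str, seed: int):
    opts = cfg.options
    if opts.get("synthetic", True):
        spec = PopulationSpec(
            n_grains=opts.get("n_grains", 30),
            m_per_grain=opts.get("m_per_grain", 10),
            ratio_mean=opts.get(f"{medium}_ratio_mean",
                                0.56 if medium == "water" else 0.66),
            ratio_sd=opts.get(f"{medium}_ratio_sd", 0.10),
            medium=medium,
            seed=seed,
        )
        curves, truth = gen_pollen_population(spec)
        cal = CalibrationRecord(k_system=spec.k_system)
    else:
        manifest = opts.get(f"{medium}_manifest")
        if not manifest:
            raise ValueError(f"no manifest given for medium {medium!r}")
        curves = cio.read_manifest(manifest)
        if not curves:
            raise ValueError(f"empty manifest for {medium!r}")
        cal = cio.read_calibration(opts["calibration"])
        truth = None
    window = tuple(opts.get("window", (0.5, 1.0)))
    return process_batch(curves, cal, window=window), truth


def run_pollen_workflow(cfg: RunConfig) -> dict:
    """Curves → stiffness → per-grain ratios → media comparison (+FEM sweep).

    Returns the report dict; tables and the JSON report are written under
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    media = cfg.options.get("media", ["water", "cacl2_5mM"])
    ratios = {}
    report: dict = {"workflow": "pollen", "media": {}}
    for i, medium in enumerate(media):
        measurements, truth = _measurements_for_medium(cfg, medium, cfg.seed + i)
        cio.write_measurements(measurements, out / f"measurements_{medium}.csv")
        df = ratios_from_measurements(measurements, medium)
        df.to_csv(out / f"ratios_{medium}.csv", index=False)
        ratios[medium] = df
        med_report = {"ratio_summary": summarize_population(df["ratio"])}
        if len(df) >= 8:
            stat, p = normality_test(df["ratio"])
            med_report["ratio_normality"] = {"statistic": stat, "p": p}
        report["media"][medium] = med_report
    if len(media) == 2:
        a, b = (ratios[m]["ratio"].to_numpy() for m in media)
        report["ratio_comparison"] = compare_groups(a, b)
    if cfg.options.get("fem_sweep"):
        sweep = pd.read_csv(cfg.options["fem_sweep"])
        report["fem_best_fit"] = select_best_fit(
            sweep,
            k_target=cfg.options.get("k_target", 8.1),
            f_target=cfg.options.get("f_target", 10.0),
        )
    cio.write_report(report, out / "pollen_report.json",
                     config=cfg.as_dict(), seed=cfg.seed)
    return report


def select_best_fit(sweep: pd.DataFrame, k_target: float, f_target: float | None = None) -> dict:
    """Pick the sweep row closest to the measured apparent stiffness.

    The joint criterion matches the colpus apparent stiffness and, when a
    reaction-force column is present, the absolute reaction force at the
    deepest sampled depth, both as relative errors.
    """
    col = sweep[sweep["site"] == "colpus_center"].dropna(subset=["k_apparent_Npm"])
    if col.empty:
        raise ValueError("sweep has no converged colpus rows")
    score = np.abs(col["k_apparent_Npm"] - k_target) / k_target
    if f_target is not None and "F_max_uN" in col.columns:
        score = score + np.abs(col["F_max_uN"] - f_target) / f_target
    best = col.loc[score.idxmin()]
    return {
        "P_MPa": float(best["P_MPa"]),
        "E_i_MPa": float(best["E_i_MPa"]),
        "E_e_MPa": float(best["E_e_MPa"]),
        "k_apparent_Npm": float(best["k_apparent_Npm"]),
        "score": float(score.min()),
    }


def run_worm_workflow(cfg: RunConfig) -> dict:
    """Build the unfolded stiffness map and compare soft/stiff bands."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = cfg.options
    if opts.get("synthetic", True):
        gen = gen_worm_map(WormGenSpec(seed=cfg.seed))
        map_ = assign_coordinates(gen["lines"], gen["declared_angles"],
                                  fiducials=gen["fiducials"])
        labels = gen["truth_labels"]
    else:
        path = opts.get("map_csv")
        if not path:
            raise ValueError("worm workflow needs map_csv or synthetic=True")
        map_ = cio.read_worm_map(path)
        labels = map_.band_labels
        if labels is None:
            raise ValueError("worm map has no band labels; supply a 'band' column")
    map_.band_labels = list(labels)
    cio.write_worm_map(map_, out / "worm_map.csv")
    grid = unfold(map_)
    grid.to_csv(out / "worm_map_unfolded.csv")
    comparison = band_comparison(map_, labels)
    report = {"workflow": "worm", "n_sites": len(map_.sites),
              "band_comparison": comparison}
    cio.write_report(report, out / "worm_report.json",
                     config=cfg.as_dict(), seed=cfg.seed)
    return report
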