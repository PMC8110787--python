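"""Force–displacement curve processing.

Turns raw micro-indentation records (stage displacement ``z`` in µm, force
``F`` in µN) into compliance-corrected apparent stiffness values.  The unit
convention is fixed package-wide: 1 µN/µm ≡ 1 N/m, so slopes computed from
(µm, µN) data are reported directly in N/m.

The apparent stiffness ``k`` is the slope ΔF/Δz of the force–displacement
curve.  Because the probe, sensor and mounting deform together with the
sample, the raw slope mixes the sample with the instrument chain; the two
act as springs in series, and the sample stiffness is recovered as

    k_sample = (1/k_measured − 1/k_system)⁻¹

where ``k_system`` is calibrated by indenting a rigid surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "ForceCurve",
    "CalibrationRecord",
    "StiffnessMeasurement",
    "ContactNotFoundError",
    "detect_contact_point",
    "fit_stiffness",
    "correct_compliance",
    "process_curve",
]

VALID_REGIONS = {"intine", "exine", "dry_exine", "worm", "calibration"}


class ContactNotFoundError(ValueError):
    """Raised when no contact point can be located on a force curve."""


@dataclass
class ForceCurve:
    """One indentation record.

    Parameters
    ----------
    z : array-like
        Displacement samples in µm, strictly increasing along the approach.
    F : array-like
        Force samples in µN, same length as ``z``.
    velocity : float
        Indentation speed in µm/s (metadata).
    approach_distance : float
        Pre-contact travel in µm (metadata).
    sensor_id, specimen_id : str
        Acquisition labels.
    region : str
        One of ``intine, exine, dry_exine, worm, calibration``.
    """

    z: np.ndarray
    F: np.ndarray
    velocity: float = 4.0
    approach_distance: float = 20.0
    sensor_id: str = ""
    specimen_id: str = ""
    region: str = "intine"
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.z.shape != self.F.shape or self.z.ndim != 1:
            raise ValueError("z and F must be 1-D arrays of equal length")
        if self.z.size < 10:
            raise ValueError("curve needs at least 10 samples")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("forces must be finite")
        if self.region not in VALID_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")

    def __len__(self) -> int:
        return self.z.size


@dataclass
class CalibrationRecord:
    """Instrument-chain stiffness from a rigid-surface indentation."""

    k_system: float
    source_curve_id: str = ""

    def __post_init__(self) -> None:
        if not self.k_system > 0:
            raise ValueError("k_system must be positive")


@dataclass
class StiffnessMeasurement:
    """One compliance-corrected apparent-stiffness value with diagnostics."""

    k: float
    k_uncorrected: float
    contact_point: float
    fit_window: tuple
    r_squared: float
    region: str = ""
    specimen_id: str = ""
    curve_id: str = ""
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "curve_id": self.curve_id,
            "specimen_id": self.specimen_id,
            "region": self.region,
            "k_Npm": self.k,
            "k_uncorrected_Npm": self.k_uncorrected,
            "contact_point_um": self.contact_point,
            "fit_window_lo": self.fit_window[0],
            "fit_window_hi": self.fit_window[1],
            "r_squared": self.r_squared,
        }


def detect_contact_point(
    curve: ForceCurve,
    noise_mult: float = 5.0,
    baseline_fraction: float = 0.25,
) -> float:
    """Locate the contact displacement z0 on an approach curve.

    The baseline force level and its scatter are estimated from the first
    ``baseline_fraction`` of samples (assumed pre-contact).  Contact is the
    first sample whose force exceeds ``baseline + noise_mult * SD``, refined
    by back-extrapolating a line fitted just past the crossing down to the
    baseline level.  For a noiseless piecewise-linear curve this returns the
    kink exactly.

    Returns the contact displacement in µm.
    """
    if noise_mult <= 0:
        raise ValueError("noise_mult must be positive")
    z, F = curve.z, curve.F
    n_base = max(int(round(baseline_fraction * len(z))), 4)
    baseline = float(np.mean(F[:n_base]))
    sd = float(np.std(F[:n_base], ddof=1))
    thresh = baseline + noise_mult * sd
    above = np.nonzero(F > thresh)[0]
    # require the crossing to be sustained, not a lone noise spike
    idx = -1
    for i in above:
        tail = F[i:min(i + 5, len(F))]
        if np.all(tail > baseline + 0.5 * noise_mult * sd):
            idx = int(i)
            break
    if idx < 0:
        raise ContactNotFoundError("no contact detected")
    if idx == 0:
        import warnings

        warnings.warn("no baseline: contact at first sample", stacklevel=2)
        return float(z[0])
    # refine: fit a line on the rising part after the crossing and extrapolate
    # back to the baseline force level
    hi = min(idx + max(10, (len(z) - idx) // 4), len(z))
    if hi - idx >= 3:
        sl, ic = np.polyfit(z[idx:hi], F[idx:hi], 1)
        if sl > 0:
            z0 = (baseline - ic) / sl
            if z[0] <= z0 <= z[idx]:
                return float(z0)
    return float(z[idx - 1])


def fit_stiffness(
    curve: ForceCurve,
    z0: float,
    window: tuple[float, float] = (0.5, 1.0),
) -> tuple[float, float]:
    """Least-squares slope of F vs z over a force-fraction window.

    ``window = (lo, hi]`` selects post-contact samples whose force lies in
    ``(lo*F_max, hi*F_max]``.  The default upper half of the force range is
    the region where experimental curves are closest to linear.

    Returns ``(k_uncorrected, r_squared)`` with the slope in N/m.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    post = curve.z > z0
    z, F = curve.z[post], curve.F[post]
    if z.size < 5:
        raise ValueError("window too narrow: fewer than 5 post-contact points")
    f_max = F.max()
    sel = (F > lo * f_max) & (F <= hi * f_max)
    if sel.sum() < 5:
        raise ValueError("window too narrow: fewer than 5 points in window")
    res = _stats.linregress(z[sel], F[sel])
    return float(res.slope), float(res.rvalue**2)


def correct_compliance(k_measured: float, cal: CalibrationRecord) -> float:
    """Series-spring compliance correction.

    k_sample = (1/k_measured − 1/k_system)⁻¹.  The correction can only
    increase the slope; it diverges as the measured stiffness approaches the
    system stiffness (a rigid sample).
    """
    if not k_measured > 0:
        raise ValueError("k_measured must be positive")
    if k_measured >= cal.k_system:
        raise ValueError("measured stiffness exceeds system stiffness")
    return 1.0 / (1.0 / k_measured - 1.0 / cal.k_system)


def process_curve(
    curve: ForceCurve,
    cal: CalibrationRecord,
    noise_mult: float = 5.0,
    window: tuple[float, float] = (0.5, 1.0),
) -> StiffnessMeasurement:
    """Full per-curve pipeline: contact → slope → compliance correction."""
    try:
        z0 = detect_contact_point(curve, noise_mult=noise_mult)
        k_raw, r2 = fit_stiffness(curve, z0, window=window)
        if k_raw <= 0:
            raise ValueError("non-positive fitted slope")
        k = correct_compliance(k_raw, cal)
    except ValueError as exc:
        raise type(exc)(f"curve {curve.curve_id or '<unnamed>'}: {exc}") from exc
    return StiffnessMeasurement(
        k=k,
        k_uncorrected=k_raw,
        contact_point=z0,
        fit_window=window,
        r_squared=r2,
        region=curve.region,
        specimen_id=curve.specimen_id,
        curve_id=curve.curve_id,
        extras={"k_system": cal.k_system, "noise_mult": noise_mult},
    )


def process_batch(
    curves: Sequence[ForceCurve],
    cal: CalibrationRecord,
    **options,
) -> list[StiffnessMeasurement]:
    """Process many curves; order of the output follows the input."""
    return [process_curve(c, cal, **options) for c in curves]
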