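"""Per-specimen aggregation and population statistics.

Apparent stiffness varies strongly between individual pollen grains, but the
*ratio* of the mean colpus (intine) stiffness to the mean exine stiffness of
the same grain is far more stable.  The per-grain construction matters: the
ratio of per-grain means is aggregated across grains, never the ratio of
pooled means.

Group comparisons follow the classical recipe: an F-test on the variances
decides between the pooled (Student) and unequal-variance (Welch) two-sample
t-test, both double-sided.  Normality is assessed with the D'Agostino–Pearson
omnibus test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .curves import StiffnessMeasurement

__all__ = [
    "Specimen",
    "RatioRecord",
    "per_grain_ratio",
    "coefficient_of_variation",
    "normality_test",
    "compare_groups",
    "summarize_population",
    "ratios_from_measurements",
]


@dataclass
class Specimen:
    """All stiffness measurements taken on one specimen."""

    specimen_id: str
    medium: str = "water"
    measurements: list[StiffnessMeasurement] = field(default_factory=list)

    def region_values(self, region: str) -> np.ndarray:
        return np.array([m.k for m in self.measurements if m.region == region])


@dataclass
class RatioRecord:
    """Per-grain intine/exine apparent-stiffness ratio."""

    specimen_id: str
    k_i_mean: float
    k_e_mean: float
    ratio: float


def per_grain_ratio(spec: Specimen) -> RatioRecord:
    """Mean colpus stiffness of one grain divided by its mean exine stiffness."""
    k_i = spec.region_values("intine")
    k_e = spec.region_values("exine")
    if k_i.size == 0 or k_e.size == 0:
        raise ValueError(
            f"incomplete specimen {spec.specimen_id!r}: needs both intine and "
            f"exine measurements"
        )
    k_i_mean, k_e_mean = float(k_i.mean()), float(k_e.mean())
    return RatioRecord(spec.specimen_id, k_i_mean, k_e_mean, k_i_mean / k_e_mean)


def ratios_from_measurements(
    measurements: list[StiffnessMeasurement], medium: str = "water"
) -> pd.DataFrame:
    """Group measurements by specimen and compute one ratio per grain."""
    by_spec: dict[str, Specimen] = {}
    for m in measurements:
        by_spec.setdefault(m.specimen_id, Specimen(m.specimen_id, medium)).measurements.append(m)
    rows = []
    for spec in by_spec.values():
        r = per_grain_ratio(spec)
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "medium": medium,
                "k_i_mean_Npm": r.k_i_mean,
                "k_e_mean_Npm": r.k_e_mean,
                "ratio": r.ratio,
            }
        )
    return pd.DataFrame(rows)


def coefficient_of_variation(values) -> float:
    """Sample SD divided by mean, as a fraction."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(v.std(ddof=1) / mean)


def normality_test(values) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus normality test.

    Returns ``(statistic, p)``.  Requires n ≥ 8 and non-degenerate data.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("normality test needs n >= 8")
    if np.ptp(v) == 0:
        raise ValueError("constant data: normality test undefined")
    stat, p = _stats.normaltest(v)
    return float(stat), float(p)


def variance_f_test(a, b) -> tuple[float, float]:
    """Two-sided F-test for equality of two variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate variances in both groups")
    if vb == 0 or va == 0:
        return np.inf, 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2 * min(_stats.f.cdf(f, dfa, dfb), _stats.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))


def compare_groups(
    a,
    b,
    variance_rule: str = "f_test",
    alpha: float = 0.05,
) -> dict:
    """Double-sided two-sample t-test with F-test-guided variance handling.

    ``variance_rule``: ``"f_test"`` (pooled unless the F-test rejects equal
    variances at ``alpha``), ``"pooled"``, or ``"welch"``.

    Returns a dict with ``t, df, p, method, f_statistic, f_p``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.array_equal(np.sort(a), np.sort(b)) and a.mean() == b.mean():
            return {
                "t": 0.0, "df": float(a.size + b.size - 2), "p": 1.0,
                "method": "pooled", "f_statistic": np.nan, "f_p": np.nan,
            }
        raise ValueError("degenerate variance in both groups")
    f_stat = f_p = np.nan
    if variance_rule == "f_test":
        f_stat, f_p = variance_f_test(a, b)
        equal_var = f_p >= alpha
    elif variance_rule == "pooled":
        equal_var = True
    elif variance_rule == "welch":
        equal_var = False
    else:
        raise ValueError(f"unknown variance_rule {variance_rule!r}")
    res = _stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "method": "pooled" if equal_var else "welch",
        "f_statistic": float(f_stat),
        "f_p": float(f_p),
    }


def summarize_population(values) -> dict:
    """Location/spread summary with the linear-interpolation quantile rule.

    Reports mean, SD, median, IQR bounds, 5th/95th percentiles, min and max —
    the quantities shown on the study's box/violin plots.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q = np.percentile(v, [5, 25, 50, 75, 95], method="linear")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(q[2]),
        "q25": float(q[1]),
        "q75": float(q[3]),
        "p5": float(q[0]),
        "p95": float(q[4]),
        "min": float(v.min()),
        "max": float(v.max()),
    }
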