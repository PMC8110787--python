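"""Per-grain ratios, repeatability, and group comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

from cellindent.curves import StiffnessMeasurement
from cellindent.stats import (
    Specimen,
    coefficient_of_variation,
    compare_groups,
    normality_test,
    per_grain_ratio,
    ratios_from_measurements,
    summarize_population,
    variance_f_test,
)


def _spec(k_i, k_e, sid="g1"):
    ms = [StiffnessMeasurement(k, k, 0, (0.5, 1), 1.0, "intine", sid) for k in k_i]
    ms += [StiffnessMeasurement(k, k, 0, (0.5, 1), 1.0, "exine", sid) for k in k_e]
    return Specimen(sid, "water", ms)


class TestPerGrainRatio:
    def test_single_grain_printed_values(self):
        r = per_grain_ratio(_spec([8.1], [14.3]))
        assert r.ratio == pytest.approx(8.1 / 14.3, rel=1e-12)
        assert r.ratio == pytest.approx(0.566, abs=5e-4)

    def test_identical_regions_give_unity(self):
        assert per_grain_ratio(_spec([7.0, 7.0], [7.0])).ratio == 1.0

    def test_hand_arithmetic(self):
        assert per_grain_ratio(_spec([2.0, 4.0], [6.0, 6.0])).ratio == pytest.approx(0.5)

    def test_missing_region_rejected(self):
        with pytest.raises(ValueError, match="incomplete specimen"):
            per_grain_ratio(_spec([2.0], []))

    def test_scale_invariance(self):
        base = per_grain_ratio(_spec([3.0, 5.0], [9.0, 11.0])).ratio
        for c in (0.1, 3.7, 100.0):
            scaled = per_grain_ratio(_spec([3.0 * c, 5.0 * c], [9.0 * c, 11.0 * c])).ratio
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_per_grain_construction_differs_from_pooled(self):
        """The mean of per-grain ratios is not the ratio of pooled means; the
        pipeline must use the former."""
        ms = []
        for sid, (ki, ke) in {"a": (2.0, 4.0), "b": (20.0, 80.0)}.items():
            ms.append(StiffnessMeasurement(ki, ki, 0, (0.5, 1), 1.0, "intine", sid))
            ms.append(StiffnessMeasurement(ke, ke, 0, (0.5, 1), 1.0, "exine", sid))
        df = ratios_from_measurements(ms)
        per_grain_mean = df["ratio"].mean()           # (0.5 + 0.25)/2 = 0.375
        pooled = (2 + 20) / (4 + 80)                  # ~0.262
        assert per_grain_mean == pytest.approx(0.375)
        assert abs(per_grain_mean - pooled) > 0.1


class TestCoefficientOfVariation:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([3.3] * 5) == 0.0

    def test_simple_value(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])

    def test_repeatability_design_recovers_nominal_cv(self):
        """n=5 specimens × m=10 repeats with 4.8% multiplicative noise gives a
        mean CV close to nominal across many seeds."""
        cvs = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            base = rng.uniform(5, 20, size=5)
            per_spec = [
                coefficient_of_variation(b * (1 + rng.normal(0, 0.048, 10)))
                for b in base
            ]
            cvs.append(np.mean(per_spec))
        assert 0.035 <= np.mean(cvs) <= 0.06


class TestNormality:
    def test_null_p_values_are_uniform(self):
        """p-values under the normal null follow U(0,1) (KS check)."""
        rng = np.random.default_rng(42)
        ps = [normality_test(rng.normal(size=500))[1] for _ in range(200)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_bimodal_mixture_rejected(self):
        """A mixture mimicking the intine/exine marginals is detected."""
        rng = np.random.default_rng(3)
        comp = rng.random(300) < 0.5
        x = np.where(comp, rng.normal(9, 1, 300), rng.normal(20, 1, 300))
        assert normality_test(x)[1] < 1e-3

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            normality_test(np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test(np.arange(5.0))


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        """4+4 fixture: pooled t = −1/(s_p√(1/2)) with s_p² = 5/3."""
        res = compare_groups([1, 2, 3, 4], [2, 3, 4, 5], variance_rule="pooled")
        assert res["t"] == pytest.approx(-1.0954451, abs=1e-6)
        assert res["df"] == 6
        assert res["p"] == pytest.approx(2 * sps.t.sf(1.0954451, 6), rel=1e-6)

    def test_symmetry_up_to_sign(self):
        a = [1.0, 2.5, 3.0, 4.8]
        b = [2.0, 3.3, 4.1, 6.0, 7.2]
        r1, r2 = compare_groups(a, b), compare_groups(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])
        assert 0 <= r1["p"] <= 1

    def test_water_vs_cacl2_settings_have_power(self):
        """Ratio populations 0.56±0.10 vs 0.66±0.10 (n=30) reject at α=0.05
        in at least 90% of seeded replicates."""
        rejected = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.56, 0.10, 30)
            b = rng.normal(0.66, 0.10, 30)
            rejected += compare_groups(a, b)["p"] < 0.05
        assert rejected / n_rep >= 0.90

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_f_test_drives_welch_choice(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1.0, 40)
        b = rng.normal(0, 6.0, 40)
        res = compare_groups(a, b)
        assert res["method"] == "welch"
        assert variance_f_test(a, b)[1] < 0.05


class TestSummary:
    def test_linear_interpolation_percentiles(self):
        s = summarize_population(np.arange(1, 101))
        assert s["median"] == pytest.approx(50.5)
        assert s["p5"] == pytest.approx(5.95)
        assert s["p95"] == pytest.approx(95.05)
        assert s["q25"] == pytest.approx(25.75)

    def test_single_value(self):
        s = summarize_population([4.2])
        for key in ("mean", "median", "min", "max", "p5", "p95"):
            assert s[key] == pytest.approx(4.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_population([])
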