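"""Force-curve processing: contact detection, slope fitting, compliance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellindent.curves import (
    CalibrationRecord,
    ContactNotFoundError,
    ForceCurve,
    correct_compliance,
    detect_contact_point,
    fit_stiffness,
    process_batch,
    process_curve,
)

from conftest import make_kink_curve


class TestContactDetection:
    def test_noiseless_kink_found_exactly(self, kink_curve):
        assert detect_contact_point(kink_curve, noise_mult=5.0) == pytest.approx(5.0, abs=1e-9)

    def test_noisy_contact_within_window_across_seeds(self):
        """With σ=0.01 µN noise the detected z0 stays in [4.8, 5.3] µm for
        at least 95% of seeded replicates."""
        hits = 0
        n = 1000
        for seed in range(n):
            c = make_kink_curve(noise_sd=0.01, rng=np.random.default_rng(seed))
            try:
                z0 = detect_contact_point(c, noise_mult=5.0)
            except ContactNotFoundError:
                continue
            hits += 4.8 <= z0 <= 5.3
        assert hits / n >= 0.95

    def test_flat_curve_raises(self):
        c = ForceCurve(z=np.linspace(0, 10, 200), F=np.zeros(200))
        with pytest.raises(ContactNotFoundError):
            detect_contact_point(c)


class TestSlopeFit:
    def test_exact_line_any_window(self):
        c = make_kink_curve(k=2.0, z0=1.0, z_max=6.0)
        for window in [(0.5, 1.0), (0.2, 0.9), (0.0, 1.0)]:
            k, r2 = fit_stiffness(c, 1.0, window=window)
            assert k == pytest.approx(2.0, rel=1e-9)
            assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_quadratic_matches_closed_form_regression(self):
        """For F = (z−z0)² the windowed slope equals the least-squares slope
        of the parabola on that force interval (computed independently)."""
        z0, f_max = 1.0, 10.0
        z = np.linspace(0, z0 + np.sqrt(f_max), 4001)
        F = np.clip(z - z0, 0, None) ** 2
        c = ForceCurve(z=z, F=F)
        k, _ = fit_stiffness(c, z0, window=(0.5, 1.0))
        # independent oracle: dense regression of y = x² restricted to the window
        x = np.linspace(np.sqrt(0.5 * f_max), np.sqrt(f_max), 200001)
        oracle = np.polyfit(x, x**2, 1)[0]
        assert k == pytest.approx(oracle, rel=1e-3)
        # continuum identity for y = x² on [x1, x2]: slope = x1 + x2
        assert oracle == pytest.approx(np.sqrt(5.0) + np.sqrt(10.0), rel=1e-6)

    def test_too_few_points_in_window(self):
        z = np.linspace(0, 10, 12)
        c = ForceCurve(z=z, F=np.clip(z - 9.0, 0, None))
        with pytest.raises(ValueError, match="window too narrow"):
            fit_stiffness(c, 9.0)


class TestComplianceCorrection:
    def test_printed_formula_value(self):
        assert correct_compliance(8.0, CalibrationRecord(40.0)) == pytest.approx(10.0)

    def test_rigid_system_limit(self):
        k = correct_compliance(5.0, CalibrationRecord(1e9))
        assert abs(k - 5.0) / 5.0 < 1e-7

    def test_series_spring_identity(self):
        assert correct_compliance(5.0, CalibrationRecord(10.0)) == pytest.approx(10.0)

    def test_exceeding_system_stiffness_rejected(self):
        with pytest.raises(ValueError, match="exceeds system stiffness"):
            correct_compliance(12.0, CalibrationRecord(10.0))

    @given(
        k_m=st.floats(0.1, 50.0),
        k_sys=st.floats(100.0, 1000.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_correction_increases_slope_and_is_monotone(self, k_m, k_sys):
        k = correct_compliance(k_m, CalibrationRecord(k_sys))
        assert k > k_m
        # monotone in k_m at fixed k_sys
        assert correct_compliance(k_m * 1.01, CalibrationRecord(k_sys)) > k
        # increases as the system softens
        assert correct_compliance(k_m, CalibrationRecord(k_sys * 0.5)) > k


class TestProcessCurve:
    def test_roundtrip_recovers_true_stiffness(self):
        k_true, k_sys = 9.3, 300.0
        k_eff = 1 / (1 / k_true + 1 / k_sys)
        c = make_kink_curve(k=k_eff, z0=3.0, z_max=6.0)
        m = process_curve(c, CalibrationRecord(k_sys))
        assert m.k == pytest.approx(k_true, rel=5e-3)
        assert m.k >= m.k_uncorrected
        assert 0 <= m.r_squared <= 1

    def test_rigid_sample_detected_as_calibration_error(self):
        c = make_kink_curve(k=400.0, z0=3.0, z_max=4.0)
        with pytest.raises(ValueError, match="exceeds system stiffness"):
            process_curve(c, CalibrationRecord(300.0))

    def test_batch_order_independent(self):
        rng = np.random.default_rng(7)
        curves = [
            make_kink_curve(k=5 + i, z0=2.0, z_max=6.0, noise_sd=0.01, rng=rng,
                            curve_id=f"c{i}")
            for i in range(10)
        ]
        cal = CalibrationRecord(300.0)
        ks = {m.curve_id: m.k for m in process_batch(curves, cal)}
        ks_rev = {m.curve_id: m.k for m in process_batch(curves[::-1], cal)}
        assert ks == ks_rev

    @pytest.mark.parametrize("k_true", [0.5, 2.0, 9.3, 50.0, 140.0])
    def test_noiseless_recovery_below_half_system_stiffness(self, k_true):
        k_sys = 300.0
        k_eff = 1 / (1 / k_true + 1 / k_sys)
        depth = 10 / k_eff  # travel to reach the 10 µN force limit
        c = make_kink_curve(k=k_eff, z0=3.0, z_max=3.0 + depth,
                            step=min(0.02, depth / 50))
        m = process_curve(c, CalibrationRecord(k_sys))
        assert m.k == pytest.approx(k_true, rel=1e-3)

    def test_unit_coherence_micro_vs_si(self):
        """Stiffness from (µm, µN) data equals stiffness from (m, N) data."""
        k_eff = 1 / (1 / 9.3 + 1 / 300.0)
        c_um = make_kink_curve(k=k_eff, z0=3.0, z_max=6.0)
        c_si = ForceCurve(z=c_um.z * 1e-6, F=c_um.F * 1e-6)
        m_um = process_curve(c_um, CalibrationRecord(300.0))
        m_si = process_curve(c_si, CalibrationRecord(300.0))
        assert m_um.k == pytest.approx(m_si.k, rel=1e-9)


class TestForceCurveValidation:
    def test_rejects_short_curves(self):
        with pytest.raises(ValueError):
            ForceCurve(z=np.arange(5.0), F=np.zeros(5))

    def test_rejects_nonmonotone_displacement(self):
        z = np.linspace(0, 1, 20)
        z[10] = z[9]
        with pytest.raises(ValueError):
            ForceCurve(z=z, F=np.zeros(20))

    def test_rejects_nonfinite_force(self):
        F = np.zeros(20)
        F[3] = np.nan
        with pytest.raises(ValueError):
            ForceCurve(z=np.linspace(0, 1, 20), F=F)
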