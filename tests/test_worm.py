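"""Cylindrical worm stiffness mapping: coordinates, unfolding, bands."""

import numpy as np
import pytest

from cellindent.synth import WormGenSpec, gen_worm_map
from cellindent.worm import (
    IndentationSite,
    WormStiffnessMap,
    assign_coordinates,
    band_comparison,
    detect_bands,
    estimated_drift,
    refold,
    two_means_labels,
    unfold,
)


def _two_line_map(theta2=90.0):
    lines = [[(0.0, 1.0), (20.0, 1.1)], [(0.0, 2.0), (20.0, 2.1)]]
    return assign_coordinates(lines, [0.0, theta2])


class TestCoordinates:
    def test_declared_angles_without_drift(self):
        m = _two_line_map()
        thetas = {s.line_index: s.theta for s in m.sites}
        assert thetas[0] == 0.0 and thetas[1] == 90.0

    def test_theta_wraps_mod_360(self):
        m = _two_line_map(theta2=370.0)
        assert {s.theta for s in m.sites if s.line_index == 1} == {10.0}
        assert IndentationSite(0, 0.0, 350.0 + 20.0, 1.0).theta == pytest.approx(10.0)

    def test_injected_drift_recovered_from_fiducials(self):
        """A +10° drift on line 2 is recovered within 2° via the tracked
        surface fiducial."""
        spec = WormGenSpec(drift=(0.0, 10.0, 0.0, 0.0, 0.0), seed=11)
        gen = gen_worm_map(spec)
        m = assign_coordinates(gen["lines"], gen["declared_angles"],
                               fiducials=gen["fiducials"])
        drift_est = estimated_drift(m, gen["declared_angles"])
        assert abs(drift_est[1] - 10.0) <= 2.0
        assert all(abs(d) <= 2.0 for i, d in enumerate(drift_est) if i != 1)

    def test_missing_rotation_metadata_rejected(self):
        with pytest.raises(ValueError):
            assign_coordinates([[(0.0, 1.0)]], [0.0, 90.0])

    def test_rotation_equivariance(self):
        """Rotating every declared angle by a constant shifts all θ by that
        constant (mod 360) and leaves the band comparison unchanged."""
        gen = gen_worm_map(WormGenSpec(seed=4))
        m0 = assign_coordinates(gen["lines"], gen["declared_angles"],
                                fiducials=gen["fiducials"])
        shifted = [a + 77.0 for a in gen["declared_angles"]]
        fid = [f + 77.0 for f in gen["fiducials"]]
        m1 = assign_coordinates(gen["lines"], shifted, fiducials=fid)
        for s0, s1 in zip(m0.sites, m1.sites):
            assert (s1.theta - s0.theta) % 360.0 == pytest.approx(77.0, abs=1e-9)
        r0 = band_comparison(m0, gen["truth_labels"])
        r1 = band_comparison(m1, gen["truth_labels"])
        assert r0["test"]["p"] == pytest.approx(r1["test"]["p"], rel=1e-12)


class TestUnfold:
    def test_grid_size_bounded_by_sites(self):
        gen = gen_worm_map(WormGenSpec(n_lines=5, sites_per_line=11, seed=0))
        m = gen["truth_map"]
        grid = unfold(m)
        assert grid.notna().sum().sum() <= 55

    def test_roundtrip_preserves_every_site(self):
        gen = gen_worm_map(WormGenSpec(seed=2))
        m = gen["truth_map"]
        long = refold(unfold(m)).set_index(["s_um", "theta_deg"])["k_Npm"]
        for s in m.sites:
            assert long.loc[(s.s, s.theta)] == pytest.approx(s.k)

    def test_holes_preserved_not_interpolated(self):
        sites = [IndentationSite(0, 0.0, 0.0, 1.0), IndentationSite(0, 20.0, 0.0, 1.2),
                 IndentationSite(1, 0.0, 90.0, 2.0)]
        grid = unfold(WormStiffnessMap(sites))
        assert np.isnan(grid.loc[90.0, 20.0])

    def test_single_line_rejected(self):
        sites = [IndentationSite(0, 0.0, 0.0, 1.0), IndentationSite(0, 20.0, 0.0, 1.2)]
        with pytest.raises(ValueError):
            unfold(WormStiffnessMap(sites))


class TestBands:
    def test_identical_groups_not_significant(self):
        sites = [IndentationSite(0, 20.0 * i, 0.0, 1.0 + 0.1 * (i % 3)) for i in range(6)]
        sites += [IndentationSite(1, 20.0 * i, 90.0, 1.0 + 0.1 * (i % 3)) for i in range(6)]
        labels = ["soft"] * 6 + ["stiff"] * 6
        res = band_comparison(WormStiffnessMap(sites), labels)
        assert res["test"]["p"] > 0.9

    def test_study_group_parameters_strongly_separated(self):
        """Soft 0.53±0.07 (n=20) vs stiff 0.75±0.11 (n=30) is highly
        significant in most seeded replicates."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            gen = gen_worm_map(WormGenSpec(seed=seed))
            m = assign_coordinates(gen["lines"], gen["declared_angles"],
                                   fiducials=gen["fiducials"])
            res = band_comparison(m, gen["truth_labels"])
            hits += res["test"]["p"] < 1e-6
        assert hits / n_rep >= 0.95

    def test_permuted_labels_calibrated_under_null(self):
        """Random label permutations give roughly uniform p-values."""
        gen = gen_worm_map(WormGenSpec(seed=9))
        m = gen["truth_map"]
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            labels = list(rng.permutation(gen["truth_labels"]))
            ps.append(band_comparison(m, labels)["test"]["p"])
        ps = np.asarray(ps)
        # uniformity coarse check: roughly alpha of permutations below alpha
        assert 0.005 <= (ps < 0.05).mean() <= 0.15
        assert abs(np.median(ps) - 0.5) < 0.2

    def test_band_spacing_recovered(self):
        """Alternating bands laid out every 90° are recovered within ±15°."""
        spec = WormGenSpec(
            n_lines=8, line_angles=tuple(range(0, 360, 45)),
            stiff_band_centers=(90.0, 270.0), stiff_band_halfwidth=20.0, seed=21,
        )
        gen = gen_worm_map(spec)
        info = detect_bands(gen["truth_map"])
        assert info["adjacent_spacings_deg"], "no bands found"
        for spacing in info["adjacent_spacings_deg"]:
            assert abs(spacing - 90.0) <= 15.0

    def test_single_group_labels_rejected(self):
        gen = gen_worm_map(WormGenSpec(seed=1))
        with pytest.raises(ValueError):
            band_comparison(gen["truth_map"], ["soft"] * len(gen["truth_map"].sites))

    def test_two_means_split_mostly_matches_truth(self):
        """2-means on k recovers the soft/stiff partition up to the overlap
        of the two group distributions (Bayes agreement ≈ 0.89)."""
        agree = []
        for seed in range(20):
            gen = gen_worm_map(WormGenSpec(seed=seed))
            labels = two_means_labels(gen["truth_map"])
            agree.append(np.mean([a == b for a, b in zip(labels, gen["truth_labels"])]))
        assert np.mean(agree) >= 0.85
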