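"""Pore profiling, ensembles, occupancancy and Ramachandran densities
against analytic fixtures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import clcgating as cg
from clcgating.geometry import make_ion_fixture, make_pore_fixture
from clcgating.structure import (SiteDefinition, occupancy_table,
                                 pore_profile, ramachandran_density,
                                 sample_macrostate_ensemble,
                                 subthreshold_extent)


@pytest.fixture(scope="module")
def cylinder():
    return make_pore_fixture("cylinder", ring_radius=4.5, atom_radius=1.5,
                             length=20.0)


class TestPoreFixtures:
    def test_cylinder_true_radius_is_ring_minus_atom(self, cylinder):
        assert cylinder.true_radius(0.0) == pytest.approx(3.0)

    def test_hourglass_waist(self):
        f = make_pore_fixture("hourglass", waist=1.5, curvature=0.05)
        # exactly the waist at z=0; off-waist the wall-tangency minimum
        # lies at or below the generating curve value
        assert f.true_radius(0.0) == pytest.approx(1.5)
        assert 1.5 < f.true_radius(4.0) <= 1.5 + 0.05 * 16 + 1e-9
        assert f.true_radius(4.0) == pytest.approx(1.5 + 0.05 * 16, abs=0.25)

    def test_rejects_nonpositive_params(self):
        with pytest.raises(ValueError, match="ring_radius"):
            make_pore_fixture("cylinder", ring_radius=-1.0)


class TestPoreProfile:
    def test_cylinder_profile_flat_at_three_angstrom(self, cylinder):
        prof = pore_profile(cylinder.coords, cylinder.radii,
                            start_point=[0, 0, 0], axis=[0, 0, 1],
                            extent=8.0, step=0.5)
        np.testing.assert_allclose(prof.radius, 3.0, atol=0.05)
        assert not prof.impassable.any()

    def test_single_offset_atom_arithmetic(self):
        # probe confined to the axis point: r = distance - atom radius
        coords = np.array([[4.0, 0, 0], [0, 4.0, 0], [-4.0, 0, 0],
                           [0, -4.0, 0]])
        radii = np.full(4, 1.5)
        prof = pore_profile(coords, radii, start_point=[0, 0, 0],
                            axis=[0, 0, 1], extent=0.1, step=1.0,
                            max_radius=0.01, grid=0.01)
        assert prof.radius[0] == pytest.approx(2.5, abs=0.02)

    def test_hourglass_bottleneck_and_subthreshold_extent(self):
        f = make_pore_fixture("hourglass", waist=1.5, curvature=0.05,
                              length=24.0, z_step=0.25, atoms_per_ring=36)
        # search disk kept inside the hourglass wall near the waist
        prof = pore_profile(f.coords, f.radii, start_point=[0, 0, 0],
                            axis=[0, 0, 1], extent=8.0, step=0.25,
                            max_radius=2.5)
        s_star, r_star = prof.bottleneck
        assert r_star == pytest.approx(1.5, abs=0.05)
        assert abs(s_star) < 0.3
        # profile tracks the analytic fixture radius near the waist
        near = np.abs(prof.s) <= 4.0
        np.testing.assert_allclose(prof.radius[near],
                                   f.true_radius(prof.s[near]), atol=0.05)
        # sub-1.8 A stretch vs the analytic crossing of the fixture curve
        from scipy.optimize import brentq
        z_cross = brentq(lambda z: f.true_radius(np.array([z]))[0] - 1.8,
                         0.1, 6.0)
        total, longest = subthreshold_extent(prof, threshold=1.8)
        assert longest == pytest.approx(2 * z_cross, abs=0.25)
        assert total == pytest.approx(longest)

    def test_blocked_slice_reported_impassable(self):
        f = make_pore_fixture("blocked", ring_radius=4.5, atom_radius=1.5,
                              block_z=0.0)
        prof = pore_profile(f.coords, f.radii, start_point=[0, 0, 0],
                            axis=[0, 0, 1], extent=4.0, step=0.5,
                            max_radius=1.0)
        i = np.argmin(np.abs(prof.s))
        assert prof.impassable[i]

    def test_monotone_under_atom_inflation(self, cylinder):
        prof1 = pore_profile(cylinder.coords, cylinder.radii,
                             start_point=[0, 0, 0], axis=[0, 0, 1],
                             extent=4.0, step=1.0)
        prof2 = pore_profile(cylinder.coords, cylinder.radii + 0.4,
                             start_point=[0, 0, 0], axis=[0, 0, 1],
                             extent=4.0, step=1.0)
        assert np.all(prof2.radius <= prof1.radius + 1e-6)

    def test_rigid_transform_invariance(self, cylinder):
        R = Rotation.from_euler("xyz", [0.4, 1.0, -0.7]).as_matrix()
        t = np.array([3.0, -2.0, 7.0])
        prof1 = pore_profile(cylinder.coords, cylinder.radii,
                             start_point=[0, 0, 0], axis=[0, 0, 1],
                             extent=4.0, step=1.0)
        prof2 = pore_profile(cylinder.coords @ R.T + t, cylinder.radii,
                             start_point=t, axis=R @ np.array([0, 0, 1.0]),
                             extent=4.0, step=1.0)
        np.testing.assert_allclose(prof2.radius, prof1.radius, atol=0.02)

    def test_polyline_path_equivalent_to_axis(self, cylinder):
        prof1 = pore_profile(cylinder.coords, cylinder.radii,
                             start_point=[0, 0, 0], axis=[0, 0, 1],
                             extent=4.0, step=1.0)
        path = np.array([[0, 0, -4.0], [0, 0, 4.0]])
        prof2 = pore_profile(cylinder.coords, cylinder.radii, path=path,
                             step=1.0)
        np.testing.assert_allclose(np.sort(prof2.radius),
                                   np.sort(prof1.radius), atol=0.02)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="4 atoms"):
            pore_profile(np.zeros((2, 3)), np.ones(2),
                         start_point=[0, 0, 0], axis=[0, 0, 1], extent=1.0)


class TestSubthresholdExtent:
    def _profile(self, s, r):
        return cg.PoreProfile(s=np.asarray(s, float), radius=np.asarray(r, float),
                              impassable=np.zeros(len(s), bool),
                              open_funnel=np.zeros(len(s), bool))

    def test_everywhere_above_threshold_gives_zero(self):
        p = self._profile(np.arange(10.0), np.full(10, 3.0))
        assert subthreshold_extent(p, 1.8) == (0.0, 0.0)

    def test_rectangular_dip_of_19_angstrom(self):
        s = np.arange(0.0, 40.0, 0.5)
        r = np.where((s >= 10) & (s < 29), 1.0, 3.0)
        total, longest = subthreshold_extent(p := self._profile(s, r), 1.8)
        assert longest == pytest.approx(19.0, abs=0.5)

    def test_two_dips_total_and_longest(self):
        s = np.arange(0.0, 30.0, 0.1)
        r = np.full_like(s, 3.0)
        r[(s >= 2) & (s < 7)] = 1.0  # 5 A
        r[(s >= 15) & (s < 22)] = 1.0  # 7 A
        total, longest = subthreshold_extent(self._profile(s, r), 1.8)
        assert total == pytest.approx(12.0, abs=0.3)
        assert longest == pytest.approx(7.0, abs=0.2)


class TestIonFixtureAndOccupancy:
    SITES = {"S_ext": np.array([0.0, 0, 10.0]), "S_cen": np.array([0.0, 0, 0]),
             "S_int": np.array([0.0, 0, -10.0])}

    def test_zero_probability_never_places_ions(self):
        ens = make_ion_fixture(self.SITES, {"X": {"S_ext": 0.0}},
                               n_samples=200, seed=1)
        assert all(len(c) == 0 for c in ens["X"])

    def test_calibrated_open_state_site_frequency(self):
        probs = {"O": {"S_ext": 0.93, "S_cen": 0.04, "S_int": 0.04}}
        ens = make_ion_fixture(self.SITES, probs, n_samples=1000, seed=2)
        sites = [SiteDefinition(n, tuple(c)) for n, c in self.SITES.items()]
        table = occupancy_table(ens, sites)
        assert table.loc["O", "S_ext"] == pytest.approx(0.93, abs=0.03)

    def test_binomial_band_at_half(self):
        ens = make_ion_fixture(self.SITES, {"X": {"S_cen": 0.5}},
                               n_samples=10_000, seed=3)
        sites = [SiteDefinition("S_cen", tuple(self.SITES["S_cen"]))]
        f = occupancy_table(ens, sites).loc["X", "S_cen"]
        assert abs(f - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_overlapping_sites_warn(self):
        near = {"A": np.zeros(3), "B": np.array([1.0, 0, 0])}
        with pytest.warns(UserWarning, match="overlap"):
            make_ion_fixture(near, {"X": {"A": 0.1}}, n_samples=5, seed=0)

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            make_ion_fixture(self.SITES, {"X": {"S_ext": 1.2}}, n_samples=2)

    def test_ion_at_center_always_counts(self):
        ens = {"X": [np.array([[0.0, 0, 10.0]])] * 50}
        sites = [SiteDefinition("S_ext", (0.0, 0.0, 10.0))]
        assert occupancy_table(ens, sites).loc["X", "S_ext"] == 1.0

    def test_larger_site_radius_never_decreases_occupancy(self):
        probs = {"X": {"S_ext": 0.4, "S_cen": 0.3, "S_int": 0.2}}
        ens = make_ion_fixture(self.SITES, probs, n_samples=500, seed=4)
        small = [SiteDefinition(n, tuple(c), radius=1.5)
                 for n, c in self.SITES.items()]
        big = [SiteDefinition(n, tuple(c), radius=3.5)
               for n, c in self.SITES.items()]
        ts = occupancy_table(ens, small)
        tb = occupancy_table(ens, big)
        assert (tb.values >= ts.values - 1e-12).all()
        assert ((ts.values >= 0) & (ts.values <= 1)).all()


class TestSampleMacrostateEnsemble:
    def test_single_frame_macrostate_returns_it_n_times(self, small_study):
        r = small_study.condition("protonated")
        micro = int(r.msmodel.active_set[
            np.flatnonzero(r.macromodel.assignments == 0)[0]])
        frame_index = {micro: ["frameA"]}
        out = sample_macrostate_ensemble(r.msmodel, r.macromodel, frame_index,
                                         state=0, n=25, seed=0)
        assert out == ["frameA"] * 25

    def test_sampling_ratio_follows_stationary_weights(self, small_study):
        r = small_study.condition("protonated")
        members = np.flatnonzero(r.macromodel.assignments == 0)
        picks = members[np.argsort(r.msmodel.stationary[members])[-2:]]
        frame_index = {int(r.msmodel.active_set[p]): [f"m{i}"]
                       for i, p in enumerate(picks)}
        w = r.msmodel.stationary[picks]
        w = w / w.sum()
        out = sample_macrostate_ensemble(r.msmodel, r.macromodel, frame_index,
                                         state=0, n=4000, seed=1)
        f1 = sum(1 for o in out if o == "m1") / 4000
        assert abs(f1 - w[1]) < 3 * np.sqrt(w[0] * w[1] / 4000) + 0.01

    def test_empty_macrostate_rejected(self, small_study):
        r = small_study.condition("protonated")
        with pytest.raises(ValueError):
            sample_macrostate_ensemble(r.msmodel, r.macromodel, {},
                                       state=99, n=5, seed=0)


class TestRamachandranDensity:
    def test_identical_frames_occupy_single_bin(self):
        H, edges, levels = ramachandran_density(np.full(100, -57.0),
                                                np.full(100, -47.0), bins=36)
        assert np.count_nonzero(H) == 1
        assert H.max() == pytest.approx(1.0)

    def test_density_sums_to_one_and_is_shift_invariant(self, rng):
        phi = rng.uniform(-180, 180, 5000)
        psi = rng.uniform(-180, 180, 5000)
        H1, _, _ = ramachandran_density(phi, psi, bins=24)
        H2, _, _ = ramachandran_density(phi + 360, psi - 720, bins=24)
        assert H1.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(H1, H2, atol=1e-12)

    def test_two_basin_weight_ratio_matches_weights(self, rng):
        n = 20_000
        basin = rng.random(n) < 0.25
        phi = np.where(basin, -60.0, 60.0) + rng.normal(0, 8, n)
        psi = np.where(basin, -45.0, 135.0) + rng.normal(0, 8, n)
        H, (xe, ye), _ = ramachandran_density(phi, psi, bins=36)
        mass_left = H[xe[:-1] < 0, :].sum()
        assert mass_left == pytest.approx(0.25, abs=0.02)

    def test_distinct_states_occupy_distinct_wells(self):
        """Closed vs open backbone ensembles give disjoint density peaks."""
        em = cg.default_emission_model()
        fms = cg.emit_features([np.zeros(3000, dtype=int),
                                np.full(3000, 2, dtype=int)], em, seed=6)
        f_phi, f_psi = "psi:I170-G169", "psi:G169-S168"
        Hc, _, _ = ramachandran_density(fms[0].column(f_phi),
                                        fms[0].column(f_psi), bins=36)
        Ho, _, _ = ramachandran_density(fms[1].column(f_phi),
                                        fms[1].column(f_psi), bins=36)
        # overlap of the two densities is negligible
        assert np.minimum(Hc, Ho).sum() < 0.01

    def test_contour_levels_cover_stated_mass(self, rng):
        phi = rng.normal(-60, 15, 10_000)
        psi = rng.normal(-45, 15, 10_000)
        H, _, levels = ramachandran_density(phi, psi, bins=36)
        for m, lev in levels.items():
            assert H[H >= lev].sum() >= m - 1e-9
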