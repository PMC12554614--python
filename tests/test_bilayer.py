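"""Bilayer trajectory analyses: centring, density, tilt, order, APL, MSD."""

import numpy as np
import pytest
from scipy import stats

from bilayerlens import bilayer, synthetic
from bilayerlens.bilayer import (
    assign_leaflets_and_center,
    delta_order,
    joint_tilt_depth,
    membrane_thickness,
    msd_diffusion,
    order_parameter_profile,
    partial_density_profile,
    periodic_voronoi_areas,
    profile_peak,
    ring_center_profile,
    ring_tilt_angles,
    voronoi_apl,
)
from bilayerlens.synthetic import (
    SyntheticBilayerSpec,
    SyntheticBrownianSpec,
    make_bilayer_trajectory,
    make_brownian,
)

SMALL_SCH = {"sn1": {2: 0.2, 9: 0.05}, "sn2": {2: 0.2, 9: 0.05}}


@pytest.fixture(scope="module")
def centered_bilayer():
    spec = SyntheticBilayerSpec(n_frames=30, seed=10, sch_targets=SMALL_SCH)
    return assign_leaflets_and_center(make_bilayer_trajectory(spec))


class TestLeafletsAndCentering:
    def test_offset_removed(self, centered_bilayer):
        traj = centered_bilayer.translated_z(np.full(centered_bilayer.n_frames, 5.0))
        recentered = assign_leaflets_and_center(traj)
        pz = recentered.coords[:, recentered.select("DOPC", "P"), 2]
        assert abs(pz.mean()) < 0.05
        assert abs(pz[pz > 0].mean() - 19.15) < 0.1

    def test_leaflet_labels_match_generator(self, centered_bilayer):
        truth = centered_bilayer.truth["leaflet_by_molecule"]
        mol_of = np.asarray(centered_bilayer.molecule_ids)
        first = np.unique(mol_of, return_index=True)[1]
        for m, idx in zip(np.unique(mol_of), first):
            assert centered_bilayer.leaflet[idx] == truth[m]

    def test_single_leaflet_rejected(self):
        spec = SyntheticBilayerSpec(n_frames=2, seed=0, sch_targets=SMALL_SCH)
        traj = make_bilayer_trajectory(spec)
        # collapse everything into one leaflet
        traj.coords[:, :, 2] = np.abs(traj.coords[:, :, 2])
        with pytest.raises(ValueError, match="unimodal|bilayer"):
            assign_leaflets_and_center(traj)


class TestDensityAndThickness:
    def test_count_conservation(self, centered_bilayer):
        prof = partial_density_profile(centered_bilayer, resname="DOPC", name="P")
        n_p = int(centered_bilayer.select("DOPC", "P").sum())
        assert prof.counts.sum() == pytest.approx(n_p * centered_bilayer.n_frames)

    def test_profile_symmetric_about_midplane(self, centered_bilayer):
        prof = partial_density_profile(centered_bilayer, resname="DOPC", name="P")
        weighted_mean = np.sum(prof.z_centers_A * prof.counts) / prof.counts.sum()
        assert abs(weighted_mean) < 0.2

    def test_empty_selection_rejected(self, centered_bilayer):
        with pytest.raises(ValueError):
            partial_density_profile(centered_bilayer, resname="XXX")

    @pytest.mark.parametrize("thickness", [38.3, 41.6, 36.5])
    def test_thickness_round_trip(self, thickness):
        spec = SyntheticBilayerSpec(
            thickness_A=thickness, n_frames=200, seed=1, sch_targets=SMALL_SCH,
            n_steroid_per_leaflet=30,
        )
        traj = assign_leaflets_and_center(make_bilayer_trajectory(spec))
        prof = partial_density_profile(traj, resname="DOPC", name="P")
        assert membrane_thickness(prof) == pytest.approx(thickness, abs=0.1)

    def test_thickness_invariant_to_translation(self, centered_bilayer):
        prof0 = partial_density_profile(centered_bilayer, resname="DOPC", name="P")
        # a shift by a bin-width multiple relocates the histogram without
        # re-binning, so the peak-to-peak distance is exactly unchanged
        shifted = centered_bilayer.translated_z(
            np.full(centered_bilayer.n_frames, 3.5)
        )
        prof1 = partial_density_profile(shifted, resname="DOPC", name="P")
        t0, t1 = membrane_thickness(prof0), membrane_thickness(prof1)
        assert t1 == pytest.approx(t0, abs=1e-9)

    def test_ring_peak_round_trip(self, centered_bilayer):
        prof = ring_center_profile(centered_bilayer, "CHL")
        zmax = float(np.max(np.abs(prof.z_centers_A)))
        peak = profile_peak(prof, (0.0, zmax))
        assert peak == pytest.approx(8.0, abs=0.25)

    def test_single_bin_profile_peak(self):
        from bilayerlens.bilayer import _histogram_profile

        z = np.full(100, 8.0)
        prof = _histogram_profile(z, None, 0.5, "t", 1, 100.0)
        occupied = prof.z_centers_A[prof.counts > 0]
        assert occupied.size == 1
        assert abs(occupied[0] - 8.0) <= 0.25  # within the 0.5 A bin

    def test_flat_profile_rejected(self):
        from bilayerlens.bilayer import DensityProfile

        prof = DensityProfile(
            z_centers_A=np.arange(-5.0, 5.0, 0.5),
            density=np.ones(20), counts=np.ones(20),
            selection="t", bin_width_A=0.5, n_frames=1, box_area_A2=1.0,
        )
        with pytest.raises(ValueError):
            profile_peak(prof, (-5.0, 5.0))


class TestTilt:
    def test_reference_directions(self):
        # geometry oracle on raw vectors: angle of (0,0,1), (1,0,0), (1,0,1)
        for v, expected in [((0, 0, 1), 0.0), ((1, 0, 0), 90.0), ((1, 0, 1), 45.0)]:
            v = np.asarray(v, dtype=float)
            theta = np.degrees(np.arccos(v[2] / np.linalg.norm(v)))
            assert theta == pytest.approx(expected)

    def test_upright_bilayer_measures_zero(self, centered_bilayer):
        tilts = ring_tilt_angles(centered_bilayer, "CHL")
        assert np.allclose(tilts.theta_deg, 0.0, atol=1e-6)

    def test_fixed_angle_recovered_in_both_leaflets(self):
        spec = SyntheticBilayerSpec(
            n_frames=3, seed=4, tilt_mode="fixed_angle", tilt_angle_deg=30.0,
            sch_targets=SMALL_SCH,
        )
        traj = assign_leaflets_and_center(make_bilayer_trajectory(spec))
        tilts = ring_tilt_angles(traj, "CHL")
        assert np.allclose(tilts.theta_deg, 30.0, atol=1e-6)

    def test_isotropic_axes_follow_sin_theta(self):
        # chi-square test of the sin(theta) law for uniformly random axes
        rng = np.random.default_rng(5)
        n = 100_000
        v = rng.normal(size=(n, 3))
        cos_t = v[:, 2] / np.linalg.norm(v, axis=1)
        theta = np.degrees(np.arccos(cos_t))
        counts, edges = np.histogram(theta, bins=np.linspace(0, 180, 19))
        expected = n * np.diff(-np.cos(np.radians(edges))) / 2.0
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 < stats.chi2.ppf(0.999, df=len(counts) - 1)

    def test_fold_convention(self):
        from bilayerlens.bilayer import TiltDistribution

        t = TiltDistribution(np.array([10.0, 170.0]), np.zeros(2), "CHL")
        folded = t.fold()
        assert np.allclose(folded.theta_deg, [10.0, 10.0])


class TestJointTiltDepth:
    def test_marginal_consistency(self):
        spec = SyntheticBilayerSpec(
            n_frames=10, seed=6, tilt_mode="broad", sch_targets=SMALL_SCH
        )
        traj = assign_leaflets_and_center(make_bilayer_trajectory(spec))
        tilts = ring_tilt_angles(traj, "CHL")
        joint, te, ze = joint_tilt_depth(tilts)
        assert joint.sum() == pytest.approx(1.0)
        theta_marginal = joint.sum(axis=1)
        counts, _ = np.histogram(tilts.theta_deg, bins=te)
        assert np.allclose(theta_marginal, counts / counts.sum())

    def test_degenerate_samples_single_cell(self):
        from bilayerlens.bilayer import TiltDistribution

        t = TiltDistribution(np.full(50, 12.0), np.full(50, 8.0), "CHL")
        joint, _, _ = joint_tilt_depth(t, theta_bins=5, z_bins=5)
        assert joint.max() == pytest.approx(1.0)
        assert np.count_nonzero(joint) == 1

    def test_independent_components_factorize(self):
        rng = np.random.default_rng(7)
        from bilayerlens.bilayer import TiltDistribution

        t = TiltDistribution(
            rng.uniform(0, 90, 20000), rng.normal(8, 0.5, 20000), "CHL"
        )
        joint, te, ze = joint_tilt_depth(t, theta_bins=6, z_bins=6)
        product = np.outer(joint.sum(axis=1), joint.sum(axis=0))
        # chi-square for independence on expected counts
        n = t.theta_deg.size
        mask = product > 0
        chi2 = n * np.sum((joint[mask] - product[mask]) ** 2 / product[mask])
        dof = (6 - 1) * (6 - 1)
        assert chi2 < stats.chi2.ppf(0.999, df=dof)


class TestOrderParameters:
    def test_limits_parallel_perpendicular_isotropic(self):
        # direct limits of the S_CH formula on constructed C-H vectors
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        s = lambda v: 0.5 * (3 * (v[2] / np.linalg.norm(v)) ** 2 - 1)
        assert s(z) == pytest.approx(1.0)
        assert s(x) == pytest.approx(-0.5)
        rng = np.random.default_rng(8)
        v = rng.normal(size=(100_000, 3))
        cos2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
        assert abs(np.mean(1.5 * cos2 - 0.5)) < 0.01

    def test_recovery_of_generator_targets(self):
        spec = SyntheticBilayerSpec(n_frames=25, seed=9)
        traj = assign_leaflets_and_center(make_bilayer_trajectory(spec))
        profiles = order_parameter_profile(traj)
        for chain, prof in profiles.items():
            targets = spec.sch_targets[chain]
            for c, s, e in zip(prof.carbons, prof.s_ch, prof.stderr):
                assert abs(s - targets[c]) < 3 * e + 0.005, (chain, c)

    def test_missing_hydrogen_reported(self):
        spec = SyntheticBilayerSpec(n_frames=2, seed=0, sch_targets=SMALL_SCH)
        traj = make_bilayer_trajectory(spec)
        defs = {"sn1": {2: ("C32", ["H2X", "H2Q"])}}  # H2Q does not exist
        with pytest.raises(ValueError, match="hydrogen"):
            order_parameter_profile(traj, defs)

    def test_delta_order_zero_against_itself(self):
        spec = SyntheticBilayerSpec(n_frames=5, seed=2, sch_targets=SMALL_SCH)
        traj = assign_leaflets_and_center(make_bilayer_trajectory(spec))
        prof = order_parameter_profile(
            traj, {"sn1": {2: ("C32", ["H2X", "H2Y"])}}
        )["sn1"]
        diff = delta_order(prof, prof)
        assert np.allclose(diff.s_ch, 0.0)

    def test_delta_order_sign_pattern(self):
        # surface ordering + core disordering against a reference, mimicking
        # the progesterone redistribution of chain order
        base = synthetic.default_sch_targets()
        shifted = {
            ch: {
                c: min(s + 0.05, 1.0) if c <= 6 else (s - 0.05 if c >= 10 else s)
                for c, s in targets.items()
            }
            for ch, targets in base.items()
        }
        ref_traj = assign_leaflets_and_center(
            make_bilayer_trajectory(SyntheticBilayerSpec(n_frames=20, seed=11))
        )
        mod_traj = assign_leaflets_and_center(
            make_bilayer_trajectory(
                SyntheticBilayerSpec(n_frames=20, seed=12, sch_targets=shifted)
            )
        )
        ref = order_parameter_profile(ref_traj)["sn1"]
        mod = order_parameter_profile(mod_traj)["sn1"]
        diff = delta_order(mod, ref)
        for c, d in zip(diff.carbons, diff.s_ch):
            if c <= 6:
                assert d > 0.0, c
            elif c >= 10:
                assert d < 0.0, c

    def test_quadrature_error_propagation(self):
        from bilayerlens.bilayer import OrderProfile

        a = OrderProfile("sn1", np.array([2]), np.array([0.2]),
                         np.array([0.01]), np.array([100]))
        b = OrderProfile("sn1", np.array([2]), np.array([0.1]),
                         np.array([0.01]), np.array([100]))
        diff = delta_order(a, b)
        assert diff.stderr[0] == pytest.approx(0.01414, abs=1e-4)


class TestVoronoiAPL:
    def test_square_lattice_exact(self):
        pts = np.array([[(i % 6 + 0.5) * 8.0, (i // 6 + 0.5) * 8.0] for i in range(36)])
        areas = periodic_voronoi_areas(pts, (48.0, 48.0))
        assert np.allclose(areas, 64.0, atol=1e-9)

    def test_random_points_conserve_box_area(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 50, size=(40, 2))
        areas = periodic_voronoi_areas(pts, (50.0, 60.0))
        assert areas.sum() == pytest.approx(50.0 * 60.0, rel=1e-9)

    def test_rasterized_oracle_agreement(self):
        # brute force: assign a fine pixel grid to nearest reference point
        # under periodic minimum-image distance
        rng = np.random.default_rng(14)
        box = 30.0
        pts = rng.uniform(0, box, size=(12, 2))
        areas = periodic_voronoi_areas(pts, (box, box))
        step = 0.1
        g = np.arange(step / 2, box, step)
        gx, gy = np.meshgrid(g, g)
        pix = np.stack([gx.ravel(), gy.ravel()], axis=1)
        d = pix[:, None, :] - pts[None, :, :]
        d -= np.round(d / box) * box
        owner = np.argmin(np.sum(d**2, axis=2), axis=1)
        brute = np.bincount(owner, minlength=len(pts)) * step**2
        assert np.allclose(areas, brute, rtol=5e-3)

    def test_apl_recovers_generator_target(self, centered_bilayer):
        res = voronoi_apl(centered_bilayer)
        assert res.per_class["all"]["mean"] == pytest.approx(64.0, rel=0.02)
        assert np.allclose(res.per_leaflet_sums, res.box_area_A2[:, None], rtol=1e-6)

    def test_coincident_points_perturbed_and_flagged(self):
        spec = SyntheticBilayerSpec(n_frames=2, seed=15, sch_targets=SMALL_SCH)
        traj = assign_leaflets_and_center(make_bilayer_trajectory(spec))
        p_idx = np.flatnonzero(traj.select("DOPC", "P"))
        traj.coords[:, p_idx[1], :2] = traj.coords[:, p_idx[0], :2]
        res = voronoi_apl(traj)
        assert res.perturbed


class TestMSD:
    def test_static_particles_give_zero(self):
        traj = make_brownian(SyntheticBrownianSpec(diffusion_um2_s=0.0, n_frames=40))
        series = msd_diffusion(traj, fit_window_ns=(10.0, 30.0))
        assert series.diffusion_um2_s == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(series.msd_A2, 0.0)

    def test_exactly_linear_msd_gives_quarter_slope(self):
        from bilayerlens.bilayer import A2_NS_TO_UM2_S, fit_diffusion_from_msd

        s = 2.0
        lag = np.arange(50, dtype=float)
        fit = fit_diffusion_from_msd(lag, s * lag, (10.0, 40.0))
        assert fit["D_um2_s"] == pytest.approx(s / 4.0 * A2_NS_TO_UM2_S, rel=1e-12)
        assert fit["intercept_A2"] == pytest.approx(0.0, abs=1e-9)

    def test_brownian_round_trip_single_seed(self):
        traj = make_brownian(SyntheticBrownianSpec(seed=0))
        series = msd_diffusion(traj, fit_window_ns=(30.0, 70.0))
        assert series.diffusion_um2_s == pytest.approx(2.6, rel=0.10)

    def test_msd_zero_at_zero_lag(self):
        traj = make_brownian(SyntheticBrownianSpec(seed=1, n_frames=20))
        series = msd_diffusion(traj, fit_window_ns=(5.0, 15.0))
        assert series.msd_A2[0] == 0.0
        assert np.all(np.diff(series.lag_ns) > 0)

    def test_fit_window_outside_range_rejected(self):
        traj = make_brownian(SyntheticBrownianSpec(seed=1, n_frames=20))
        with pytest.raises(ValueError):
            msd_diffusion(traj, fit_window_ns=(50.0, 80.0))

    def test_wrapped_reconstruction_matches_unwrapped(self):
        traj = make_brownian(SyntheticBrownianSpec(seed=3, n_frames=60, box_xy_A=30.0))
        direct = msd_diffusion(traj, fit_window_ns=(10.0, 30.0))
        traj.unwrapped = None
        rebuilt = msd_diffusion(traj, fit_window_ns=(10.0, 30.0))
        assert rebuilt.diffusion_um2_s == pytest.approx(direct.diffusion_um2_s, rel=1e-9)


class TestInvariances:
    def test_estimators_invariant_to_rigid_z_shift(self, centered_bilayer):
        shifted = centered_bilayer.translated_z(
            np.full(centered_bilayer.n_frames, -2.5)
        )
        tilts0 = ring_tilt_angles(centered_bilayer, "CHL")
        tilts1 = ring_tilt_angles(shifted, "CHL")
        assert np.allclose(tilts0.theta_deg, tilts1.theta_deg)
        apl0 = voronoi_apl(centered_bilayer).per_class["all"]["mean"]
        apl1 = voronoi_apl(shifted).per_class["all"]["mean"]
        assert apl1 == pytest.approx(apl0, rel=1e-9)
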