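"""Superposition, RMSD, fluctuation/B-factor and flexible-region analytics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from parabind import flexibility, synthetic
from parabind.flexibility import (
    B_FACTOR_CONSTANT,
    FluctuationProfile,
    Trajectory,
    displacement,
    flexible_regions,
    fluctuation_profile,
    rmsd_series,
    superpose,
)


def _random_rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
    trans = rng.normal(scale=5.0, size=3)
    return rot, trans


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(12, 3))
        sp = superpose(pts, pts)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_removed(self, rng):
        pts = rng.normal(size=(15, 3))
        rot, trans = _random_rigid(rng)
        sp = superpose(pts, pts @ rot.T + trans)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_proper_rotation_enforced(self, rng):
        # mirrored coordinates cannot be superposed by a proper rotation
        pts = rng.normal(size=(20, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        sp = superpose(pts, mirrored)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0)
        assert sp.rmsd > 0.1

    def test_matches_scipy_align_vectors(self, rng):
        """Cross-check the optimum against an independent library solver."""
        for _ in range(5):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            sp = superpose(a, b)
            rot_sp, ssd = Rotation.align_vectors(
                a - a.mean(axis=0), b - b.mean(axis=0)
            )
            rmsd_scipy = np.sqrt(
                np.mean(
                    np.sum(
                        (rot_sp.apply(b - b.mean(axis=0)) - (a - a.mean(axis=0))) ** 2,
                        axis=1,
                    )
                )
            )
            assert sp.rmsd == pytest.approx(rmsd_scipy, abs=1e-9)

    def test_weights_shift_optimum(self, rng):
        a = rng.normal(size=(8, 3))
        b = a.copy()
        b[0] += [4.0, 0, 0]  # one displaced atom
        w_hi = np.ones(8)
        w_hi[0] = 100.0
        sp_w = superpose(a, b, w_hi)
        sp_u = superpose(a, b)
        fit_w = b @ sp_w.rotation.T + sp_w.translation
        fit_u = b @ sp_u.rotation.T + sp_u.translation
        # upweighting the displaced atom pulls the fit toward aligning it
        assert np.linalg.norm(fit_w[0] - a[0]) < np.linalg.norm(fit_u[0] - a[0])

    def test_degenerate_inputs_rejected(self, rng):
        line = np.outer(np.arange(6, dtype=float), [1.0, 2.0, 0.5])
        with pytest.raises(ValueError):
            superpose(line, rng.normal(size=(6, 3)))
        with pytest.raises(ValueError):
            superpose(np.zeros((5, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestRmsdSeries:
    def test_static_trajectory_zero(self):
        traj = synthetic.simulate_trajectory(
            synthetic.default_trajectory_scenario(
                core_sigma=0.0, loop_sigma=0.0, n_frames=4, n_residues=12,
                loop_interval=(3, 6),
            )
        )
        assert np.allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_single_frame(self):
        traj = Trajectory(
            coords=np.random.default_rng(0).normal(size=(1, 8, 3)),
            residue_ids=np.arange(1, 9),
            masses=np.full(8, 12.0),
        )
        assert rmsd_series(traj)[0] == pytest.approx(0.0, abs=1e-12)

    def test_drift_gives_increasing_trend(self):
        scen = synthetic.wing_marker_trajectory_scenario(
            seed=1, core_sigma=0.05, loop_sigma=0.05, n_frames=60
        )
        series = rmsd_series(synthetic.simulate_trajectory(scen))
        # marker drifts linearly: late-window RMSD well above early-window
        assert series[-10:].mean() > 3.0 * series[1:11].mean()

    def test_rigid_motion_invariance(self, rng):
        scen = synthetic.default_trajectory_scenario(seed=3, n_frames=20, n_residues=15,
                                                     loop_interval=(5, 9))
        traj = synthetic.simulate_trajectory(scen)
        moved = traj.coords.copy()
        for i in range(moved.shape[0]):
            rot, trans = _random_rigid(rng)
            moved[i] = moved[i] @ rot.T + trans
        traj2 = Trajectory(moved, traj.residue_ids, traj.masses)
        assert np.allclose(rmsd_series(traj), rmsd_series(traj2), atol=1e-8)


class TestFluctuations:
    def test_isotropic_gaussian_identity(self):
        """<dr^2> = 3 sigma^2 for isotropic per-axis noise, B = 8 pi^2."""
        scen = synthetic.default_trajectory_scenario(
            seed=6, n_frames=2000, core_sigma=1.0, loop_sigma=1.0
        )
        prof = fluctuation_profile(synthetic.simulate_trajectory(scen))
        assert prof.msf.mean() == pytest.approx(3.0, rel=0.05)
        assert prof.bfactor.mean() == pytest.approx(8 * np.pi**2, rel=0.05)

    def test_b_factor_identity_machine_precision(self):
        scen = synthetic.default_trajectory_scenario(seed=2, n_frames=50, n_residues=20,
                                                     loop_interval=(5, 10))
        prof = fluctuation_profile(synthetic.simulate_trajectory(scen))
        assert np.allclose(prof.bfactor, B_FACTOR_CONSTANT * prof.msf, rtol=1e-15)

    def test_per_region_sigma_recovery(self):
        scen = synthetic.default_trajectory_scenario(seed=9, n_frames=2000)
        prof = fluctuation_profile(synthetic.simulate_trajectory(scen))
        lo, hi = scen.loop_interval
        in_loop = (prof.residue_ids >= lo) & (prof.residue_ids <= hi)
        assert prof.msf[in_loop].mean() == pytest.approx(3 * scen.loop_sigma**2, rel=0.05)
        assert prof.msf[~in_loop].mean() == pytest.approx(3 * scen.core_sigma**2, rel=0.05)

    def test_loop_exceeds_core(self):
        scen = synthetic.default_trajectory_scenario(seed=4, n_frames=300)
        prof = fluctuation_profile(synthetic.simulate_trajectory(scen))
        lo, hi = scen.loop_interval
        in_loop = (prof.residue_ids >= lo) & (prof.residue_ids <= hi)
        assert prof.bfactor[in_loop].min() > prof.bfactor[~in_loop].max()

    def test_single_frame_rejected(self):
        traj = Trajectory(
            coords=np.zeros((1, 5, 3)) + np.arange(15).reshape(1, 5, 3),
            residue_ids=np.arange(1, 6),
            masses=np.full(5, 12.0),
        )
        with pytest.raises(ValueError):
            fluctuation_profile(traj)

    def test_equal_masses_match_arithmetic_mean(self):
        """With two atoms per residue and equal masses, the residue MSF is
        the plain average; with unequal masses it shifts toward the heavy
        atom."""
        rng = np.random.default_rng(5)
        n_res, n_frames = 6, 400
        ids = np.repeat(np.arange(1, n_res + 1), 2)
        sigma = np.where(np.arange(2 * n_res) % 2 == 0, 0.5, 1.5)
        ref = np.tile(synthetic._reference_chain(n_res), (1, 2)).reshape(n_res * 2, 3)
        coords = ref[None] + rng.normal(size=(n_frames, 2 * n_res, 3)) * sigma[None, :, None]
        equal = fluctuation_profile(Trajectory(coords, ids, np.full(2 * n_res, 10.0)))
        heavy = np.where(np.arange(2 * n_res) % 2 == 0, 100.0, 1.0)
        weighted = fluctuation_profile(Trajectory(coords, ids, heavy))
        assert np.all(weighted.msf < equal.msf)  # pulled toward the quiet atom

    def test_rigid_motion_invariance(self, rng):
        scen = synthetic.default_trajectory_scenario(seed=7, n_frames=30, n_residues=15,
                                                     loop_interval=(4, 8))
        traj = synthetic.simulate_trajectory(scen)
        moved = traj.coords.copy()
        for i in range(moved.shape[0]):
            rot, trans = _random_rigid(rng)
            moved[i] = moved[i] @ rot.T + trans
        p1 = fluctuation_profile(traj)
        p2 = fluctuation_profile(Trajectory(moved, traj.residue_ids, traj.masses))
        assert np.allclose(p1.msf, p2.msf, atol=1e-8)


class TestFlexibleRegions:
    def test_flat_profile_empty(self):
        prof = FluctuationProfile(np.arange(1, 31), np.ones(30), np.full(30, 26.3))
        assert flexible_regions(prof) == []

    def test_loop_localized_with_peak(self):
        scen = synthetic.default_trajectory_scenario(seed=3, n_frames=400)
        prof = fluctuation_profile(synthetic.simulate_trajectory(scen))
        regions = flexible_regions(prof)
        assert len(regions) == 1
        lo, hi = scen.loop_interval
        assert lo - 2 <= regions[0].start_residue <= regions[0].end_residue <= hi + 2
        assert lo <= regions[0].peak_residue <= hi

    def test_two_separated_loops(self):
        b = np.full(100, 20.0)
        b[19:30] = 300.0
        b[59:70] = 280.0
        prof = FluctuationProfile(np.arange(1, 101), b / B_FACTOR_CONSTANT, b)
        regions = flexible_regions(prof)
        assert [(r.start_residue, r.end_residue) for r in regions] == [
            (20, 30),
            (60, 70),
        ]

    def test_gap_tolerance_merges(self):
        b = np.full(60, 10.0)
        b[20:25] = 200.0
        b[26:31] = 200.0  # single-residue dip
        prof = FluctuationProfile(np.arange(1, 61), b / B_FACTOR_CONSTANT, b)
        regions = flexible_regions(prof)
        assert len(regions) == 1
        assert (regions[0].start_residue, regions[0].end_residue) == (21, 31)


class TestDisplacement:
    def test_identical_frames_zero(self):
        traj = synthetic.simulate_trajectory(
            synthetic.default_trajectory_scenario(
                core_sigma=0.0, loop_sigma=0.0, n_frames=3, n_residues=20,
                loop_interval=(5, 8),
            )
        )
        assert displacement(traj, 10) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_thirty_angstrom_excursion(self):
        scen = synthetic.wing_marker_trajectory_scenario(seed=0, n_frames=200)
        traj = synthetic.simulate_trajectory(scen)
        lo, hi = scen.loop_interval
        core = [r for r in range(1, scen.n_residues + 1) if not lo <= r <= hi]
        d = displacement(traj, scen.marker_residue, core)
        # single-frame loop noise (sigma 2 A/axis) puts ~3 A scatter on the norm
        assert d == pytest.approx(30.0, abs=9.0)

    def test_core_marker_stays_put(self):
        scen = synthetic.wing_marker_trajectory_scenario(seed=1, n_frames=100)
        traj = synthetic.simulate_trajectory(scen)
        lo, hi = scen.loop_interval
        core = [r for r in range(1, scen.n_residues + 1) if not lo <= r <= hi]
        assert displacement(traj, core[0], core[1:]) < 3.0

    def test_unknown_marker(self):
        traj = synthetic.simulate_trajectory(
            synthetic.default_trajectory_scenario(n_frames=3, n_residues=10,
                                                  loop_interval=(3, 5))
        )
        with pytest.raises(ValueError):
            displacement(traj, 99)


class TestTrajectoryIO:
    def test_pdb_roundtrip(self, tmp_path):
        traj = synthetic.simulate_trajectory(
            synthetic.default_trajectory_scenario(seed=1, n_frames=3, n_residues=10,
                                                  loop_interval=(4, 6))
        )
        path = tmp_path / "traj.pdb"
        flexibility.write_trajectory_pdb(traj, path)
        text = path.read_text()
        assert "MODEL" in text and "ENDMDL" in text and " CA " in text
        back = flexibility.read_trajectory_pdb(path)
        assert back.coords.shape == traj.coords.shape
        assert np.allclose(back.coords, traj.coords, atol=1e-2)  # PDB precision
        assert np.array_equal(back.residue_ids, traj.residue_ids)

    def test_profile_csv(self, tmp_path):
        prof = FluctuationProfile(np.arange(1, 4), np.ones(3), np.full(3, 26.3))
        path = tmp_path / "prof.csv"
        flexibility.write_profile_csv(prof, path)
        assert path.read_text().splitlines()[0] == "residue,msf_A2,bfactor_A2"
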