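"""RMSD superposition, first-passage detection, dihedrals, helicity, winding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from torquefold.analysis import (FoldingResult, RmsdSeries, folding_time,
                                 helicity, kabsch_superpose, phi_psi_series,
                                 rmsd_series, rotation_propagation,
                                 summarize_runs)
from torquefold.chain import (Conformation, Sequence, add_handles,
                              build_extended_conformation, build_ideal_helix,
                              build_topology, _build_chain)
from torquefold.dynamics import Trajectory
from _oracles import quaternion_grid_rmsd


@pytest.fixture(scope="module")
def helix_system():
    top = build_topology(add_handles(Sequence("A" * 15), 2))
    conf, sel = build_ideal_helix(top, core_only=True)
    return top, conf, sel



class TestKabsch:
    def test_identity(self, helix_system):
        _, conf, sel = helix_system
        r, t, rmsd = kabsch_superpose(conf.positions[sel], conf.positions[sel])
        assert rmsd < 1e-7
        assert np.allclose(r, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self, helix_system):
        _, conf, sel = helix_system
        mobile = conf.positions[sel]
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        target = mobile @ rot.T + np.array([0.4, -1.0, 2.0])
        r, t, rmsd = kabsch_superpose(mobile, target)
        assert rmsd < 1e-9
        assert np.allclose(r, rot, atol=1e-6)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.standard_normal((6, 3))
            b = rng.standard_normal((6, 3))
            r, _, _ = kabsch_superpose(a, b)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_orientation_search(self):
        rng = np.random.default_rng(2)
        mobile = rng.standard_normal((4, 3))
        target = rng.standard_normal((4, 3))
        _, _, rmsd = kabsch_superpose(mobile, target)
        assert abs(rmsd - quaternion_grid_rmsd(mobile, target)) < 1e-6

    def test_degenerate_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_metric_properties(self):
        rng = np.random.default_rng(3)
        a, b, c = (rng.standard_normal((5, 3)) for _ in range(3))
        rab = kabsch_superpose(a, b)[2]
        rba = kabsch_superpose(b, a)[2]
        assert rab == pytest.approx(rba, abs=1e-9)
        rac = kabsch_superpose(a, c)[2]
        rbc = kabsch_superpose(b, c)[2]
        assert rac <= rab + rbc + 1e-9


class TestRmsdSeries:
    def test_native_copies_are_zero(self, helix_system):
        top, conf, sel = helix_system
        traj = Trajectory(np.array([0.0, 1.0, 2.0]),
                          np.repeat(conf.positions[None], 3, axis=0))
        s = rmsd_series(traj, conf.positions[sel], sel)
        assert np.all(s.values < 1e-7)

    def test_single_displaced_atom_closed_form(self, helix_system):
        top, conf, sel = helix_system
        moved = conf.positions.copy()
        # displace one selected atom along a direction and pin the frame by
        # comparing against the *unsuperposed* closed form with superposition
        # disabled through symmetry: displacement of 0.1 nm on one of n atoms
        # gives rmsd <= 0.1/sqrt(n); superposition can only reduce it
        moved[sel[5]] += np.array([0.0, 0.0, 0.1])
        traj = Trajectory(np.array([0.0]), moved[None])
        s = rmsd_series(traj, conf.positions[sel], sel)
        n = len(sel)
        assert s.values[0] <= 0.1 / np.sqrt(n) + 1e-12
        assert s.values[0] > 0.5 * 0.1 / np.sqrt(n)

    def test_rigid_motion_invariance(self, helix_system):
        top, conf, sel = helix_system
        rng = np.random.default_rng(4)
        frames = []
        base = conf.positions + 0.05 * rng.standard_normal(conf.positions.shape)
        for _ in range(4):
            rot = Rotation.random(random_state=rng).as_matrix()
            frames.append(base @ rot.T + rng.standard_normal(3))
        traj0 = Trajectory(np.arange(4.0) + 1, np.repeat(base[None], 4, axis=0))
        traj1 = Trajectory(np.arange(4.0) + 1, np.array(frames))
        s0 = rmsd_series(traj0, conf.positions[sel], sel)
        s1 = rmsd_series(traj1, conf.positions[sel], sel)
        assert np.abs(s0.values - s1.values).max() < 1e-9


class TestFoldingTime:
    def test_first_passage(self):
        s = RmsdSeries(np.array([0.0, 10, 20, 30]), np.array([0.5, 0.3, 0.19, 0.25]))
        assert folding_time(s, 0.2) == 20.0

    def test_never_reached(self):
        s = RmsdSeries(np.array([0.0, 10]), np.array([0.5, 0.3]))
        assert folding_time(s, 0.2) is None

    def test_first_frame_already_folded(self):
        s = RmsdSeries(np.array([5.0, 10]), np.array([0.1, 0.3]))
        assert folding_time(s, 0.2) == 5.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            folding_time(RmsdSeries(np.array([]), np.array([])), 0.2)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        times = np.arange(50.0)
        vals = np.abs(rng.standard_normal(50)) * 0.4
        s = RmsdSeries(times, vals)
        for lo, hi in [(0.1, 0.2), (0.05, 0.3), (0.2, 0.35)]:
            tl, th = folding_time(s, lo), folding_time(s, hi)
            if tl is not None:
                assert th is not None and th <= tl


class TestDihedralSeries:
    def test_ideal_helix_angles(self, helix_system):
        top, conf, _ = helix_system
        traj = Trajectory(np.array([0.0]), conf.positions[None])
        phi, psi = phi_psi_series(traj, top)
        assert np.nanmax(np.abs(phi[0, 1:] + 57.0)) < 0.1
        assert np.nanmax(np.abs(psi[0, :-1] + 47.0)) < 0.1
        assert np.isnan(phi[0, 0]) and np.isnan(psi[0, -1])

    def test_extended_is_trans(self, helix_system):
        top, _, _ = helix_system
        ext = build_extended_conformation(top)
        traj = Trajectory(np.array([0.0]), ext.positions[None])
        phi, psi = phi_psi_series(traj, top)
        assert np.nanmax(np.abs(np.abs(phi[0, 1:]) - 180.0)) < 1e-6
        assert np.nanmax(np.abs(np.abs(psi[0, :-1]) - 180.0)) < 1e-6

    def test_rigid_rotation_changes_nothing(self, helix_system):
        top, conf, _ = helix_system
        rot = Rotation.from_euler("xyz", [30, -60, 15], degrees=True).as_matrix()
        moved = conf.positions @ rot.T + 2.0
        t0 = Trajectory(np.array([0.0]), conf.positions[None])
        t1 = Trajectory(np.array([0.0]), moved[None])
        p0, s0 = phi_psi_series(t0, top)
        p1, s1 = phi_psi_series(t1, top)
        assert np.nanmax(np.abs(p0 - p1)) < 1e-9
        assert np.nanmax(np.abs(s0 - s1)) < 1e-9


class TestHelicity:
    def test_helix_is_one(self, helix_system):
        top, conf, _ = helix_system
        assert helicity(conf, top) == 1.0

    def test_extended_is_zero(self, helix_system):
        top, _, _ = helix_system
        assert helicity(build_extended_conformation(top), top) == 0.0

    def test_half_helical_chain(self):
        top = build_topology(add_handles(Sequence("A" * 18), 2))
        n = top.n_residues
        phi = np.full(n, 180.0)
        psi = np.full(n, 180.0)
        core = np.arange(2, n - 2)
        half = core[: len(core) // 2]
        phi[half] = -57.0
        psi[half] = -47.0
        conf = Conformation(_build_chain(top, phi, psi))
        assert helicity(conf, top) == pytest.approx(0.5, abs=0.06)

    def test_requires_positive_radius(self, helix_system):
        top, conf, _ = helix_system
        with pytest.raises(ValueError):
            helicity(conf, top, basin_radius_deg=0.0)


class TestRotationPropagation:
    def test_static_trajectory_zero(self, helix_system):
        top, conf, _ = helix_system
        traj = Trajectory(np.arange(5.0) + 1,
                          np.repeat(conf.positions[None], 5, axis=0))
        w = rotation_propagation(traj, top)
        assert np.abs(w).max() == 0.0

    def test_rigid_corotation_winds_every_residue(self, helix_system):
        top, conf, _ = helix_system
        ca0 = conf.positions[top.res_atom[0, 1]]
        frames = []
        steps = 16
        for k in range(steps + 1):
            ang = np.deg2rad(720.0 * k / steps)
            ct, st = np.cos(ang), np.sin(ang)
            rel = conf.positions - ca0
            out = rel.copy()
            out[:, 1] = ct * rel[:, 1] - st * rel[:, 2]
            out[:, 2] = st * rel[:, 1] + ct * rel[:, 2]
            frames.append(out + ca0)
        traj = Trajectory(np.arange(steps + 1.0) + 1, np.array(frames))
        w = rotation_propagation(traj, top)
        assert np.abs(w[-1, 1:] - 720.0).max() < 1e-6

    def test_coarse_sampling_rejected(self, helix_system):
        top, conf, _ = helix_system
        ca0 = conf.positions[top.res_atom[0, 1]]
        frames = [conf.positions]
        ang = np.deg2rad(180.0)
        ct, st = np.cos(ang), np.sin(ang)
        rel = conf.positions - ca0
        out = rel.copy()
        out[:, 1] = ct * rel[:, 1] - st * rel[:, 2]
        out[:, 2] = st * rel[:, 1] + ct * rel[:, 2]
        frames.append(out + ca0)
        traj = Trajectory(np.array([1.0, 2.0]), np.array(frames))
        with pytest.raises(ValueError):
            rotation_propagation(traj, top)


class TestSummary:
    def test_non_folding_convention(self):
        r = FoldingResult("P1", "free", 0, None, 500.0, 0.8)
        assert r.cell == "500/500"

    def test_folding_cell(self):
        r = FoldingResult("P1", "cw", 0, 22.0, 100.0, 0.1)
        assert r.cell == "22/100"

    def test_table_shape_and_stats(self):
        results = [
            FoldingResult("P1", "cw", 0, 22.0, 100.0, 0.1),
            FoldingResult("P1", "cw", 1, 30.0, 100.0, 0.15),
            FoldingResult("P1", "free", 0, None, 500.0, 0.6),
        ]
        df = summarize_runs(results)
        assert df.loc["P1", "cw"] == "22/100 30/100"
        assert df.loc["P1", "free"] == "500/500"
        assert df.loc["P1", "cw_median_fold_ps"] == 26.0
        assert df.loc["P1", "cw_fold_fraction"] == 1.0
        assert df.loc["P1", "free_fold_fraction"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_runs([])

    def test_folding_time_beyond_duration_rejected(self):
        with pytest.raises(ValueError):
            FoldingResult("P1", "cw", 0, 600.0, 500.0, 0.1)
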