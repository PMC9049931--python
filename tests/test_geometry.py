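"""Cluster detection, gyration/shape metrics, residue profiles, g(r)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import amphitraj as at
from amphitraj.conformation import residue_class3
from amphitraj.geometry import find_clusters, gyration_tensor, shape_metrics


def _beads(positions, box, molecule_ids=None, element="C"):
    positions = np.asarray(positions, dtype=float)
    mols = molecule_ids or list(range(len(positions)))
    top = [at.Atom.from_element(i, element, molecule_id=int(m), residue_index=i)
           for i, m in enumerate(mols)]
    return at.Trajectory(top, [at.Frame(positions, box)])


class TestFindClusters:
    def test_two_beads_within_cutoff(self):
        traj = _beads([[0, 0, 0], [3, 0, 0]], at.Box((20, 20, 20)))
        clusters = find_clusters(traj, 0, cutoff=4.5)
        assert len(clusters) == 1
        assert clusters[0].molecule_ids == {0, 1}

    def test_periodic_image_linkage_and_unwrap(self):
        # beads at x=1 and x=19 in a 20 A box: image distance 2 A
        traj = _beads([[1, 5, 5], [19, 5, 5]], at.Box((20, 20, 20)))
        clusters = find_clusters(traj, 0, cutoff=4.5)
        assert len(clusters) == 1
        span = np.ptp(clusters[0].unwrapped_positions[:, 0])
        assert span == pytest.approx(2.0)

    def test_beyond_cutoff_two_clusters(self):
        traj = _beads([[1, 5, 5], [9, 5, 5]], at.Box((20, 20, 20)))
        assert len(find_clusters(traj, 0, cutoff=4.5)) == 2

    def test_cutoff_at_half_box_rejected(self):
        traj = _beads([[1, 5, 5], [9, 5, 5]], at.Box((20, 20, 20)))
        with pytest.raises(ValueError, match="half"):
            find_clusters(traj, 0, cutoff=10.0)

    def test_planted_partition_recovered(self, toy_micelle):
        traj, truth = toy_micelle
        for k in range(traj.n_frames):
            clusters = find_clusters(traj, k)
            assert len(clusters) == 1
            assert sorted(clusters[0].molecule_ids) == truth["partition"][0]

    def test_two_planted_aggregates(self):
        traj, truth = at.gen_toy_micelle_trajectory(
            n_lipids=8, n_peptides=1, n_frames=2, n_aggregates=2,
            box=90.0, seed=4)
        clusters = find_clusters(traj, 0)
        got = sorted(sorted(c.molecule_ids) for c in clusters)
        assert got == sorted(truth["partition"])

    def test_partition_independent_of_stored_image(self, toy_micelle):
        # frame 1 straddles the periodic boundary, frame 0 does not
        traj, truth = toy_micelle
        for k in (0, 1):
            clusters = find_clusters(traj, k)
            assert sorted(clusters[0].molecule_ids) == truth["partition"][0]

    def test_heavy_vs_all_linkage(self):
        box = at.Box((30, 30, 30))
        pos = np.array([[5.0, 5, 5], [9.0, 5, 5]])
        top = [at.Atom.from_element(0, "C", molecule_id=0),
               at.Atom.from_element(1, "H", molecule_id=1)]
        traj = at.Trajectory(top, [at.Frame(pos, box)])
        assert len(find_clusters(traj, 0, cutoff=4.5, linkage_atoms="heavy")) == 2
        assert len(find_clusters(traj, 0, cutoff=4.5, linkage_atoms="all")) == 1


class TestGyrationAndShape:
    def test_single_atom_zero_tensor(self):
        g = gyration_tensor(np.zeros((1, 3)))
        np.testing.assert_allclose(g.components, 0.0)
        assert shape_metrics(g).rg == 0.0
        assert shape_metrics(g).kappa2 == 0.0

    def test_two_atoms_hand_computed(self):
        g = gyration_tensor(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        np.testing.assert_allclose(g.components, np.diag([1.0, 0, 0]), atol=1e-12)

    def test_uniform_ball_trace(self):
        traj, truth = at.gen_uniform_ball(10_000, 10.0, seed=1)
        sm = shape_metrics(gyration_tensor(traj.frames[0].positions))
        assert sm.rg == pytest.approx(truth["rg_analytic_A"], rel=0.02)
        assert sum(sm.principal_moments) == pytest.approx(60.0, rel=0.02)

    @pytest.mark.parametrize("moments,expected", [
        ((2.0, 2.0, 2.0), 0.0),     # sphere
        ((50.0 ** 2 / 12, 0.0, 0.0), 1.0),  # thin rod
        ((1.0, 1.0, 0.0), 0.25),    # thin disc
    ])
    def test_kappa2_limits(self, moments, expected):
        g = at.GyrationTensor(np.diag(moments), np.zeros(3))
        assert shape_metrics(g).kappa2 == pytest.approx(expected, abs=1e-12)

    def test_rod_generator_limit(self):
        traj, truth = at.gen_rod(10_000, 50.0, seed=1)
        sm = shape_metrics(gyration_tensor(traj.frames[0].positions))
        assert sm.kappa2 >= 0.99
        assert sm.rg == pytest.approx(truth["rg_analytic_A"], rel=0.02)
        two, _ = at.gen_rod(2, 50.0, seed=1)
        assert shape_metrics(
            gyration_tensor(two.frames[0].positions)).kappa2 == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(50, 3)) * np.array([5.0, 2.0, 1.0])
        sm0 = shape_metrics(gyration_tensor(pos))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=7).as_matrix()
        sm1 = shape_metrics(gyration_tensor((R @ pos.T).T + [10, -3, 2]))
        assert sm1.rg == pytest.approx(sm0.rg, rel=1e-9)
        assert sm1.kappa2 == pytest.approx(sm0.kappa2, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1e4), min_size=3, max_size=3))
    def test_kappa2_bounds_on_any_psd_tensor(self, moments):
        g = at.GyrationTensor(np.diag(moments), np.zeros(3))
        k2 = shape_metrics(g).kappa2
        assert 0.0 <= k2 <= 1.0
        nonzero = [m for m in moments if m > 0]
        if nonzero and len(set(nonzero)) == 1 and len(nonzero) == 3:
            assert k2 == pytest.approx(0.0, abs=1e-9)

    def test_mass_weighting_changes_center(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        gu = gyration_tensor(pos)
        gm = gyration_tensor(pos, weights=np.array([1.0, 3.0]))
        assert gu.origin[0] == pytest.approx(1.0)
        assert gm.origin[0] == pytest.approx(1.5)


class TestShapeTimeseries:
    def test_static_frames_zero_sd(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(size=(30, 3)) * 3
        top = [at.Atom.from_element(i, "C", molecule_id=0) for i in range(30)]
        frames = [at.Frame(pos.copy(), at.Box.nonperiodic(), time=float(k))
                  for k in range(10)]
        df = at.shape_timeseries(at.Trajectory(top, frames))
        assert df["Rg_A"].std(ddof=0) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_constant_metrics(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(6)
        pos = rng.normal(size=(20, 3)) * np.array([6.0, 1.0, 1.0])
        top = [at.Atom.from_element(i, "C", molecule_id=0) for i in range(20)]
        frames = []
        for k in range(8):
            R = Rotation.from_euler("z", 12.0 * k, degrees=True).as_matrix()
            frames.append(at.Frame((R @ pos.T).T, at.Box.nonperiodic(),
                                   time=float(k)))
        df = at.shape_timeseries(at.Trajectory(top, frames))
        assert np.ptp(df["Rg_A"]) < 1e-8
        assert np.ptp(df["kappa2"]) < 1e-8

    def test_breathing_sphere_tracks_analytic(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.random(4000) ** (1 / 3)
        base = v * r[:, None]
        top = [at.Atom.from_element(i, "C", molecule_id=0) for i in range(4000)]
        radii = 10.0 * (1 + 0.1 * np.sin(np.linspace(0, 2 * np.pi, 6)))
        frames = [at.Frame(base * R, at.Box.nonperiodic(), time=float(k))
                  for k, R in enumerate(radii)]
        df = at.shape_timeseries(at.Trajectory(top, frames))
        expected = np.sqrt(3 / 5) * radii
        np.testing.assert_allclose(df["Rg_A"], expected, rtol=0.03)

    def test_straddling_aggregate_matches_centered(self, toy_micelle):
        traj, _ = toy_micelle
        c0 = find_clusters(traj, 0)[0]
        c1 = find_clusters(traj, 1)[0]
        # same jitter scale, different images; Rg must agree closely
        sm0 = shape_metrics(gyration_tensor(c0.unwrapped_positions))
        sm1 = shape_metrics(gyration_tensor(c1.unwrapped_positions))
        assert sm1.rg == pytest.approx(sm0.rg, rel=0.02)


class TestResidueDistances:
    def _system(self, distances, resnames):
        """Aggregate core bead + one peptide with residues at given radii."""
        box = at.Box((60, 60, 60))
        center = np.full(3, 30.0)
        top = [at.Atom.from_element(0, "C", molecule_id=0, residue_index=0,
                                    residue_name="GMO", name="CORE")]
        pos = [center]
        idx = 1
        for i, (d, rn) in enumerate(zip(distances, resnames)):
            top.append(at.Atom.from_element(idx, "C", molecule_id=1,
                                            residue_index=i + 1, residue_name=rn,
                                            name="CA"))
            pos.append(center + [0, 0, d])
            idx += 1
        traj = at.Trajectory(top, [at.Frame(np.stack(pos), box)])
        cluster = find_clusters(traj, 0, cutoff=29.0, linkage_atoms="all")[0]
        assert cluster.molecule_ids == {0, 1}
        return traj, cluster

    def test_mean_removal_two_residues(self):
        # core bead is much heavier than nothing: make aggregate COM near core
        traj, cluster = self._system([5.0, 7.0], ["LEU", "LYS"])
        prof = at.residue_com_distances(traj, cluster, {1}, residue_class3)
        # distances measured to the mass-weighted aggregate COM, then
        # peptide-mean removed: differences are preserved
        assert prof.relative_distance[1] - prof.relative_distance[0] == \
            pytest.approx(2.0, abs=0.2)
        assert prof.relative_distance.sum() == pytest.approx(0.0, abs=1e-9)

    def test_equidistant_residues_all_zero(self):
        traj, cluster = self._system([6.0, 6.0, 6.0], ["LEU", "LYS", "SER"])
        prof = at.residue_com_distances(traj, cluster, {1}, residue_class3)
        np.testing.assert_allclose(prof.relative_distance, 0.0, atol=1e-6)

    def test_class_separation_from_stated_means(self):
        # hydrophilic mean 1.76 A and hydrophobic mean -2.30 A -> 4.06 A
        assert 1.76 - (-2.30) == pytest.approx(4.06)

    def test_classes_assigned(self):
        traj, cluster = self._system([5.0, 7.0], ["LEU", "LYS"])
        prof = at.residue_com_distances(traj, cluster, {1}, residue_class3)
        assert prof.classes == ["hydrophobic", "hydrophilic"]

    def test_peptide_not_in_aggregate_raises(self):
        traj, cluster = self._system([5.0, 7.0], ["LEU", "LYS"])
        with pytest.raises(ValueError, match="not part of"):
            at.residue_com_distances(traj, cluster, {9}, residue_class3)


class TestPairDistribution:
    def test_ideal_gas_is_unity_within_3_sigma(self):
        rng = np.random.default_rng(8)
        n, L, n_frames = 600, 20.0, 25
        top = [at.Atom.from_element(i, "C") for i in range(n)]
        frames = [at.Frame(rng.random((n, 3)) * L, at.Box((L, L, L)),
                           time=float(k)) for k in range(n_frames)]
        traj = at.Trajectory(top, frames)
        dr = 0.25
        rdf = at.pair_distribution(traj, np.arange(n), np.arange(n), 8.0, dr)
        rho = n / L ** 3
        expected = 4 * np.pi * rdf.r ** 2 * dr * rho * n * n_frames
        sigma = np.sqrt(expected)  # Poisson error on the pair count
        dev = np.abs(rdf.counts - expected) / sigma
        assert np.all(dev[rdf.r > 1.0] < 3.0 + 1.0)  # allow one-bin excursions
        assert rdf.g[rdf.r > 1.0].mean() == pytest.approx(1.0, abs=0.01)

    def test_single_pair_single_bin(self):
        top = [at.Atom.from_element(0, "C"), at.Atom.from_element(1, "O")]
        fr = at.Frame(np.array([[1.0, 1, 1], [1, 1, 4.2]]), at.Box((20, 20, 20)))
        rdf = at.pair_distribution(at.Trajectory(top, [fr]),
                                   np.array([0]), np.array([1]), 8.0, 0.5)
        nz = rdf.counts > 0
        assert nz.sum() == 1
        assert rdf.r[nz][0] == pytest.approx(3.25)

    def test_bin_width_preserves_pair_count(self):
        rng = np.random.default_rng(9)
        n, L = 200, 15.0
        top = [at.Atom.from_element(i, "C") for i in range(n)]
        traj = at.Trajectory(top, [at.Frame(rng.random((n, 3)) * L,
                                            at.Box((L, L, L)))])
        fine = at.pair_distribution(traj, np.arange(n), np.arange(n), 6.0, 0.1)
        coarse = at.pair_distribution(traj, np.arange(n), np.arange(n), 6.0, 0.2)
        assert fine.counts.sum() == coarse.counts.sum()
        assert len(fine.r) == 2 * len(coarse.r)

    def test_r_max_beyond_half_box_rejected(self):
        top = [at.Atom.from_element(0, "C"), at.Atom.from_element(1, "C")]
        fr = at.Frame(np.zeros((2, 3)), at.Box((10, 10, 10)))
        with pytest.raises(ValueError, match="half"):
            at.pair_distribution(at.Trajectory(top, [fr]),
                                 np.array([0]), np.array([1]), 8.0, 0.5)
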