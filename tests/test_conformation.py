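"""Torsions, hydrogen bonds, secondary structure, RMSD, composition."""

import numpy as np
import pytest

import amphitraj as at
from amphitraj.conformation import (
    assign_frame_secondary_structure, backbone_torsions, dihedral,
    hbond_energy, superpose,
)


class TestDihedral:
    def test_planar_trans_is_180(self):
        p = [np.array([0.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([1.0, 0, 0]), np.array([1.0, -1, 0])]
        assert dihedral(*p) == pytest.approx(180.0)

    def test_cis_is_zero(self):
        p = [np.array([0.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([1.0, 0, 0]), np.array([1.0, 1, 0])]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-120.0, 130.0),
                                         (60.0, 45.0)])
    def test_builder_measurer_inverse_pair(self, phi, psi):
        traj, _ = at.gen_ideal_helix("A" * 12, phi=phi, psi=psi)
        geo = backbone_torsions(traj, 0)
        np.testing.assert_allclose(geo.phi[1:-1], phi, atol=0.5)
        np.testing.assert_allclose(geo.psi[1:-1], psi, atol=0.5)

    def test_termini_flagged_undefined(self, ideal_helix_20):
        traj, _ = ideal_helix_20
        geo = backbone_torsions(traj, 0)
        assert np.isnan(geo.phi[0])
        assert np.isnan(geo.psi[-1])

    def test_missing_backbone_atom_names_residue(self, ideal_helix_20):
        traj, _ = ideal_helix_20
        top = [a for a in traj.topology if not (a.residue_index == 5
                                                and a.name == "CA")]
        pos = np.stack([traj.frames[0].positions[a.index] for a in top])
        top = [at.Atom(index=i, name=a.name, element=a.element, mass=a.mass,
                       electron_count=a.electron_count,
                       residue_index=a.residue_index,
                       residue_name=a.residue_name)
               for i, a in enumerate(top)]
        broken = at.Trajectory(top, [at.Frame(pos, at.Box.nonperiodic())])
        with pytest.raises(ValueError, match="residue 5"):
            backbone_torsions(broken, 0)


class TestHbondEnergy:
    def test_helix_i_i4_bond_formed(self, ideal_helix_20):
        traj, _ = ideal_helix_20
        geo = backbone_torsions(traj, 0)
        e = hbond_energy(geo, donor=4, acceptor=0)
        assert e < -0.5  # canonical N-H...O=C around 2 A

    def test_long_range_energy_vanishes(self, extended_chain_20):
        traj, _ = extended_chain_20
        geo = backbone_torsions(traj, 0)
        e = hbond_energy(geo, donor=19, acceptor=0)  # far apart on a line
        assert abs(e) < 0.5

    def test_adjacent_residues_excluded(self, ideal_helix_20):
        traj, _ = ideal_helix_20
        geo = backbone_torsions(traj, 0)
        assert hbond_energy(geo, donor=5, acceptor=4) == 0.0
        assert hbond_energy(geo, donor=5, acceptor=5) == 0.0


class TestSecondaryStructure:
    def test_ideal_helix_interior_labeled_h(self, ideal_helix_20):
        traj, truth = ideal_helix_20
        series = at.assign_secondary_structure(traj)
        labels = series.labels[0]
        lo, hi = truth["expected_h_span"]
        assert np.all(labels[lo:hi + 1] == "H")
        assert np.all(labels[:lo] != "H")
        assert np.all(labels[hi + 1:] != "H")

    def test_extended_chain_no_helix(self, extended_chain_20):
        traj, _ = extended_chain_20
        series = at.assign_secondary_structure(traj)
        assert not np.any(series.labels == "H")

    def test_rigid_motion_invariance(self, ideal_helix_20):
        from scipy.spatial.transform import Rotation
        traj, _ = ideal_helix_20
        R = Rotation.random(random_state=9).as_matrix()
        moved = at.Trajectory(
            traj.topology,
            [at.Frame((R @ traj.frames[0].positions.T).T + [5, 6, 7],
                      at.Box.nonperiodic())])
        a = at.assign_secondary_structure(traj).labels
        b = at.assign_secondary_structure(moved).labels
        np.testing.assert_array_equal(a, b)

    def test_helicity_arithmetic(self):
        labels = np.array([["H"] * 10, ["C"] * 10])
        series = at.SecondaryStructureSeries(labels=labels,
                                             times=np.array([0.0, 1.0]),
                                             residue_names=["ALA"] * 10)
        mean, sd, per_frame = at.helicity(series)
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.5)
        np.testing.assert_allclose(per_frame, [1.0, 0.0])

    def test_all_h_and_half_h(self):
        all_h = at.SecondaryStructureSeries(
            labels=np.full((3, 8), "H"), times=np.arange(3.0),
            residue_names=["ALA"] * 8)
        mean, sd, _ = at.helicity(all_h)
        assert (mean, sd) == (1.0, 0.0)
        half = np.full((3, 8), "C")
        half[:, :4] = "H"
        mean, _, _ = at.helicity(at.SecondaryStructureSeries(
            labels=half, times=np.arange(3.0), residue_names=["ALA"] * 8))
        assert mean == pytest.approx(0.5)

    def test_stride_subsampling(self, ideal_helix_20):
        traj, _ = ideal_helix_20
        frames = [at.Frame(traj.frames[0].positions.copy(),
                           at.Box.nonperiodic(), time=2.0 * k)
                  for k in range(6)]
        multi = at.Trajectory(traj.topology, frames)
        series = at.assign_secondary_structure(multi, stride_ps=4.0)
        assert series.n_frames == 3
        with pytest.raises(ValueError, match="multiple"):
            at.assign_secondary_structure(multi, stride_ps=3.0)


class TestSuperposeAndRmsd:
    def test_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 3))
        R, t, r = superpose(x, x)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_translation_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 3))
        R, t, r = superpose(x, x + [3.0, -1.0, 2.0])
        assert r == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(t, [3.0, -1.0, 2.0], atol=1e-10)

    def test_matches_brute_force_rotation_grid(self):
        """Optimal RMSD agrees with a dense rotation-grid search."""
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(4, 3)) * 3
        R_true = Rotation.from_euler("zyx", [25, -40, 65],
                                     degrees=True).as_matrix()
        mobile = (R_true @ ref.T).T + rng.normal(scale=0.05, size=(4, 3))
        _, _, r_kabsch = superpose(mobile, ref)
        best = np.inf
        grid = Rotation.random(4000, random_state=11)
        for R in grid.as_matrix():
            rot = (R @ (mobile - mobile.mean(0)).T).T + ref.mean(0)
            best = min(best, np.sqrt(np.mean(np.sum((rot - ref) ** 2, axis=1))))
        assert r_kabsch <= best + 1e-3

    def test_never_worse_than_unsuperposed(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(10, 3)) * 4
        mob = ref + rng.normal(scale=0.5, size=(10, 3))
        _, _, r = superpose(mob, ref)
        raw = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
        assert r <= raw + 1e-12

    def test_collinear_set_rejected(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(x, x * 2.0)

    def test_rmsd_series_zero_for_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(5)
        base = rng.normal(size=(12, 3)) * 5
        top = [at.Atom.from_element(i, "C", name="CA") for i in range(12)]
        frames = []
        for k in range(5):
            R = Rotation.from_euler("y", 30.0 * k, degrees=True).as_matrix()
            frames.append(at.Frame((R @ base.T).T + k, at.Box.nonperiodic(),
                                   time=float(k)))
        df = at.rmsd_series(at.Trajectory(top, frames), np.arange(12))
        np.testing.assert_allclose(df["rmsd_A"], 0.0, atol=1e-10)

    def test_single_displaced_atom(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(16, 3)) * 5
        moved = base.copy()
        moved[3] += [0.8, 0, 0]
        # compare the Kabsch result against an independent dense search
        from scipy.spatial.transform import Rotation
        _, _, r = superpose(moved, base)
        best = np.inf
        for R in Rotation.random(3000, random_state=12).as_matrix():
            rot = (R @ (moved - moved.mean(0)).T).T
            shift = base.mean(0) + (rot.mean(0) - rot.mean(0))
            rot = rot - rot.mean(0) + base.mean(0)
            best = min(best, np.sqrt(np.mean(np.sum((rot - base) ** 2, axis=1))))
        assert r <= best + 1e-3
        assert r == pytest.approx(0.8 / np.sqrt(16), rel=0.1)

    def test_exclude_terminal_span(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(10, 3)) * 5
        wagging = base.copy()
        wagging[-2:] += [3.0, 0, 0]  # mobile C-terminal tail
        top = [at.Atom.from_element(i, "C", name="CA") for i in range(10)]
        frames = [at.Frame(base, at.Box.nonperiodic(), 0.0),
                  at.Frame(wagging, at.Box.nonperiodic(), 1.0)]
        traj = at.Trajectory(top, frames)
        full = at.rmsd_series(traj, np.arange(10))
        trimmed = at.rmsd_series(traj, np.arange(10), exclude_last=2)
        assert trimmed["rmsd_A"].iloc[1] < full["rmsd_A"].iloc[1]
        assert trimmed["rmsd_A"].iloc[1] == pytest.approx(0.0, abs=1e-10)


class TestClassifyResidues:
    def test_ll37_composition(self):
        res = at.classify_residues(at.LL37_SEQUENCE)
        assert len(res.sequence) == 37
        assert res.percent == {"charged": 43, "hydrophobic": 43, "polar": 14}
        assert round(100 * res.basic_fraction_of_charged) == 69
        assert res.net_charge == 6

    def test_all_basic(self):
        res = at.classify_residues("KKKK")
        assert res.percent["charged"] == 100
        assert res.net_charge == 4

    def test_all_glycine_hydrophobic_neutral(self):
        res = at.classify_residues("GGGG")
        assert res.percent["hydrophobic"] == 100
        assert res.net_charge == 0

    def test_fractions_sum_to_one(self):
        res = at.classify_residues("ACDEFGHIKLMNPQRSTVWY")
        assert sum(res.fractions.values()) == pytest.approx(1.0)
        assert res.net_charge == \
            res.subcharges.count("basic") - res.subcharges.count("acidic")

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            at.classify_residues("AXA")


class TestChimera:
    def test_half_helical_half_extended(self):
        """A chain built helical then extended shows intermediate helicity."""
        traj, _ = at.gen_ideal_helix("A" * 20, -57.0, -47.0)
        ext, _ = at.gen_ideal_helix("A" * 20, 180.0, 180.0)
        geo_h = backbone_torsions(traj, 0)
        labels_full = assign_frame_secondary_structure(geo_h)
        n_h_full = int(np.sum(labels_full == "H"))
        # helical span 2..17 inclusive on the 20-mer
        assert n_h_full == 16
        labels_ext = assign_frame_secondary_structure(backbone_torsions(ext, 0))
        assert int(np.sum(labels_ext == "H")) == 0
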