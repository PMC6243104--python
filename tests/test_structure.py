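import numpy as np
import pytest

from loopmsm import featurize, structure, trajio
from loopmsm.errors import MappingError, SelectionError
from loopmsm.structure import (HBond, derive_donors_acceptors, find_hbonds,
                               golden_section_sphere, hbond_occupancy, kabsch,
                               nearest_frame_by_rmsd, shrake_rupley)
from loopmsm.synthetic import hbond_triad, rigid_transform

from conftest import make_peptide_ensemble


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.linalg.det(q)


class TestFindHBonds:
    DONORS = [(0, 1)]
    ACC = np.array([2])

    def _run(self, dist, dev, **kw):
        return find_hbonds(hbond_triad(dist, dev), self.DONORS, self.ACC, **kw)

    def test_collinear_within_cutoff_detected(self):
        bonds = self._run(2.9, 0.0)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-9)
        assert bonds[0].deviation == pytest.approx(0.0, abs=1e-6)

    def test_bent_rejected_far_rejected(self):
        assert self._run(2.9, 25.0) == []
        assert self._run(3.3, 0.0) == []

    def test_cutoff_grid_exact(self):
        for dist in (2.5, 3.0, 3.19, 3.21, 3.5):
            for dev in (0.0, 10.0, 19.5, 20.5, 40.0):
                bonds = self._run(dist, dev)
                should = dist <= 3.2 and dev <= 20.0
                assert (len(bonds) == 1) == should, (dist, dev)

    def test_default_cutoffs(self):
        assert structure.HBOND_DIST_CUTOFF == 3.2
        assert structure.HBOND_ANGLE_CUTOFF == 20.0

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(0)
        pos = hbond_triad(3.0, 12.0)
        base = self._run(3.0, 12.0)
        r = random_rotation(rng)
        moved = pos @ r.T + np.array([4.0, -7.0, 2.0])
        bonds = find_hbonds(moved, self.DONORS, self.ACC)
        assert len(bonds) == len(base) == 1
        assert bonds[0].distance == pytest.approx(base[0].distance, abs=1e-9)
        assert bonds[0].deviation == pytest.approx(base[0].deviation, abs=1e-6)

    def test_acceptor_equal_to_donor_skipped(self):
        pos = hbond_triad(2.9, 0.0)
        bonds = find_hbonds(pos, [(0, 1)], np.array([0, 2]))
        assert len(bonds) == 1 and bonds[0].acceptor == 2


class TestDonorsAcceptors:
    def test_triad_fixture_typed(self, toy_dir):
        ens = trajio.load_structure(toy_dir["hbond_good"])
        sel = trajio.select_loop(ens, "1-2")
        donors, acceptors = derive_donors_acceptors(
            ens.universe, sel.atoms_all, ens.coordinates[0][0])
        assert donors == [(0, 1)]
        assert acceptors.tolist() == [2]

    def test_peptide_backbone_typing(self, peptide_ensemble):
        ens, _ = peptide_ensemble
        sel = trajio.select_loop(ens, "1-6")
        donors, acceptors = derive_donors_acceptors(
            ens.universe, sel.atoms_all, ens.coordinates[0][0])
        assert len(donors) == 5        # N-H of residues 2..6
        assert len(acceptors) == 6     # backbone O of every residue

    def test_no_hydrogens_is_error(self, tmp_path):
        ens, _ = make_peptide_ensemble(n_frames=1, tmp_path=tmp_path,
                                       with_hydrogens=False)
        sel = trajio.select_loop(ens, "1-6")
        with pytest.raises(SelectionError, match="hydrogen"):
            derive_donors_acceptors(ens.universe, sel.atoms_all)


class TestOccupancy:
    def _bond(self):
        return HBond(0, 1, 2, 2.9, 3.0)

    def test_always_present_is_one(self):
        frames = [[self._bond()]] * 4
        occ = hbond_occupancy(frames, [0, 0, 0, 0], pair=(0, 2))
        assert occ[0] == 1.0

    def test_crafted_eight_frame_toy(self):
        b = self._bond()
        frames = [[b], [], [b], [], [b], [b], [b], [b]]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]   # state 0: 2/4, state 1: 4/4
        occ = hbond_occupancy(frames, labels, pair=(0, 2))
        assert occ[0] == 0.5
        assert occ[1] == 1.0

    def test_never_formed_is_zero(self):
        frames = [[], [], []]
        occ = hbond_occupancy(frames, [0, 0, 1], pair=(0, 2))
        assert occ[0] == 0.0 and occ[1] == 0.0

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            hbond_occupancy([[]], [0, 1], pair=(0, 2))


class TestSASA:
    def test_isolated_atom_analytic_area(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]), probe=1.4,
                             n_points=960)
        want = 4 * np.pi * 3.1**2    # ~120.76 A^2
        assert area[0] == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(120.76, abs=0.01)

    def test_fully_buried_atom_is_zero(self):
        # central atom caged by 26 tight neighbors
        offsets = [np.array([i, j, k], dtype=float)
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
        coords = np.vstack([[0.0, 0.0, 0.0], 1.2 * np.array(offsets)])
        radii = np.full(len(coords), 1.7)
        areas = shrake_rupley(coords, radii)
        assert areas[0] == 0.0

    def test_two_sphere_analytic_cap(self):
        # equal spheres, center distance d < 2R: buried cap area 2*pi*R*h,
        # h = R - d/2
        r_vdw, probe, d = 1.7, 1.4, 3.0
        big_r = r_vdw + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = shrake_rupley(coords, np.array([r_vdw, r_vdw]), probe=probe,
                              n_points=960)
        h = big_r - d / 2
        want = 4 * np.pi * big_r**2 - 2 * np.pi * big_r * h
        for a in areas:
            assert a == pytest.approx(want, rel=0.01)

    def test_union_bounded_by_sum_of_isolated(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(8, 3)) * 2.0
        radii = np.full(8, 1.5)
        union = shrake_rupley(coords, radii).sum()
        isolated = sum(shrake_rupley(c[None, :], np.array([1.5]))[0]
                       for c in coords)
        assert union <= isolated + 1e-9

    def test_sphere_points_deterministic_unit_norm(self):
        pts = golden_section_sphere(960)
        assert pts.shape == (960, 3)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, golden_section_sphere(960))

    def test_ensemble_wrapper(self, peptide_ensemble):
        ens, _ = peptide_ensemble
        sel = trajio.select_loop(ens, "2-5")
        val = structure.sasa(ens, 0, 0, sel)
        assert val > 0

    def test_backbone_radii_resolve_to_bondi(self, peptide_ensemble):
        ens, _ = peptide_ensemble
        radii = structure.atomic_radii(ens.universe, np.arange(5))
        assert set(np.round(radii, 2)) <= {1.2, 1.52, 1.55, 1.7}

    def test_unknown_element_raises(self, tmp_path):
        from loopmsm.synthetic import write_pdb
        p = tmp_path / "weird.pdb"
        write_pdb(p, [{"name": "XX", "resname": "UNK", "chain": "A",
                       "resid": 1, "xyz": (0, 0, 0), "element": "X"}])
        ens = trajio.load_structure(p)
        with pytest.raises(SelectionError):
            structure.atomic_radii(ens.universe, np.array([0]))


class TestKabsch:
    def test_identical_sets_zero_rmsd(self):
        rng = np.random.default_rng(2)
        p = rng.normal(size=(10, 3))
        _, _, val = kabsch(p, p)
        assert val <= 1e-12

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(15, 3)) * 4
        r = random_rotation(rng)
        q = p @ r.T + np.array([1.0, -2.0, 3.0])
        _, _, val = kabsch(p, q)
        assert val <= 1e-10

    def test_three_point_quaternion_oracle(self):
        p = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.2, 0.3]])
        q = np.array([[0.2, 0.1, 0], [1.4, 0.5, 0.1], [1.0, 1.5, 0.2]])
        _, _, got = kabsch(p, q)

        # Horn's quaternion method: largest eigenvalue of the 4x4 key matrix
        pc = p - p.mean(axis=0)
        qc = q - q.mean(axis=0)
        m = pc.T @ qc
        sxx, sxy, sxz = m[0]
        syx, syy, syz = m[1]
        szx, szy, szz = m[2]
        k = np.array([
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ])
        lam_max = np.linalg.eigvalsh(k)[-1]
        e0 = (pc**2).sum() + (qc**2).sum()
        want = np.sqrt(max(e0 - 2 * lam_max, 0.0) / len(p))
        assert got == pytest.approx(want, abs=1e-10)

    def test_alignment_never_increases_rmsd(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.normal(size=(8, 3)) * 3
            q = rng.normal(size=(8, 3)) * 3
            before = structure.rmsd(p, q)
            _, _, after = kabsch(p, q)
            assert after <= before + 1e-12

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(5)
        p = rng.normal(size=(6, 3))
        q = rng.normal(size=(6, 3))
        r, _, _ = kabsch(p, q)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)


class TestNearestFrame:
    def test_reference_identical_to_frame(self, tmp_path, peptide_ensemble):
        ens, _ = peptide_ensemble
        sel = trajio.select_loop(ens, "1-6")
        ref_path = tmp_path / "ref.pdb"
        trajio.write_frame(ens, 0, 3, ref_path)
        ref = trajio.load_structure(ref_path)
        ref_sel = trajio.select_loop(ref, "1-6")
        t, f, val = nearest_frame_by_rmsd(ens, ref, ref_sel.atoms_backbone,
                                          ref_sel.atoms_ca)
        assert (t, f) == (0, 3)
        assert val <= 2e-3   # PDB writer precision

    def test_rigid_transformed_reference(self, tmp_path, peptide_ensemble):
        ens, _ = peptide_ensemble
        xyz = ens.coordinates[0][2]
        rng = np.random.default_rng(6)
        r = random_rotation(rng)
        moved = xyz @ r.T + np.array([8.0, 1.0, -4.0])
        ref = trajio.TrajectoryEnsemble(
            universe=ens.universe.copy(), coordinates=[moved[None]],
            frame_interval=1.0)
        sel = trajio.select_loop(ens, "1-6")
        t, f, val = nearest_frame_by_rmsd(ens, ref, sel.atoms_backbone,
                                          sel.atoms_ca)
        assert (t, f) == (0, 2)
        assert val <= 1e-9

    def test_unmatched_atoms_raise(self, tmp_path, peptide_ensemble):
        ens, _ = peptide_ensemble
        other, _ = make_peptide_ensemble(n_frames=1, n_res=6, first_resid=50,
                                         tmp_path=tmp_path / "other")
        sel = trajio.select_loop(other, "50-55")
        with pytest.raises(MappingError):
            nearest_frame_by_rmsd(ens, other, sel.atoms_backbone, sel.atoms_ca)


class TestCentroidDihedralTable:
    def test_matches_featurizer_in_degrees(self, peptide_ensemble):
        ens, _ = peptide_ensemble
        sel = trajio.select_loop(ens, "1-6")
        table = structure.centroid_dihedral_table(ens, [(0, 1), (0, 4)], sel)
        series = featurize.backbone_dihedrals(ens, sel)
        sub = table[(table.state == "state 1") & table.value_deg.notna()]
        got = {f"{r.angle}:{r.residue}": r.value_deg for r in sub.itertuples()}
        for j, lab in enumerate(series.angle_labels):
            want = np.degrees(series.angles[0][1, j])
            assert got[lab] == pytest.approx(want, abs=1e-9)

    def test_identical_frames_identical_tables(self, peptide_ensemble):
        ens, _ = peptide_ensemble
        sel = trajio.select_loop(ens, "2-5")
        table = structure.centroid_dihedral_table(ens, [(0, 3), (0, 3)], sel)
        a = table[table.state == "state 1"].reset_index(drop=True)
        b = table[table.state == "state 2"].reset_index(drop=True)
        np.testing.assert_allclose(a.value_deg.to_numpy(),
                                   b.value_deg.to_numpy())

    def test_termini_flagged_nan(self, peptide_ensemble):
        ens, _ = peptide_ensemble
        sel = trajio.select_loop(ens, "1-6")
        table = structure.centroid_dihedral_table(ens, [(0, 0)], sel)
        nan_rows = table[table.value_deg.isna()]
        kinds = set(nan_rows.angle + ":" + nan_rows.residue.str.split().str[-1])
        assert kinds == {"phi:1", "psi:6"}
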