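"""Site detection, truncated models, geometry tables, superposition."""

import io

import numpy as np
import pandas as pd
import pytest

from neetkit.sites import (GeometryTable, bond_geometry, build_model,
                           detect_cluster_sites, load_structure,
                           redox_delta_report, superpose_rmsd)
from neetkit.synthetic import gen_mock_neet_structure


class TestDetection:
    def test_mock_site_detected(self, mock_site, mock_pdb_and_truth):
        _, truth = mock_pdb_and_truth
        assert mock_site.coordination_class == truth["coordination_class"]
        lig = {(r.get_id()[1], d.get_name()) for r, d in mock_site.ligands}
        expected = {(int(k), v) for k, v in truth["donor_atoms"].items()}
        assert lig == expected

    def test_fe_y_is_his_bound(self, mock_site):
        his_n = [d for r, d in mock_site.ligands if r.get_resname() == "HIS"]
        assert len(his_n) == 1
        d = np.linalg.norm(his_n[0].coord - mock_site.fe_y.coord)
        assert d <= 2.6

    def test_no_iron_no_sites(self):
        pdb = ("ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
               "  1.00  0.00           C\nEND\n")
        sites = detect_cluster_sites(load_structure(io.StringIO(pdb)))
        assert sites == []

    def test_detection_invariant_to_rigid_motion(self, mock_pdb_and_truth):
        pdb_text, _ = mock_pdb_and_truth
        # rotate every coordinate by a fixed rotation + translation
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        lines = []
        for line in pdb_text.splitlines():
            if line.startswith(("ATOM", "HETATM")):
                xyz = np.array([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
                xyz = xyz @ R.T + np.array([5.0, -3.0, 2.0])
                line = (line[:30] + f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        + line[54:])
            lines.append(line)
        moved = load_structure(io.StringIO("\n".join(lines)))
        sites = detect_cluster_sites(moved)
        assert len(sites) == 1
        assert sites[0].coordination_class == "3Cys:1His"


class TestTruncatedModels:
    def test_level1_has_no_backbone(self, mock_site, mock_structure):
        m = build_model(mock_site, mock_structure, 1)
        names = {a[0] for a in m.atoms if a[3] != "FES"}
        assert names.isdisjoint({"N", "CA", "C", "O"})
        # 4 core + 3x(CB,SG) + His CB + 5-atom imidazole
        assert len(m.atoms) == 4 + 6 + 6
        assert len(m.caps) == 4   # one methyl-cap H per ligand C-beta

    def test_shell_boundary_inclusion(self):
        for d, included in ((3.9, True), (4.1, False)):
            pdb, _ = gen_mock_neet_structure(extra_residue_distance=d)
            structure = load_structure(io.StringIO(pdb))
            site = detect_cluster_sites(structure)[0]
            m3 = build_model(site, structure, 3)
            resids = {a[4] for a in m3.atoms}
            assert (25 in resids) == included

    def test_level_nesting(self, mock_site, mock_structure):
        m1 = build_model(mock_site, mock_structure, 1)
        m3 = build_model(mock_site, mock_structure, 3)
        assert m1.atom_keys() <= m3.atom_keys()

    def test_level2_spans_and_chain_break(self, mock_site, mock_structure,
                                          mock_pdb_and_truth):
        m2 = build_model(mock_site, mock_structure, 2)
        resids = {a[4] for a in m2.atoms}
        assert set(range(10, 20)) <= resids     # ligands plus spanning residues
        # spanning residues contribute backbone only
        gly_names = {a[0] for a in m2.atoms if a[4] == 13}
        assert gly_names == {"N", "CA", "C", "O"}
        # deleting a spanning residue creates a reported chain break
        pdb_text, _ = mock_pdb_and_truth
        broken = "\n".join(l for l in pdb_text.splitlines()
                           if not (" GLY A  13" in l))
        structure = load_structure(io.StringIO(broken))
        site = detect_cluster_sites(structure)[0]
        with pytest.raises(ValueError, match="13"):
            build_model(site, structure, 2)

    def test_formal_charges(self, mock_site, mock_structure):
        assert build_model(mock_site, mock_structure, 1,
                           state="oxidized").net_charge == -2
        assert build_model(mock_site, mock_structure, 1,
                           state="reduced").net_charge == -3


class TestGeometry:
    def test_planted_distances_recovered(self, mock_site, mock_pdb_and_truth):
        _, truth = mock_pdb_and_truth
        table = bond_geometry(mock_site)
        got = dict(zip(table.df["bond"], table.df["R_nm"]))
        for bond, r in truth["bond_lengths_nm"].items():
            assert got[bond] == pytest.approx(r, abs=2e-4), bond

    def test_rigid_motion_invariance(self, mock_pdb_and_truth):
        pdb_text, truth = mock_pdb_and_truth
        structure = load_structure(io.StringIO(pdb_text))
        t1 = bond_geometry(detect_cluster_sites(structure)[0])
        for atom in structure.get_atoms():
            atom.coord = atom.coord + np.array([10.0, -4.0, 7.0])
        t2 = bond_geometry(detect_cluster_sites(structure)[0])
        assert np.allclose(t1.df["R_nm"], t2.df["R_nm"], atol=1e-9)


class TestRedoxDelta:
    def test_identical_tables(self):
        df = pd.DataFrame({"bond": ["a", "b"], "R_nm": [0.22, 0.23],
                           "K_r": [3e4, 2e4]})
        rep = redox_delta_report(GeometryTable(df.copy(), "oxidized"),
                                 GeometryTable(df.copy(), "reduced"))
        assert (rep["dR_nm"] == 0).all()
        assert (rep["K_ratio"] == 1).all()

    def test_his_bond_weakening_numbers(self):
        ox = GeometryTable(pd.DataFrame(
            {"bond": ["FeY-NHis"], "R_nm": [0.218], "K_r": [16359.4]}))
        red = GeometryTable(pd.DataFrame(
            {"bond": ["FeY-NHis"], "R_nm": [0.230], "K_r": [7740.4]}))
        rep = redox_delta_report(ox, red)
        assert rep["dR_nm"].iloc[0] == pytest.approx(0.012)
        assert rep["K_ratio"].iloc[0] == pytest.approx(0.473, abs=5e-4)
        assert bool(rep["weakened"].iloc[0])

    def test_label_mismatch(self):
        a = GeometryTable(pd.DataFrame({"bond": ["x"], "R_nm": [0.2]}))
        b = GeometryTable(pd.DataFrame({"bond": ["y"], "R_nm": [0.2]}))
        with pytest.raises(ValueError, match="match"):
            redox_delta_report(a, b)


def quaternion_rmsd(A, B):
    """Independent quaternion (Kearsley) superposition oracle."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    m = B - A
    p = B + A
    K = np.zeros((4, 4))
    x_m, y_m, z_m = m[:, 0], m[:, 1], m[:, 2]
    x_p, y_p, z_p = p[:, 0], p[:, 1], p[:, 2]
    K[0, 0] = (x_m**2 + y_m**2 + z_m**2).sum()
    K[1, 1] = (x_m**2 + y_p**2 + z_p**2).sum()
    K[2, 2] = (x_p**2 + y_m**2 + z_p**2).sum()
    K[3, 3] = (x_p**2 + y_p**2 + z_m**2).sum()
    K[0, 1] = K[1, 0] = (y_p * z_m - y_m * z_p).sum()
    K[0, 2] = K[2, 0] = (x_m * z_p - x_p * z_m).sum()
    K[0, 3] = K[3, 0] = (x_p * y_m - x_m * y_p).sum()
    K[1, 2] = K[2, 1] = (x_m * y_m - x_p * y_p).sum()
    K[1, 3] = K[3, 1] = (x_m * z_m - x_p * z_p).sum()
    K[2, 3] = K[3, 2] = (y_m * z_m - y_p * z_p).sum()
    lam = np.linalg.eigvalsh(K)[0]
    return np.sqrt(max(lam, 0.0) / len(A))


class TestSuperposition:
    def test_rigid_copy_rmsd_zero(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        R = q * np.sign(np.linalg.det(q))
        B = A @ R.T + np.array([1.0, 2.0, 3.0])
        rmsd, _, _ = superpose_rmsd(A, B)
        assert rmsd < 1e-10

    def test_identity(self):
        A = np.random.default_rng(1).normal(size=(5, 3))
        rmsd, R, t = superpose_rmsd(A, A)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_single_displacement_bound(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(20, 3))
        B = A.copy()
        B[4] += np.array([0.3, 0, 0])
        rmsd, _, _ = superpose_rmsd(A, B)
        assert rmsd <= 0.3 * np.sqrt(1 / 20) + 1e-12

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            rmsd, _, _ = superpose_rmsd(A, B)
            assert rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-8)

    def test_collinear_rejected(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            superpose_rmsd(A, A)
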