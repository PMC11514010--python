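"""Structure I/O, Kabsch superposition, bond tables and contact geometry."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from agphot.structures import (
    Structure,
    bond_table,
    contact_report,
    read_structure,
    rmsd_report,
    superpose,
    write_structure,
)

rng = np.random.default_rng(12345)


def random_structure(n=12, elements=None, seed_rng=rng):
    coords = seed_rng.uniform(-5, 5, size=(n, 3))
    els = elements or ["C"] * n
    return Structure(elements=list(els), coords=coords, name="rand")


def rigid_copy(s, R, t):
    return Structure(
        elements=list(s.elements),
        coords=s.coords @ R.T + t,
        name=s.name + "-moved",
        selections=dict(s.selections),
    )


class TestIO:
    def test_xyz_round_trip(self, tmp_path):
        s = random_structure(7, elements=["Ag"] * 4 + ["Cl", "N", "O"])
        p = tmp_path / "s.xyz"
        write_structure(s, p)
        back = read_structure(p)
        assert back.elements == s.elements
        assert np.allclose(back.coords, s.coords, atol=1e-4)

    def test_toy_xyz_in_order(self, tmp_path):
        p = tmp_path / "toy.xyz"
        p.write_text("3\nwater\nO 0.0 0.0 0.0\nH 0.96 0.0 0.0\nH -0.24 0.93 0.0\n")
        s = read_structure(p)
        assert s.elements == ["O", "H", "H"]
        assert s.n_atoms == 3

    def test_malformed_xyz_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\nbad\nO 0.0 0.0 0.0\nH 0.96 oops 0.0\n")
        with pytest.raises(ValueError, match=":4"):
            read_structure(p)

    def test_pdb_parse_with_altloc_keeps_first(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.450   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA BALA A   1       1.550   0.000   0.000  0.40  0.00           C\n"
            "ATOM      4  O   ALA A   1       2.100   1.100   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="altloc"):
            s = read_structure(p)
        assert s.n_atoms == 3
        ca = s.coords[s.elements.index("C")]
        assert ca[0] == pytest.approx(1.45)
        assert s.atom_meta[0]["resname"] == "ALA"
        assert s.atom_meta[0]["chain"] == "A"

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="Xx"):
            Structure(elements=["Xx"], coords=np.zeros((1, 3)))


class TestSuperpose:
    def test_self_superposition_is_identity(self):
        s = random_structure(10)
        res = superpose(s, s, list(range(10)))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_transform(self):
        s = random_structure(15)
        R = Rotation.from_euler("zyx", [31.0, -57.0, 110.0], degrees=True).as_matrix()
        t = np.array([1.0, -4.0, 2.5])
        moved = rigid_copy(s, R, t)
        res = superpose(moved, s, list(range(15)))
        assert res.rmsd < 1e-8
        assert np.allclose(res.rotation, R.T, atol=1e-8)  # inverse of the applied rotation
        assert np.allclose(res.transform(moved.coords), s.coords, atol=1e-8)

    def test_agrees_with_scipy_align_vectors(self):
        """Independent oracle: scipy's Kabsch implementation."""
        a = random_structure(20)
        b = random_structure(20)
        res = superpose(a, b, list(range(20)))
        A = a.coords - a.coords.mean(axis=0)
        B = b.coords - b.coords.mean(axis=0)
        rot, rssd = Rotation.align_vectors(B, A)
        assert np.allclose(res.rotation, rot.as_matrix(), atol=1e-8)
        assert res.rmsd == pytest.approx(rssd / np.sqrt(20), rel=1e-8)

    def test_small_selection_rejected(self):
        s = random_structure(5)
        with pytest.raises(ValueError, match=">= 3"):
            superpose(s, s, [0, 1])

    def test_size_mismatch_rejected(self):
        a = random_structure(6)
        b = random_structure(6)
        a.add_selection("x", (0, 1, 2, 3))
        b.add_selection("x", (0, 1, 2))
        with pytest.raises(ValueError, match="differ"):
            superpose(a, b, "x")

    def test_rotation_always_proper(self):
        for _ in range(25):
            a = random_structure(4)
            b = random_structure(4)
            res = superpose(a, b, list(range(4)))
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
            assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)

    def test_collinear_set_flagged_and_proper(self):
        coords = np.array([[float(i), 0.0, 0.0] for i in range(4)])
        a = Structure(elements=["C"] * 4, coords=coords)
        b = Structure(elements=["C"] * 4, coords=coords[::-1].copy())
        res = superpose(a, b, list(range(4)))
        assert res.degenerate
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rmsd_invariant_under_common_rigid_motion(self):
        a = random_structure(12)
        b = random_structure(12)
        base = superpose(a, b, list(range(12))).rmsd
        R = Rotation.from_euler("xyz", [12.0, 85.0, -40.0], degrees=True).as_matrix()
        t = np.array([3.0, 3.0, -1.0])
        res = superpose(rigid_copy(a, R, t), rigid_copy(b, R, t), list(range(12)))
        assert res.rmsd == pytest.approx(base, abs=1e-8)

    def test_superposition_never_increases_rmsd(self):
        for _ in range(10):
            a = random_structure(8)
            b = random_structure(8)
            before = float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))
            assert superpose(a, b, list(range(8))).rmsd <= before + 1e-12


class TestRmsdReport:
    def test_perturbed_subsets(self):
        base = random_structure(20, elements=["Ag"] * 8 + ["C"] * 12)
        base.add_selection("cluster", tuple(range(8)))
        base.add_selection("ligand", tuple(range(8, 20)))
        moved_coords = base.coords.copy()
        pert = np.random.default_rng(7)
        moved_coords[:8] += 0.1 * pert.standard_normal((8, 3))
        moved_coords[8:] += 2.0 * pert.standard_normal((12, 3))
        moved = Structure(
            elements=list(base.elements),
            coords=moved_coords,
            selections=dict(base.selections),
        )
        base.add_selection("all", tuple(range(20)))
        moved.add_selection("all", tuple(range(20)))
        t = rmsd_report(moved, base, ["cluster", "ligand", "all"])
        r = dict(zip(t["selection"], t["rmsd"]))
        assert r["cluster"] < r["all"] < r["ligand"] * 1.5
        assert r["cluster"] < 0.3 < r["ligand"]

    def test_identical_structures_all_zero(self):
        s = random_structure(9)
        s.add_selection("a", (0, 1, 2, 3))
        s.add_selection("b", (4, 5, 6, 7, 8))
        t = rmsd_report(s, s, ["a", "b"])
        assert np.allclose(t["rmsd"], 0.0, atol=1e-12)

    def test_empty_selection_list(self):
        s = random_structure(5)
        assert len(rmsd_report(s, s, [])) == 0

    def test_unknown_label(self):
        s = random_structure(5)
        with pytest.raises(KeyError, match="nope"):
            rmsd_report(s, s, ["nope"])


class TestBondTable:
    def test_constructed_pair(self):
        s = Structure(
            elements=["Ag", "Ag", "Cl"],
            coords=np.array([[0.0, 0, 0], [2.9, 0, 0], [10.0, 0, 0]]),
        )
        rows = bond_table(s, ("Ag", "Ag"), 3.2)
        assert rows == [(0, 1, pytest.approx(2.9))]

    def test_cutoff_below_all_distances(self):
        s = Structure(elements=["Ag", "Ag"], coords=np.array([[0.0, 0, 0], [2.9, 0, 0]]))
        assert bond_table(s, ("Ag", "Ag"), 2.0) == []

    def test_closed_boundary(self):
        s = Structure(elements=["Ag", "Cl"], coords=np.array([[0.0, 0, 0], [3.2, 0, 0]]))
        assert len(bond_table(s, ("Ag", "Cl"), 3.2)) == 1

    def test_matches_all_pairs_oracle(self):
        g = np.random.default_rng(3)
        els = list(g.choice(["Ag", "Cl", "C"], size=20))
        s = Structure(elements=els, coords=g.uniform(-4, 4, (20, 3)))
        for pair in [("Ag", "Ag"), ("Ag", "Cl"), ("C", "Ag")]:
            cutoff = 3.5
            d = cdist(s.coords, s.coords)
            want = sorted(
                (d[i, j], i, j)
                for i in range(20)
                for j in range(i + 1, 20)
                if {s.elements[i], s.elements[j]} == set(pair)
                or (pair[0] == pair[1] and s.elements[i] == s.elements[j] == pair[0])
                if d[i, j] <= cutoff
            )
            got = bond_table(s, pair, cutoff)
            assert [(i, j) for _, i, j in want] == [(i, j) for i, j, _ in got]
            assert np.allclose([w[0] for w in want], [g_[2] for g_ in got])

    def test_unknown_element(self):
        s = random_structure(3)
        with pytest.raises(ValueError):
            bond_table(s, ("Zz", "Ag"), 3.0)


class TestContacts:
    def hbond_structure(self):
        # carbonyl O ... amino N at 2.72 Å with amino hydrogens, the motif
        # stabilizing the emitter's ligand shell; one H points at the acceptor
        coords = np.array(
            [
                [0.0, 0.0, 0.0],  # O (acceptor)
                [2.72, 0.0, 0.0],  # N (donor)
                [1.80, 0.3, 0.0],  # H on N, directed toward O
                [3.1, 0.9, 0.0],  # second H on N, pointing away
            ]
        )
        s = Structure(elements=["O", "N", "H", "H"], coords=coords)
        s.add_selection("donors", (1,))
        s.add_selection("acceptors", (0,))
        return s

    def test_contact_at_272(self):
        s = self.hbond_structure()
        rows = contact_report(s, "donors", "acceptors", 3.5)
        assert len(rows) == 1
        assert rows[0]["distance"] == pytest.approx(2.72)

    def test_too_short_dmax_empty(self):
        s = self.hbond_structure()
        assert contact_report(s, "donors", "acceptors", 2.0) == []

    def test_exactly_at_dmax_included(self):
        s = self.hbond_structure()
        assert len(contact_report(s, "donors", "acceptors", 2.72)) == 1

    def test_angle_criterion(self):
        s = self.hbond_structure()
        rows = contact_report(s, "donors", "acceptors", 3.5, angle_min=90.0)
        assert len(rows) == 1
        assert rows[0]["angle"] is not None
        assert contact_report(s, "donors", "acceptors", 3.5, angle_min=179.0) == []

    def test_angle_without_hydrogens_is_an_error(self):
        s = Structure(
            elements=["O", "N"], coords=np.array([[0.0, 0, 0], [2.72, 0, 0]])
        )
        s.add_selection("donors", (1,))
        s.add_selection("acceptors", (0,))
        with pytest.raises(ValueError, match="hydrogen"):
            contact_report(s, "donors", "acceptors", 3.5, angle_min=120.0)
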