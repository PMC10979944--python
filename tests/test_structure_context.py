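import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from flavscreen.structure_context import (
    Atom,
    MembraneSlab,
    Structure,
    detect_bishis_sites,
    estimate_slab,
    find_tm_segments,
    kabsch_superpose,
    ligand_contacts,
    motif_pocket_distance,
    read_structure,
)
from flavscreen.synthetic import gen_helix_bundle


def rmsd_minimizer_oracle(P, Q, rng, n_starts=8):
    """Independent oracle: minimize RMSD numerically over rotation vectors.

    The optimal translation aligns centroids for any rotation, so only the
    3 rotation parameters are searched (multi-start Nelder-Mead).
    """
    P = np.asarray(P, float) - np.asarray(P, float).mean(axis=0)
    Q = np.asarray(Q, float) - np.asarray(Q, float).mean(axis=0)

    def f(r):
        R = Rotation.from_rotvec(r).as_matrix()
        d = P @ R.T - Q
        return float(np.sqrt((d**2).sum() / len(P)))

    best = np.inf
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(f, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def pdb_line(record, serial, name, altloc, resname, chain, resseq, x, y, z, occ, element):
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}\n"
    )


class TestReadStructure:
    def test_toy_pdb_exact_coordinates(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(
            pdb_line("ATOM", 1, " N", " ", "ALA", "A", 1, 1.0, 2.0, 3.0, 1.0, "N")
            + pdb_line("ATOM", 2, " CA", " ", "ALA", "A", 1, 2.5, 2.0, 3.0, 1.0, "C")
            + pdb_line("ATOM", 3, " C", " ", "ALA", "A", 1, 3.0, 3.5, 3.0, 1.0, "C")
            + "END\n"
        )
        st = read_structure(path)
        assert len(st.atoms) == 3
        ca = st.get_atom("A", 1, "CA")
        assert (ca.x, ca.y, ca.z) == (2.5, 2.0, 3.0)
        assert st.chains == ("A",)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            pdb_line("ATOM", 1, " CA", "A", "SER", "A", 1, 0.0, 0.0, 0.0, 0.40, "C")
            + pdb_line("ATOM", 2, " CA", "B", "SER", "A", 1, 9.0, 0.0, 0.0, 0.60, "C")
            + "END\n"
        )
        st = read_structure(path)
        assert len(st.atoms) == 1
        assert st.atoms[0].x == 9.0

    def test_hetatm_heme_retained(self, tmp_path):
        path = tmp_path / "hem.pdb"
        path.write_text(
            pdb_line("ATOM", 1, " CA", " ", "HIS", "A", 1, 0.0, 0.0, 0.0, 1.0, "C")
            + pdb_line("HETATM", 2, "FE", " ", "HEM", "A", 200, 5.0, 0.0, 0.0, 1.0, "FE")
            + "END\n"
        )
        st = read_structure(path)
        assert [a.residue_name for a in st.select(residue_name="HEM")] == ["HEM"]

    def test_duplicate_plain_atom_is_error(self):
        a = Atom("CA", "C", "ALA", 1, "A", 0, 0, 0)
        with pytest.raises(ValueError, match="duplicate"):
            Structure((a, a))

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            Structure((Atom("CA", "C", "ALA", 1, "A", float("nan"), 0, 0),))


class TestKabsch:
    def test_identity_superposition_has_zero_rmsd(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]])
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3))

    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(20, 3))
        R0 = Rotation.random(rng=rng).as_matrix()
        Q = P @ R0.T + np.array([3.0, -1.0, 2.0])
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd <= 1e-8
        assert np.allclose(R, R0, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_triangle_matches_numeric_minimizer(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        Q = np.array([[0.0, 0, 0], [1, 0, 0], [0, 2, 0]])
        _, _, rmsd = kabsch_superpose(P, Q)
        oracle = rmsd_minimizer_oracle(P, Q, np.random.default_rng(0))
        assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_rmsd_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        P, Q = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert kabsch_superpose(P, Q)[2] == pytest.approx(kabsch_superpose(Q, P)[2], abs=1e-10)

    def test_reflection_never_used(self):
        # mirror-image points: best proper rotation cannot reach rmsd 0
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        Q = P.copy()
        Q[:, 2] *= -1
        R, _, rmsd = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_input_validation(self):
        P = np.zeros((3, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(P, np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLigandContacts:
    def heme_structure(self, ne2_z):
        atoms = (
            Atom("FE", "FE", "HEM", 200, "A", 0.0, 0.0, 0.0),
            Atom("NE2", "N", "HIS", 10, "A", 0.0, 0.0, ne2_z),
        )
        return Structure(atoms)

    def test_axial_his_contact_at_bond_distance(self):
        (c,) = ligand_contacts(self.heme_structure(2.2), "HEM", {"NE2"}, 3.0)
        assert c.distance == pytest.approx(2.2)
        assert c.protein_atom == ("A", 10, "NE2")
        assert c.ligand_atom == ("A", 200, "FE")

    def test_atom_beyond_cutoff_not_reported(self):
        assert ligand_contacts(self.heme_structure(3.5), "HEM", {"NE2"}, 3.0) == []

    def test_positive_cutoff_required(self):
        with pytest.raises(ValueError):
            ligand_contacts(self.heme_structure(2.2), "HEM", {"NE2"}, 0.0)

    def test_two_his_per_heme_iron_in_bis_his_geometry(self):
        atoms = (
            Atom("FE", "FE", "HEM", 200, "A", 0.0, 0.0, 0.0),
            Atom("NE2", "N", "HIS", 10, "A", 0.0, 0.0, 2.2),
            Atom("NE2", "N", "HIS", 40, "A", 0.0, 0.0, -2.2),
            Atom("NE2", "N", "HIS", 70, "A", 0.0, 9.0, 0.0),
        )
        contacts = ligand_contacts(Structure(atoms), "HEM", {"NE2"}, 3.0)
        assert len(contacts) == 2  # axial pair only


def ideal_helix(n=40, axis=np.eye(3), origin=np.zeros(3), chain="A", start_res=1):
    """Calpha trace of an ideal helix along axis[:,2]."""
    atoms = []
    for j in range(n):
        local = np.array(
            [2.3 * np.cos(np.radians(100 * j)), 2.3 * np.sin(np.radians(100 * j)), 1.5 * j]
        )
        p = origin + axis @ local
        atoms.append(Atom("CA", "C", "ALA", start_res + j, chain, *p))
    return atoms


class TestSlabAndSegments:
    def test_single_helix_normal_is_z(self):
        st = Structure(tuple(ideal_helix()))
        slab = estimate_slab(st)
        assert np.allclose(np.abs(slab.normal), [0, 0, 1], atol=1e-6)

    def test_normal_equivariant_under_rotation(self):
        rng = np.random.default_rng(3)
        R = Rotation.random(rng=rng).as_matrix()
        st = Structure(tuple(ideal_helix()))
        st_rot = Structure(tuple(ideal_helix(axis=R)))
        n0 = np.array(estimate_slab(st).normal)
        n1 = np.array(estimate_slab(st_rot).normal)
        assert min(np.linalg.norm(R @ n0 - n1), np.linalg.norm(R @ n0 + n1)) < 1e-6

    def test_bundle_center_matches_planted_midpoints(self, bundle):
        st, _ = bundle
        slab = estimate_slab(st)
        # helices are symmetric about the origin by construction
        assert np.linalg.norm(np.array(slab.center)) < 1.0

    def test_six_planted_crossings_found(self, bundle):
        st, _ = bundle
        slab = estimate_slab(st)
        segments = find_tm_segments(st, slab)
        assert len(segments) == 6
        for s in segments:
            assert 15 <= s.end_res - s.start_res + 1 <= 45

    def test_soluble_structure_has_no_segments(self):
        slab = MembraneSlab((0.0, 0.0, 1.0), (0.0, 0.0, 0.0), 15.0)
        st = Structure(tuple(ideal_helix(n=8)))  # z extent ~10 A, no traversal
        assert find_tm_segments(st, slab) == []

    def test_helix_parallel_to_membrane_plane_not_a_segment(self):
        slab = MembraneSlab((0.0, 0.0, 1.0), (0.0, 0.0, 0.0), 15.0)
        axis = np.array([[0.0, 0, 1], [0, 1, 0], [1, 0, 0]])  # helix along x
        st = Structure(tuple(ideal_helix(n=40, axis=axis)))
        assert find_tm_segments(st, slab) == []

    def test_slab_invariants(self):
        with pytest.raises(ValueError):
            MembraneSlab((0.0, 0.0, 2.0), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            MembraneSlab((0.0, 0.0, 1.0), (0.0, 0.0, 0.0), half_thickness=0)


def bishis_enumeration_oracle(structure, slab, max_d=8.0, central_fraction=0.5):
    """Exhaustive His NE2 pair enumeration with the same filters."""
    ne2 = {
        (a.chain_id, a.residue_seq): a.pos
        for a in structure.atoms
        if a.residue_name == "HIS" and a.atom_name == "NE2"
    }
    keys = sorted(ne2)
    out = set()
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            d = np.linalg.norm(ne2[a] - ne2[b])
            depth = slab.depth((ne2[a] + ne2[b]) / 2)
            if d <= max_d and abs(depth) <= central_fraction * slab.half_thickness:
                out.add(frozenset((a, b)))
    return out


class TestBisHisSites:
    def planted_pair(self, depth, d=4.4):
        """Two TM helices with facing NE2 atoms at a given membrane depth."""
        h1 = ideal_helix(n=30, origin=np.array([-6.0, 0, -21.75]), start_res=1)
        h2 = ideal_helix(n=30, origin=np.array([6.0, 0, -21.75]), start_res=101)
        atoms = h1 + h2
        atoms.append(Atom("NE2", "N", "HIS", 15, "A", -d / 2, 0.0, depth))
        atoms.append(Atom("NE2", "N", "HIS", 115, "A", d / 2, 0.0, depth))
        # rename the two CA residues to HIS so the residues are histidines
        atoms = [
            Atom(a.atom_name, a.element, "HIS" if a.residue_seq in (15, 115) else a.residue_name,
                 a.residue_seq, a.chain_id, a.x, a.y, a.z)
            for a in atoms
        ]
        return Structure(tuple(atoms))

    def slab(self):
        return MembraneSlab((0.0, 0.0, 1.0), (0.0, 0.0, 0.0), 15.0)

    def test_central_pair_detected_cross_segment(self):
        st = self.planted_pair(depth=0.0)
        slab = self.slab()
        segments = find_tm_segments(st, slab)
        (site,) = detect_bishis_sites(st, slab, segments)
        assert site.ne2_distance == pytest.approx(4.4)
        assert abs(site.midpoint_depth) < 1e-9
        assert site.cross_segment

    def test_peripheral_pair_rejected_by_centrality(self):
        st = self.planted_pair(depth=14.0)
        assert detect_bishis_sites(st, self.slab(), central_fraction=0.5) == []

    def test_no_histidine_gives_empty_result(self):
        st = Structure(tuple(ideal_helix()))
        assert detect_bishis_sites(st, self.slab()) == []

    def test_matches_exhaustive_enumeration_on_bundles(self):
        for seed in range(5):
            st, truth = gen_helix_bundle(
                6, 30, his_pair_depths=[0.0, 0.0], n_decoy_his=3, seed=seed
            )
            slab = estimate_slab(st)
            sites = detect_bishis_sites(st, slab)
            found = {frozenset((s.his_a, s.his_b)) for s in sites}
            assert found == bishis_enumeration_oracle(st, slab)
            assert found == {frozenset(p) for p in truth.planted_his_pairs}

    def test_invariant_under_global_rigid_motion(self, bundle):
        st, _ = bundle
        rng = np.random.default_rng(9)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 20
        moved = Structure(
            tuple(
                Atom(a.atom_name, a.element, a.residue_name, a.residue_seq, a.chain_id,
                     *(R @ a.pos + t))
                for a in st.atoms
            )
        )
        sites0 = detect_bishis_sites(st, estimate_slab(st))
        sites1 = detect_bishis_sites(moved, estimate_slab(moved))
        assert {frozenset((s.his_a, s.his_b)) for s in sites0} == {
            frozenset((s.his_a, s.his_b)) for s in sites1
        }
        for s0, s1 in zip(sites0, sites1):
            assert s0.ne2_distance == pytest.approx(s1.ne2_distance, abs=1e-6)

    def test_threshold_validation(self, bundle):
        st, _ = bundle
        slab = estimate_slab(st)
        with pytest.raises(ValueError):
            detect_bishis_sites(st, slab, max_ne2_distance=0)
        with pytest.raises(ValueError):
            detect_bishis_sites(st, slab, central_fraction=1.5)


class TestPocketDistance:
    def serine_structure(self):
        return Structure(
            (
                Atom("CA", "C", "SER", 5, "A", -1.0, 0.0, 0.0),
                Atom("OG", "O", "SER", 5, "A", 0.0, 0.0, 0.0),
                Atom("N1", "N", "FMN", 300, "A", 3.0, 4.0, 0.0),
                Atom("CA", "C", "ALA", 6, "A", 7.0, 7.0, 7.0),
            )
        )

    def test_three_four_five_triangle(self):
        st = self.serine_structure()
        d = motif_pocket_distance(st, ("A", 5), [("A", 300, "N1")])
        assert d == pytest.approx(5.0)

    def test_non_ser_thr_residue_rejected(self):
        st = self.serine_structure()
        with pytest.raises(ValueError, match="not SER/THR"):
            motif_pocket_distance(st, ("A", 6), [("A", 300, "N1")])

    def test_distance_invariant_under_rigid_motion(self):
        st = self.serine_structure()
        rng = np.random.default_rng(2)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3)
        moved = Structure(
            tuple(
                Atom(a.atom_name, a.element, a.residue_name, a.residue_seq, a.chain_id,
                     *(R @ a.pos + t))
                for a in st.atoms
            )
        )
        d0 = motif_pocket_distance(st, ("A", 5), [("A", 300, "N1")])
        d1 = motif_pocket_distance(moved, ("A", 5), [("A", 300, "N1")])
        assert d0 == pytest.approx(d1, abs=1e-9)
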