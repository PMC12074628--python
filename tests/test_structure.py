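"""Contacts, superposition, hydrogen bonds and docking-suitability triage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from vkorcall.structure import (
    Atom,
    Structure,
    detect_hbonds,
    kabsch_superpose,
    ligand_neighborhood,
    load_regions,
    read_structure,
    superpose_structures,
    triage_mutation,
)
from vkorcall.synth import write_pdb


def atom(resnum, name, element, xyz, resname="ALA", lig=False, occ=1.0, alt=""):
    return Atom(
        chain="A", residue_number=resnum, residue_name=resname, atom_name=name,
        element=element, x=xyz[0], y=xyz[1], z=xyz[2], occupancy=occ,
        altloc=alt, is_ligand=lig,
    )


def toy_structure(protein_atoms, ligand_atoms):
    atoms = tuple(protein_atoms) + tuple(
        Atom(**{**a.__dict__, "is_ligand": True, "residue_name": "LIG"})
        for a in ligand_atoms
    )
    return Structure(atoms=atoms, ligand_selector="LIG")


def random_toy(rng, n_protein=50, n_ligand=6, box=12.0):
    protein = [
        atom(int(i // 4) + 1, f"C{i % 4}", rng.choice(["C", "N", "O", "S"]),
             rng.uniform(-box, box, 3))
        for i in range(n_protein)
    ]
    ligand = [
        atom(900, f"L{i}", rng.choice(["C", "N", "O"]), rng.uniform(-4, 4, 3))
        for i in range(n_ligand)
    ]
    return toy_structure(protein, ligand)


class TestReadStructure:
    def test_roundtrip_through_pdb(self, tmp_path):
        s = toy_structure(
            [atom(1, "CA", "C", (0, 0, 0)), atom(2, "CA", "C", (3, 0, 0))],
            [atom(900, "O1", "O", (1.0, 2.0, 3.0))],
        )
        path = write_pdb(s, tmp_path / "toy.pdb")
        loaded = read_structure(path, "LIG")
        assert len(loaded.atoms) == 3
        lig = loaded.ligand_atoms()
        assert len(lig) == 1
        assert lig[0].coords == pytest.approx([1.0, 2.0, 3.0])

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        s = Structure(
            atoms=(
                atom(1, "CA", "C", (0, 0, 0), occ=0.6, alt="A"),
                atom(1, "CA", "C", (5, 0, 0), occ=0.4, alt="B"),
                atom(2, "O1", "O", (9, 9, 9), resname="LIG", lig=True),
            ),
            ligand_selector="LIG",
        )
        path = write_pdb(s, tmp_path / "alt.pdb")
        loaded = read_structure(path, "LIG")
        cas = [a for a in loaded.atoms if a.atom_name == "CA"]
        assert len(cas) == 1
        assert cas[0].x == pytest.approx(0.0)

    def test_missing_ligand_selector_errors(self, tmp_path):
        s = toy_structure([atom(1, "CA", "C", (0, 0, 0))], [atom(9, "O1", "O", (1, 1, 1))])
        path = write_pdb(s, tmp_path / "t.pdb")
        with pytest.raises(ValueError, match="XYZ"):
            read_structure(path, "XYZ")


class TestLigandNeighborhood:
    def test_cutoff_arithmetic(self):
        s = toy_structure(
            [atom(1, "CA", "C", (4.9, 0, 0)), atom(2, "CA", "C", (5.1, 0, 0))],
            [atom(900, "O1", "O", (0, 0, 0))],
        )
        contacts = ligand_neighborhood(s, cutoff=5.0)
        assert contacts.residue_numbers == {1}
        assert contacts.min_distances[("A", 1, "ALA")] == pytest.approx(4.9)

    def test_tiny_cutoff_empty(self):
        s = toy_structure([atom(1, "CA", "C", (3, 0, 0))], [atom(9, "O1", "O", (0, 0, 0))])
        assert ligand_neighborhood(s, cutoff=0.1).members == ()

    def test_hydrogens_ignored(self):
        s = toy_structure(
            [atom(1, "H1", "H", (1, 0, 0)), atom(2, "CA", "C", (20, 0, 0))],
            [atom(900, "O1", "O", (0, 0, 0))],
        )
        assert ligand_neighborhood(s, cutoff=5.0).members == ()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_toy(rng)
        contacts = ligand_neighborhood(s, cutoff=5.0)
        # O(n^2) oracle: explicit double loop over heavy atoms
        expected = set()
        for pa in s.protein_atoms():
            for la in s.ligand_atoms():
                if np.linalg.norm(pa.coords - la.coords) <= 5.0:
                    expected.add(pa.residue_number)
        assert contacts.residue_numbers == expected

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(99)
        s = random_toy(rng)
        sets = [ligand_neighborhood(s, c).residue_numbers for c in (2.0, 5.0, 8.0)]
        assert sets[0] <= sets[1] <= sets[2]


class TestKabsch:
    def test_identity_superposition(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered_to_zero_rmsd(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (12, 3))
        rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_reported_rmsd_matches_applied_transform(self):
        rng = np.random.default_rng(2)
        fixed = rng.uniform(-5, 5, (8, 3))
        mobile = fixed + rng.normal(0, 0.5, (8, 3))
        res = kabsch_superpose(fixed, mobile)
        moved = res.apply(mobile)
        direct = np.sqrt(((moved - fixed) ** 2).sum() / len(fixed))
        assert res.rmsd == pytest.approx(direct, abs=1e-12)

    def test_invariance_under_prior_rigid_motion(self):
        rng = np.random.default_rng(3)
        fixed = rng.uniform(-5, 5, (9, 3))
        mobile = fixed + rng.normal(0, 0.8, (9, 3))
        base = kabsch_superpose(fixed, mobile).rmsd
        for seed in range(5):
            r = Rotation.random(rng=np.random.RandomState(seed)).as_matrix()
            t = np.random.default_rng(seed).uniform(-10, 10, 3)
            assert kabsch_superpose(fixed, mobile @ r.T + t).rmsd == pytest.approx(
                base, abs=1e-9
            )

    @given(
        angles=st.tuples(*[st.floats(-180, 180, allow_nan=False)] * 3),
        shift=st.tuples(*[st.floats(-50, 50, allow_nan=False)] * 3),
    )
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_rmsd_invariant_under_any_rigid_motion(self, angles, shift):
        rng = np.random.default_rng(17)
        fixed = rng.uniform(-5, 5, (7, 3))
        mobile = fixed + rng.normal(0, 0.5, (7, 3))
        base = kabsch_superpose(fixed, mobile).rmsd
        rot = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        moved = mobile @ rot.T + np.asarray(shift)
        assert kabsch_superpose(fixed, moved).rmsd == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_rotation_search_oracle(self, seed):
        """SVD solution equals an independent minimizer: coarse Euler-angle
        grid followed by simplex refinement, centroids aligned per rotation."""
        rng = np.random.default_rng(seed)
        fixed = rng.uniform(-4, 4, (5, 3))
        mobile = fixed + rng.normal(0, 0.6, (5, 3))

        f0 = fixed - fixed.mean(axis=0)
        m0 = mobile - mobile.mean(axis=0)

        def rmsd_of(angles):
            rot = Rotation.from_euler("xyz", angles).as_matrix()
            return np.sqrt((((m0 @ rot.T) - f0) ** 2).sum() / len(f0))

        grid = np.linspace(-np.pi, np.pi, 13)
        best = min(
            ((a, b, c) for a in grid for b in grid for c in grid),
            key=rmsd_of,
        )
        refined = minimize(rmsd_of, best, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14})
        assert kabsch_superpose(fixed, mobile).rmsd == pytest.approx(
            refined.fun, abs=1e-3
        )

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="3 atom pairs"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="paired"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_residue_paired_superposition_with_selection(self):
        rng = np.random.default_rng(5)
        protein = []
        for rn in range(1, 5):
            base = rng.uniform(-5, 5, 3)
            for i, name in enumerate(["N", "CA", "C", "O", "CB"]):
                protein.append(atom(rn, name, name[0], base + [i * 0.8, 0, 0]))
        fixed = toy_structure(protein, [atom(900, "O1", "O", (50, 50, 50))])
        rot = Rotation.from_euler("y", 80, degrees=True).as_matrix()
        moved_atoms = [
            Atom(**{**a.__dict__, "x": c[0], "y": c[1], "z": c[2]})
            for a in fixed.atoms
            for c in [a.coords @ rot.T + 4.0]
        ]
        mobile = Structure(atoms=tuple(moved_atoms), ligand_selector="LIG")
        res = superpose_structures(fixed, mobile, range(1, 5), selection="backbone")
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.atom_pair_count == 16  # 4 residues x N/CA/C/O


class TestHbonds:
    def test_polar_pair_reported_carbon_not(self):
        s = toy_structure(
            [atom(1, "OG", "O", (2.8, 0, 0)), atom(2, "CB", "C", (0, 2.8, 0))],
            [atom(900, "O1", "O", (0, 0, 0))],
        )
        bonds = detect_hbonds(s, dist_cutoff=3.5)
        assert len(bonds) == 1
        pa, la, d = bonds[0]
        assert pa.atom_name == "OG" and d == pytest.approx(2.8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_polar_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_toy(rng, n_protein=60)
        bonds = detect_hbonds(s, dist_cutoff=3.5)
        expected = sorted(
            (round(float(np.linalg.norm(pa.coords - la.coords)), 9),
             pa.atom_name, la.atom_name)
            for pa in s.protein_atoms()
            for la in s.ligand_atoms()
            if pa.element in "NOS" and la.element in "NOS"
            and np.linalg.norm(pa.coords - la.coords) <= 3.5
        )
        got = sorted((round(d, 9), pa.atom_name, la.atom_name) for pa, la, d in bonds)
        assert got == expected
        assert [b[2] for b in bonds] == sorted(b[2] for b in bonds)


class TestTriage:
    REGIONS = {"cap domain": [(51, 78)], "cytoplasmic interface": [(1, 10)]}

    def binding_site_model(self):
        """Synthetic stand-in complex: the residues reported in contact with
        the ligand (87, 123, 128, 139) placed within 5 A of it, all other
        mutated residues far away."""
        near = {87, 123, 128, 139}
        far = {7, 28, 36, 42, 59, 61, 96, 78, 85}
        protein = []
        rng = np.random.default_rng(42)
        for i, rn in enumerate(sorted(near)):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            protein.append(atom(rn, "CB", "C", direction * rng.uniform(3.0, 4.5)))
        for rn in sorted(far):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            protein.append(atom(rn, "CB", "C", direction * rng.uniform(12, 30)))
        return toy_structure(protein, [atom(900, "O1", "O", (0, 0, 0))])

    def test_contact_residue_suitable(self):
        s = self.binding_site_model()
        contacts = ligand_neighborhood(s, 5.0)
        d = triage_mutation("Y139F", 139, contacts, self.REGIONS)
        assert d.decision == "suitable"

    def test_cap_domain_residue_not_suitable_with_reason(self):
        s = self.binding_site_model()
        contacts = ligand_neighborhood(s, 5.0)
        d = triage_mutation("W59R", 59, contacts, self.REGIONS)
        assert d.decision == "not_suitable"
        assert d.reason == "cap domain"

    def test_absent_residue_errors(self):
        s = self.binding_site_model()
        contacts = ligand_neighborhood(s, 5.0)
        with pytest.raises(ValueError, match="absent"):
            triage_mutation("X999X", 999, contacts, self.REGIONS)

    def test_suitable_set_on_synthetic_complex(self):
        """On the synthetic binding-site model the suitable set over the full
        mutation panel is exactly {F87, I123, L128, Y139}."""
        s = self.binding_site_model()
        contacts = ligand_neighborhood(s, 5.0)
        regions = load_regions()
        panel = {
            "S7G": 7, "H28Q": 28, "N36H": 36, "L42P": 42, "W59R": 59,
            "R61W": 61, "Q78H": 78, "C85R": 85, "F87L": 87, "C96G": 96,
            "I123F": 123, "I123S": 123, "L128S": 128, "Y139F": 139, "Y139C": 139,
        }
        suitable = {
            label
            for label, rn in panel.items()
            if triage_mutation(label, rn, contacts, regions).decision == "suitable"
        }
        assert suitable == {"F87L", "I123F", "I123S", "L128S", "Y139F", "Y139C"}
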