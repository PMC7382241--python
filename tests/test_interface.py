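import itertools

import numpy as np
import pytest

from ternalyze.errors import GeometryError
from ternalyze.interface import (
    contact_residues,
    detect_hydrogen_bonds,
    detect_pi_stacking,
    model_substituent_clash,
    shared_contact_residues,
)
from ternalyze.structure_io import Atom, Residue, Structure, annotate_roles, assign_radii


class ContactPairStub:
    """Minimal stand-in for a presenter-side contact record."""

    def __init__(self, seq_id):
        from types import SimpleNamespace

        self.residue_a = SimpleNamespace(seq_id=seq_id, label=f"P/ALA{seq_id}")
        self.atoms_a = {"CA"}


def build_complex(residue_specs):
    """residue_specs: list of (chain, seq, name, role, [(atom_name, xyz), ...])."""
    residues, role_map = [], {}
    serial = 0
    for chain, seq, name, role, atoms in residue_specs:
        alist = []
        for atom_name, xyz in atoms:
            serial += 1
            element = atom_name[0]
            alist.append(Atom(serial=serial, name=atom_name, element=element,
                              position=np.asarray(xyz, float)))
        residues.append(Residue(chain_id=chain, seq_id=seq, name=name,
                                atoms=alist))
        role_map.setdefault(role, set()).add(chain)
    st = assign_radii(Structure(residues=residues))
    return annotate_roles(st, {r: sorted(cs) for r, cs in role_map.items()})


class TestContacts:
    def test_cutoff_inclusion_and_exclusion(self):
        cplx = build_complex([
            ("P", 1, "ALA", "presenter", [("CA", (0, 0, 0))]),
            ("T", 1, "ALA", "target", [("CA", (3.5, 0, 0))]),
        ])
        assert len(contact_residues(cplx, 4.0, ("presenter", "target"))) == 1
        assert contact_residues(cplx, 3.0, ("presenter", "target")) == []

    def test_symmetry_in_role_order(self, mock_ternary):
        cplx, _ = mock_ternary
        ab = contact_residues(cplx, 4.0, ("presenter", "target"))
        ba = contact_residues(cplx, 4.0, ("target", "presenter"))
        pairs_ab = {(c.residue_a.key, c.residue_b.key) for c in ab}
        pairs_ba = {(c.residue_b.key, c.residue_a.key) for c in ba}
        assert pairs_ab == pairs_ba

    def test_monotone_in_cutoff(self, mock_ternary):
        cplx, _ = mock_ternary
        previous = set()
        for cutoff in (3.0, 3.5, 4.0, 5.0, 6.0):
            pairs = {(c.residue_a.key, c.residue_b.key)
                     for c in contact_residues(cplx, cutoff,
                                               ("presenter", "target"))}
            assert previous <= pairs
            previous = pairs

    def test_matches_bruteforce_on_small_fixture(self, rng):
        n_p, n_t = 12, 15
        specs = []
        for i in range(n_p):
            specs.append(("P", i + 1, "ALA", "presenter",
                          [("CA", rng.uniform(0, 12, 3))]))
        for i in range(n_t):
            specs.append(("T", i + 1, "ALA", "target",
                          [("CA", rng.uniform(0, 12, 3))]))
        cplx = build_complex(specs)
        found = {(c.residue_a.seq_id, c.residue_b.seq_id)
                 for c in contact_residues(cplx, 4.0, ("presenter", "target"))}
        pres = cplx.residues_with_role("presenter")
        targ = cplx.residues_with_role("target")
        brute = set()
        for rp, rt in itertools.product(pres, targ):
            dmin = min(np.linalg.norm(a.position - b.position)
                       for a in rp.atoms for b in rt.atoms)
            if dmin <= 4.0:
                brute.add((rp.seq_id, rt.seq_id))
        assert found == brute

    def test_designed_contacts_recovered_exactly(self, mock_ternary):
        cplx, truth = mock_ternary
        found = {(c.residue_a.seq_id, c.residue_b.chain_id, c.residue_b.seq_id)
                 for c in contact_residues(cplx, 4.0, ("presenter", "target"))}
        assert found == truth.contacts

    def test_rejects_nonpositive_cutoff(self, mock_ternary):
        cplx, _ = mock_ternary
        with pytest.raises(ValueError):
            contact_residues(cplx, 0.0)


class TestHydrogenBonds:
    def ideal_pair(self, d=2.8, angle_deg=180.0):
        # donor OG (Ser) with CB antecedent; acceptor OE1 (Glu) with CD
        theta = np.radians(180.0 - angle_deg)
        acceptor = (d * np.cos(theta), d * np.sin(theta), 0.0)
        return build_complex([
            ("P", 1, "SER", "presenter",
             [("CB", (-1.5, 0, 0)), ("OG", (0, 0, 0))]),
            ("T", 1, "GLU", "target",
             [("CD", (acceptor[0] + 1.3, acceptor[1], 0)), ("OE1", acceptor)]),
        ])

    def test_ideal_geometry_detected(self):
        bonds = detect_hydrogen_bonds(self.ideal_pair(), roles=("presenter", "target"))
        assert len(bonds) == 1
        bond = bonds[0]
        assert bond.distance == pytest.approx(2.8)
        assert bond.angle_at_donor == pytest.approx(180.0, abs=1e-6)
        assert bond.donor_is_sidechain and bond.acceptor_is_sidechain

    def test_long_distance_rejected(self):
        bonds = detect_hydrogen_bonds(self.ideal_pair(d=5.0),
                                      roles=("presenter", "target"))
        assert bonds == []

    def test_bad_angle_rejected(self):
        bonds = detect_hydrogen_bonds(self.ideal_pair(angle_deg=90.0),
                                      roles=("presenter", "target"))
        assert bonds == []

    def test_ligand_typing_table_used(self):
        cplx = build_complex([
            ("L", 1, "LIG", "ligand", [("C16", (-1.4, 0, 0)), ("O16", (0, 0, 0))]),
            ("T", 1, "GLN", "target",
             [("CD", (2.8 + 1.3, 0, 0)), ("OE1", (2.8, 0, 0)),
              ("NE2", (2.8, 3.0, 0))]),
        ])
        for res in cplx.structure.residues:
            for a in res.atoms:
                a.is_hetero = res.chain_id == "L"
        bonds = detect_hydrogen_bonds(
            cplx, roles=("ligand", "target"),
            ligand_typing={("LIG", "O16"): "both"})
        # hydroxyl donates to OE1 and accepts from NE2 is too far/bad angle;
        # at least the donor bond to the carbonyl must be found
        assert any(b.acceptor_atom.name == "OE1" for b in bonds)

    def test_monotone_in_distance_cutoff(self):
        cplx = self.ideal_pair(d=3.3)
        short = detect_hydrogen_bonds(cplx, d_max=3.0, roles=("presenter", "target"))
        wide = detect_hydrogen_bonds(cplx, d_max=3.5, roles=("presenter", "target"))
        assert len(short) <= len(wide)
        assert len(wide) == 1


def hexagon(center, radius=1.39, z=0.0):
    pts = []
    for k in range(6):
        ang = np.pi / 3 * k
        pts.append((center[0] + radius * np.cos(ang),
                    center[1] + radius * np.sin(ang), center[2] + z))
    return pts


class TestPiStacking:
    RING = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]

    def phe(self, chain, seq, center, role):
        return (chain, seq, "PHE", role,
                list(zip(self.RING, hexagon(center))))

    def test_parallel_rings_detected(self):
        cplx = build_complex([
            self.phe("L", 1, (0, 0, 0), "ligand"),
            self.phe("T", 1, (0, 0, 3.8), "target"),
        ])
        events = detect_pi_stacking(cplx, roles=("ligand", "target"))
        assert len(events) == 1
        assert events[0].centroid_distance == pytest.approx(3.8, abs=1e-6)
        assert events[0].interplanar_angle == pytest.approx(0.0, abs=1e-6)

    def test_distant_rings_ignored(self):
        cplx = build_complex([
            self.phe("L", 1, (0, 0, 0), "ligand"),
            self.phe("T", 1, (0, 0, 10.0), "target"),
        ])
        assert detect_pi_stacking(cplx, roles=("ligand", "target")) == []

    def test_ligand_ring_dictionary(self):
        names = [f"C{i}" for i in range(1, 7)]
        cplx = build_complex([
            ("L", 1, "LIG", "ligand", list(zip(names, hexagon((0, 0, 0))))),
            self.phe("T", 1, (0, 0, 4.0), "target"),
        ])
        events = detect_pi_stacking(
            cplx, roles=("ligand", "target"), ligand_rings={"LIG": [names]})
        assert len(events) == 1


class TestSharedContacts:
    def test_identical_reports_intersect_fully(self, mock_ternary):
        cplx, truth = mock_ternary
        pairs = contact_residues(cplx, 4.0, ("presenter", "target"))
        shared = shared_contact_residues([("c1", pairs), ("c2", pairs)])
        assert set(shared) == {p for p, _, _ in truth.contacts}

    def test_disjoint_reports_intersect_empty(self, mock_ternary):
        cplx, _ = mock_ternary
        pairs = contact_residues(cplx, 4.0, ("presenter", "target"))
        # second complex deploys an entirely different presenter residue range
        shifted = [
            ContactPairStub(seq_id=cp.residue_a.seq_id + 100)
            for cp in pairs
        ]
        assert shared_contact_residues([("c1", pairs), ("c2", shifted)]) == {}

    def test_requires_two_reports(self, mock_ternary):
        cplx, _ = mock_ternary
        pairs = contact_residues(cplx, 4.0, ("presenter", "target"))
        with pytest.raises(ValueError):
            shared_contact_residues([("only", pairs)])


class TestSubstituentClash:
    def carbonyl_host(self, env_atoms):
        """sp² carbon with two ring neighbours; env_atoms on the target."""
        return build_complex([
            ("L", 1, "LIG", "ligand",
             [("C18", (0, 0, 0)), ("C17", (-1.2, 0.9, 0)), ("C19", (1.2, 0.9, 0))]),
            ("T", 1, "ALA", "target", env_atoms),
        ])

    def test_open_solvent_no_clash(self):
        cplx = self.carbonyl_host([("CA", (0, 10, 0))])
        attachment = cplx.structure.residues[0].atom("C18")
        report = model_substituent_clash(cplx, attachment)
        assert report.clashing_atoms == []
        # oxygen placed along the external bisector (-y here)
        assert report.added_position[1] < 0

    def test_coincident_atom_reports_full_overlap(self):
        cplx = self.carbonyl_host([("CA", (0, -1.23, 0))])
        attachment = cplx.structure.residues[0].atom("C18")
        report = model_substituent_clash(cplx, attachment)
        assert len(report.clashing_atoms) == 1
        _, atom, overlap = report.clashing_atoms[0]
        assert atom.name == "CA"
        assert overlap == pytest.approx(1.52 + 1.70, abs=1e-6)

    def test_wrong_neighbour_count_is_geometry_error(self):
        cplx = build_complex([
            ("L", 1, "LIG", "ligand", [("C18", (0, 0, 0))]),
            ("T", 1, "ALA", "target", [("CA", (8, 0, 0))]),
        ])
        attachment = cplx.structure.residues[0].atom("C18")
        with pytest.raises(GeometryError):
            model_substituent_clash(cplx, attachment)
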