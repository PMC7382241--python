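"""Interface enumeration: contacts, hydrogen bonds, π-stacking, clash modeling.

All criteria are heavy-atom geometric rules, appropriate for crystal
structures without modeled hydrogens:

* contact: any heavy-atom pair across the role boundary within a distance
  cutoff (default 4.0 Å);
* hydrogen bond: donor-acceptor heavy-atom distance <= 3.5 Å with an
  antecedent-donor-acceptor angle >= 120° whenever the donor has a bonded
  heavy-atom antecedent;
* π-stacking: aromatic ring centroids within 5.5 Å, reported with the
  interplanar angle;
* steric clash of a modeled substituent: van der Waals overlap
  r_i + r_j - d above a threshold (default 0.4 Å, the conventional
  severe-clash bound).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, GeometryError, TernalyzeError
from .structure_io import AnnotatedComplex, Atom, Residue

__all__ = [
    "ContactPair",
    "HydrogenBond",
    "PiStackEvent",
    "ClashReport",
    "contact_residues",
    "detect_hydrogen_bonds",
    "detect_pi_stacking",
    "shared_contact_residues",
    "model_substituent_clash",
]

MAIN_CHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Heavy-atom hydrogen-bond donors/acceptors for the standard amino acids.
# Main-chain N (donor, except proline) and O/OXT (acceptor) are implicit.
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
}

COVALENT_CUTOFF = 1.8  # Å, heavy-atom bond detection within a residue


@dataclass
class ContactPair:
    residue_a: Residue
    residue_b: Residue
    min_distance: float
    n_atom_pairs: int
    atoms_a: set[str] = field(default_factory=set)
    atoms_b: set[str] = field(default_factory=set)


@dataclass
class HydrogenBond:
    donor_atom: Atom
    acceptor_atom: Atom
    donor_residue: Residue
    acceptor_residue: Residue
    distance: float
    angle_at_donor: float | None  # degrees; None when no antecedent exists
    donor_is_sidechain: bool = True
    acceptor_is_sidechain: bool = True


@dataclass
class PiStackEvent:
    residue_a: Residue
    residue_b: Residue
    centroid_distance: float
    interplanar_angle: float  # degrees, folded into [0, 90]


@dataclass
class ClashReport:
    added_element: str
    added_position: np.ndarray
    clashing_atoms: list[tuple[Residue, Atom, float]]  # (residue, atom, overlap Å)
    clash_threshold: float


def _role_atoms(
    cplx: AnnotatedComplex, role: str
) -> tuple[list[Residue], list[Atom], np.ndarray, list[int]]:
    residues = cplx.residues_with_role(role)
    atoms: list[Atom] = []
    owner: list[int] = []
    for ri, res in enumerate(residues):
        for a in res.heavy_atoms():
            atoms.append(a)
            owner.append(ri)
    if not atoms:
        raise TernalyzeError(f"role {role!r} has no heavy atoms")
    coords = np.array([a.position for a in atoms])
    return residues, atoms, coords, owner


def contact_residues(
    cplx: AnnotatedComplex,
    cutoff: float = 4.0,
    roles: tuple[str, str] = ("presenter", "target"),
) -> list[ContactPair]:
    """Residue pairs across the role boundary with a heavy-atom pair <= cutoff."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    res_a, atoms_a, xyz_a, own_a = _role_atoms(cplx, roles[0])
    res_b, atoms_b, xyz_b, own_b = _role_atoms(cplx, roles[1])
    pairs = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), r=cutoff)
    found: dict[tuple[int, int], ContactPair] = {}
    for ia, blist in enumerate(pairs):
        for ib in blist:
            d = float(np.linalg.norm(xyz_a[ia] - xyz_b[ib]))
            key = (own_a[ia], own_b[ib])
            cp = found.get(key)
            if cp is None:
                cp = ContactPair(res_a[key[0]], res_b[key[1]], d, 0)
                found[key] = cp
            cp.min_distance = min(cp.min_distance, d)
            cp.n_atom_pairs += 1
            cp.atoms_a.add(atoms_a[ia].name)
            cp.atoms_b.add(atoms_b[ib].name)
    return sorted(
        found.values(),
        key=lambda c: (c.residue_a.chain_id, c.residue_a.seq_id,
                       c.residue_b.chain_id, c.residue_b.seq_id),
    )


def _donors_acceptors(
    res: Residue, ligand_typing: dict[tuple[str, str], str] | None
) -> tuple[list[Atom], list[Atom]]:
    donors: list[Atom] = []
    acceptors: list[Atom] = []
    standard = res.name in SIDECHAIN_DONORS or res.name in SIDECHAIN_ACCEPTORS or any(
        a.name in MAIN_CHAIN_ATOMS for a in res.atoms
    )
    if res.is_hetero or not standard:
        if ligand_typing is None:
            warnings.warn(f"no donor/acceptor typing for {res.label}; skipped",
                          stacklevel=2)
            return [], []
        for a in res.heavy_atoms():
            kind = ligand_typing.get((res.name, a.name))
            if kind in ("donor", "both"):
                donors.append(a)
            if kind in ("acceptor", "both"):
                acceptors.append(a)
        return donors, acceptors
    for a in res.heavy_atoms():
        if a.name == "N" and res.name != "PRO":
            donors.append(a)
        if a.name in ("O", "OXT"):
            acceptors.append(a)
        if a.name in SIDECHAIN_DONORS.get(res.name, ()):
            donors.append(a)
        if a.name in SIDECHAIN_ACCEPTORS.get(res.name, ()):
            acceptors.append(a)
    return donors, acceptors


def _antecedents(res: Residue, atom: Atom) -> list[Atom]:
    out = []
    for other in res.heavy_atoms():
        if other is atom:
            continue
        if np.linalg.norm(other.position - atom.position) <= COVALENT_CUTOFF:
            out.append(other)
    return out


def detect_hydrogen_bonds(
    cplx: AnnotatedComplex,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    roles: tuple[str, str] = ("presenter", "target"),
    ligand_typing: dict[tuple[str, str], str] | None = None,
) -> list[HydrogenBond]:
    """Heavy-atom hydrogen bonds across the role boundary.

    ``ligand_typing`` maps (residue name, atom name) to "donor", "acceptor"
    or "both" for hetero groups lacking standard typing.
    """
    res_a = cplx.residues_with_role(roles[0])
    res_b = cplx.residues_with_role(roles[1])
    bonds: list[HydrogenBond] = []
    for side_a, side_b in ((res_a, res_b), (res_b, res_a)):
        for ra in side_a:
            donors, _ = _donors_acceptors(ra, ligand_typing)
            if not donors:
                continue
            for rb in side_b:
                _, acceptors = _donors_acceptors(rb, ligand_typing)
                for d_atom in donors:
                    for a_atom in acceptors:
                        dist = float(np.linalg.norm(
                            d_atom.position - a_atom.position))
                        if dist > d_max:
                            continue
                        angle = None
                        ok = True
                        ants = _antecedents(ra, d_atom)
                        if ants:
                            angles = []
                            for ant in ants:
                                v1 = ant.position - d_atom.position
                                v2 = a_atom.position - d_atom.position
                                c = np.dot(v1, v2) / (
                                    np.linalg.norm(v1) * np.linalg.norm(v2))
                                angles.append(math.degrees(
                                    math.acos(np.clip(c, -1, 1))))
                            angle = max(angles)
                            ok = angle >= angle_min
                        if ok:
                            bonds.append(HydrogenBond(
                                donor_atom=d_atom,
                                acceptor_atom=a_atom,
                                donor_residue=ra,
                                acceptor_residue=rb,
                                distance=dist,
                                angle_at_donor=angle,
                                donor_is_sidechain=d_atom.name not in MAIN_CHAIN_ATOMS,
                                acceptor_is_sidechain=(
                                    a_atom.name not in MAIN_CHAIN_ATOMS),
                            ))
    bonds.sort(key=lambda b: (b.donor_residue.chain_id, b.donor_residue.seq_id,
                              b.distance))
    return bonds


def _ring_geometry(res: Residue, atom_names: list[str]) -> tuple[np.ndarray, np.ndarray] | None:
    pts = []
    for name in atom_names:
        a = res.atom(name)
        if a is None:
            return None
        pts.append(a.position)
    pts = np.array(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]  # normal = least-variance direction


def detect_pi_stacking(
    cplx: AnnotatedComplex,
    centroid_max: float = 5.5,
    roles: tuple[str, str] = ("ligand", "target"),
    ligand_rings: dict[str, list[list[str]]] | None = None,
) -> list[PiStackEvent]:
    """Aromatic ring pairs across the role boundary within a centroid cutoff.

    ``ligand_rings`` supplies ring atom-name lists for hetero residues, keyed
    by residue name (Phe/Tyr/Trp/His rings are built in).
    """
    def rings_of(res: Residue):
        if res.name in AROMATIC_RINGS:
            defs = AROMATIC_RINGS[res.name]
        elif ligand_rings and res.name in ligand_rings:
            defs = ligand_rings[res.name]
        else:
            return []
        out = []
        for names in defs:
            geo = _ring_geometry(res, names)
            if geo is None:
                if ligand_rings and res.name in ligand_rings:
                    raise ConfigurationError(
                        f"ring atoms {names} not all present in {res.label}")
                continue
            out.append(geo)
        return out

    events: list[PiStackEvent] = []
    for ra in cplx.residues_with_role(roles[0]):
        rings_a = rings_of(ra)
        if not rings_a:
            continue
        for rb in cplx.residues_with_role(roles[1]):
            for ca, na in rings_a:
                for cb, nb in rings_of(rb):
                    d = float(np.linalg.norm(ca - cb))
                    if d > centroid_max:
                        continue
                    cosang = abs(float(np.dot(na, nb)))
                    angle = math.degrees(math.acos(np.clip(cosang, 0, 1)))
                    events.append(PiStackEvent(ra, rb, d, angle))
    events.sort(key=lambda e: e.centroid_distance)
    return events


def shared_contact_residues(
    reports: list[tuple[str, list[ContactPair]]],
    presenter_side: str = "a",
) -> dict[int, dict[str, dict]]:
    """Presenter residues contacting the target in every listed complex.

    ``reports`` pairs a complex name with its presenter-target contact list;
    the presenter residue of each pair sits on side ``presenter_side``
    ("a" or "b").  Returns {seq_id: {complex name: {"residue": label,
    "side_chain": bool, "main_chain": bool}}} for the intersection over
    presenter residue numbers (author numbering is assumed consistent, as for
    one presenter protein solved in several complexes).
    """
    if len(reports) < 2:
        raise ValueError("need at least two complexes to intersect")
    per_complex: list[dict[int, dict]] = []
    for name, pairs in reports:
        entry: dict[int, dict] = {}
        for cp in pairs:
            res = cp.residue_a if presenter_side == "a" else cp.residue_b
            atoms = cp.atoms_a if presenter_side == "a" else cp.atoms_b
            rec = entry.setdefault(res.seq_id, {
                "residue": res.label, "side_chain": False, "main_chain": False})
            for an in atoms:
                if an in MAIN_CHAIN_ATOMS:
                    rec["main_chain"] = True
                else:
                    rec["side_chain"] = True
        per_complex.append(entry)
    shared = set(per_complex[0])
    for entry in per_complex[1:]:
        shared &= set(entry)
    return {
        seq_id: {reports[i][0]: per_complex[i][seq_id]
                 for i in range(len(reports))}
        for seq_id in sorted(shared)
    }


def model_substituent_clash(
    cplx: AnnotatedComplex,
    attachment: Atom,
    element: str = "O",
    bond_length: float = 1.23,
    geometry: str = "sp2_bisector",
    clash_threshold: float = 0.4,
    radii: dict[str, float] | None = None,
) -> ClashReport:
    """Place a substituent atom on ``attachment`` and list vdW clashes.

    Under the sp² carbonyl rule the new atom sits at ``bond_length`` along
    the external bisector of the attachment's two bonded heavy neighbours
    (the direction a carbonyl oxygen would take on a ring carbon).
    """
    if geometry != "sp2_bisector":
        raise ConfigurationError(f"unknown geometry rule {geometry!r}")
    from .structure_io import RADII_SETS, FALLBACK_RADIUS

    table = radii or RADII_SETS["naccess"]
    host_res = None
    for res in cplx.structure.residues:
        if any(a is attachment for a in res.atoms):
            host_res = res
            break
    if host_res is None:
        raise ValueError("attachment atom not found in complex")
    neighbors = _antecedents(host_res, attachment)
    if len(neighbors) != 2:
        raise GeometryError(
            f"sp2 rule needs exactly 2 bonded heavy neighbours, "
            f"found {len(neighbors)} for {host_res.label}/{attachment.name}")
    v1 = neighbors[0].position - attachment.position
    v2 = neighbors[1].position - attachment.position
    bisector = -(v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2))
    norm = np.linalg.norm(bisector)
    if norm < 1e-9:
        raise GeometryError("neighbours are antiparallel; bisector undefined")
    new_pos = attachment.position + bond_length * bisector / norm
    r_new = table.get(element.upper(), FALLBACK_RADIUS)
    clashes: list[tuple[Residue, Atom, float]] = []
    skip = {id(attachment)} | {id(n) for n in neighbors}
    for res in cplx.structure.residues:
        for a in res.heavy_atoms():
            if id(a) in skip:
                continue
            r_a = a.vdw_radius or table.get(a.element.upper(), FALLBACK_RADIUS)
            d = float(np.linalg.norm(a.position - new_pos))
            overlap = r_new + r_a - d
            if overlap > clash_threshold:
                clashes.append((res, a, overlap))
    clashes.sort(key=lambda t: -t[2])
    return ClashReport(
        added_element=element,
        added_position=new_pos,
        clashing_atoms=clashes,
        clash_threshold=clash_threshold,
    )
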