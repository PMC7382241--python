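"""Workflow helpers for analyzing published presenter-ligand-target structures.

The package's quantitative claims about real complexes (BSA partition,
contact-set intersection, hotspot membership, loop displacement) are
computed from deposited coordinate files.  Those files are not shipped with
the package; place them under ``data/structures/`` (PDB or mmCIF, e.g.
``6oqa.cif`` for the FKBP12-WDB002-CEP250 heterotetramer together with the
FKBP12-rapamycin-FRB and FKBP12-FK506-calcineurin entries) and point
:func:`load_reference_complex` at them with the appropriate chain role map.
"""

from __future__ import annotations

import os

import numpy as np
from Bio.SeqUtils import molecular_weight

from .structure_io import (
    AnnotatedComplex,
    Structure,
    annotate_roles,
    assign_radii,
    parse_structure_file,
)

__all__ = [
    "load_reference_complex",
    "auto_role_map",
    "binary_unit_versus_target",
    "chain_sequence",
    "fragment_mass_kda",
]

DEFAULT_DATA_DIR = os.path.join("data", "structures")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}


def auto_role_map(
    structure: Structure,
    presenter_size: tuple[int, int] = (90, 125),
    ligand_min_atoms: int = 25,
) -> dict[str, list[str]]:
    """Heuristic role assignment for FKBP-family ternary entries.

    Polymer chains of FKBP12 size (~107 residues) become the presenter,
    large non-water hetero groups the ligand, remaining polymer chains the
    target.  Small hetero groups (ions, buffer) should be stripped at parse
    time; this helper only orients the canonical three-entity layout and is
    meant to be overridden with an explicit map for unusual depositions.
    """
    presenter, ligand, target = [], [], []
    for chain_id, residues in structure.chains().items():
        polymer = [r for r in residues if not r.is_hetero]
        hetero = [r for r in residues if r.is_hetero]
        if polymer:
            n = len(polymer)
            (presenter if presenter_size[0] <= n <= presenter_size[1]
             else target).append(f"{chain_id}:poly")
        for res in hetero:
            if len(res.heavy_atoms()) >= ligand_min_atoms:
                ligand.append(f"{chain_id}.{res.seq_id}")
    role_map: dict[str, list[str]] = {}
    if presenter:
        role_map["presenter"] = presenter
    if ligand:
        role_map["ligand"] = ligand
    if target:
        role_map["target"] = target
    return role_map


def load_reference_complex(
    basename: str,
    role_map: dict[str, list[str]] | None = None,
    data_dir: str = DEFAULT_DATA_DIR,
    radii_set: str = "naccess",
) -> AnnotatedComplex:
    """Load ``<data_dir>/<basename>.(pdb|cif)`` and annotate entity roles.

    With ``role_map=None`` the :func:`auto_role_map` heuristic is applied.
    Raises FileNotFoundError with the expected locations when the
    coordinate file has not been provided.
    """
    candidates = [
        os.path.join(data_dir, basename + ext)
        for ext in (".pdb", ".cif", ".mmcif", ".ent")
    ]
    for path in candidates:
        if os.path.exists(path):
            structure = parse_structure_file(path)
            assign_radii(structure, radii_set)
            return annotate_roles(
                structure, role_map or auto_role_map(structure), name=basename)
    raise FileNotFoundError(
        f"no coordinate file for {basename!r}; expected one of {candidates}. "
        "Download the deposited entry and place it there.")


def binary_unit_versus_target(cplx: AnnotatedComplex) -> AnnotatedComplex:
    """Reduce a symmetric assembly to one presenter-ligand unit + full target.

    Crystals of coiled-coil targets often contain two presenter-ligand
    binary units flanking one dimer; published per-interface figures refer
    to a single unit.  Keeps the first presenter chain, its nearest ligand
    group, and every target residue.
    """
    presenters = cplx.residues_with_role("presenter")
    ligands = cplx.residues_with_role("ligand")
    targets = cplx.residues_with_role("target")
    if not presenters or not ligands:
        raise ValueError("complex lacks presenter or ligand residues")
    first_chain = presenters[0].chain_id
    kept_presenter = [r for r in presenters if r.chain_id == first_chain]
    pres_xyz = np.array([a.position for r in kept_presenter
                         for a in r.heavy_atoms()])
    centroid = pres_xyz.mean(axis=0)

    def ligand_distance(res):
        xyz = np.array([a.position for a in res.heavy_atoms()])
        return float(np.linalg.norm(xyz.mean(axis=0) - centroid))

    kept_ligand = min(ligands, key=ligand_distance)
    keep = ({r.key for r in kept_presenter} | {kept_ligand.key}
            | {r.key for r in targets})
    residues = [r for r in cplx.structure.residues if r.key in keep]
    sub = Structure(residues=residues, name=cplx.name + "-unit")
    roles = {r.key: cplx.roles[r.key] for r in residues}
    return AnnotatedComplex(structure=sub, roles=roles, name=sub.name)


def chain_sequence(cplx: AnnotatedComplex, role: str, chain_id: str,
                   seq_range: tuple[int, int] | None = None) -> str:
    """One-letter sequence of one chain of a role, optionally windowed."""
    out = []
    for res in cplx.residues_with_role(role):
        if res.chain_id != chain_id:
            continue
        if seq_range and not seq_range[0] <= res.seq_id <= seq_range[1]:
            continue
        out.append(THREE_TO_ONE.get(res.name, "X"))
    return "".join(out)


# average (isotope-abundance-weighted) masses; Biopython handles the table
def fragment_mass_kda(sequence: str) -> float:
    """Average molecular mass of a peptide fragment in kDa.

    ``sequence`` is one-letter amino-acid code; mass includes the terminal
    water of the free peptide.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return molecular_weight(sequence.upper(), seq_type="protein",
                            monoisotopic=False) / 1000.0
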