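"""Hydrophobic hotspot mapping on protein surfaces.

A hotspot is a connected patch of solvent-exposed hydrophobic residues —
on a two-stranded coiled coil the a/d seam of both protomers typically
merges into one cross-protomer patch.  Patch flatness is the RMSD of the
patch's exposed heavy-atom centers from their least-squares plane: an ideal
flat interface scores near zero, a groove or invagination scores higher.
Heptad registry assignment scans the seven possible phases and keeps the one
maximizing mean hydrophobicity at the a/d seam positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, UndefinedResultError
from .sasa import compute_sasa
from .structure_io import AnnotatedComplex, Residue

__all__ = [
    "HotspotPatch",
    "HYDROPHOBICITY_SCALES",
    "MAX_ASA",
    "hydrophobicity_map",
    "detect_hydrophobic_patches",
    "patch_flatness",
    "assign_heptad",
]

# Kyte-Doolittle hydropathy (three-letter codes).
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
HYDROPHOBICITY_SCALES = {"kyte_doolittle": KYTE_DOOLITTLE}

# Theoretical maximum accessible surface areas (Å², Gly-X-Gly based);
# used to convert absolute residue SASA into relative exposure.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_DEFAULT_MAX_ASA = 200.0  # pseudo-residues / nonstandard names

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class HotspotPatch:
    residues: list[Residue]
    exposed_area: float  # Å², summed residue SASA
    mean_hydrophobicity: float
    flatness_rmsd: float | None = None

    @property
    def residue_labels(self) -> list[str]:
        return [r.label for r in self.residues]

    @property
    def seq_ids(self) -> set[int]:
        return {r.seq_id for r in self.residues}


def _residue_sasa(
    cplx: AnnotatedComplex, role: str
) -> tuple[list[Residue], np.ndarray, np.ndarray]:
    """Per-residue SASA (and per-atom areas) of a role computed in isolation."""
    residues = cplx.residues_with_role(role)
    atoms = []
    owner = []
    for ri, res in enumerate(residues):
        for a in res.heavy_atoms():
            atoms.append(a)
            owner.append(ri)
    result = compute_sasa(atoms)
    per_res = np.zeros(len(residues))
    for area, ri in zip(result.per_atom_area, owner):
        per_res[ri] += area
    return residues, per_res, result.per_atom_area


def hydrophobicity_map(
    cplx: AnnotatedComplex,
    role: str = "target",
    scale_name: str = "kyte_doolittle",
    exposure_min: float = 0.05,
) -> dict[tuple[str, int, str], float]:
    """Hydrophobicity of solvent-exposed residues of a role.

    Residues whose relative SASA (against the theoretical maximum for the
    residue type) falls at or below ``exposure_min`` are excluded; unknown
    residue names score 0 with a warning.
    """
    try:
        scale = HYDROPHOBICITY_SCALES[scale_name]
    except KeyError:
        raise ConfigurationError(
            f"unknown hydrophobicity scale {scale_name!r}") from None
    residues, per_res, _ = _residue_sasa(cplx, role)
    out: dict[tuple[str, int, str], float] = {}
    unknown: set[str] = set()
    for res, area in zip(residues, per_res):
        # full-atom residues: theoretical max-ASA reference; reduced
        # pseudo-residues (<= 3 spheres): own isolated-residue area
        heavy = res.heavy_atoms()
        if res.name in MAX_ASA and len(heavy) > 3:
            reference = MAX_ASA[res.name]
        else:
            reference = compute_sasa(heavy).total or _DEFAULT_MAX_ASA
        rel = area / reference
        if rel <= exposure_min:
            continue
        if res.name not in scale:
            unknown.add(res.name)
        out[res.key] = scale.get(res.name, 0.0)
    if unknown:
        warnings.warn(
            f"residues {sorted(unknown)} not in scale {scale_name!r}; scored 0",
            stacklevel=2,
        )
    return out


def _sidechain_centroid(res: Residue) -> np.ndarray:
    side = [a for a in res.heavy_atoms()
            if a.name not in ("N", "CA", "C", "O", "OXT")]
    pool = side or res.heavy_atoms()
    return np.mean([a.position for a in pool], axis=0)


def detect_hydrophobic_patches(
    cplx: AnnotatedComplex,
    role: str = "target",
    adjacency_cutoff: float = 6.0,
    hydrophobicity_min: float = 1.0,
    scale_name: str = "kyte_doolittle",
    exposure_min: float = 0.05,
    with_flatness: bool = False,
) -> list[HotspotPatch]:
    """Connected components of exposed hydrophobic residues, largest first.

    Residues are linked when their side-chain centroids lie within
    ``adjacency_cutoff``; patches may span both protomers of a dimer.
    """
    hmap = hydrophobicity_map(cplx, role, scale_name, exposure_min)
    residues, per_res, _ = _residue_sasa(cplx, role)
    member_idx = [
        i for i, res in enumerate(residues)
        if res.key in hmap and hmap[res.key] >= hydrophobicity_min
    ]
    if not member_idx:
        return []
    centroids = np.array([_sidechain_centroid(residues[i]) for i in member_idx])
    dist = cdist(centroids, centroids)
    adj = csr_matrix(dist <= adjacency_cutoff)
    n_comp, labels = connected_components(adj, directed=False)
    patches: list[HotspotPatch] = []
    for comp in range(n_comp):
        idxs = [member_idx[j] for j in range(len(member_idx)) if labels[j] == comp]
        members = [residues[i] for i in idxs]
        area = float(sum(per_res[i] for i in idxs))
        mean_h = float(np.mean([hmap[r.key] for r in members]))
        patch = HotspotPatch(members, area, mean_h)
        if with_flatness and _n_exposed_atoms(patch, cplx, role) >= 4:
            patch.flatness_rmsd = patch_flatness(patch, cplx, role)
        patches.append(patch)
    patches.sort(key=lambda p: -p.exposed_area)
    return patches


def _exposed_atom_coords(
    patch: HotspotPatch, cplx: AnnotatedComplex, role: str
) -> np.ndarray:
    residues, _, per_atom = _residue_sasa(cplx, role)
    keys = {r.key for r in patch.residues}
    coords = []
    i = 0
    for res in residues:
        for a in res.heavy_atoms():
            if res.key in keys and per_atom[i] > 0:
                coords.append(a.position)
            i += 1
    return np.array(coords) if coords else np.zeros((0, 3))


def _n_exposed_atoms(patch: HotspotPatch, cplx: AnnotatedComplex, role: str) -> int:
    return len(_exposed_atom_coords(patch, cplx, role))


def patch_flatness(
    patch: HotspotPatch, cplx: AnnotatedComplex, role: str = "target"
) -> float:
    """RMSD (Å) of the patch's exposed heavy atoms from their best-fit plane."""
    coords = _exposed_atom_coords(patch, cplx, role)
    if len(coords) < 4:
        raise UndefinedResultError(
            f"flatness undefined: patch has {len(coords)} exposed atoms (< 4)")
    centered = coords - coords.mean(axis=0)
    _, s, _ = np.linalg.svd(centered, full_matrices=False)
    # smallest singular value captures out-of-plane spread
    return float(s[2] / np.sqrt(len(coords)))


def assign_heptad(
    sequence: list[str] | str,
    scale_name: str = "kyte_doolittle",
) -> list[str]:
    """Assign heptad letters a..g to a helical sequence.

    ``sequence`` is a list of three-letter codes (or a one-letter string).
    The phase maximizing mean hydrophobicity over a/d positions wins;
    ties break to the earliest phase.
    """
    if isinstance(sequence, str):
        sequence = [ONE_TO_THREE.get(c.upper(), "UNK") for c in sequence]
    if len(sequence) < 7:
        raise ValueError(f"need >= 7 residues, got {len(sequence)}")
    scale = HYDROPHOBICITY_SCALES.get(scale_name)
    if scale is None:
        raise ConfigurationError(f"unknown hydrophobicity scale {scale_name!r}")
    values = np.array([scale.get(r, 0.0) for r in sequence])
    letters = "abcdefg"
    best_phase, best_score = 0, -np.inf
    for phase in range(7):
        pos = (np.arange(len(sequence)) + phase) % 7
        seam = (pos == 0) | (pos == 3)  # a and d
        score = values[seam].mean() if seam.any() else -np.inf
        if score > best_score + 1e-12:
            best_phase, best_score = phase, score
    return [letters[(i + best_phase) % 7] for i in range(len(sequence))]
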