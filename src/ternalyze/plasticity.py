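"""Presenter-protein plasticity across ternary complexes.

The presenter (e.g. an FKBP-family protein) is superposed between two solved
complexes by the Kabsch algorithm on all paired Cα atoms; the per-residue
Cα displacement after superposition profiles backbone plasticity such as
recognition-loop remodeling.  End-to-end chain length uses terminal-triplet
Cα centroids by default, which is robust to terminal disorder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConditioningError, PairingError
from .structure_io import AnnotatedComplex, Residue

__all__ = [
    "DisplacementProfile",
    "kabsch_superpose",
    "displacement_profile",
    "end_to_end_length",
]


@dataclass
class DisplacementProfile:
    displacements: dict[int, float]  # seq_id -> Å
    rmsd_overall: float
    selection: str

    def max_displacement(self) -> tuple[int, float]:
        seq_id = max(self.displacements, key=self.displacements.get)
        return seq_id, self.displacements[seq_id]


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Returns (rotation 3x3, translation 3-vector, rmsd) with the transform
    applied as ``mobile @ R.T + t``.  Reflections are rejected (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise PairingError(
            f"paired Nx3 selections required, got {mobile.shape} vs {reference.shape}")
    n = len(mobile)
    if n < 3:
        raise PairingError(f"need >= 3 atom pairs, got {n}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ConditioningError("selection is collinear; rotation ill-conditioned")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = rc - rot @ mc
    moved = mobile @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, t, rmsd


def _ca_by_seqid(cplx: AnnotatedComplex, role: str) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for res in cplx.residues_with_role(role):
        ca = res.atom("CA")
        if ca is None:
            continue
        if res.seq_id in out:
            raise PairingError(
                f"role {role!r} spans residues with duplicate seq_id "
                f"{res.seq_id}; restrict the role to a single chain")
        out[res.seq_id] = ca.position
    return out


def displacement_profile(
    complex_1: AnnotatedComplex,
    complex_2: AnnotatedComplex,
    role: str = "presenter",
    trim_outliers: bool = False,
    min_pairs: int = 20,
) -> DisplacementProfile:
    """Per-residue Cα displacement of a shared protein between two complexes.

    Residues are paired by author seq_id; superposition is fitted on all
    paired Cα (optionally iteratively trimming >2σ outliers from the fit
    core), then displacement = Cα distance after superposition.
    """
    ca1 = _ca_by_seqid(complex_1, role)
    ca2 = _ca_by_seqid(complex_2, role)
    shared = sorted(set(ca1) & set(ca2))
    if len(shared) < min_pairs:
        raise PairingError(
            f"only {len(shared)} pairable residues (< {min_pairs})")
    p1 = np.array([ca1[i] for i in shared])
    p2 = np.array([ca2[i] for i in shared])
    core = np.ones(len(shared), dtype=bool)
    selection = f"all paired Cα ({role})"
    for _ in range(10 if trim_outliers else 1):
        rot, t, _ = kabsch_superpose(p1[core], p2[core])
        moved = p1 @ rot.T + t
        disp = np.linalg.norm(moved - p2, axis=1)
        if not trim_outliers:
            break
        thresh = disp[core].mean() + 2.0 * disp[core].std()
        new_core = disp <= thresh
        if new_core.sum() < max(3, min_pairs // 2) or np.array_equal(new_core, core):
            break
        core = new_core
        selection = f"trimmed Cα core ({role}, {core.sum()}/{len(shared)})"
    rmsd = float(np.sqrt(np.mean(disp[core] ** 2)))
    return DisplacementProfile(
        displacements={seq: float(d) for seq, d in zip(shared, disp)},
        rmsd_overall=rmsd,
        selection=selection,
    )


def end_to_end_length(
    residues: list[Residue],
    definition: str = "triplet_centroid",
) -> float:
    """Chain end-to-end length (Å) under the named endpoint definition.

    ``triplet_centroid``: distance between the centroids of the first and
    last three ordered Cα atoms.  ``termini``: first-to-last single Cα.
    """
    cas = [r.atom("CA") for r in residues]
    cas = [a.position for a in cas if a is not None]
    if len(cas) < 6:
        raise ValueError(f"need >= 6 residues with Cα, got {len(cas)}")
    if definition == "triplet_centroid":
        start = np.mean(cas[:3], axis=0)
        end = np.mean(cas[-3:], axis=0)
    elif definition == "termini":
        start, end = cas[0], cas[-1]
    else:
        raise ValueError(f"unknown endpoint definition {definition!r}")
    return float(np.linalg.norm(end - start))
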