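"""Synthetic study systems with known ground truth.

Every pipeline stage can be exercised without external downloads:

* parametric two-stranded parallel coiled coils built from a Crick-style
  superhelical parameterization, with a designed heptad registry and
  hydrophobic a/d seam;
* mock presenter-ligand-target ternary complexes whose presenter-target
  contact set is placed by construction, with the ligand either docked
  against the coil or retracted into solvent;
* sphere systems with closed-form (single, pair) or dense Monte Carlo
  oracle SASA;
* replicated spectral-count tables with Poisson background shared across
  conditions and one spiked treated-only protein.

Fixtures use one Cα plus one pseudo-side-chain sphere per residue — enough
geometry for SASA, contact, patch, and registry logic without a rotamer
library.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GeometryError
from .nsaf import SpectralCountTable
from .structure_io import (
    AnnotatedComplex,
    Atom,
    Residue,
    Structure,
    annotate_roles,
    assign_radii,
)

__all__ = [
    "CoilSpec",
    "MockTernarySpec",
    "MockTernaryTruth",
    "SphereFixture",
    "generate_coiled_coil",
    "generate_mock_ternary",
    "generate_sphere_fixture",
    "two_sphere_accessible_area",
    "generate_spectral_counts",
]

HYDROPHOBIC_SEAM_DEFAULT = "LVFL"  # one-letter codes cycled over a/d positions
POLAR_FILLER = ["GLU", "GLN", "LYS", "SER", "ARG", "ASP"]
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
# pseudo-side-chain sphere offset from Cα (Å) by residue bulk
_SIDE_OFFSET = {
    "GLY": 0.0, "ALA": 1.5, "SER": 1.5, "CYS": 1.8, "THR": 1.8, "VAL": 2.0,
    "PRO": 1.8, "ASP": 2.0, "ASN": 2.0, "ILE": 2.3, "LEU": 2.3, "MET": 2.5,
    "GLU": 2.5, "GLN": 2.5, "HIS": 2.5, "LYS": 2.8, "PHE": 2.8, "ARG": 3.0,
    "TYR": 3.0, "TRP": 3.2,
}
_CA_CA = 3.8  # target consecutive Cα distance, Å


@dataclass
class CoilSpec:
    """Parameters of a two-stranded parallel coiled-coil fixture.

    Defaults follow canonical dimeric coiled-coil geometry: superhelix
    radius ~4.9 Å, pitch ~140 Å, minor-helix radius 2.26 Å, 3.5 residues
    per minor-helix turn (exact heptad periodicity).
    """

    n_residues: int = 28
    superhelix_radius: float = 4.9
    superhelix_pitch: float = 140.0
    helix_radius: float = 2.26
    residues_per_turn: float = 3.5
    phase: int = 0            # heptad registry: residue i is letter (i+phase)%7
    seam: str = HYDROPHOBIC_SEAM_DEFAULT
    sequence: list[str] | None = None   # explicit 3-letter codes per position
    start_seq: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 7:
            raise ValueError("n_residues must be >= 7")
        for label, v in (("superhelix_radius", self.superhelix_radius),
                         ("superhelix_pitch", self.superhelix_pitch),
                         ("helix_radius", self.helix_radius)):
            if not v > 0:
                raise ValueError(f"{label} must be > 0")

    def heptad_letter(self, i: int) -> str:
        return "abcdefg"[(i + self.phase) % 7]

    def residue_names(self) -> list[str]:
        if self.sequence is not None:
            if len(self.sequence) != self.n_residues:
                raise ValueError("sequence length != n_residues")
            return list(self.sequence)
        names = []
        seam_codes = [_ONE_TO_THREE[c.upper()] for c in self.seam]
        n_seam = 0
        for i in range(self.n_residues):
            if self.heptad_letter(i) in ("a", "d"):
                names.append(seam_codes[n_seam % len(seam_codes)])
                n_seam += 1
            else:
                names.append(POLAR_FILLER[i % len(POLAR_FILLER)])
        return names


def _coil_backbone(spec: CoilSpec, rise: float, strand_phase: float) -> np.ndarray:
    """Cα trace of one strand for a given rise-per-residue along the axis."""
    t = np.arange(spec.n_residues, dtype=float)
    w0 = 2.0 * np.pi * rise / spec.superhelix_pitch   # superhelical rad/residue
    w1 = 2.0 * np.pi / spec.residues_per_turn          # minor-helix rad/residue
    theta0 = w0 * t + strand_phase
    axis = np.column_stack([
        spec.superhelix_radius * np.cos(theta0),
        spec.superhelix_radius * np.sin(theta0),
        rise * t,
    ])
    tangent = np.column_stack([
        -spec.superhelix_radius * w0 * np.sin(theta0),
        spec.superhelix_radius * w0 * np.cos(theta0),
        np.full_like(t, rise),
    ])
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-np.cos(theta0), -np.sin(theta0),
                              np.zeros_like(t)])  # toward the supercoil axis
    binormal = np.cross(tangent, normal)
    # minor-helix phase offset keeps the a/d seam facing the partner strand
    # for any heptad registry phase
    phi = w1 * (t + spec.phase)
    return axis + spec.helix_radius * (
        np.cos(phi)[:, None] * normal + np.sin(phi)[:, None] * binormal
    )


def generate_coiled_coil(spec: CoilSpec) -> Structure:
    """Two parallel strands (chains A, B) wound about a common z axis.

    The rise per residue is calibrated so consecutive Cα-Cα distances are
    3.8 Å; a/d seam side chains face the partner strand by construction
    (minor-helix phase zero points at the supercoil axis).
    """
    def mean_bond(rise: float) -> float:
        ca = _coil_backbone(spec, rise, 0.0)
        return float(np.mean(np.linalg.norm(np.diff(ca, axis=0), axis=1)))

    lo, hi = 0.05, _CA_CA
    if mean_bond(lo) > _CA_CA or mean_bond(hi) < _CA_CA:
        raise GeometryError(
            "unrealizable coil parameters: cannot calibrate 3.8 Å Cα spacing "
            f"(radius={spec.superhelix_radius}, pitch={spec.superhelix_pitch})")
    rise = brentq(lambda h: mean_bond(h) - _CA_CA, lo, hi, xtol=1e-10)

    names = spec.residue_names()
    residues: list[Residue] = []
    serial = 0
    for chain_id, strand_phase in (("A", 0.0), ("B", np.pi)):
        ca_trace = _coil_backbone(spec, rise, strand_phase)
        # local minor-helix axis points for side-chain direction
        t = np.arange(spec.n_residues, dtype=float)
        w0 = 2.0 * np.pi * rise / spec.superhelix_pitch
        theta0 = w0 * t + strand_phase
        axis = np.column_stack([
            spec.superhelix_radius * np.cos(theta0),
            spec.superhelix_radius * np.sin(theta0),
            rise * t,
        ])
        for i in range(spec.n_residues):
            serial += 1
            atoms = [Atom(serial=serial, name="CA", element="C",
                          position=ca_trace[i])]
            offset = _SIDE_OFFSET.get(names[i], 2.0)
            if offset > 0:
                if spec.heptad_letter(i) in ("a", "d"):
                    # knobs-into-holes: seam side chains pack toward the
                    # dimer core, stopping short of the supercoil axis so
                    # they stay partially solvent-exposed
                    core = np.array([0.0, 0.0, ca_trace[i][2]])
                    direction = core - ca_trace[i]
                    gap = np.linalg.norm(direction)
                    offset = min(offset, max(gap - 1.4, 0.5))
                else:
                    direction = ca_trace[i] - axis[i]
                direction /= np.linalg.norm(direction)
                serial += 1
                atoms.append(Atom(serial=serial, name="CB", element="C",
                                  position=ca_trace[i] + offset * direction))
            residues.append(Residue(
                chain_id=chain_id,
                seq_id=spec.start_seq + i,
                name=names[i],
                atoms=atoms,
            ))
    structure = Structure(residues=residues, name="synthetic-coiled-coil")
    assign_radii(structure)
    return structure


@dataclass
class MockTernarySpec:
    """Mock ternary complex: coil target + designed presenter contacts + ligand."""

    coil: CoilSpec = field(default_factory=CoilSpec)
    contacts: list[tuple[str, int]] = field(
        default_factory=lambda: [("A", 9), ("A", 13), ("B", 10), ("B", 16), ("A", 20)]
    )  # (target chain, target seq_id) each touched by one presenter residue;
    # defaults sit on outward-facing (non-seam) heptad positions
    n_presenter_extra: int = 20   # non-contacting presenter bulk atoms
    n_ligand_atoms: int = 6
    contact_distance: float = 3.4  # Å, designed heavy-atom contact distance
    ligand_gap: float = 0.0        # extra retraction of the ligand (Å)
    seed: int = 0


@dataclass
class MockTernaryTruth:
    contacts: set[tuple[int, str, int]]  # (presenter seq_id, target chain, target seq_id)
    ligand_docked: bool


def _outward_direction(res: Residue) -> np.ndarray:
    ca = res.atom("CA")
    cb = res.atom("CB")
    if ca is None:
        raise GeometryError(f"{res.label} lacks CA")
    if cb is None:
        d = ca.position.copy()
        d[2] = 0.0
        n = np.linalg.norm(d)
        if n < 1e-6:
            raise GeometryError(f"{res.label} on the supercoil axis")
        return d / n
    d = cb.position - ca.position
    return d / np.linalg.norm(d)


def generate_mock_ternary(
    spec: MockTernarySpec,
) -> tuple[AnnotatedComplex, MockTernaryTruth]:
    """Build the mock complex and emit its ground truth.

    Each designed contact is realised by one single-atom presenter residue
    placed ``contact_distance`` beyond the target residue's side-chain
    sphere surface gap along its outward direction; the remaining presenter
    bulk sits on a lattice 18 Å out.  The ligand chain is a short atom run
    docked against the first contact residue (or retracted by
    ``ligand_gap``).  The construction is validated: a designed contact atom
    within 4 Å of an undesigned target residue raises GeometryError.
    """
    rng = np.random.default_rng(spec.seed)
    coil = generate_coiled_coil(spec.coil)
    chains = coil.chains()
    residues = list(coil.residues)
    serial = max(a.serial for a in coil.atoms())

    by_key = {(r.chain_id, r.seq_id): r for r in coil.residues}
    truth_contacts: set[tuple[int, str, int]] = set()
    presenter_residues: list[Residue] = []
    contact_positions = []
    outward_dirs = []
    pseq = 1
    for chain_id, seq_id in spec.contacts:
        if (chain_id, seq_id) not in by_key:
            raise GeometryError(f"designed contact {chain_id}/{seq_id} not in coil")
        tres = by_key[(chain_id, seq_id)]
        anchor = tres.atom("CB") or tres.atom("CA")
        u = _outward_direction(tres)
        pos = anchor.position + spec.contact_distance * u
        serial += 1
        presenter_residues.append(Residue(
            chain_id="P", seq_id=pseq, name="ALA",
            atoms=[Atom(serial=serial, name="CA", element="C", position=pos)],
        ))
        truth_contacts.add((pseq, chain_id, seq_id))
        contact_positions.append(pos)
        outward_dirs.append(u)
        pseq += 1

    # validate: each contact atom within 4 Å of its designed residue only
    for (pseq_i, chain_id, seq_id), pos in zip(sorted(truth_contacts),
                                               contact_positions):
        for res in coil.residues:
            dmin = min(np.linalg.norm(a.position - pos)
                       for a in res.heavy_atoms())
            designed = (res.chain_id, res.seq_id) == (chain_id, seq_id)
            if designed and dmin > 4.0:
                raise GeometryError(
                    f"designed contact P/{pseq_i} ~ {res.label} at {dmin:.2f} Å")
            if not designed and dmin <= 4.0:
                raise GeometryError(
                    f"contact design infeasible: P/{pseq_i} also touches "
                    f"{res.label} ({dmin:.2f} Å)")

    # presenter bulk: lattice blob well clear of the target
    coil_xyz = coil.coordinates()
    center = np.array([
        coil_xyz[:, 0].max() + 22.0, 0.0, coil_xyz[:, 2].mean()])
    side = int(np.ceil(spec.n_presenter_extra ** (1 / 3)))
    offsets = [(i, j, k) for i in range(side) for j in range(side)
               for k in range(side)][: spec.n_presenter_extra]
    for (i, j, k) in offsets:
        serial += 1
        jitter = rng.uniform(-0.3, 0.3, 3)
        pos = center + 4.0 * (np.array([i, j, k], dtype=float)
                              - (side - 1) / 2.0) + jitter
        presenter_residues.append(Residue(
            chain_id="P", seq_id=pseq, name="ALA",
            atoms=[Atom(serial=serial, name="CA", element="C", position=pos)],
        ))
        pseq += 1

    # ligand: short run of hetero atoms against the first designed contact
    lig_chain, lig_seq = spec.contacts[0]
    lres = by_key[(lig_chain, lig_seq)]
    anchor = (lres.atom("CB") or lres.atom("CA")).position
    u = _outward_direction(lres)
    tangent = np.cross(u, [0.0, 0.0, 1.0])
    tangent /= np.linalg.norm(tangent)
    # lifted along z so the ligand run clears the presenter contact atom
    base = (anchor + (spec.contact_distance + spec.ligand_gap) * u
            + np.array([0.0, 0.0, 3.0]))
    lig_atoms = []
    for i in range(spec.n_ligand_atoms):
        serial += 1
        lig_atoms.append(Atom(
            serial=serial, name=f"C{i + 1}", element="C",
            position=base + 1.5 * i * tangent + 0.8 * (i % 2) * u,
            is_hetero=True,
        ))
    ligand_residue = Residue(chain_id="L", seq_id=1, name="LIG", atoms=lig_atoms)

    structure = Structure(
        residues=residues + presenter_residues + [ligand_residue],
        name="mock-ternary",
    )
    assign_radii(structure)
    cplx = annotate_roles(
        structure,
        {"target": sorted(chains), "presenter": ["P"], "ligand": ["L"]},
        name="mock-ternary",
    )
    return cplx, MockTernaryTruth(
        contacts=truth_contacts,
        ligand_docked=spec.ligand_gap < 2.0,
    )


def two_sphere_accessible_area(
    r1: float, r2: float, d: float, probe: float = 1.4
) -> float:
    """Closed-form accessible area of two intersecting probe-expanded spheres.

    Each sphere loses the spherical cap cut off by the radical plane of the
    intersection circle: buried cap area on sphere i is 2·π·R_i·h_i with
    h_i = R_i − x_i, x_1 = (d² + R_1² − R_2²) / 2d, x_2 = d − x_1.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4.0 * np.pi * (R1 ** 2 + R2 ** 2)
    if d <= abs(R1 - R2):
        return 4.0 * np.pi * max(R1, R2) ** 2
    x1 = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    x2 = d - x1
    a1 = 4.0 * np.pi * R1 * R1 - 2.0 * np.pi * R1 * (R1 - x1)
    a2 = 4.0 * np.pi * R2 * R2 - 2.0 * np.pi * R2 * (R2 - x2)
    return a1 + a2


def monte_carlo_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_samples: int = 40000,
    seed: int = 0,
) -> float:
    """Dense random-direction sampling SASA oracle (O(N²), seeded).

    Independent of the production path: sample directions are drawn from a
    seeded normal distribution rather than the deterministic spiral, and
    occlusion is a brute-force all-pairs test.
    """
    rng = np.random.default_rng(seed)
    expanded = radii + probe
    total = 0.0
    n = len(coords)
    for i in range(n):
        dirs = rng.normal(size=(n_samples, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * dirs
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= expanded[j] ** 2
        total += 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return float(total)


@dataclass
class SphereFixture:
    atoms: list[Atom]
    expected_area: float
    kind: str
    is_analytic: bool


def generate_sphere_fixture(kind: str = "single", seed: int = 0,
                            probe: float = 1.4) -> SphereFixture:
    """Toy atom systems with closed-form or Monte Carlo oracle SASA."""
    def mk(positions, radii):
        return [Atom(serial=i + 1, name="X", element="C", position=p,
                     vdw_radius=r)
                for i, (p, r) in enumerate(zip(positions, radii))]

    if kind == "single":
        atoms = mk([[0.0, 0.0, 0.0]], [1.7])
        return SphereFixture(atoms, 4.0 * np.pi * (1.7 + probe) ** 2,
                             kind, True)
    if kind == "pair":
        atoms = mk([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]], [1.7, 1.7])
        return SphereFixture(
            atoms, two_sphere_accessible_area(1.7, 1.7, 2.0, probe), kind, True)
    if kind == "triad":
        positions = np.array([[0.0, 0.0, 0.0], [2.4, 0.0, 0.0],
                              [1.2, 2.1, 0.0]])
        radii = np.array([1.7, 1.55, 1.52])
        atoms = mk(positions, radii)
        return SphereFixture(
            atoms, monte_carlo_sasa(positions, radii, probe, seed=seed),
            kind, False)
    if kind.startswith("random-"):
        n = int(kind.split("-", 1)[1])
        rng = np.random.default_rng(seed)
        positions = rng.uniform(0.0, 8.0, size=(n, 3))
        radii = rng.choice([1.52, 1.55, 1.70, 1.80], size=n)
        atoms = mk(positions, radii)
        return SphereFixture(
            atoms, monte_carlo_sasa(positions, radii, probe, seed=seed + 1),
            kind, False)
    raise ValueError(f"unknown sphere fixture kind {kind!r}")


def generate_spectral_counts(
    n_proteins: int = 200,
    n_reps: int = 3,
    spike_index: int | None = 0,
    spike_mean: float = 50.0,
    background_rate: float = 5.0,
    seed: int = 0,
    treated: str = "treated",
    control: str = "control",
) -> SpectralCountTable:
    """Replicated count table: shared Poisson background + treated-only spike.

    Background proteins draw i.i.d. Poisson(``background_rate``) counts in
    both conditions; the spiked protein draws Poisson(``spike_mean``) in
    treated replicates and is absent from controls.  Lengths are uniform on
    100-2,500 residues.
    """
    if n_proteins < 2:
        raise ValueError("n_proteins must be >= 2")
    if not background_rate > 0:
        raise ValueError("background_rate must be > 0")
    if spike_index is not None and not 0 <= spike_index < n_proteins:
        raise ValueError(f"spike index {spike_index} out of range")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(100, 2501, size=n_proteins)
    data = {
        "protein": [f"P{i:04d}" for i in range(n_proteins)],
        "length": lengths,
    }
    t_cols = [f"{treated}_{r + 1}" for r in range(n_reps)]
    c_cols = [f"{control}_{r + 1}" for r in range(n_reps)]
    for col in t_cols + c_cols:
        data[col] = rng.poisson(background_rate, size=n_proteins)
    if spike_index is not None:
        for col in t_cols:
            data[col][spike_index] = rng.poisson(spike_mean)
        for col in c_cols:
            data[col][spike_index] = 0
    return SpectralCountTable(
        pd.DataFrame(data), conditions={treated: t_cols, control: c_cols})
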