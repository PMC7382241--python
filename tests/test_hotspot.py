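import numpy as np
import pytest

from ternalyze.errors import ConfigurationError, UndefinedResultError
from ternalyze.hotspot import (
    HotspotPatch,
    assign_heptad,
    detect_hydrophobic_patches,
    hydrophobicity_map,
    patch_flatness,
)
from ternalyze.structure_io import Atom, Residue, Structure, annotate_roles, assign_radii
from ternalyze.synthetic import CoilSpec, generate_coiled_coil


class TestHydrophobicityMap:
    def test_exposed_leucines_share_scale_value(self, seam_coil_complex):
        hmap = hydrophobicity_map(seam_coil_complex, "target")
        leu_values = {
            hmap[r.key]
            for r in seam_coil_complex.residues_with_role("target")
            if r.name == "LEU" and r.key in hmap
        }
        assert leu_values == {3.8}

    def test_unknown_residue_scores_zero_with_warning(self):
        st = Structure(residues=[
            Residue(chain_id="T", seq_id=i + 1, name=name, atoms=[
                Atom(serial=i + 1, name="CA", element="C",
                     position=np.array([4.0 * i, 0, 0]))])
            for i, name in enumerate(["XYZ", "LEU"])
        ])
        assign_radii(st)
        cplx = annotate_roles(st, {"target": ["T"]})
        with pytest.warns(UserWarning, match="XYZ"):
            hmap = hydrophobicity_map(cplx, "target")
        assert hmap[("T", 1, "")] == 0.0

    def test_unknown_scale_rejected(self, seam_coil_complex):
        with pytest.raises(ConfigurationError):
            hydrophobicity_map(seam_coil_complex, "target", "no_scale")

    def test_phe_outranks_gln(self, seam_coil_complex):
        hmap = hydrophobicity_map(seam_coil_complex, "target")
        by_name = {}
        for r in seam_coil_complex.residues_with_role("target"):
            if r.key in hmap:
                by_name.setdefault(r.name, hmap[r.key])
        assert by_name["PHE"] > by_name["GLN"]


class TestPatchDetection:
    def test_designed_seam_forms_single_patch(self, seam_coil_complex):
        patches = detect_hydrophobic_patches(seam_coil_complex, "target")
        assert len(patches) == 1
        seam_ids = {1, 4, 8, 11, 15, 18, 22, 25}
        assert patches[0].seq_ids == seam_ids
        chains = {r.chain_id for r in patches[0].residues}
        assert chains == {"A", "B"}  # spans both protomers

    def test_all_polar_coil_has_no_patches(self):
        coil = generate_coiled_coil(CoilSpec(seam="SS"))
        cplx = annotate_roles(coil, {"target": ["A", "B"]})
        assert detect_hydrophobic_patches(cplx, "target") == []

    def test_every_member_in_exactly_one_patch(self, seam_coil_complex):
        patches = detect_hydrophobic_patches(seam_coil_complex, "target")
        hmap = hydrophobicity_map(seam_coil_complex, "target")
        members = [k for k, v in hmap.items() if v >= 1.0]
        assigned = [r.key for p in patches for r in p.residues]
        assert sorted(assigned) == sorted(members)

    def test_rigid_motion_invariance(self, seam_coil_complex):
        from scipy.spatial.transform import Rotation

        patches_before = detect_hydrophobic_patches(seam_coil_complex, "target")
        flat_before = patch_flatness(patches_before[0], seam_coil_complex, "target")
        coil2 = generate_coiled_coil(CoilSpec())
        rot = Rotation.from_euler("zyx", [31, -12, 77], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        for atom in coil2.atoms():
            atom.position = rot @ atom.position + shift
        cplx2 = annotate_roles(coil2, {"target": ["A", "B"]})
        patches_after = detect_hydrophobic_patches(cplx2, "target")
        assert [p.seq_ids for p in patches_after] == [
            p.seq_ids for p in patches_before]
        flat_after = patch_flatness(patches_after[0], cplx2, "target")
        assert flat_after == pytest.approx(flat_before, abs=1e-6)


class TestFlatness:
    def single_atom_residues(self, coords):
        residues = [
            Residue(chain_id="T", seq_id=i + 1, name="LEU", atoms=[
                Atom(serial=i + 1, name="CA", element="C", position=c)])
            for i, c in enumerate(coords)
        ]
        st = assign_radii(Structure(residues=residues))
        return annotate_roles(st, {"target": ["T"]})

    def test_coplanar_points_score_zero(self):
        coords = [np.array([x, y, 0.0]) for x in range(4) for y in range(3)]
        coords = [c * 4.0 for c in coords]
        cplx = self.single_atom_residues(coords)
        patch = HotspotPatch(cplx.structure.residues, 1.0, 3.8)
        assert patch_flatness(patch, cplx, "target") == pytest.approx(0.0, abs=1e-9)

    def test_sphere_cap_matches_second_moment(self):
        # cap of radius 10 Å, half-angle 30°: area-uniform sampling means z
        # uniform on [R cos a, R]; best plane is z = mean, so
        # RMSD -> R(1 - cos a)/sqrt(12)
        R, alpha = 10.0, np.radians(30.0)
        n = 400
        golden = np.pi * (1 + np.sqrt(5.0))
        i = np.arange(n) + 0.5
        z = R * np.cos(alpha) + (R - R * np.cos(alpha)) * i / n
        theta = golden * i
        rho = np.sqrt(R**2 - z**2)
        coords = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
        cplx = self.single_atom_residues(list(coords))
        patch = HotspotPatch(cplx.structure.residues, 1.0, 3.8)
        expected = R * (1 - np.cos(alpha)) / np.sqrt(12.0)
        assert patch_flatness(patch, cplx, "target") == pytest.approx(
            expected, rel=0.05)

    def test_degenerate_patch_rejected(self):
        cplx = self.single_atom_residues(
            [np.array([4.0 * i, 0, 0]) for i in range(3)])
        patch = HotspotPatch(cplx.structure.residues, 1.0, 3.8)
        with pytest.raises(UndefinedResultError):
            patch_flatness(patch, cplx, "target")


class TestHeptad:
    @pytest.mark.parametrize("phase", range(7))
    def test_recovers_generator_registry(self, phase):
        spec = CoilSpec(phase=phase)
        names = spec.residue_names()
        letters = assign_heptad(names)
        expected = [spec.heptad_letter(i) for i in range(len(names))]
        assert letters == expected

    def test_uniform_sequence_tie_breaks_to_phase_zero(self):
        letters = assign_heptad(["LEU"] * 14)
        assert letters[:7] == list("abcdefg")

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            assign_heptad(["LEU"] * 6)
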