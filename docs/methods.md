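# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic benchmarks do and do not demonstrate about
real crystallographic data.

## Structure model and radii

Structures parse through gemmi (PDB and mmCIF) into a minimal hierarchy of
atoms, residues and chains keyed by **author numbering**, so residue labels
in reports match the crystallographic literature (Leu2190, not a renumbered
index). Alternate locations collapse to the highest-occupancy conformer;
zero-occupancy atoms, waters and common ions/cryoprotectants are dropped by
default (flags retain them).

Van der Waals radii are assigned per element from a named table; the
default `naccess` set uses the united-atom values C 1.70, N 1.55, O 1.52,
S 1.80 Å. Published interface-area figures rarely state the radii set or
probe used, so the set name, probe radius and point count are recorded in
every report, and agreement with literature "∼" values should be expected
only to within a few percent. Crystal structures usually lack hydrogens;
all SASA, contact and hydrogen-bond computations therefore operate on heavy
atoms only, and the hydrogen-bond criterion is a heavy-atom geometric rule
(donor–acceptor ≤ 3.5 Å; antecedent–donor–acceptor angle ≥ 120° whenever a
covalently bonded heavy antecedent exists within 1.8 Å). Ligand
donor/acceptor atoms and aromatic rings have no standard typing, so both
are supplied through small editable dictionaries.

## SASA and buried-surface-area conventions

SASA is Shrake–Rupley: a deterministic golden-spiral set of test points
(default 960) on each probe-expanded sphere (probe 1.4 Å), occlusion tested
against k-d-tree neighbours. At 960 points the total differs from a
4,000-point computation by well under 0.5 % on all fixtures, and single-
and two-sphere systems match the closed-form spherical-cap areas to ≈0.05 %.

Buried surface area is the **two-sided** quantity
SASA(A) + SASA(B) − SASA(A∪B) — the convention under which typical
protein–protein interfaces span 1,500–3,000 Å². For a ternary complex the
reported partition is the pairwise-subcomplex decomposition: the
ligand→target term is BSA(ligand, target) with presenter atoms removed from
the coordinate frame, and symmetrically for the presenter term. Burial is
not additive — atoms occluded by both partners are counted in both pairwise
terms — so the additivity residual
|ligand_target + presenter_target − total| is always reported rather than
silently absorbed. On the mock ternary fixture the residual is ≈8 % of the
total. The unit of analysis for symmetric crystals (two presenter–ligand
units flanking one coiled-coil dimer) is a single binary unit against the
full dimer, extracted by `reference.binary_unit_versus_target`.

## Hotspots, flatness and heptad registry

Hydrophobicity uses the Kyte–Doolittle scale with patch membership at
scale ≥ 1.0 (the threshold that includes Ala and everything more
hydrophobic). A residue counts as surface when its relative SASA exceeds
0.05; the reference area is the theoretical Gly-X-Gly maximum for full-atom
residues, but for reduced pseudo-residue models (≤ 3 spheres) the residue's
own isolated-atom area is used instead — a full-residue reference would
misclassify reduced residues whose pseudo-spheres can never reach it.
Patches are connected components under side-chain-centroid adjacency
≤ 6.0 Å, deliberately permissive enough to bridge the two protomers of a
dimeric coiled coil, as real interface hotspots do. Flatness is the RMSD
of the patch's exposed heavy atoms from their total-least-squares plane
(smallest singular value of the centered coordinates over √n); it is
rigid-motion invariant by construction and validated against the
closed-form second moment of a spherical cap.

Heptad registry maximizes mean hydrophobicity over the a/d positions
across the seven possible phases, breaking ties toward the earliest phase;
on generated coils it recovers the designed registry for every phase.

## Presenter plasticity

Superposition is the Kabsch algorithm with the reflection guard
(det = +1); collinear selections are rejected as ill-conditioned.
Displacement profiles pair residues by author seq_id (the natural pairing
for one presenter protein solved in several complexes; roles spanning
duplicate numbering are rejected with guidance to select one chain), fit on
**all** paired Cα by default, and report per-residue Cα distances after
superposition. An optional trim mode iteratively excludes >2σ outliers
from the fit core, since published displacement figures rarely state their
fitting core; both selections are recorded in the output. End-to-end
length defaults to the distance between centroids of the first and last
three ordered Cα ("triplet centroid"), which is robust to terminal
disorder; a single-atom terminus definition is available, and because
published end-to-end figures depend strongly on the endpoint convention the
definition string is part of the result.

## Ternary equilibrium model

The core model is minimal and sequential: P + L ⇌ PL (K₁),
PL + T ⇌ PLT (K₂), excluding direct ligand–target binding because
compound-alone engagement is not observed for presenter-dependent
molecules. The coupled mass balances reduce to nested strictly monotone
one-dimensional root problems solved by Brent bracketing on the physical
intervals, which cannot diverge; returned states carry explicit residuals,
all ≤ 10⁻⁹ relative. The solution is checked against an independent
log-grid brute-force minimizer in the tests.

Two optional arms extend the model without changing the default:
a competitor pocket binder (P + C ⇌ PC, K₃) for chemical-reversal
experiments, and a direct L + T ⇌ LT arm (K_LT, default infinite). A
consequence worth stating plainly: **the default two-step model cannot
produce a hook effect** — ternary occupancy is monotone non-decreasing in
total ligand and plateaus, because every bound target arrives via PL. The
bell-shaped hook requires the ligand to saturate both proteins separately,
i.e. a finite K_LT; the titration tests assert the plateau for the default
model and the hook in the finite-K_LT regime.

## NSAF scoring

NSAF_i = (SpC_i / L_i) / Σ_j (SpC_j / L_j) per replicate, summing to 1 by
construction (any display scaling such as ×10⁵ is cosmetic and recorded).
Candidate calling is the reproducible presence rule — detected in ≥ 3
treated replicates, ≤ 0 total control counts, ranked by mean treated
NSAF — mirroring how affinity-enrichment hits are called when a target
appears only in treated samples. Published per-protein NSAF magnitudes
depend on an unreported scale factor, so only the formula, normalization
and calling logic are asserted, never a specific display value.

## Synthetic generators: what they emulate, and what they don't

The coiled-coil generator uses a Crick-style superhelical parameterization
(defaults: superhelix radius 4.9 Å, pitch 140 Å, minor-helix radius
2.26 Å, 3.5 residues per turn — canonical dimeric values) with the rise
per residue calibrated by root-finding so consecutive Cα distances are
3.8 ± 0.1 Å. Each residue is one Cα sphere plus one pseudo-side-chain
sphere offset by residue bulk; seam (a/d) side chains point into the dimer
core knobs-into-holes fashion, stopping 1.4 Å short of the axis so they
remain partially exposed. Mock ternary complexes place one single-atom
presenter residue 3.4 Å outside each designed target residue, a presenter
bulk lattice 22 Å clear of the coil, and a short hetero-atom ligand run
either docked against the coil or retracted into solvent; the construction
validates that designed contacts (and only those) fall within the 4.0 Å
cutoff and raises a geometry error for infeasible designs (e.g. contacts
on core-facing seam positions).

These fixtures exercise the full geometric logic — occlusion, burial,
adjacency, connectivity, superposition — but they are geometric, not
physical: no full side chains, no rotamers, no energies, no crystallographic
noise. Passing them demonstrates algorithmic correctness and internal
consistency, not agreement with any particular deposited structure; the
real-structure workflow in `ternalyze.reference` exists for that purpose
and requires the user to supply the coordinate files under
`data/structures/`.

Spectral-count tables draw i.i.d. Poisson(5) background counts shared
across conditions, a Poisson(50) treated-only spike, and lengths uniform on
100–2,500 residues — three replicates per condition, matching common
affinity-proteomics designs. Real data have correlated backgrounds and
carry-over peptides that the presence rule handles less cleanly; the
spiked-recovery benchmark (rank 1 in ≥ 95 % of seeds) measures the rule
under the idealized background only.

## Problem sizes and determinism

Test and acceptance workloads use small systems chosen for rapid iteration:
28-residue-per-strand coils (112 atoms), ~140-atom mock complexes,
20-sphere SASA oracles with 40,000-sample Monte Carlo references, 100
random equilibrium systems and 20–40 spectral-count seeds. Every stochastic
component flows from an explicit seed; all generators are bit-reproducible
under a fixed seed.
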