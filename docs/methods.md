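# Methods

`wulffgraft` builds an atomistic model of a polysaccharide-coated
magnetite nanoparticle (a gum-arabic-type coat on an Fe3O4 core), places
it above a DPPC bilayer in water, and provides the geometric analyses a
study of such a system needs: hydrogen-bond statistics between the sugar
coat and the lipid headgroups, the NP–membrane approach distance, and the
ROI-based MRI formulas used to evaluate the particle as a contrast agent.
This note records the models, the defaults and why, and what the
synthetic data do and do not establish.

## Crystal core

The conventional magnetite cell is an inverse spinel (Fd-3m, a = 8.3958 Å)
with Fe on the tetrahedral 8a and octahedral 16d Wyckoff sites and O on
32e; symmetry expansion gives 24 Fe + 32 O per cell (Z = 8). Expansion is
done with gemmi's space-group algebra; symmetry-equivalent positions are
merged at 10⁻³ Å — far below any interatomic distance, so the tolerance
cannot merge distinct atoms. A file without usable symmetry is an error
rather than a silent P1 fallback, because P1 on a symmetric asymmetric
unit silently corrupts the stoichiometry; `allow_p1_fallback=True` makes
the choice explicit.

The equilibrium particle shape is the Wulff construction: every facet
family {hkl} contributes half-spaces n·r ≤ d with d ∝ γ(hkl), and the
particle is the bounded intersection. Facet families expand through the
cell's point group ({100} → 6 planes, {111} → 8). Default energies are
γ(100) = 1.0, γ(111) = 1.15 — a documented, overridable ratio chosen to
give a cube with truncated corners ({111} planes cut the cube corners
whenever γ(111)/γ(100) < √3); no ab initio energies are computed. The
shape is scaled so the face-to-face extent along the lowest-γ normal
equals the target diameter (3 nm default). "Diameter" is face-to-face
extent, not a vertex–vertex diagonal, which is the natural reading for a
cube-like particle.

Vertices and faces come from `scipy.spatial.HalfspaceIntersection`;
boundedness is pre-checked by linear programming in the six axis
directions, so an open facet set fails with a geometry error instead of a
Qhull crash. Carving keeps exactly the bulk atoms satisfying every
half-space inequality, boundary atoms included (≤, not <): the rule is
deterministic and reproducible by a one-line per-atom filter, which the
tests use as an oracle. The supercell replication is auto-expanded until
the shape fits (a 3-nm shape needs 4×4×4 of the 8.4-Å cell) and the
expansion is logged.

The carved 3-nm core measures 2.947 nm atom-to-atom along <100>: the
lattice quantizes the extent to atomic planes spaced a/8 ≈ 0.105 nm, so
the atomistic extent sits within one plane spacing below the geometric
3-nm envelope. The acceptance checks use exactly this tolerance.

## Surface classification and grafting sites

Fe sites are classified by O-neighbour count within 2.35 Å (between the
Fe–O bond at ~1.9–2.1 Å and the next shell): 6 → octahedral, 4 →
tetrahedral. Surface atoms necessarily lose neighbours, so an
undercoordinated surface Fe inherits the bulk class of its
crystallographic site label (16d → octahedral); without this rule no
surface atom would ever count as octahedral and grafting would be
impossible. Surface membership means lying within a skin (1.5 Å default)
of a boundary facet plane; the outward normal is the generating face
normal, averaged at edges and corners.

Grafting sites are chosen among surface octahedral Fe by deterministic
farthest-point sampling: the seed picks the first site by index order,
and each subsequent site maximizes its minimum distance to the chosen
set (ties to the lowest atom id). Both a chain count (N = 64 default) and
a target density (chains/nm², converted through the Wulff polyhedron
surface area) are supported. For the default build the two conventions
disagree in the source numbers (64 chains vs 3 chains/nm²: 64 chains on
the 42.4-nm² truncated cube is 1.51 chains/nm²); the build takes N = 64
as primary and *reports* the realized density rather than silently
reconciling them.

## Polysaccharide chains

The coat composition is L-arabinose : D-galactose : L-rhamnose :
D-glucuronic acid = 3:3:1:1. Composition alone does not fix a linkage
topology, so the builder adopts a documented gum-arabic-like default: a
1→4-linked backbone repeat of three galactoses plus one glucuronate, each
backbone residue carrying one 1→3-linked single-residue branch (arabinose
on the galactoses, rhamnose on the glucuronate). Every 8-residue repeat
realizes the 3:3:1:1 ratio exactly.

Monomer templates are idealized ⁴C₁-like pyranose and furanose rings with
literature-standard bond lengths (C–C 1.52, C–O 1.43, O–H 0.96, C–H
1.09 Å), shipped as versioned JSON fixtures with coordinates, bonds,
partial charges and link bookkeeping in one authoritative file each
(checksums in a manifest; `fixtures regen` rebuilds them from the
geometry code). Charges are built from electroneutral groups (hydroxyl
−0.42/+0.42, C–H ±0.09, ring-O triads) so each residue sums exactly to
its formal charge; glucuronate is modelled ionized (−1) by default. These
are simplified placeholder magnitudes, not force-field charges — the
arithmetic invariants (integer molecular totals that survive link
formation) are what the package guarantees.

Chain geometry: the polymerization degree is the smallest repeat count
whose fully extended length reaches the 6.5-nm target (three repeats, 24
residues, for the default), and the end-to-end length — root attachment
atom to the most distal backbone atom — is then tuned to the target by a
uniform ±θ zig-zag tilt of the glycosidic segments, solved by bisection
to machine precision. The tilt plays the role of glycosidic torsion
adjustment; residue spins about their own glycosidic axes leave the
backbone trace (and hence the solved length) unchanged, which is what
makes the later clash resolution length-safe. Glycosidic condensation is
modelled explicitly: the child loses its anomeric hydroxyl, the parent
link oxygen loses its proton and becomes the bridging ether.

Attachment bonds the chain's deprotonated anomeric oxygen to a surface
Fe at 1.95 Å. At 64 chains the brush is dense: neighbouring lattice sites
sit 5.9 Å apart while a chain's arms reach several Å off-axis, so rigid
parallel placement is geometrically impossible. Three deterministic
mechanisms make the packing feasible, in escalating order: (1) chains
fan out radially from the particle centre, so neighbours diverge
linearly with height; (2) a spin (15°) and small-tilt (≤18°) scan about
the grafting axis, plus a set of equal-length conformer variants with
different branch-arm helical pitch; (3) flexible refinement, re-spinning
individual residues of the incoming chain against the already-grafted
environment. The build fails loudly (placement error) if a site still
cannot clear the 0.9-Å minimum-distance floor; the default build clears
it at every site, and the assembled particle's global minimum pair
distance is checked in the report. The 0.9-Å floor is an
overlap-exclusion sanity bound, not a van-der-Waals contact distance — a
grafted brush this dense is expected to interdigitate, and an energy
minimization in any MD engine would relax the remaining close contacts.

## Topology and charges

Bonds are inputs (template bonds, glycosidic links, Fe–O links, and
optionally the magnetite core as an Fe–O bonded network within 2.35 Å;
a config switch leaves the core bond-free for restrained/frozen-core
setups). Angles are all simple paths of length two, proper dihedrals all
simple paths of length three with four distinct atoms; both are stored
lexicographically-smaller-endpoint-first, so shuffled bond input yields
an identical canonical topology, and paths traversing a central bond in
both directions deduplicate. Improper dihedrals are out of scope. The
angle count obeys Σ_v C(deg v, 2) exactly, which the tests assert against
an exhaustive path-search oracle.

Charge assignment is a scheme lookup: ligand atoms carry template
charges; magnetite uses bulk-neutral placeholders (Fe +1.2, O −0.9 for
the 3:4 lattice — the values a real simulation would take from its force
field); water is TIP3P (−0.834/+0.417); DPPC is zwitterionic (choline
+1, phosphate −1). A carved particle is not 3:4 stoichiometric, so the
core carries a net scheme charge that is reported, not hidden.

## Membrane and solvation

The bilayer is a tetragonal near-square grid: exactly N lipids per
leaflet at 0.63 nm² per lipid (fluid-phase DPPC convention; the source
gives none), tails inward, phosphate planes 3.8 nm apart, bilayer normal
on z. The DPPC template is an all-atom fixture with CHARMM-style names;
its phosphate ({P, O11–O14}) and choline ({N, C11–C15}) groups are the
acceptor groups of the analysis stage.

Solvation tiles rigid TIP3P-geometry waters (O–H 0.9572 Å, H–O–H 104.52°)
at the bulk number density 33.4 nm⁻³; per-axis lattice counts are chosen
to best match density × volume, so even small boxes land within a few
per cent of bulk density. Waters whose O lies within 2.4 Å of a solute
heavy atom, or inside the hydrophobic slab between the phosphate planes,
are removed. Orientations are drawn from the seed, so solvation is
reproducible bit-for-bit.

Assembly places the NP above the upper leaflet with the minimum
NP-atom-to-phosphate-plane distance equal to the requested gap (5 Å
default) and 1 nm of solvent padding. The component index (NP / lipid /
water id sets) partitions the system exactly. The assembled default
system comes to ~717k atoms; the total depends on box padding choices
that the source does not state, so the build logs its own total and
asserts nothing about it.

## Hydrogen-bond analysis

A bond is counted when the donor heavy atom D (with a covalently attached
H) and acceptor A satisfy D–A ≤ cutoff and the D–H···A angle at the
hydrogen ≥ a minimum. Defaults: OH···O 3.5 Å / 150°; CH···O 3.8 Å / 130°,
looser because the carbon-donor hydrogen bond is weaker and less
directional. No cutoffs are stated in the source; these are standard
geometric criteria and both are configurable. CH···O records appear only
when that criteria set is enabled, so disabling it can only lower any
summary cell — a monotonicity the tests assert.

Summaries aggregate per (donor residue type, acceptor group) cell: the
time-averaged bond count per frame, the same normalized per residue of
that type, and a block-averaged standard error (5 blocks default).
Detection is KD-tree accelerated but defined exactly as the O(N²)
all-pairs scan the tests compare against.

The NP–membrane approach metric is the signed minimum z-distance from NP
atoms to the mean phosphate plane; negative values mean penetration.

## Imaging formulas

SNR = 0.655 × ROI_tumor / averageROI_background, where
averageROI_background is the mean of the per-ROI means (not the pooled
pixel mean). CNR = SNR_pre − SNR_post with the sign kept exactly as the
printed formula despite its counterintuitive direction; the magnitude is
reported alongside. Caliper tumor volume is V = (length/2)·width². SNR is
homogeneous of degree zero in global intensity scaling, which the tests
assert.

## Synthetic data: what it shows and what it does not

The hydrogen-bond trajectory generator plants donor–H–acceptor triplets
that satisfy the criteria in a chosen fraction of frames, with optional
sub-threshold jitter, and returns the realized per-cell means exactly.
It validates the detector and the summary statistics — set-exact
agreement with brute force, recovery of planted means within block
errors — but it is not an MD trajectory: it has no correlated dynamics,
no competing acceptors and no density, so passing these tests says the
*measurement* is correct, not that any particular per-residue bond count
would be observed in a real simulation. The production 50-ns MD of the
~600k-atom system is out of scope (cluster-scale, engine-specific), so
reported bond averages from such simulations cannot be checked here.
Likewise the ROI image generator produces disjoint, exactly-controlled
ROIs; real MR images differ in noise structure and ROI placement.

## Problem sizes and determinism

Defaults run on one CPU in seconds to minutes: core carving on a 4×4×4
supercell (~3.6k bulk atoms, 2,298 carved), the 64-chain graft (~32k
atoms, the slowest step at a few seconds), the 489-per-leaflet bilayer
(127k atoms), full solvated assembly (~717k atoms, ~15 s). Oracle-based
tests run reduced problems (≤6×6×6 supercells, ≤30-atom graphs,
120–200-atom frames) because the oracles are deliberately quadratic or
exhaustive. All randomness — site seeding, water orientations, synthetic
generators — funnels through explicit integer seeds; identical configs
produce byte-identical artifacts.

## Known limitations

- Charges and the idealized sugar/lipid geometries are construction
  placeholders: the output is a *starting structure* for an MD engine,
  not an equilibrated or force-field-parameterized system.
- No energy minimization, no equilibration, no force constants, no
  CHARMM36 parameter redistribution.
- Monomer ring conformers are idealized; no anomeric chemistry
  validation or conformational sampling of the glycans.
- Counterions are not added by default (box neutralization is unstated
  in the source); the net charge is reported so users can neutralize in
  their MD tooling.
- The Wulff machinery assumes the cell's point group closes the facet
  families; non-crystallographic shape constraints are out of scope.
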