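# Methods

This note records the models, conventions and numerical choices behind the
package, in the order the pipeline uses them.

## Structure model and PDB I/O

Structures are chain → residue → atom hierarchies with coordinates in Å
and 1-based residue numbering on the Aβ 1–42 convention (regions:
N-terminal 1–17, central 18–30, C-terminal 31–42; "core" 17–42).
Trajectories are one topology plus per-frame coordinate arrays and map
1:1 onto multi-model PDB; the frame interval defaults to 10 ps. The PDB
reader resolves alternate locations to the highest-occupancy conformer
(ties keep the first encountered), infers elements from columns 77–78
with name heuristics as fallback (amide-proton analysis depends on
reliable hydrogen flags), rejects insertion codes, and reports the line
number of any malformed record. The writer is the exact fixed-column
inverse; round-tripping preserves identity to the format's 3-decimal
precision.

## Synthetic peptides and assemblies

Backbones are grown by internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, standard angles, ω = 180°) with per-residue φ/ψ. Sidechains
are grafted from Chemical Component Dictionary ideal coordinates at their
default rotamer; when the default rotamer collides with already-built
atoms, a deterministic χ1 (and, for single-γ-branch sidechains, χ2) grid
search keeps the closest non-bonded heavy-atom approach above ~1.7 Å.
Amide protons are placed trigonally in the peptide plane; the C-terminus
carries a charged carboxylate (O + OXT).

Named conformations: helix (−57°, −47°); extended (180°, 180°); β-strand
(−139°, 135°). The two-residue hairpin turn is type-I′-like with relaxed
flanking torsions, fitted once so that an ideal-geometry hairpin closes
with cross-strand Cα–Cα distances near 4.9–5.3 Å and no steric overlap;
the turn type itself is a fixture choice — the experimental constraint is
only that a turn exists near G37–G38.

The 42-mer monomer fixture is a β-meander: strand 18–24, a broad central
turn at 25–28 pairing F19 against L34 (minimum sidechain heavy-atom
distance ≈ 5 Å, matching the NOE-derived proximity), strand 29–36, the
G37–G38 hairpin turn, and strand 39–42 closing the C-terminal hairpin
(34↔41 pairing). Both turns' torsions were fitted jointly, once, against
those geometric targets. The N-terminus (1–16) is α-helical by default
(or extended), with a dedicated linker torsion at residue 17 that directs
it away from the core — mimicking the modeling practice of adding
N-terminal helices after assembling the hydrophobic core.

The standard dodecamer fixture is a dimer of C3-symmetric hexamers:
chain A plus a z-flipped copy at azimuth 60° form the asymmetric 2-chain
unit (so adjacent hairpin turns alternate direction — antiparallel
neighbors), three units form a C3 ring about z with hairpins toward the
axis and N-termini radiating outward, and a second ring, flipped and
staggered by 20°, stacks 15 Å below. Ring radius 13 Å was chosen as the
tightest packing that keeps all inter-chain heavy-atom distances above
~1.7 Å; the resulting particle is ~60–90 Å across with several hundred
inter-hexamer C-terminal contacts, so the C-terminal amides are shielded
while the N-termini stay solvent-facing. Assembly constructors raise an
error if any inter-copy heavy-atom pair falls under 1.0 Å. With extended
(non-helical) N-termini the 56 Å arms sweep the stacking interface;
constructing that variant requires a looser geometry (e.g. ring radius
19 Å, separation 35 Å).

## Trajectory generator

Frames are the reference coordinates plus i.i.d. Gaussian noise with
per-residue, per-Cartesian-coordinate σ; the closed-form B-factor of an
atom is then 8π²σ², which is what the parameter-recovery checks exploit.
The default σ profile is 0.4 Å for the core (17–42) and 1.2 Å for the
N-terminus (1–16), reproducing the qualitative mobility split of the
simulations being emulated. With unwinding enabled, residues 1–16 of each
42-mer chain are rebuilt every frame with backbone torsions interpolated
(shortest angular path) from the α-helix toward an extended coil,
anchored on the residue-17 backbone triad — a linear-in-torsion stand-in
for helix decay, chosen because only the endpoint (random coil), not the
kinetics, is constrained. The generator is bit-reproducible under a fixed
seed. What it deliberately does not emulate: solvent, forces, correlated
motions, and any relaxation of the core fold — so passing ensemble tests
demonstrates correctness of the statistics, not realism of the dynamics.

Emulated production scale is 2 ns sampled every 10 ps (200 frames). The
acceptance script analyzes 100 frames and the test suite 8–30, with SASA
lattices of 480–960 points, as desk-scale settings; all statistics
reported are means over the stated problem sizes.

## Rigid assembly search

The docking surrogate is a transparent exhaustive grid, designed to be
checkable against brute-force enumeration: zyz-Euler rotations at a fixed
step (default 30°; the pipeline default is 90°) about the mobile
centroid, times a translation lattice (default 1.5 Å; pipeline 3.0 Å)
covering the shell where the partners' surfaces can touch. A contact is a
heavy-atom pair under 5 Å, a clash under 2.5 Å (thresholds exclusive,
with a 1e-9 Å guard); score = contacts − 10·clashes, so steric
feasibility dominates and interface size ranks feasible placements.
Candidates must include at least one contact whose **both** atoms lie in
the required region (C-terminal 31–42 for all oligomer stages); ties
break on fewer clashes, then grid order, making ranked lists
byte-reproducible. Pair counting uses the pair-difference KD-tree trick
(contacts for offset t = difference vectors within the cutoff of t), so
one tree per rotation serves every translation.

C3 symmetrization searches axis positions on an in-plane offset grid
(directions default to the fixture's z axis) and scores the three
inter-copy interfaces of the exact 120° generator, so realized hexamers
are exactly symmetric. Stacking searches the C2 flip family — 180°
rotations about in-plane axes swept around the hexamer's C3 axis (taken
from the inertia tensor's unique principal axis) — combined with axial
translation.

The charged-occlusion filter compares each charged group's *relative*
exposure in the assembled complex against the isolated subunit and
rejects candidates that newly bury a group below 10%. Groups are scored
as units (heavy atoms plus their bonded protons, summed in numerator and
reference; LYS amine, ARG guanidinium nitrogens, ASP/GLU carboxylates,
and each chain's terminal O+OXT referenced to the last residue of an
extended A-A-x peptide): per-atom ratios for proton-shadowed nitrogens
divide two near-zero areas and turn the filter into noise. The pipeline
searches deep candidate lists and filters lazily until the requested
number pass, mirroring an examine-many / keep-few protocol; no
post-docking refinement is applied, so accepted models are rigid-body
artifacts by construction. An optional parallel-strand orientation check
is not applied by default.

## Surface analysis

SASA is Shrake–Rupley with a deterministic Fibonacci lattice (default 960
points, probe 1.4 Å) over Bondi radii (H = 1.20 Å), hydrogens treated as
ordinary atoms; the isolated-sphere value is exact by construction and
the two-sphere value converges to the spherical-cap closed form. rSASA
normalizes by the same atom in an uncapped extended (φ=ψ=180°) AxA
reference tripeptide (GxA selectable; no rule for choosing between them
is imposed), cached per (residue type, atom, flank, parameters); values
are not clamped and may exceed 1. For trajectories, SASA is averaged over
frames *before* division — one ratio of mean areas, not a mean of ratios.
Protection is the fraction of backbone amide protons with time-averaged
rSASA strictly below 10%. An α-helix is intrinsically protected under
this definition (the amide protons hydrogen-bond into the helix), so on
the helical fixture the N-terminus scores high protection at frame 0 and
loses it as the helices unwind; region comparisons therefore use
time-averaged trajectories. Buried interface area is
SASA(A) + SASA(B) − SASA(AB) with identical parameters throughout.

## Contact energies and packing

Per-residue atomic contact energies sum the type-pair energy of every
heavy-atom pair within 6 Å, crediting both residues (the per-residue
profile is self-contained; the grand total is twice the unordered-pair
sum). Pairs within the same or sequence-adjacent residues of one chain
are excluded as covalent neighbors; cross-chain pairs always count. The
shipped parameter file (`data/ace_table_synthetic.tsv`) is a clearly
labelled synthetic stand-in: 18 atom types with energies built from a
hydrophobicity scale so that the sign semantics hold
(hydrophobic–hydrophobic < 0, polar/charged > 0, symmetric); any table in
the documented format (TYPES header, triangular ENERGY rows, ASSIGN
entries with a `*` wildcard resname) can be substituted.

Packing density: an atom is buried when its SASA at the burial probe
(1.4 Å) is zero; for each buried atom, points sampled uniformly in a
surrounding ball (radius r + 2.5 Å) are assigned to the
nearest-sphere-surface cell (additively weighted Voronoi, which also
splits overlap regions), and the density is the occupied fraction of the
atom's cell. Monte-Carlo sampling (default 10⁴ points/atom) is seeded and
reproducible; on a touching-sphere FCC crystal the central atom recovers
the analytic packing fraction π/√18 within the sampling error. Note that
axis-aligned *regular* grids alias against such a lattice's symmetry
planes — the grid-integration oracle in the tests uses an incommensurate
offset for exactly that reason.

## Ensemble statistics

Superposition is least-squares with a proper rotation (degenerate —
collinear or coincident — point sets rejected); RMSD series fit each
frame on the same selection they report (core = Cα 17–42, total = all
Cα), so rigid-body motion contributes nothing. Rg is mass-weighted over
heavy atoms (fixture hydrogens are idealized and carry no information).
B-factors are (8π²/3)·⟨|x−⟨x⟩|²⟩ per atom over a trailing window (default
last 500 ps), averaged atom → residue (mainchain) → chain position. The
F19–L34 monitor takes the minimum sidechain heavy-atom pair distance per
chain per frame (the NOE constraint names sidechain proximity, not
specific atoms); tolerance fractions count every (chain, frame) sample.
Convergence reports the coefficient of variation and the per-ns OLS slope
of any scalar series; with no force field in scope the pipeline applies
it to the Rg series.

## Known limitations

Models are rigid-body assemblies of ideal-geometry peptides: no
minimization, no flexibility, no solvent; contact counts and scores are
grid-resolution-dependent; the contact-energy magnitudes are synthetic
(signs and relative order are meaningful, absolute kcal/mol are not); and
the trajectory generator's statistics are exactly Gaussian, so ensemble
estimators are validated against closed forms rather than against real
dynamics. The packing-density comparison against an experimental crystal
structure requires an externally supplied PDB file (`packing_density`
accepts any parsed structure).
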