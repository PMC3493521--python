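# globulomer

Constraint-guided assembly and ensemble analysis of amyloid-β (Aβ42)
oligomer models.

Soluble Aβ42 dodecamers ("globulomers") are a repeatedly implicated toxic
species in Alzheimer's disease, yet no single experimental structure pins
down their fold. What experiments do constrain is a set of structural
statistics: the C-terminal region (residues 31–42) is sequestered from
solvent (protease resistance, slow amide H/D exchange), the K28 sidechain
amine is shielded from cross-linking while the central turn stays exposed,
the F19 and L34 sidechains sit within NOE distance (< 7.5 Å), and the
particle is roughly spherical, 40–60 Å across. This package implements a
desk-scale workflow for building dodecamer models compatible with those
constraints and for scoring any model or trajectory against them:

- **Assembly** — hierarchical constrained rigid-body search: monomers with
  a single C-terminal β-hairpin (turn at G37–G38) are docked into dimers
  restricted to C-terminal contacts, dimers are closed into C3-symmetric
  hexamers, and hexamers are stacked into 12-chain dodecamers, discarding
  candidates whose interfaces occlude charged groups.
- **Surface** — Shrake–Rupley SASA; relative SASA
  `rSASA(atom) = SASA(atom in molecule) / SASA(atom in extended AxA or GxA
  tripeptide)`; the H/D-exchange protection proxy (amide proton protected
  when time-averaged rSASA < 10%); interface buried area
  `ΔSASA = SASA(A) + SASA(B) − SASA(AB)`.
- **Contacts** — per-residue atomic contact energies (type-pair
  desolvation pseudo-energies summed over heavy-atom pairs within 6 Å;
  negative = hydrophobically stabilized) and interior packing density by
  Monte-Carlo integration of each buried atom's additively weighted
  Voronoi cell.
- **Ensemble** — Kabsch superposition, core/total RMSD series, radii of
  gyration, crystallographic B-factors `B = (8π²/3)⟨|Δx|²⟩`, minimum
  sidechain-distance monitors, and convergence diagnostics (coefficient of
  variation, per-ns drift).
- **Synthetic data** — ideal-geometry peptide builders (helix, extended,
  β-hairpin, and the full 42-mer β-meander monomer), Cn ring assemblies, a
  standard dodecamer fixture, and a Gaussian-fluctuation trajectory
  generator with progressive N-terminal helix unwinding, so the entire
  pipeline runs and is tested without downloading any structure.

## Worked example

```sh
globulomer analyze --seed 1 --out runs/demo
```

builds the standard synthetic dodecamer (two stacked C3 hexamer rings,
C-terminal hairpins inward, α-helical N-termini outward), simulates a
2 ns fluctuation trajectory in which the N-terminal helices progressively
unwind, and prints:

```
Rg total 30.7 A / core 21.7 A; protection total 0.35; K28 Nz rSASA 0.47
```

meaning: the flexible N-termini inflate the particle's radius of gyration
by ~40% over its core (the same qualitative split the structural data
demand); about a third of all backbone amide protons are protected
(rSASA < 10%), concentrated in the C-terminal core (67% there vs 7% in the
N-terminus); and the K28 sidechain amine retains only ~half of its
reference exposure even though it sits on the particle surface. The full
report (`runs/demo/report.json`) also carries the F19–L34 distance monitor
(mean 4.8 Å, 100% of samples under the 7.5 Å NOE tolerance), per-residue
B-factor and amide-rSASA profiles as TSV, C-terminal contact-energy
profiles, packing density and convergence statistics.

`globulomer build` runs the hierarchical assembly search and writes ranked
candidate models (multi-model PDB) with per-stage filter reports;
`globulomer fixture` emits the synthetic structures themselves.

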