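"""Atomic contact energies and interior packing density.

Atomic contact energies (ACE) are pairwise, atom-type-based pseudo-energies
proportional to the desolvation free energy of moving atoms from water into
the protein interior; summed per residue over heavy-atom pairs within a
distance cutoff they profile the hydrophobic burial of each position.
Negative values indicate a hydrophobic (stabilizing) environment.

The parameter file shipped with this package
(``data/ace_table_synthetic.tsv``) is a synthetic stand-in: it keeps the
18-type structure and the sign semantics of published atomic contact
energy sets (hydrophobic-hydrophobic contacts negative, polar/charged
contacts positive, energies symmetric) but its numeric values are
constructed from a hydrophobicity scale, not fitted to crystal structures.
Any table in the same format can be substituted.

Packing density is the fraction of an interior atom's space-filling cell
occupied by van der Waals volume, estimated per buried atom by Monte-Carlo
sampling of its additively-weighted (nearest-sphere-surface) Voronoi cell;
well-packed protein cores give mean values near 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .sasa import BONDI_RADII, SasaParams, shrake_rupley
from .structures import Structure

__all__ = [
    "AceTable",
    "AceProfile",
    "PackingResult",
    "load_default_ace_table",
    "residue_ace_profile",
    "packing_density",
]


@dataclass
class AceTable:
    """Atom-type contact-energy parameters.

    ``type_assignment`` maps (resname, atom name) to a type label; the
    wildcard resname ``"*"`` matches any residue (used for the terminal
    carboxylate OXT).  ``energies`` is symmetric in its (type, type) key.
    """

    atom_types: list[str]
    type_assignment: dict[tuple[str, str], str]
    energies: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (a, b), e in list(self.energies.items()):
            if self.energies.get((b, a), e) != e:
                raise ValueError(f"energies not symmetric for ({a}, {b})")
            self.energies[(b, a)] = e

    def assign(self, resname: str, atom_name: str) -> str:
        t = self.type_assignment.get((resname, atom_name))
        if t is None:
            t = self.type_assignment.get(("*", atom_name))
        if t is None:
            raise KeyError(
                f"atom ({resname!r}, {atom_name!r}) has no contact-energy type"
            )
        return t

    def energy(self, type_a: str, type_b: str) -> float:
        return self.energies[(type_a, type_b)]

    @classmethod
    def from_file(cls, path) -> "AceTable":
        """Read the plain-text table format: a TYPES header line, ENERGY
        lines forming a lower-triangular matrix, and ASSIGN lines mapping
        (resname, atom name) to a type."""
        types: list[str] = []
        energies: dict[tuple[str, str], float] = {}
        assignment: dict[tuple[str, str], str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "TYPES":
                    types = fields[1:]
                elif fields[0] == "ENERGY":
                    ti = fields[1]
                    row = [float(x) for x in fields[2:]]
                    i = types.index(ti)
                    if len(row) != i + 1:
                        raise ValueError(f"triangular row for {ti} has wrong length")
                    for j, e in enumerate(row):
                        energies[(ti, types[j])] = e
                        energies[(types[j], ti)] = e
                elif fields[0] == "ASSIGN":
                    _, resname, atom, t = fields
                    if t not in types:
                        raise ValueError(f"assignment to unknown type {t!r}")
                    assignment[(resname, atom)] = t
                else:
                    raise ValueError(f"unrecognized record {fields[0]!r}")
        if not types:
            raise ValueError("no TYPES header found")
        return cls(types, assignment, energies)


def load_default_ace_table() -> AceTable:
    """The synthetic 18-type table shipped with the package."""
    with resources.as_file(
        resources.files("globulomer.data") / "ace_table_synthetic.tsv"
    ) as path:
        return AceTable.from_file(path)


@dataclass
class AceProfile:
    per_residue: dict[tuple[str, int], float]
    cutoff: float

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def total(self) -> float:
        return float(sum(self.per_residue.values()))

    def region_values(self, resnum_lo: int, resnum_hi: int) -> dict[tuple[str, int], float]:
        return {
            k: v for k, v in self.per_residue.items() if resnum_lo <= k[1] <= resnum_hi
        }


def residue_ace_profile(
    s: Structure,
    table: AceTable | None = None,
    cutoff: float = 6.0,
    exclusion: int = 1,
) -> AceProfile:
    """Per-residue summed atomic contact energies (kcal/mol).

    Every heavy-atom pair closer than ``cutoff`` contributes its type-pair
    energy to *both* residues' totals, so the profile's grand total is
    twice the sum over unordered pairs.  Pairs within the same chain are
    skipped when the residues are within ``exclusion`` of each other in
    sequence (covalent neighbors are not "contacts"); pairs across chains
    always count.  Hydrogens are ignored.
    """
    if table is None:
        table = load_default_ace_table()
    info: list[tuple[str, int, str]] = []  # (chain, resnum, type)
    coords: list[np.ndarray] = []
    per_residue: dict[tuple[str, int], float] = {}
    for c in s.chains:
        for r in c.residues:
            per_residue[(c.chain_id, r.resnum)] = 0.0
            for a in r.atoms:
                if a.is_hydrogen:
                    continue
                info.append((c.chain_id, r.resnum, table.assign(r.resname, a.name)))
                coords.append(a.coords)
    xyz = np.array(coords)
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(cutoff):
        ci, ri, ti = info[i]
        cj, rj, tj = info[j]
        if ci == cj and abs(ri - rj) <= exclusion:
            continue
        e = table.energy(ti, tj)
        per_residue[(ci, ri)] += e
        per_residue[(cj, rj)] += e
    return AceProfile(per_residue, cutoff)


@dataclass
class PackingResult:
    per_atom: dict[int, float]
    mean: float | None

    def __post_init__(self) -> None:
        for i, d in self.per_atom.items():
            if not (0.0 < d <= 1.0):
                raise ValueError(f"packing density {d} for atom {i} outside (0, 1]")


def packing_density(
    s: Structure,
    radii: dict[str, float] | None = None,
    burial_probe: float = 1.4,
    mc_samples: int = 10_000,
    seed: int = 0,
) -> PackingResult:
    """Mean interior packing density by Monte-Carlo cell integration.

    Heavy atoms only.  An atom is *buried* when its SASA at
    ``burial_probe`` is zero.  For each buried atom, points are sampled
    uniformly in a ball around it; a point belongs to the atom's cell when
    this atom's sphere surface is the nearest (additively-weighted Voronoi
    / power-diagram-like partition, which also assigns overlap regions to
    the nearest surface), and is *occupied* when it lies inside any atom's
    van der Waals sphere.  The density is occupied-cell over cell volume.
    Atoms whose cell extends beyond the sampling ball are interior-bounded
    by construction (buried atoms are surrounded by neighbors), so the
    truncation bias is negligible at the default ball radius.

    Returns per-atom densities for buried atoms and their mean (``None``,
    with empty ``per_atom``, when nothing is buried).
    """
    if radii is None:
        radii = dict(BONDI_RADII)
    if mc_samples < 1:
        raise ValueError("mc_samples must be positive")
    heavy_idx = [i for i, (_, _, a) in enumerate(s.iter_atoms()) if not a.is_hydrogen]
    if not heavy_idx:
        raise ValueError("structure has no heavy atoms")
    sub = np.asarray(heavy_idx)
    xyz = s.coords[sub]
    elements = [s.elements()[i] for i in sub]
    r = np.array([radii[e] for e in elements])
    sasa = shrake_rupley(
        s, SasaParams(probe_radius=burial_probe, radii_set=radii), subset=sub
    )
    buried_local = [k for k, i in enumerate(sub) if sasa.per_atom[int(i)] == 0.0]
    if not buried_local:
        return PackingResult({}, None)
    rng = np.random.default_rng(seed)
    tree = cKDTree(xyz)
    rmax = float(r.max())
    per_atom: dict[int, float] = {}
    for k in buried_local:
        ball = r[k] + 2.5  # sampling ball comfortably contains a buried cell
        neigh = tree.query_ball_point(xyz[k], ball + 2.0 * rmax)
        ncoords = xyz[neigh]
        nradii = r[neigh]
        self_pos = neigh.index(k)
        # uniform sampling in the ball
        u = rng.standard_normal((mc_samples, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        rad = ball * rng.random(mc_samples) ** (1.0 / 3.0)
        pts = xyz[k] + u * rad[:, None]
        d = np.linalg.norm(pts[:, None, :] - ncoords[None, :, :], axis=2)
        surf = d - nradii[None, :]
        owner = np.argmin(surf, axis=1)
        in_cell = owner == self_pos
        n_cell = int(in_cell.sum())
        if n_cell == 0:
            continue
        occupied = (surf[in_cell] <= 0.0).any(axis=1)
        per_atom[int(sub[k])] = float(occupied.sum() / n_cell)
    if not per_atom:
        return PackingResult({}, None)
    return PackingResult(per_atom, float(np.mean(list(per_atom.values()))))
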