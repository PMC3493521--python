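"""Solvent-accessible surface areas and derived exposure statistics.

SASA is computed with the Shrake-Rupley sphere-point method: each atom's
van der Waals sphere is inflated by the probe radius and covered with a
deterministic Fibonacci point lattice; the accessible area is the fraction
of points not inside any neighbor's inflated sphere times the inflated
sphere's area.  An isolated atom is therefore exact by construction, and
the two-sphere case converges to the closed-form spherical-cap value as
the lattice is refined.

Relative SASA (rSASA) normalizes an atom's SASA by the SASA of the same
atom in an extended reference tripeptide (AxA or GxA), the convention used
to compare amide-proton exposure against hydrogen/deuterium-exchange
protection data.  An amide proton with time-averaged rSASA below 10% is
classified as protected.  rSASA is not clamped: values slightly above 1
occur when the local environment shields the reference atom more than the
molecule does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import RegionSpec, Structure, Trajectory, select

__all__ = [
    "SasaParams",
    "SasaResult",
    "RsasaRecord",
    "BONDI_RADII",
    "shrake_rupley",
    "rsasa",
    "protection_fraction",
    "interface_buried_sasa",
    "clear_reference_cache",
]

#: Bondi van der Waals radii (A); hydrogens participate with 1.20 A.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "Se": 1.90,
}


@dataclass
class SasaParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radii_set: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 16:
            raise ValueError("n_points must be at least 16")

    def radius(self, element: str) -> float:
        try:
            return self.radii_set[element]
        except KeyError:
            raise KeyError(f"no van der Waals radius defined for element {element!r}")


@dataclass
class SasaResult:
    per_atom: dict[int, float]
    params: SasaParams

    @property
    def total(self) -> float:
        return float(sum(self.per_atom.values()))


@dataclass
class RsasaRecord:
    atom: tuple[str, int, str]
    value: float
    reference_context: str


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def shrake_rupley(
    s: Structure, p: SasaParams | None = None, subset: Sequence[int] | None = None
) -> SasaResult:
    """Per-atom solvent-accessible surface area (A^2).

    ``subset`` restricts which atoms' areas are computed (all atoms still
    occlude).  Hydrogens are ordinary atoms with their own radius.
    """
    if p is None:
        p = SasaParams()
    xyz = s.coords
    if xyz.shape[0] == 0:
        raise ValueError("structure has no atoms")
    elements = s.elements()
    radii = np.array([p.radius(e) for e in elements]) + p.probe_radius
    targets = np.arange(xyz.shape[0]) if subset is None else np.asarray(list(subset), int)
    sphere = _fibonacci_sphere(p.n_points)
    tree = cKDTree(xyz)
    max_r = float(radii.max())
    out: dict[int, float] = {}
    for i in targets:
        ri = radii[i]
        neighbors = tree.query_ball_point(xyz[i], ri + max_r)
        neighbors = [j for j in neighbors if j != i]
        pts = xyz[i] + ri * sphere
        exposed = np.ones(p.n_points, dtype=bool)
        for j in neighbors:
            if not exposed.any():
                break
            d2 = ((pts - xyz[j]) ** 2).sum(1)
            exposed &= d2 > radii[j] ** 2
        out[int(i)] = float(exposed.mean() * 4.0 * np.pi * ri**2)
    return SasaResult(out, p)


# reference tripeptide SASA cache: (resname-letter, atom name, flank) -> A^2
_REFERENCE_CACHE: dict[tuple[str, str, str], float] = {}


def clear_reference_cache() -> None:
    _REFERENCE_CACHE.clear()


def _reference_sasa(res_letter: str, atom_name: str, flank: str, p: SasaParams) -> float:
    key = (res_letter, atom_name, flank + f"|{p.probe_radius}|{p.n_points}")
    if key not in _REFERENCE_CACHE:
        from .peptides import build_reference_tripeptide

        ref = build_reference_tripeptide(res_letter, flank)
        central = ref.chains[0].residue(2)
        idx = None
        for k, (_, r, a) in enumerate(ref.iter_atoms()):
            if r.resnum == 2 and a.name == atom_name:
                idx = k
                break
        if idx is None:
            raise KeyError(
                f"reference tripeptide {flank}{res_letter}A has no atom "
                f"{atom_name!r} in residue {central.resname}2"
            )
        area = shrake_rupley(ref, p, subset=[idx]).per_atom[idx]
        _REFERENCE_CACHE[key] = area
    return _REFERENCE_CACHE[key]


_LETTER_BY_RESNAME: dict[str, str] = {}


def _res_letter(resname: str) -> str:
    if not _LETTER_BY_RESNAME:
        from .peptides import AA3

        _LETTER_BY_RESNAME.update({v: k for k, v in AA3.items()})
    try:
        return _LETTER_BY_RESNAME[resname]
    except KeyError:
        raise KeyError(f"no reference tripeptide for residue {resname!r}")


def _mean_sasa_over_frames(
    s: Structure | Trajectory, indices: Sequence[int], p: SasaParams
) -> dict[int, float]:
    """SASA per atom index; for trajectories the per-frame SASA is averaged
    before any ratio is formed (average-of-areas, not average-of-ratios)."""
    if isinstance(s, Trajectory):
        acc = {int(i): 0.0 for i in indices}
        work = s.topology.copy()
        for frame in s.frames:
            work.set_coords(frame)
            res = shrake_rupley(work, p, subset=indices)
            for k, v in res.per_atom.items():
                acc[k] += v
        return {k: v / s.n_frames for k, v in acc.items()}
    return shrake_rupley(s, p, subset=indices).per_atom


def rsasa(
    s: Structure | Trajectory,
    targets: list[tuple[int, str]],
    p: SasaParams | None = None,
    flank: str = "A",
) -> list[RsasaRecord]:
    """Relative SASA of ``(resnum, atom name)`` targets, one record per
    chain containing the target.

    The denominator is the same atom's SASA in the extended reference
    tripeptide (AxA for ``flank="A"``, GxA for ``"G"``), computed once per
    (residue type, atom, flank).  Trajectory input averages the numerator
    over frames.  A zero reference area is rejected as undefined.
    """
    if p is None:
        p = SasaParams()
    topo = s.topology if isinstance(s, Trajectory) else s
    keys = topo.atom_keys()
    resnames = {
        (c.chain_id, r.resnum): r.resname
        for c in topo.chains
        for r in c.residues
    }
    wanted: list[tuple[int, tuple[str, int, str]]] = []
    for resnum, name in targets:
        found = [i for i, (ch, rn, an) in enumerate(keys) if rn == resnum and an == name]
        if not found:
            raise KeyError(f"no atom {name!r} in residue {resnum} in any chain")
        wanted.extend((i, keys[i]) for i in found)
    areas = _mean_sasa_over_frames(s, [i for i, _ in wanted], p)
    records = []
    for i, (ch, rn, an) in wanted:
        letter = _res_letter(resnames[(ch, rn)])
        ref = _reference_sasa(letter, an, flank, p)
        if ref == 0:
            raise ZeroDivisionError(
                f"reference SASA for {flank}{letter}A atom {an!r} is zero; "
                "rSASA undefined"
            )
        records.append(
            RsasaRecord((ch, rn, an), areas[i] / ref, f"{flank}{letter}A")
        )
    return records


def protection_fraction(
    s: Structure | Trajectory,
    region: RegionSpec,
    p: SasaParams | None = None,
    threshold: float = 0.10,
    flank: str = "A",
) -> float:
    """Fraction of backbone amide protons in ``region`` with (time-averaged)
    rSASA strictly below ``threshold`` — the H/D-exchange protection proxy."""
    if p is None:
        p = SasaParams()
    topo = s.topology if isinstance(s, Trajectory) else s
    spec = RegionSpec(region.name, region.ranges, "amide_proton")
    idx = select(topo, spec)
    if not idx:
        raise ValueError(f"region {region.name!r} contains no amide protons")
    keys = topo.atom_keys()
    resnames = {(c.chain_id, r.resnum): r.resname for c in topo.chains for r in c.residues}
    areas = _mean_sasa_over_frames(s, idx, p)
    protected = 0
    for i in idx:
        ch, rn, an = keys[i]
        ref = _reference_sasa(_res_letter(resnames[(ch, rn)]), an, flank, p)
        if ref == 0:
            raise ZeroDivisionError(f"zero reference SASA for amide proton of {resnames[(ch, rn)]}{rn}")
        if areas[i] / ref < threshold:
            protected += 1
    return protected / len(idx)


def interface_buried_sasa(
    complex_structure: Structure,
    part_a: Iterable[str],
    part_b: Iterable[str],
    p: SasaParams | None = None,
) -> float:
    """Buried surface area on complex formation (A^2):
    SASA(A alone) + SASA(B alone) - SASA(A:B), identical parameters
    throughout.  ``part_a``/``part_b`` are disjoint chain-id sets covering
    the complex."""
    if p is None:
        p = SasaParams()
    a, b = set(part_a), set(part_b)
    if not a or not b:
        raise ValueError("both chain sets must be non-empty")
    if a & b:
        raise ValueError(f"chain sets overlap: {sorted(a & b)}")
    all_chains = {c.chain_id for c in complex_structure.chains}
    if a | b != all_chains:
        raise ValueError("chain sets must cover the complex")
    sasa_ab = shrake_rupley(complex_structure, p).total
    sasa_a = shrake_rupley(complex_structure.subset_chains(a), p).total
    sasa_b = shrake_rupley(complex_structure.subset_chains(b), p).total
    return sasa_a + sasa_b - sasa_ab
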