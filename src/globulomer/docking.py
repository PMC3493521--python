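"""Constrained rigid-body assembly: dimer search, C3 symmetrization and
hexamer stacking, with contact-based candidate filters.

The search replaces external docking servers with a transparent,
exhaustively enumerable surrogate so every stage is oracle-checkable:

* placements come from a deterministic grid — Euler rotations at a fixed
  angular step times a Cartesian translation lattice bounded by the shell
  where the two partners' surfaces can touch;
* a *contact* is a heavy-atom pair closer than ``contact_cutoff`` (5 A by
  default), a *clash* one closer than ``clash_cutoff`` (2.5 A);
* score = contacts - 10 x clashes, so steric feasibility dominates while
  interface size ranks feasible placements;
* candidates must make at least ``min_required_contacts`` contacts whose
  two atoms both lie in the required region (the C-terminal segment for
  the oligomer builds), mirroring the constraint that assembly proceed
  through C-terminal interactions;
* ties break on fewer clashes, then on grid enumeration order, making the
  ranked list byte-reproducible.

Distance thresholds are exclusive; an epsilon guard (1e-9 A) keeps the
KD-tree counting consistent with strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import (
    RegionSpec,
    Structure,
    TransformOp,
    apply_transform,
    select,
)

__all__ = [
    "DockConstraint",
    "DockCandidate",
    "ChargedGroupRule",
    "AxisGrid",
    "rigid_dock",
    "symmetrize_c3",
    "stack_to_dodecamer",
    "filter_candidates",
    "realize_candidate",
]

_EPS = 1e-9


@dataclass
class DockConstraint:
    required_contact_region: RegionSpec
    contact_cutoff: float = 5.0
    clash_cutoff: float = 2.5
    min_required_contacts: int = 1

    def __post_init__(self) -> None:
        if not self.clash_cutoff < self.contact_cutoff:
            raise ValueError("clash_cutoff must be smaller than contact_cutoff")


@dataclass
class DockCandidate:
    """A rigid placement with its contact statistics.

    ``placement`` maps the mobile partner's original coordinates into the
    complex frame.  ``kind`` records which search produced it ("dock":
    fixed + transformed mobile; "c3": placement is the 120-deg ring
    generator applied to the searched subunit; "stack": placement maps the
    hexamer onto its stacked partner).
    """

    placement: TransformOp
    n_contacts: int
    n_clashes: int
    score: float
    filter_report: dict[str, bool] = field(default_factory=dict)
    kind: str = "dock"
    grid_index: int = 0

    def __post_init__(self) -> None:
        if self.n_clashes < 0:
            raise ValueError("n_clashes must be non-negative")
        expected = self.n_contacts - 10 * self.n_clashes
        if self.score != expected:
            raise ValueError(f"score {self.score} inconsistent with counts ({expected})")


@dataclass
class ChargedGroupRule:
    """Charged sidechain groups that an interface must not occlude.

    A candidate fails when any listed atom's rSASA drops below
    ``min_rsasa`` in the assembled complex while it was at least
    ``min_rsasa`` in the isolated subunit.  The C-terminal carboxylate
    (O/OXT of each chain's last residue) is always included.
    """

    group_atoms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "LYS": ("NZ",),
            "ARG": ("NH1", "NH2"),
            "ASP": ("OD1", "OD2"),
            "GLU": ("OE1", "OE2"),
        }
    )
    min_rsasa: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_rsasa <= 1.0:
            raise ValueError("min_rsasa must be within [0, 1]")


@dataclass
class AxisGrid:
    """Search grid for C3 symmetrization: candidate axis directions (unit
    vectors) and in-plane offsets of the axis position."""

    directions: list[np.ndarray] = field(
        default_factory=lambda: [np.array([0.0, 0.0, 1.0])]
    )
    offset_step: float = 2.0
    offset_max: float = 8.0


def _heavy_coords(s: Structure) -> np.ndarray:
    return s.coords[s.heavy_mask()]


def _region_heavy_mask(s: Structure, region: RegionSpec) -> np.ndarray:
    spec = RegionSpec(region.name, region.ranges, "heavy")
    idx = set(select(s, spec))
    heavy = [i for i, (_, _, a) in enumerate(s.iter_atoms()) if not a.is_hydrogen]
    return np.array([i in idx for i in heavy], dtype=bool)


def _count_pairs(a: np.ndarray, b: np.ndarray, cutoff: float) -> int:
    if a.shape[0] == 0 or b.shape[0] == 0:
        return 0
    return int(cKDTree(a).count_neighbors(cKDTree(b), cutoff - _EPS))


def _rank(cands: list[DockCandidate], top_k: int | None) -> list[DockCandidate]:
    cands.sort(key=lambda c: (-c.score, c.n_clashes, c.grid_index))
    return cands if top_k is None else cands[:top_k]


def _euler_grid(rot_step: float) -> list[Rotation]:
    if abs(360.0 / rot_step - round(360.0 / rot_step)) > 1e-9:
        raise ValueError("rot_step must divide 360")
    alphas = np.arange(0.0, 360.0, rot_step)
    betas = np.arange(0.0, 180.0 + _EPS, rot_step)
    gammas = np.arange(0.0, 360.0, rot_step)
    out = []
    for a in alphas:
        for b in betas:
            for g in gammas:
                out.append(Rotation.from_euler("zyz", [a, b, g], degrees=True))
    return out


def translation_grid(
    fixed_heavy: np.ndarray, mobile_heavy: np.ndarray, contact_cutoff: float,
    trans_step: float,
) -> np.ndarray:
    """Centroid-displacement lattice covering the shell where the two
    partners' surfaces can touch: multiples of ``trans_step`` with
    |t| <= r_fixed + r_mobile + cutoff (radii = max centroid distance)."""
    r_fix = float(np.linalg.norm(fixed_heavy - fixed_heavy.mean(0), axis=1).max())
    r_mob = float(np.linalg.norm(mobile_heavy - mobile_heavy.mean(0), axis=1).max())
    r_max = r_fix + r_mob + contact_cutoff
    n = int(np.floor(r_max / trans_step))
    axis = np.arange(-n, n + 1) * trans_step
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    return pts[np.linalg.norm(pts, axis=1) <= r_max + _EPS]


def rigid_dock(
    fixed: Structure,
    mobile: Structure,
    c: DockConstraint,
    rot_step: float = 30.0,
    trans_step: float = 1.5,
    top_k: int = 10,
) -> list[DockCandidate]:
    """Exhaustive grid search of rigid placements of ``mobile`` against
    ``fixed``.

    Rotations sweep a zyz-Euler grid at ``rot_step`` (applied about the
    mobile centroid); translations sweep :func:`translation_grid`.  Each
    surviving candidate records the transform in the original frame, the
    contact/clash counts and the score; the ranked top ``top_k`` are
    returned (possibly empty — a valid outcome when the constraint cannot
    be met)."""
    if fixed.n_atoms == 0 or mobile.n_atoms == 0:
        raise ValueError("both structures must be non-empty")
    fixed_heavy = _heavy_coords(fixed)
    mobile_heavy = _heavy_coords(mobile)
    fix_region = _region_heavy_mask(fixed, c.required_contact_region)
    mob_region = _region_heavy_mask(mobile, c.required_contact_region)
    c_fix = fixed_heavy.mean(0)
    c_mob = mobile_heavy.mean(0)
    trans = translation_grid(fixed_heavy, mobile_heavy, c.contact_cutoff, trans_step)
    cands: list[DockCandidate] = []
    grid_index = 0
    for rot in _euler_grid(rot_step):
        rmat = rot.as_matrix()
        mob_rot = (mobile_heavy - c_mob) @ rmat.T  # centered at origin
        # pair-displacement trick: the contact count for centroid offset t
        # is the number of (fixed - mobile) difference vectors within the
        # cutoff of t, so one KD-tree serves every translation.
        diffs = (fixed_heavy - c_fix)[:, None, :] - mob_rot[None, :, :]
        diff_tree = cKDTree(diffs.reshape(-1, 3))
        n_contact = diff_tree.query_ball_point(
            trans, c.contact_cutoff - _EPS, return_length=True
        )
        n_clash = diff_tree.query_ball_point(
            trans, c.clash_cutoff - _EPS, return_length=True
        )
        if fix_region.any() and mob_region.any():
            rdiffs = diffs[fix_region][:, mob_region, :].reshape(-1, 3)
            rtree = cKDTree(rdiffs)
            n_region = rtree.query_ball_point(
                trans, c.contact_cutoff - _EPS, return_length=True
            )
        else:
            n_region = np.zeros(len(trans), dtype=int)
        for ti in range(len(trans)):
            grid_index += 1
            if n_region[ti] < c.min_required_contacts:
                continue
            nc = int(n_contact[ti])
            nx = int(n_clash[ti])
            placement = TransformOp(rmat, c_fix + trans[ti] - rmat @ c_mob)
            cands.append(
                DockCandidate(
                    placement, nc, nx, nc - 10 * nx,
                    filter_report={"required_region_contacts": True},
                    kind="dock", grid_index=grid_index,
                )
            )
    return _rank(cands, top_k)


def _c3_copies(subunit: Structure, generator: TransformOp) -> list[Structure]:
    second = apply_transform(subunit, generator)
    third = apply_transform(second, generator)
    return [subunit, second, third]


def symmetrize_c3(
    dimer: Structure,
    c: DockConstraint,
    axis_search: AxisGrid | None = None,
    top_k: int = 10,
) -> list[DockCandidate]:
    """Search C3 axes that close ``dimer`` into a hexamer.

    For each candidate axis (direction x in-plane offset), the dimer and
    its two 120-deg images are scored on inter-copy contacts and clashes;
    candidates whose inter-copy interfaces lack the required region are
    dropped.  The returned placement is the exact 120-deg generator, so
    the realized hexamer has exact 3-fold symmetry.
    """
    if len(dimer.chains) < 2:
        raise ValueError("input must have at least 2 chains")
    if axis_search is None:
        axis_search = AxisGrid()
    heavy = _heavy_coords(dimer)
    region = _region_heavy_mask(dimer, c.required_contact_region)
    cands: list[DockCandidate] = []
    grid_index = 0
    n = int(np.floor(axis_search.offset_max / axis_search.offset_step))
    offsets_1d = np.arange(-n, n + 1) * axis_search.offset_step
    centroid = heavy.mean(0)
    for direction in axis_search.directions:
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        # orthonormal in-plane basis for axis offsets
        probe = np.array([1.0, 0.0, 0.0])
        if abs(probe @ d) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        e1 = probe - (probe @ d) * d
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        for ox in offsets_1d:
            for oy in offsets_1d:
                grid_index += 1
                point = centroid + ox * e1 + oy * e2
                gen = TransformOp.rotation_about_axis(d, 120.0, center=point)
                copy2 = gen.apply(heavy)
                copy3 = gen.apply(copy2)
                nc = _count_pairs(heavy, copy2, c.contact_cutoff) + _count_pairs(
                    heavy, copy3, c.contact_cutoff
                ) + _count_pairs(copy2, copy3, c.contact_cutoff)
                nreg = (
                    _count_pairs(heavy[region], copy2[region], c.contact_cutoff)
                    + _count_pairs(heavy[region], copy3[region], c.contact_cutoff)
                    + _count_pairs(copy2[region], copy3[region], c.contact_cutoff)
                    if region.any()
                    else 0
                )
                if nreg < c.min_required_contacts:
                    continue
                nx = _count_pairs(heavy, copy2, c.clash_cutoff) + _count_pairs(
                    heavy, copy3, c.clash_cutoff
                ) + _count_pairs(copy2, copy3, c.clash_cutoff)
                cands.append(
                    DockCandidate(
                        gen, nc, nx, nc - 10 * nx,
                        filter_report={"required_region_contacts": True},
                        kind="c3", grid_index=grid_index,
                    )
                )
    return _rank(cands, top_k)


def _c3_axis(hexamer: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and symmetry-axis direction of a C3 assembly, from the
    unique principal axis of the inertia tensor."""
    xyz = _heavy_coords(hexamer)
    centroid = xyz.mean(0)
    x = xyz - centroid
    inertia = (x**2).sum() * np.eye(3) - x.T @ x
    w, v = np.linalg.eigh(inertia)
    # the C3 axis is the eigenvalue most separated from the other two
    gaps = [abs(w[i] - w[(i + 1) % 3]) + abs(w[i] - w[(i + 2) % 3]) for i in range(3)]
    return centroid, v[:, int(np.argmax(gaps))]


def stack_to_dodecamer(
    hexamer: Structure,
    c: DockConstraint,
    angle_step: float = 30.0,
    axial_step: float = 1.5,
    top_k: int = 10,
) -> list[DockCandidate]:
    """Search C2 stackings of a second hexamer copy against ``hexamer``.

    The flip family: 180-deg rotations about in-plane axes perpendicular
    to the hexamer's C3 axis (swept at ``angle_step``), combined with a
    translation along the C3 axis (swept at ``axial_step`` over the range
    where the copies can touch).  Candidates are filtered and scored as in
    :func:`rigid_dock`; realized models have 12 chains.
    """
    if len(hexamer.chains) != 6:
        raise ValueError("input must be a hexamer with 6 chains")
    heavy = _heavy_coords(hexamer)
    region = _region_heavy_mask(hexamer, c.required_contact_region)
    centroid, axis = _c3_axis(hexamer)
    z_extent = np.abs((heavy - centroid) @ axis).max()
    n_ax = int(np.floor((2 * z_extent + c.contact_cutoff) / axial_step))
    axials = np.arange(-n_ax, n_ax + 1) * axial_step
    probe = np.array([1.0, 0.0, 0.0])
    if abs(probe @ axis) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = probe - (probe @ axis) * axis
    e1 /= np.linalg.norm(e1)
    cands: list[DockCandidate] = []
    grid_index = 0
    for theta in np.arange(0.0, 180.0, angle_step):
        flip_axis = Rotation.from_rotvec(np.deg2rad(theta) * axis).apply(e1)
        flip = TransformOp.rotation_about_axis(flip_axis, 180.0, center=centroid)
        flipped = flip.apply(heavy)
        for dz in axials:
            grid_index += 1
            shift = dz * axis
            placement = TransformOp(flip.rotation, flip.translation + shift)
            moved = flipped + shift
            nreg = (
                _count_pairs(heavy[region], moved[region], c.contact_cutoff)
                if region.any()
                else 0
            )
            if nreg < c.min_required_contacts:
                continue
            nc = _count_pairs(heavy, moved, c.contact_cutoff)
            nx = _count_pairs(heavy, moved, c.clash_cutoff)
            cands.append(
                DockCandidate(
                    placement, nc, nx, nc - 10 * nx,
                    filter_report={"required_region_contacts": True},
                    kind="stack", grid_index=grid_index,
                )
            )
    return _rank(cands, top_k)


def realize_candidate(
    cand: DockCandidate, parent: Structure, mobile: Structure | None = None
) -> Structure:
    """Build the complex a candidate describes.

    "dock": ``parent`` (fixed) + transformed ``mobile``; "c3": ``parent``
    and its two generator images; "stack": ``parent`` + its transformed
    copy.  Chains are re-lettered uniquely.
    """
    from .peptides import _merge

    if cand.kind == "dock":
        if mobile is None:
            raise ValueError("dock candidates need the mobile structure")
        return _merge([parent, apply_transform(mobile, cand.placement)])
    if cand.kind == "c3":
        return _merge(_c3_copies(parent, cand.placement))
    if cand.kind == "stack":
        return _merge([parent, apply_transform(parent, cand.placement)])
    raise ValueError(f"unknown candidate kind {cand.kind!r}")


def _group_with_protons(residue, names: tuple[str, ...]) -> list[str]:
    """The listed heavy atoms plus their bonded protons (PDB naming:
    H + the heavy atom's name without its element letter, e.g. NZ ->
    HZ1/HZ2/HZ3, NH1 -> HH11/HH12)."""
    out = [n for n in names if residue.has_atom(n)]
    for n in names:
        stem = "H" + n[1:]
        for a in residue.atoms:
            if a.is_hydrogen and a.name.startswith(stem) and a.name[len(stem):].isdigit():
                out.append(a.name)
    return out


def _charged_group_targets(s: Structure, rule: ChargedGroupRule):
    """(chain, resnum, group label, atom names) for every charged group,
    including the terminal carboxylate (O + OXT) of each chain."""
    out = []
    for c in s.chains:
        for r in c.residues:
            names = rule.group_atoms.get(r.resname, ())
            if names:
                group = _group_with_protons(r, names)
                if group:
                    out.append((c.chain_id, r.resnum, "sidechain", tuple(group)))
        last = c.residues[-1]
        term = tuple(n for n in ("O", "OXT") if last.has_atom(n))
        if term:
            out.append((c.chain_id, last.resnum, "cterm", term))
    return out


def _charged_rsasa(s: Structure, rule: ChargedGroupRule, p) -> dict[tuple[str, int, str], float]:
    """Group rSASA of charged groups: the summed SASA of each group's
    atoms (heavy + bonded protons) over the same sum in the extended
    reference — per-atom ratios would divide near-zero areas for
    proton-shadowed nitrogens.

    Keys are (chain, resnum, group label).  The terminal carboxylate is
    referenced to the last residue of an extended A-A-x peptide, since
    the mid-chain reference has no OXT."""
    from .peptides import build_peptide, ConformationSpec
    from .sasa import shrake_rupley as _sr, _res_letter, _reference_sasa

    keys = s.atom_keys()
    index = {k: i for i, k in enumerate(keys)}
    targets = _charged_group_targets(s, rule)
    idx = sorted(
        {index[(ch, rn, an)] for ch, rn, _, group in targets for an in group}
    )
    resnames = {(c.chain_id, r.resnum): r.resname for c in s.chains for r in c.residues}
    areas = _sr(s, p, subset=idx).per_atom
    terminal_cache: dict[tuple[str, tuple[str, ...]], float] = {}
    out = {}
    for ch, rn, label, group in targets:
        letter = _res_letter(resnames[(ch, rn)])
        numer = sum(areas[index[(ch, rn, an)]] for an in group)
        if label == "cterm":
            key = (letter, group)
            if key not in terminal_cache:
                ref = build_peptide("AA" + letter, ConformationSpec("extended"))
                ref_idx = [
                    k for k, (_, r, a) in enumerate(ref.iter_atoms())
                    if r.resnum == 3 and a.name in group
                ]
                terminal_cache[key] = sum(
                    _sr(ref, p, subset=ref_idx).per_atom[k] for k in ref_idx
                )
            denom = terminal_cache[key]
        else:
            denom = sum(_reference_sasa(letter, an, "A", p) for an in group)
        if denom == 0:
            raise ZeroDivisionError(f"zero reference SASA for group {(ch, rn, label)}")
        out[(ch, rn, label)] = numer / denom
    return out


def filter_candidates(
    candidates: list[DockCandidate],
    parent: Structure,
    rule: ChargedGroupRule | None = None,
    mobile: Structure | None = None,
    sasa_params=None,
    max_passing: int | None = None,
) -> list[DockCandidate]:
    """Drop candidates whose interface occludes charged sidechains.

    For each candidate the complex is realized and every charged-group
    atom's rSASA compared against the same atom in the isolated subunit; a
    candidate fails when the interface buries an atom below
    ``rule.min_rsasa`` that was exposed in isolation.  Passing candidates
    keep their original rank order; every evaluated candidate's
    ``filter_report`` is annotated.  With ``max_passing``, evaluation
    stops (and unevaluated candidates are discarded) once that many have
    passed — the deep-ranked tail of an exhaustive search rarely deserves
    a surface computation.
    """
    from .sasa import SasaParams

    if rule is None:
        rule = ChargedGroupRule()
    if sasa_params is None:
        sasa_params = SasaParams()
    isolated: dict[int, dict] = {}
    out = []
    for cand in candidates:
        if max_passing is not None and len(out) >= max_passing:
            break
        complex_structure = realize_candidate(cand, parent, mobile)
        complex_rsasa = _charged_rsasa(complex_structure, rule, sasa_params)
        # map complex chains back to their source subunit chains in order
        sources = []
        if cand.kind == "dock":
            sources = [parent, mobile] if mobile is not None else [parent]
        elif cand.kind == "c3":
            sources = [parent, parent, parent]
        else:
            sources = [parent, parent]
        iso_values: dict[tuple[str, int, str], float] = {}
        offset = 0
        for src_i, src in enumerate(sources):
            if src_i not in isolated:
                isolated[src_i] = _charged_rsasa(src, rule, sasa_params)
            src_chains = [c.chain_id for c in src.chains]
            complex_chains = [
                c.chain_id
                for c in complex_structure.chains[offset : offset + len(src_chains)]
            ]
            for (ch, rn, an), v in isolated[src_i].items():
                new_ch = complex_chains[src_chains.index(ch)]
                iso_values[(new_ch, rn, an)] = v
            offset += len(src_chains)
        occluded = any(
            complex_rsasa[t] < rule.min_rsasa and iso_values.get(t, 0.0) >= rule.min_rsasa
            for t in complex_rsasa
        )
        cand.filter_report["charged_groups_exposed"] = not occluded
        if not occluded:
            out.append(cand)
    return out
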