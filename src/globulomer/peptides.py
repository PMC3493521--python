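"""Synthetic peptide, assembly and trajectory generators.

Everything the analysis pipeline consumes can be generated here, so no
experimental structure ever has to be downloaded for testing: ideal-geometry
peptides in helical, extended or beta-hairpin conformations; extended
reference tripeptides (AxA / GxA) for relative-SASA normalization;
Cn-symmetric ring assemblies; and Gaussian-fluctuation trajectories with an
optional progressive unwinding of an alpha-helical N-terminus.

Backbones are grown by natural-extension internal coordinates (bond
N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A, standard angles, omega fixed at
180 deg) with user-controlled phi/psi.  Sidechains are grafted from the
Chemical Component Dictionary ideal coordinates shipped with biotite, at
their default (CCD) rotamer, by superposing each template's N/CA/C triad
onto the built backbone.  Amide protons are placed trigonally in the
peptide plane; the C-terminus carries a charged carboxylate (O + OXT).

The amyloid-beta 42-mer fixtures encode the monomer topology used for the
oligomer models: a central turn (G25-K28) bringing the F19 and L34
sidechains into NOE contact range, a C-terminal beta-hairpin with its turn
at G37-G38, and an optionally alpha-helical N-terminus (residues 1-16).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Atom, Chain, RegionSpec, Residue, Structure, Trajectory, select
from .trajectory_stats import kabsch_superpose

__all__ = [
    "ConformationSpec",
    "FluctuationSpec",
    "ClashError",
    "ABETA42_SEQUENCE",
    "build_peptide",
    "build_reference_tripeptide",
    "build_cn_assembly",
    "simulate_trajectory",
    "build_abeta_monomer",
    "build_dodecamer_fixture",
    "default_sigma_profile",
]

#: Amyloid-beta 1-42 sequence (1-letter), numbering D1 ... A42.
ABETA42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Ideal peptide geometry (Angstroms / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (180.0, 180.0)
#: Ideal antiparallel beta-strand torsions used for hairpin strands.
STRAND_PHI_PSI = (-139.0, 135.0)
#: Type-I'-like two-residue turn with relaxed flanking torsions, fitted once
#: against ideal-geometry closure targets (cross-strand CA-CA near 4.9-5.3 A
#: with no non-bonded heavy-atom pair under 1.9 A): torsions for the
#: residues (i, i+1, i+2, i+3) of a turn whose first turn residue is i+1.
HAIRPIN_TURN = ((-140.5, 104.5), (79.4, 30.2), (90.0, 22.2), (-87.3, 171.6))

CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


class ClashError(ValueError):
    """Raised when a generated assembly contains near-overlapping atoms."""


@dataclass
class ConformationSpec:
    """Backbone conformation recipe for :func:`build_peptide`.

    ``kind`` selects helix (phi=-57, psi=-47), extended (phi=psi=180) or
    hairpin (two beta strands joined by a type-I' turn whose first turn
    residue is ``turn_center``).  Explicit ``phi``/``psi`` override the
    kind's defaults for non-turn residues.
    """

    kind: str
    phi: float | None = None
    psi: float | None = None
    turn_center: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "extended", "hairpin"):
            raise ValueError(f"unknown conformation kind {self.kind!r}")
        for t in (self.phi, self.psi):
            if t is not None and not (-180.0 < t <= 180.0):
                raise ValueError(f"torsion {t} outside (-180, 180]")
        if self.kind == "hairpin" and self.turn_center is None:
            raise ValueError("hairpin conformation requires turn_center")


@dataclass
class FluctuationSpec:
    """Gaussian fluctuation recipe for :func:`simulate_trajectory`.

    ``per_residue_sigma`` maps residue number to the per-Cartesian-
    coordinate standard deviation in Angstroms (missing residues get 0);
    ``unwind_nterm`` linearly interpolates backbone torsions of residues
    1-16 from the alpha-helical start toward an extended conformation over
    the course of the trajectory.
    """

    per_residue_sigma: dict[int, float] = field(default_factory=dict)
    n_frames: int = 200
    frame_interval: float = 10.0
    unwind_nterm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(s < 0 for s in self.per_residue_sigma.values()):
            raise ValueError("sigma values must be non-negative")

    def sigma(self, resnum: int) -> float:
        return self.per_residue_sigma.get(resnum, 0.0)


def default_sigma_profile(core_sigma: float = 0.4, nterm_sigma: float = 1.2) -> dict[int, float]:
    """Default fluctuation profile for dodecamer fixtures: a quiet
    hydrophobic core (residues 17-42) under a mobile N-terminus (1-16)."""
    prof = {r: nterm_sigma for r in range(1, 17)}
    prof.update({r: core_sigma for r in range(17, 43)})
    return prof


# ---------------------------------------------------------------------------
# Internal-coordinate backbone construction
# ---------------------------------------------------------------------------


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension reference frame placement of atom d bonded to c,
    with angle b-c-d and torsion a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _backbone(torsions: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone heavy atoms + amide H + terminal OXT for n residues."""
    n_res = len(torsions)
    res: list[dict[str, np.ndarray]] = [dict() for _ in range(n_res)]
    res[0]["N"] = np.zeros(3)
    res[0]["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    res[0]["C"] = res[0]["CA"] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        _, psi_prev = torsions[i - 1]
        phi_i, _ = torsions[i]
        p = res[i - 1]
        res[i]["N"] = _place(p["N"], p["CA"], p["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        res[i]["CA"] = _place(p["CA"], p["C"], res[i]["N"], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        res[i]["C"] = _place(p["C"], res[i]["N"], res[i]["CA"], BOND_CA_C, ANGLE_N_CA_C, phi_i)
    for i in range(n_res):
        _, psi_i = torsions[i]
        r = res[i]
        r["O"] = _place(r["N"], r["CA"], r["C"], BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)
        if i == n_res - 1:
            r["OXT"] = _place(r["N"], r["CA"], r["C"], 1.25, ANGLE_CA_C_O, psi_i)
    for i in range(n_res):
        r = res[i]
        if i == 0:
            direction = -(_unit(r["CA"] - r["N"]) + _unit(r["C"] - r["N"]))
        else:
            direction = -(_unit(r["CA"] - r["N"]) + _unit(res[i - 1]["C"] - r["N"]))
        r["H"] = r["N"] + BOND_N_H * _unit(direction)
    return res


_TEMPLATE_CACHE: dict[str, tuple[np.ndarray, list[tuple[str, str]], np.ndarray]] = {}
_BACKBONE_TEMPLATE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H2", "HXT"}


def _sidechain_template(resname: str):
    """CCD ideal-coordinate sidechain for ``resname``: (triad N/CA/C coords,
    [(name, element)], sidechain coords)."""
    if resname not in _TEMPLATE_CACHE:
        import biotite.structure.info as struct_info

        tmpl = struct_info.residue(resname)
        if tmpl is None:
            raise ValueError(f"unknown residue {resname!r}")
        names = [str(x) for x in tmpl.atom_name]
        triad = np.array([tmpl.coord[names.index(x)] for x in ("N", "CA", "C")])
        keep = [i for i, x in enumerate(names) if x not in _BACKBONE_TEMPLATE_NAMES]
        meta = [(names[i], str(tmpl.element[i]).capitalize()) for i in keep]
        _TEMPLATE_CACHE[resname] = (triad, meta, tmpl.coord[keep].copy())
    return _TEMPLATE_CACHE[resname]


def _rotate_about_bond(coords: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                       angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = _unit(p1 - p0)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    return (coords - p1) @ rot.T + p1


def _relieve_sidechain(names: list[str], elements: list[str], placed: np.ndarray,
                       ca: np.ndarray, prior_heavy: np.ndarray) -> np.ndarray:
    """Greedy chi1 (and, if needed, chi2) rotation of a grafted sidechain to
    clear steric overlap with previously built atoms.

    The CCD default rotamer is kept whenever it is clash-free; otherwise
    the rotation maximizing the closest heavy-atom approach is chosen.
    Deterministic by construction (fixed candidate grids, first-best wins).
    """
    heavy = [i for i, e in enumerate(elements) if e != "H" and names[i] != "CB"]
    if "CB" not in names or prior_heavy.shape[0] == 0 or not heavy:
        return placed
    cb = placed[names.index("CB")]
    movable1 = [i for i, n in enumerate(names) if n not in ("HA", "HA2", "HA3")]

    def min_dist(xyz: np.ndarray) -> float:
        d = np.linalg.norm(
            xyz[[i for i in heavy]][:, None, :] - prior_heavy[None, :, :], axis=2
        )
        return float(d.min())

    if min_dist(placed) >= 1.7:
        return placed
    # chi2 only for single-gamma-branch sidechains (rotating a branched CB
    # would distort the other branch's bond angles)
    chi2_axis = "CG" if "CG" in names and "CG2" not in names else None
    best = (min_dist(placed), placed)
    for chi1 in (0.0, 120.0, 240.0):
        for chi2 in ((0.0, 120.0, 240.0) if chi2_axis else (0.0,)):
            xyz = placed.copy()
            if chi1:
                xyz[movable1] = _rotate_about_bond(xyz[movable1], ca, cb, chi1)
            if chi2 and chi2_axis:
                cg = xyz[names.index(chi2_axis)]
                movable2 = [
                    i for i in movable1
                    if names[i] not in ("CB", chi2_axis, "HB", "HB1", "HB2", "HB3")
                ]
                if movable2:
                    xyz[movable2] = _rotate_about_bond(xyz[movable2], xyz[names.index("CB")], cg, chi2)
            score = min_dist(xyz)
            if score > best[0]:
                best = (score, xyz)
            if score >= 1.7 and (chi1, chi2) == (0.0, 0.0):
                return xyz
    return best[1]


def _build_from_torsions(
    sequence: str,
    torsions: list[tuple[float, float]],
    chain_id: str = "A",
    start_resnum: int = 1,
) -> Structure:
    for letter in sequence:
        if letter not in AA3:
            raise ValueError(f"unknown residue letter {letter!r}")
    if len(sequence) != len(torsions):
        raise ValueError("one (phi, psi) pair per residue required")
    bb = _backbone(torsions)
    residues: list[Residue] = []
    serial = 0
    for i, letter in enumerate(sequence):
        resname = AA3[letter]
        atoms: list[Atom] = []

        def add(name: str, element: str, coords: np.ndarray) -> None:
            nonlocal serial
            serial += 1
            atoms.append(
                Atom(serial, name, element, np.asarray(coords, dtype=float),
                     is_hydrogen=element == "H")
            )

        r = bb[i]
        add("N", "N", r["N"])
        add("CA", "C", r["CA"])
        add("C", "C", r["C"])
        add("O", "O", r["O"])
        if resname != "PRO":
            add("H", "H", r["H"])
        triad, meta, side = _sidechain_template(resname)
        built_triad = np.array([r["N"], r["CA"], r["C"]])
        t, _ = kabsch_superpose(triad, built_triad)
        placed = t.apply(side)
        side_names = [n for n, _ in meta]
        side_elements = [e for _, e in meta]
        if resname != "PRO":
            prior_heavy = np.array(
                [a.coords for res in residues for a in res.atoms if not a.is_hydrogen]
                + [a.coords for a in atoms if not a.is_hydrogen],
            ).reshape(-1, 3)
            placed = _relieve_sidechain(side_names, side_elements, placed, r["CA"], prior_heavy)
        for (name, element), xyz in zip(meta, placed):
            add(name, element, xyz)
        if i == len(sequence) - 1:
            add("OXT", "O", r["OXT"])
        residues.append(Residue(resname, start_resnum + i, atoms))
    return Structure([Chain(chain_id, residues)])


def _hairpin_torsions(n_res: int, turn_index: int) -> list[tuple[float, float]]:
    """Strand / turn / strand torsion list; ``turn_index`` is the 0-based
    position of the first of the two turn residues."""
    if not (1 <= turn_index and turn_index + 2 <= n_res - 1):
        raise ValueError("turn_center must be strictly inside the chain")
    torsions = [STRAND_PHI_PSI] * n_res
    for k, pair in enumerate(HAIRPIN_TURN):
        torsions[turn_index - 1 + k] = pair
    return torsions


def build_peptide(
    sequence: str,
    conf: ConformationSpec,
    chain_id: str = "A",
    start_resnum: int = 1,
) -> Structure:
    """Build an ideal-geometry peptide in the requested conformation.

    Returns a single-chain :class:`Structure` with backbone hydrogens
    placed, CCD default-rotamer sidechains, and a carboxylate C-terminus.
    Residue numbers start at ``start_resnum`` (use 31 for the C-terminal
    hairpin of the 42-mer so that the turn lands on G37-G38).
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    n = len(sequence)
    if conf.kind == "helix":
        pair = (conf.phi if conf.phi is not None else HELIX_PHI_PSI[0],
                conf.psi if conf.psi is not None else HELIX_PHI_PSI[1])
        torsions = [pair] * n
    elif conf.kind == "extended":
        pair = (conf.phi if conf.phi is not None else EXTENDED_PHI_PSI[0],
                conf.psi if conf.psi is not None else EXTENDED_PHI_PSI[1])
        torsions = [pair] * n
    else:
        turn_index = conf.turn_center - start_resnum
        torsions = _hairpin_torsions(n, turn_index)
        if conf.phi is not None or conf.psi is not None:
            strand = (conf.phi if conf.phi is not None else STRAND_PHI_PSI[0],
                      conf.psi if conf.psi is not None else STRAND_PHI_PSI[1])
            turn_span = range(turn_index - 1, turn_index + 3)
            for i in range(n):
                if i not in turn_span:
                    torsions[i] = strand
    return _build_from_torsions(sequence, torsions, chain_id, start_resnum)


def build_reference_tripeptide(x: str, flank: str = "A") -> Structure:
    """Extended flank-x-flank tripeptide used as the rSASA denominator.

    ``flank`` is "A" (AxA) or "G" (GxA); all backbone torsions are 180 deg
    and hydrogens are placed.  The central residue is at position 2.
    """
    if flank not in ("A", "G"):
        raise ValueError("flank must be 'A' or 'G'")
    if x not in AA3:
        raise ValueError(f"unknown residue letter {x!r}")
    return build_peptide(flank + x + "A", ConformationSpec("extended"))


def _relabel_chains(chains: list[Chain]) -> list[Chain]:
    if len(chains) > len(CHAIN_LETTERS):
        raise ValueError("too many chains to relabel uniquely")
    out = []
    for letter, c in zip(CHAIN_LETTERS, chains):
        out.append(Chain(letter, c.residues))
    return out


def _min_intercopy_distance(copies: list[Structure]) -> float:
    from scipy.spatial import cKDTree

    best = np.inf
    clouds = []
    for s in copies:
        mask = s.heavy_mask()
        clouds.append(s.coords[mask])
    for i in range(len(clouds)):
        tree = cKDTree(clouds[i])
        for j in range(i + 1, len(clouds)):
            d, _ = tree.query(clouds[j], k=1)
            best = min(best, float(d.min()))
    return best


def _merge(copies: list[Structure], title: str = "") -> Structure:
    chains: list[Chain] = []
    for s in copies:
        chains.extend(c for c in s.chains)
    merged = Structure(_relabel_chains(chains), title)
    merged.validate()
    return merged


def build_cn_assembly(
    subunit: Structure, n: int, axis: np.ndarray, ring_radius: float
) -> Structure:
    """Cn ring: ``n`` copies of ``subunit`` related by 360/n-deg rotations
    about ``axis`` (through the origin), with the subunit centroid shifted
    radially to ``ring_radius``.  Chains are re-lettered uniquely; copies
    closer than 1.0 A (heavy atoms) raise :class:`ClashError`."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if ring_radius < 0:
        raise ValueError("ring_radius must be non-negative")
    axis = _unit(np.asarray(axis, dtype=float))
    centroid = subunit.coords.mean(0)
    radial = centroid - np.dot(centroid, axis) * axis
    if np.linalg.norm(radial) < 1e-9:
        # centroid on the axis: pick any perpendicular direction
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, axis)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        u = _unit(probe - np.dot(probe, axis) * axis)
    else:
        u = _unit(radial)
    shift = (ring_radius - float(np.linalg.norm(radial))) * u
    base = subunit.copy()
    base.set_coords(base.coords + shift)
    from .structures import TransformOp, apply_transform

    copies = [base]
    for k in range(1, n):
        t = TransformOp.rotation_about_axis(axis, 360.0 * k / n)
        copies.append(apply_transform(base, t))
    dmin = _min_intercopy_distance(copies)
    if dmin < 1.0:
        raise ClashError(
            f"inter-copy heavy-atom distance {dmin:.2f} A < 1.0 A; "
            "increase ring_radius"
        )
    return _merge(copies, title=f"C{n} assembly")


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

_NTERM_LAST = 16  # helical segment is residues 1..16; residue 17 anchors it


def _measure_unwind_chains(s: Structure) -> list[Chain]:
    out = []
    for c in s.chains:
        nums = {r.resnum for r in c.residues}
        if 1 in nums and set(range(1, _NTERM_LAST + 2)) <= nums:
            out.append(c)
    return out


def _interp_angle(a: float, b: float, lam: float) -> float:
    """Shortest-path interpolation between two angles in degrees."""
    delta = (b - a + 180.0) % 360.0 - 180.0
    return a + lam * delta


def _unwound_coords(chain: Chain, base: dict[tuple[int, str], np.ndarray], lam: float):
    """Rebuild residues 1..16 of ``chain`` with torsions interpolated from
    the helical start toward extended by fraction ``lam``, anchored on the
    residue-17 backbone triad.  Returns {(resnum, name): coords}."""
    seq = "".join(
        next(k for k, v in AA3.items() if v == r.resname)
        for r in chain.residues
        if r.resnum <= _NTERM_LAST + 1
    )
    phi = _interp_angle(HELIX_PHI_PSI[0], -180.0, lam)
    psi = _interp_angle(HELIX_PHI_PSI[1], -180.0, lam)
    torsions = [(phi, psi)] * _NTERM_LAST + [STRAND_PHI_PSI]
    seg = _build_from_torsions(seq, torsions, chain.chain_id, 1)
    seg_chain = seg.chains[0]
    anchor_built = np.array([seg_chain.residue(_NTERM_LAST + 1).atom(n).coords for n in ("N", "CA", "C")])
    anchor_ref = np.array([base[(_NTERM_LAST + 1, n)] for n in ("N", "CA", "C")])
    t, _ = kabsch_superpose(anchor_built, anchor_ref)
    out: dict[tuple[int, str], np.ndarray] = {}
    for r in seg_chain.residues:
        if r.resnum > _NTERM_LAST:
            continue
        for a in r.atoms:
            out[(r.resnum, a.name)] = t.apply(a.coords[None, :])[0]
    return out


def simulate_trajectory(s: Structure, fl: FluctuationSpec) -> Trajectory:
    """Generate a synthetic trajectory around ``s``.

    Frame f = reference + i.i.d. Gaussian noise with per-coordinate
    standard deviation sigma(residue); with ``unwind_nterm`` the reference
    for residues 1-16 of each 42-mer chain additionally interpolates,
    frame by frame, from the initial alpha-helix toward an extended coil
    (the closed-form B-factor of an atom remains 8 pi^2 sigma^2 plus the
    systematic unwinding contribution).  A fixed seed makes the output
    bit-reproducible.
    """
    rng = np.random.default_rng(fl.seed)
    base = s.coords
    keys = s.atom_keys()
    sigmas = np.array([fl.sigma(resnum) for _, resnum, _ in keys])
    unwind_chains = _measure_unwind_chains(s) if fl.unwind_nterm else []
    if fl.unwind_nterm and not unwind_chains:
        raise ValueError("unwind_nterm requested but no chain has residues 1-17")
    key_index = {k: i for i, k in enumerate(keys)}
    base_by_chain: dict[str, dict[tuple[int, str], np.ndarray]] = {}
    for c in unwind_chains:
        base_by_chain[c.chain_id] = {
            (r.resnum, a.name): a.coords for r in c.residues for a in r.atoms
        }
    frames: list[np.ndarray] = []
    for f in range(fl.n_frames):
        ref = base.copy()
        if unwind_chains:
            lam = f / max(fl.n_frames - 1, 1)
            for c in unwind_chains:
                rebuilt = _unwound_coords(c, base_by_chain[c.chain_id], lam)
                for (resnum, name), xyz in rebuilt.items():
                    idx = key_index.get((c.chain_id, resnum, name))
                    if idx is None:
                        raise ValueError(
                            f"chain {c.chain_id} residue {resnum} atom {name}: "
                            "topology does not match the ideal-geometry builder; "
                            "unwinding requires builder-generated N-termini"
                        )
                    ref[idx] = xyz
        noise = rng.standard_normal(ref.shape) * sigmas[:, None]
        frames.append(ref + noise)
    return Trajectory(s.copy(), frames, frame_interval=fl.frame_interval)


def build_abeta_core_monomer(chain_id: str = "A") -> Structure:
    """The 17-42 core monomer (beta-meander, no N-terminus) used as the
    docking subunit; helical N-termini are grafted onto accepted
    assemblies afterwards."""
    torsions = [_MONOMER_CORE_TORSIONS[r] for r in range(17, 43)]
    s = _build_from_torsions(ABETA42_SEQUENCE[16:42], torsions, chain_id, 17)
    return _canonicalize_monomer(s)


def graft_helical_nterm(s: Structure) -> Structure:
    """Prepend alpha-helical residues 1-16 to every chain starting at
    residue 17, anchored on that residue's backbone triad."""
    out_chains = []
    for chain in s.chains:
        if chain.residues[0].resnum != 17:
            out_chains.append(Chain(chain.chain_id, [r for r in chain.residues]))
            continue
        anchor = chain.residue(17)
        seq = ABETA42_SEQUENCE[:17]
        torsions = [HELIX_PHI_PSI] * 16 + [_HELIX_LINKER_17]
        seg = _build_from_torsions(seq, torsions, chain.chain_id, 1)
        seg_chain = seg.chains[0]
        built = np.array([seg_chain.residue(17).atom(n).coords for n in ("N", "CA", "C")])
        ref = np.array([anchor.atom(n).coords for n in ("N", "CA", "C")])
        t, _ = kabsch_superpose(built, ref)
        new_residues = []
        for r in seg_chain.residues:
            if r.resnum > 16:
                continue
            atoms = [
                Atom(a.serial, a.name, a.element, t.apply(a.coords[None, :])[0],
                     is_hydrogen=a.is_hydrogen)
                for a in r.atoms
            ]
            new_residues.append(Residue(r.resname, r.resnum, atoms))
        out_chains.append(Chain(chain.chain_id, new_residues + [r for r in chain.residues]))
    out = Structure(out_chains, s.title)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Amyloid-beta 42-mer fixtures
# ---------------------------------------------------------------------------

#: Per-residue (phi, psi) for the 42-mer monomer fixture: helical or coil
#: N-terminus (1-16), beta-meander core with a broad central turn (25-28)
#: pairing F19 against L34, and the C-terminal hairpin turn at G37-G38.
#: The two turns were fitted jointly (once) so that the meander pairs F19
#: against L34 across the central turn and closes the C-terminal hairpin
#: (34<->41) without steric overlap; strand residues use STRAND_PHI_PSI.
_MONOMER_CORE_TORSIONS: dict[int, tuple[float, float]] = {
    **{r: STRAND_PHI_PSI for r in range(17, 25)},
    25: (-130.8, 101.4),
    26: (89.0, 71.2),
    27: (59.1, 34.4),
    28: (-104.4, 157.9),
    **{r: STRAND_PHI_PSI for r in range(29, 36)},
    36: (-62.8, 166.4),
    37: (73.9, 38.8),
    38: (73.4, 34.0),
    39: (-125.1, 93.2),
    **{r: STRAND_PHI_PSI for r in range(40, 43)},
}


#: Linker torsion at residue 17 directing a helical N-terminus away from
#: the hairpin core (fitted once together with the meander turns).
_HELIX_LINKER_17 = (-70.0, -30.0)


def _monomer_torsions(helical_nterm: bool) -> list[tuple[float, float]]:
    nterm = HELIX_PHI_PSI if helical_nterm else EXTENDED_PHI_PSI
    torsions = []
    for r in range(1, 43):
        if r <= _NTERM_LAST:
            torsions.append(nterm)
        elif r == 17 and helical_nterm:
            torsions.append(_HELIX_LINKER_17)
        else:
            torsions.append(_MONOMER_CORE_TORSIONS[r])
    return torsions


def _canonicalize_monomer(s: Structure) -> Structure:
    """Place the C-terminal core at the origin with the hairpin strand axis
    along -z and the N-terminus pointing along +x (the outward direction
    used by the ring assemblies)."""
    ca = {r.resnum: r.atom("CA").coords for r in s.chains[0].residues}
    cterm_cent = np.mean([ca[r] for r in range(31, 43)], axis=0)
    # "outward" reference: the N-terminal segment when present, else the
    # central region of the 17-42 core
    out_res = [r for r in range(1, 17) if r in ca] or [r for r in range(17, 31) if r in ca]
    nterm_cent = np.mean([ca[r] for r in out_res], axis=0)
    e_z = -_unit(ca[36] - ca[31])
    out = nterm_cent - cterm_cent
    e_x = _unit(out - np.dot(out, e_z) * e_z)
    e_y = np.cross(e_z, e_x)
    rot = np.stack([e_x, e_y, e_z])
    res = s.copy()
    res.set_coords((res.coords - cterm_cent) @ rot.T)
    return res


def build_abeta_monomer(helical_nterm: bool = True, chain_id: str = "A") -> Structure:
    """The 42-mer monomer fixture in its canonical assembly frame."""
    s = _build_from_torsions(ABETA42_SEQUENCE, _monomer_torsions(helical_nterm), chain_id)
    return _canonicalize_monomer(s)


def build_abeta_dimer(helical_nterm: bool = True, ring_radius: float = 13.0) -> Structure:
    """The asymmetric 2-chain unit of the hexamer ring.

    Chain A sits at azimuth 0 deg with its hairpin at ``ring_radius`` from
    the z axis; chain B is the z-flipped copy at azimuth 60 deg, so the
    C-terminal turns of adjacent chains alternate direction (antiparallel
    neighbors) around the eventual ring.
    """
    from .structures import TransformOp, apply_transform

    monomer = build_abeta_monomer(helical_nterm)
    monomer.set_coords(monomer.coords + np.array([ring_radius, 0.0, 0.0]))
    flip = TransformOp.rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0)
    rot60 = TransformOp.rotation_about_axis(np.array([0.0, 0.0, 1.0]), 60.0)
    second = apply_transform(monomer, rot60.compose(flip))
    return _merge([monomer, second])


def build_dodecamer_fixture(
    helical_nterm: bool = True,
    ring_radius: float = 13.0,
    stack_separation: float = 15.0,
    stagger_deg: float = 20.0,
) -> Structure:
    """The standard dodecamer fixture: a dimer of C3-symmetric hexamers.

    Three copies of the 2-chain unit from :func:`build_abeta_dimer` form a
    C3 ring of six monomers about z, C-terminal hairpins facing the axis
    and N-termini radiating outward; a second hexamer, flipped upside
    down, staggered by ``stagger_deg`` and shifted down the axis, stacks
    against the first.  The result has 12 chains, a shielded C-terminal
    core, solvent-facing N-termini, and exact C3 symmetry per hexamer.
    """
    from .structures import TransformOp, apply_transform

    dimer = build_abeta_dimer(helical_nterm, ring_radius)
    centroid_radius = float(
        np.linalg.norm(dimer.coords.mean(0)[:2])
    )
    hexamer = build_cn_assembly(dimer, 3, np.array([0.0, 0.0, 1.0]), centroid_radius)
    flip_stack = TransformOp.rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0)
    stagger = TransformOp.rotation_about_axis(np.array([0.0, 0.0, 1.0]), stagger_deg)
    lower = apply_transform(hexamer, stagger.compose(flip_stack))
    lower.set_coords(lower.coords + np.array([0.0, 0.0, -stack_separation]))
    dodecamer = _merge([hexamer, lower], title="synthetic dodecamer fixture")
    dmin = _min_intercopy_distance([hexamer, lower])
    if dmin < 1.0:
        raise ClashError(f"hexamer stacking clash ({dmin:.2f} A); increase separation")
    return dodecamer
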