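"""Hierarchical structure model, PDB I/O, atom selection and rigid transforms.

The object model is deliberately small: a :class:`Structure` is an ordered
list of chains, each an ordered list of residues, each an ordered list of
atoms with Cartesian coordinates in Angstroms.  A :class:`Trajectory` is a
single topology plus a stack of per-frame coordinate arrays, which is also
the in-memory image of a multi-model PDB file.  All analysis code in this
package consumes these two types.

Residue numbering is 1-based and follows the amyloid-beta 1-42 convention
used throughout (F19, K28, L34, the G37-G38 turn, and the three regions
N-terminal 1-17 / central 18-30 / C-terminal 31-42).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Trajectory",
    "RegionSpec",
    "TransformOp",
    "PDBFormatError",
    "TopologyMismatchError",
    "InvalidRotationError",
    "parse_pdb",
    "write_pdb",
    "select",
    "apply_transform",
]

MAINCHAIN_NAMES = frozenset({"N", "CA", "C", "O"})
#: Backbone atoms excluded from sidechain selections (CA belongs to the
#: backbone here, so glycine has an empty sidechain).
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3"})

AtomFilter = Literal["all", "heavy", "mainchain", "calpha", "sidechain", "amide_proton"]


class PDBFormatError(ValueError):
    """Raised for unparseable or unsupported PDB content."""


class TopologyMismatchError(PDBFormatError):
    """Raised when MODEL blocks of a multi-model file disagree on atoms."""


class InvalidRotationError(ValueError):
    """Raised when a transform's rotation is not a proper rotation."""


@dataclass
class Atom:
    """A single atom: PDB-style name, element, position and thermal factor."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    resname: str
    resnum: int
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"residue {self.resname}{self.resnum}: duplicate atom names")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.resname}{self.resnum} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums = [r.resnum for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"chain {self.chain_id}: resnum not strictly increasing")

    def residue(self, resnum: int) -> Residue:
        for r in self.residues:
            if r.resnum == resnum:
                return r
        raise KeyError(f"chain {self.chain_id} has no residue {resnum}")


@dataclass
class Structure:
    """An ordered chain/residue/atom hierarchy with Angstrom coordinates."""

    chains: list[Chain] = field(default_factory=list)
    title: str = ""

    # -- iteration & array views -------------------------------------------
    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates in topology order (a copy)."""
        if self.n_atoms == 0:
            return np.empty((0, 3))
        return np.array([a.coords for _, _, a in self.iter_atoms()])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError(f"expected ({self.n_atoms}, 3) coordinates, got {xyz.shape}")
        for (_, _, a), row in zip(self.iter_atoms(), xyz):
            a.coords = row.copy()

    def atom_keys(self) -> list[tuple[str, int, str]]:
        """(chain_id, resnum, atom name) per atom, in topology order."""
        return [(c.chain_id, r.resnum, a.name) for c, r, a in self.iter_atoms()]

    def elements(self) -> list[str]:
        return [a.element for _, _, a in self.iter_atoms()]

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for _, _, a in self.iter_atoms()], dtype=bool)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def copy(self) -> "Structure":
        chains = [
            Chain(
                c.chain_id,
                [
                    Residue(r.resname, r.resnum, [replace(a, coords=a.coords.copy()) for a in r.atoms])
                    for r in c.residues
                ],
            )
            for c in self.chains
        ]
        return Structure(chains, self.title)

    def validate(self) -> None:
        keys = self.atom_keys()
        if len(keys) != len(set(keys)):
            raise ValueError("(chain, resnum, atom name) not jointly unique")

    def subset_chains(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = set(chain_ids)
        missing = wanted - {c.chain_id for c in self.chains}
        if missing:
            raise KeyError(f"no such chains: {sorted(missing)}")
        s = self.copy()
        s.chains = [c for c in s.chains if c.chain_id in wanted]
        return s


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology.

    ``frames`` is a list of (n_atoms, 3) arrays; ``frame_interval`` is the
    sampling spacing in picoseconds (10 ps by convention here).
    """

    topology: Structure
    frames: list[np.ndarray]
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        n = self.topology.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise TopologyMismatchError(
                    f"frame {i}: expected ({n}, 3) coordinates, got {f.shape}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.frames[i])
        return s


@dataclass
class RegionSpec:
    """A named residue-range selection with an atom-level filter.

    ``ranges`` are inclusive (start, end) residue-number pairs; the default
    regions used in this package are N-terminal 1-17, central 18-30,
    C-terminal 31-42 and core 17-42.
    """

    name: str
    ranges: list[tuple[int, int]]
    atom_filter: AtomFilter = "all"

    def __post_init__(self) -> None:
        for a, b in self.ranges:
            if a > b:
                raise ValueError(f"region {self.name}: range ({a}, {b}) has start > end")
        spans = sorted(self.ranges)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"region {self.name}: overlapping ranges")
        if self.atom_filter not in (
            "all",
            "heavy",
            "mainchain",
            "calpha",
            "sidechain",
            "amide_proton",
        ):
            raise ValueError(f"unknown atom_filter {self.atom_filter!r}")

    def contains(self, resnum: int) -> bool:
        return any(a <= resnum <= b for a, b in self.ranges)


@dataclass
class TransformOp:
    """A proper rigid motion x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        det = np.linalg.det(self.rotation)
        if err > 1e-9 or abs(det - 1.0) > 1e-9:
            raise InvalidRotationError(
                f"not a proper rotation (orthonormality error {err:.2e}, det {det:.6f})"
            )

    @classmethod
    def identity(cls) -> "TransformOp":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def rotation_about_axis(
        cls, axis: np.ndarray, angle_deg: float, center: np.ndarray | None = None
    ) -> "TransformOp":
        """Rotation by ``angle_deg`` about ``axis`` through ``center`` (default origin)."""
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("axis must be non-zero")
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm).as_matrix()
        center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        return cls(rot, center - rot @ center)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    def compose(self, other: "TransformOp") -> "TransformOp":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return TransformOp(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_STANDARD_ELEMENTS = ("C", "N", "O", "S", "P", "H")


def _infer_element(name: str, raw_name_field: str) -> str:
    """PDB element inference when columns 77-78 are blank.

    The element occupies columns 13-14 of the name field when present; a
    name starting in column 14 (single-letter element) is the common case
    for protein atoms.  Digit-led names (``1HB``) and ``H*`` names are
    hydrogens.
    """
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise PDBFormatError(f"cannot infer element for atom name {name!r}")
    if name[0].isdigit() or stripped[0] == "H":
        return "H"
    two = raw_name_field[:2].strip()
    if two.upper() in ("FE", "ZN", "MG", "NA", "CL", "CA", "BR", "CU", "MN", "SE"):
        # Only trust a two-letter metal symbol when it starts in column 13.
        if len(raw_name_field) >= 1 and raw_name_field[0] != " ":
            return two.capitalize()
    first = stripped[0].upper()
    if first in _STANDARD_ELEMENTS:
        return first
    raise PDBFormatError(f"cannot infer element for atom name {name!r}")


def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17]
        resname = line[17:20].strip()
        chain_id = line[21:22]
        resnum = int(line[22:26])
        icode = line[26:27]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        b_field = line[60:66].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        bfactor = float(b_field) if b_field else 0.0
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: unparseable ATOM/HETATM record ({exc})") from exc
    if icode.strip():
        raise PDBFormatError(f"line {lineno}: insertion codes are not supported")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if element:
        element = element.capitalize()
    else:
        element = _infer_element(name, line[12:16])
    return serial, name, altloc, resname, chain_id, resnum, x, y, z, occupancy, bfactor, element


def _build_structure(records: list[tuple]) -> Structure:
    """Assemble parsed ATOM records into a Structure, resolving altlocs."""
    chains: list[Chain] = []
    chain_map: dict[str, Chain] = {}
    res_map: dict[tuple[str, int], Residue] = {}
    # altloc resolution: (chain, resnum, name) -> (occupancy, first_index)
    chosen: dict[tuple[str, int, str], tuple[float, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for serial, name, altloc, resname, chain_id, resnum, x, y, z, occ, b, element in records:
        key = (chain_id, resnum, name)
        atom = Atom(
            serial=serial,
            name=name,
            element=element,
            coords=np.array([x, y, z]),
            occupancy=occ,
            bfactor=b,
            is_hydrogen=element in ("H", "D"),
        )
        if key in chosen:
            if altloc.strip() == "":
                raise PDBFormatError(f"duplicate atom {key} without alternate-location codes")
            if occ > chosen[key][0]:  # strict: ties keep the first encountered
                chosen[key] = (occ, atom)
            continue
        chosen[key] = (occ, atom)
        order.append((chain_id, resnum, resname, name))
    for chain_id, resnum, resname, name in order:
        if chain_id not in chain_map:
            chain_map[chain_id] = Chain(chain_id, [])
            chains.append(chain_map[chain_id])
        rkey = (chain_id, resnum)
        if rkey not in res_map:
            res_map[rkey] = Residue(resname, resnum, [])
            chain_map[chain_id].residues.append(res_map[rkey])
        res_map[rkey].atoms.append(chosen[(chain_id, resnum, name)][1])
    for c in chains:  # re-validate strict ordering after assembly
        Chain(c.chain_id, c.residues)
    s = Structure(chains)
    s.validate()
    return s


def parse_pdb(text: str, frame_interval: float = 10.0) -> Structure | Trajectory:
    """Parse PDB text into a :class:`Structure` or, if it holds two or more
    MODEL blocks, a :class:`Trajectory`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first encountered); hydrogens are flagged from the
    element column, falling back to name heuristics.  Insertion codes are
    rejected.
    """
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    saw_model = False
    title_parts: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            saw_model = True
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            models.append(current)
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
        elif rec == "TITLE ":
            title_parts.append(line[10:].strip())
    if current and (not saw_model or in_model):
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBFormatError("no ATOM/HETATM records found")
    first = _build_structure(models[0])
    first.title = " ".join(title_parts)
    if len(models) == 1:
        return first
    ref_keys = first.atom_keys()
    frames = [first.coords]
    for i, recs in enumerate(models[1:], start=2):
        s = _build_structure(recs)
        if s.atom_keys() != ref_keys:
            raise TopologyMismatchError(f"MODEL {i} atom list differs from MODEL 1")
        frames.append(s.coords)
    return Trajectory(first, frames, frame_interval=frame_interval)


def _format_atom_name(name: str, element: str) -> str:
    # Single-letter elements start in column 14 unless the name is 4 chars.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[0].isdigit():
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(serial: int, a: Atom, resname: str, chain_id: str, resnum: int) -> str:
    if serial > 99999:
        raise ValueError("serial overflow: structure has more than 99999 atoms")
    x, y, z = a.coords
    for v in (x, y, z):
        if abs(v) >= 10000:
            raise ValueError(f"coordinate {v} does not fit PDB fixed columns")
    return (
        f"ATOM  {serial:5d} {_format_atom_name(a.name, a.element)} {resname:<3s} "
        f"{chain_id}{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def _structure_lines(s: Structure) -> list[str]:
    lines: list[str] = []
    serial = 0
    for c in s.chains:
        for r in c.residues:
            for a in r.atoms:
                serial += 1
                lines.append(_atom_line(serial, a, r.resname, c.chain_id, r.resnum))
        serial += 1
        if serial > 99999:
            raise ValueError("serial overflow: structure has more than 99999 atoms")
        last = c.residues[-1]
        lines.append(f"TER   {serial:5d}      {last.resname:<3s} {c.chain_id}{last.resnum:4d}")
    return lines


def write_pdb(s: Structure | Trajectory) -> str:
    """Serialize to fixed-column PDB text (MODEL/ENDMDL blocks for trajectories)."""
    if isinstance(s, Trajectory):
        out: list[str] = []
        work = s.topology.copy()
        for i, frame in enumerate(s.frames, start=1):
            work.set_coords(frame)
            out.append(f"MODEL     {i:4d}")
            out.extend(_structure_lines(work))
            out.append("ENDMDL")
        out.append("END")
        return "\n".join(out) + "\n"
    if s.n_atoms == 0:
        raise ValueError("cannot write an empty structure")
    lines = _structure_lines(s)
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Selection and transforms
# ---------------------------------------------------------------------------


def _passes_filter(res: Residue, atom: Atom, f: AtomFilter) -> bool:
    if f == "all":
        return True
    if f == "heavy":
        return not atom.is_hydrogen
    if f == "mainchain":
        return atom.name in MAINCHAIN_NAMES
    if f == "calpha":
        return atom.name == "CA" and not atom.is_hydrogen
    if f == "sidechain":
        return not atom.is_hydrogen and atom.name not in BACKBONE_NAMES
    if f == "amide_proton":
        return atom.is_hydrogen and atom.name == "H" and res.has_atom("N")
    raise ValueError(f"unknown atom_filter {f!r}")


def select(
    s: Structure, spec: RegionSpec, chains: set[str] | None = None
) -> list[int]:
    """Atom indices (topology order) matching ``spec``, optionally restricted
    to a set of chain ids.

    The residue-range restriction is applied first, the atom filter second.
    An ``amide_proton`` selection on a hydrogen-free structure returns an
    empty list with a warning, since that usually means the input was built
    without protons.
    """
    out: list[int] = []
    any_hydrogen = False
    for i, (c, r, a) in enumerate(s.iter_atoms()):
        any_hydrogen = any_hydrogen or a.is_hydrogen
        if chains is not None and c.chain_id not in chains:
            continue
        if not spec.contains(r.resnum):
            continue
        if _passes_filter(r, a, spec.atom_filter):
            out.append(i)
    if spec.atom_filter == "amide_proton" and not out and not any_hydrogen:
        warnings.warn(
            "amide_proton selection on a structure without hydrogens; "
            "build fixtures with hydrogens or add them before rSASA analysis",
            stacklevel=2,
        )
    return out


def apply_transform(
    s: Structure, t: TransformOp, subset: Sequence[int] | None = None
) -> Structure:
    """Return a copy of ``s`` with x' = R x + t applied to ``subset``
    (default: all atoms).  Topology is unchanged."""
    out = s.copy()
    xyz = out.coords
    if subset is None:
        xyz = t.apply(xyz)
    else:
        idx = np.asarray(list(subset), dtype=int)
        xyz[idx] = t.apply(xyz[idx])
    out.set_coords(xyz)
    return out
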