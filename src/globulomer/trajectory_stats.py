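"""Ensemble statistics over trajectories.

Implements the analysis surface used for the oligomer simulations: least-
squares superposition (Kabsch), RMSD time series against a reference over a
core and a total selection, radii of gyration, crystallographic-convention
B-factors from positional fluctuations, minimum sidechain-distance monitors
(NOE-style), and convergence diagnostics (coefficient of variation and
linear drift) for any scalar series.

Conventions
-----------
* RMSD is computed after superposing each frame on the same selection it is
  reported over (fit selection == report selection).
* B = (8 pi^2 / 3) <|x - <x>|^2>, i.e. the isotropic crystallographic
  B-factor in A^2; per-residue values average mainchain atoms, and profiles
  average equivalent positions over chains.
* Rg is mass-weighted over heavy atoms by default (hydrogen positions in
  synthetic fixtures are idealized, so they carry no information).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import (
    RegionSpec,
    Structure,
    Trajectory,
    TransformOp,
    select,
)

__all__ = [
    "RmsdSeries",
    "BfactorProfile",
    "DistanceSeries",
    "ConvergenceReport",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "bfactor_profile",
    "distance_series",
    "convergence_stats",
]

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "Se": 78.971,
}

B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class RmsdSeries:
    times: np.ndarray
    core: np.ndarray
    total: np.ndarray
    core_selection: RegionSpec
    total_selection: RegionSpec


@dataclass
class BfactorProfile:
    per_residue: dict[int, float]
    window: tuple[float, float]


@dataclass
class DistanceSeries:
    """Per-frame minimum sidechain heavy-atom distance between two residues.

    ``per_frame`` averages over chains; ``samples`` holds every
    (chain, frame) minimum so that tolerance fractions count each chain."""

    times: np.ndarray
    per_frame: np.ndarray
    samples: np.ndarray
    mean: float

    def fraction_under(self, tolerance: float) -> float:
        return float(np.mean(self.samples < tolerance))


@dataclass
class ConvergenceReport:
    cv: float
    slope: float
    window: tuple[float, float]


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[TransformOp, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper-rotation rigid transform T with T(mobile) ~ reference
    and the post-fit (weighted) RMSD in Angstroms.  Point sets must contain
    at least 3 non-collinear points; degenerate sets are rejected because
    the optimal rotation is then not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    cm = (w[:, None] * mobile).sum(0) / w.sum()
    cr = (w[:, None] * reference).sum(0) / w.sum()
    mob_c = mobile - cm
    ref_c = reference - cr
    for pts in (mob_c, ref_c):
        if np.linalg.matrix_rank(pts * np.sqrt(w)[:, None], tol=1e-9) < 2:
            raise ValueError("degenerate (collinear or coincident) point set")
    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    rmat = rot.as_matrix()
    d = ref_c - mob_c @ rmat.T
    rmsd = float(np.sqrt((w * (d**2).sum(1)).sum() / w.sum()))
    return TransformOp(rmat, cr - rmat @ cm), rmsd


def _matched_selection(
    topology: Structure, reference: Structure, region: RegionSpec
) -> tuple[list[int], list[int]]:
    idx_t = select(topology, region)
    idx_r = select(reference, region)
    keys_t = topology.atom_keys()
    keys_r = reference.atom_keys()
    if [keys_t[i] for i in idx_t] != [keys_r[i] for i in idx_r]:
        raise ValueError(
            f"selection {region.name!r} does not match between trajectory "
            "topology and reference structure"
        )
    if not idx_t:
        raise ValueError(f"selection {region.name!r} is empty")
    return idx_t, idx_r


def rmsd_series(
    t: Trajectory, reference: Structure, core: RegionSpec, total: RegionSpec
) -> RmsdSeries:
    """RMSD vs ``reference`` per frame, over a core and a total selection.

    Each frame is superposed on the selection it is reported over, so the
    two series are independent; rigid-body motion contributes nothing.
    """
    out: dict[str, np.ndarray] = {}
    ref_coords = reference.coords
    for label, region in (("core", core), ("total", total)):
        idx_t, idx_r = _matched_selection(t.topology, reference, region)
        ref_sel = ref_coords[idx_r]
        vals = np.empty(t.n_frames)
        for i, frame in enumerate(t.frames):
            _, vals[i] = kabsch_superpose(frame[idx_t], ref_sel)
        out[label] = vals
    return RmsdSeries(t.times, out["core"], out["total"], core, total)


def radius_of_gyration(
    s: Structure, selection: RegionSpec | None = None, mass_weighted: bool = True
) -> float:
    """Mass-weighted radius of gyration (A) over heavy atoms of a selection."""
    if selection is None:
        selection = RegionSpec("all", [(-(10**6), 10**6)], "heavy")
    idx = set(select(s, selection))
    atoms = [
        (r, a)
        for i, (_, r, a) in enumerate(s.iter_atoms())
        if i in idx and not a.is_hydrogen
    ]
    if not atoms:
        raise ValueError(f"selection {selection.name!r} has no heavy atoms")
    xyz = np.array([a.coords for _, a in atoms])
    if mass_weighted:
        m = np.array([ATOMIC_MASSES[a.element] for _, a in atoms])
    else:
        m = np.ones(len(atoms))
    centroid = (m[:, None] * xyz).sum(0) / m.sum()
    return float(np.sqrt((m * ((xyz - centroid) ** 2).sum(1)).sum() / m.sum()))


def bfactor_profile(
    t: Trajectory,
    window: tuple[float, float],
    atoms: RegionSpec | None = None,
) -> BfactorProfile:
    """Per-residue B-factors from positional variance over a time window.

    Per atom, B = (8 pi^2 / 3) <|x - <x>|^2> over the frames whose time
    falls in ``window`` (inclusive); atom values are averaged over each
    residue's selected (by default mainchain) atoms, then over chains at
    the same residue position.
    """
    if atoms is None:
        atoms = RegionSpec("mainchain", [(-(10**6), 10**6)], "mainchain")
    times = t.times
    mask = (times >= window[0]) & (times <= window[1])
    if mask.sum() == 0:
        raise ValueError(f"window {window} contains no frames")
    if mask.sum() < 2:
        raise ValueError(f"window {window} contains fewer than 2 frames")
    idx = select(t.topology, atoms)
    if not idx:
        raise ValueError("atom selection is empty")
    stack = np.stack([t.frames[i] for i in np.flatnonzero(mask)])  # (F, N, 3)
    sub = stack[:, idx, :]
    msf = ((sub - sub.mean(0)) ** 2).sum(2).mean(0)  # per-atom <|dx|^2>
    b_atom = B_FACTOR_PREFACTOR * msf
    keys = t.topology.atom_keys()
    # atom -> residue mean within each chain, then mean over chains
    per_chain_res: dict[tuple[str, int], list[float]] = {}
    for j, ai in enumerate(idx):
        ch, resnum, _ = keys[ai]
        per_chain_res.setdefault((ch, resnum), []).append(b_atom[j])
    per_pos: dict[int, list[float]] = {}
    for (_, resnum), vals in per_chain_res.items():
        per_pos.setdefault(resnum, []).append(float(np.mean(vals)))
    return BfactorProfile(
        {rn: float(np.mean(v)) for rn, v in sorted(per_pos.items())}, window
    )


def distance_series(
    t: Trajectory | Structure, res_a: int, res_b: int
) -> DistanceSeries:
    """Minimum sidechain heavy-atom distance between residues ``res_a`` and
    ``res_b`` within each chain, per frame.

    The NOE-style monitor used for the F19-L34 proximity constraint: the
    per-frame value averages the per-chain minima; ``fraction_under``
    counts every (chain, frame) sample against a distance tolerance.
    Glycine has no sidechain heavy atoms and is rejected.
    """
    if isinstance(t, Structure):
        t = Trajectory(t, [t.coords], frame_interval=1.0)
    topo = t.topology
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for chain in topo.chains:
        try:
            ra = chain.residue(res_a)
            rb = chain.residue(res_b)
        except KeyError:
            continue
        spec_a = RegionSpec("a", [(res_a, res_a)], "sidechain")
        spec_b = RegionSpec("b", [(res_b, res_b)], "sidechain")
        ia = select(topo, spec_a, chains={chain.chain_id})
        ib = select(topo, spec_b, chains={chain.chain_id})
        if not ia:
            raise ValueError(
                f"residue {ra.resname}{res_a} in chain {chain.chain_id} has no "
                "sidechain heavy atoms"
            )
        if not ib:
            raise ValueError(
                f"residue {rb.resname}{res_b} in chain {chain.chain_id} has no "
                "sidechain heavy atoms"
            )
        pairs.append((np.asarray(ia), np.asarray(ib)))
    if not pairs:
        raise ValueError(f"no chain contains both residues {res_a} and {res_b}")
    per_frame = np.empty(t.n_frames)
    samples = np.empty((t.n_frames, len(pairs)))
    for f, frame in enumerate(t.frames):
        for c, (ia, ib) in enumerate(pairs):
            d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :], axis=2)
            samples[f, c] = d.min()
        per_frame[f] = samples[f].mean()
    return DistanceSeries(
        t.times, per_frame, samples.ravel(), float(per_frame.mean())
    )


def convergence_stats(
    series: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] | None = None,
) -> ConvergenceReport:
    """Coefficient of variation and per-ns drift of a scalar series.

    ``times`` are in ps; the OLS slope is reported per nanosecond.  A zero
    mean makes the coefficient of variation undefined and is rejected.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape != times.shape:
        raise ValueError("series and times must have the same shape")
    if window is None:
        window = (float(times.min()), float(times.max()))
    mask = (times >= window[0]) & (times <= window[1])
    if mask.sum() < 3:
        raise ValueError("convergence window must contain at least 3 points")
    y = series[mask]
    x = times[mask]
    mean = y.mean()
    if mean == 0:
        raise ZeroDivisionError("series mean is zero; coefficient of variation undefined")
    cv = float(y.std(ddof=0) / abs(mean))
    slope_per_ps = float(np.polyfit(x, y, 1)[0])
    return ConvergenceReport(cv=cv, slope=slope_per_ps * 1000.0, window=window)
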