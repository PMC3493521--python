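"""End-to-end pipeline: fixture generation, hierarchical assembly and the
full trajectory-analysis battery.

``run_build`` reproduces the hierarchical assembly protocol at desk scale:
a 17-42 hairpin-core monomer is docked into dimers under the C-terminal
contact constraint, dimers are closed into C3 hexamers, hexamers stacked
into dodecamers, with the charged-group occlusion filter applied at every
level and alpha-helical N-termini grafted onto accepted dodecamers.

``run_analyze`` computes the ensemble report for a structure/trajectory
pair: core and total RMSD series, radii of gyration (full and core),
per-residue B-factors over a trailing window, the amide-proton rSASA
profile with per-region protection fractions (start vs end of the
trajectory, so helix unwinding shows up as a protection drop), the K28
sidechain-amine rSASA, the F19-L34 NOE distance monitor, per-residue
atomic contact energies for the C-terminal region, interior packing
density, and convergence diagnostics on the radius-of-gyration series.

Every number in the report is recomputable by calling the owning module
directly with the logged parameters; the report carries the config hash,
seed and package version for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .contact_energy import load_default_ace_table, packing_density, residue_ace_profile
from .docking import (
    AxisGrid,
    ChargedGroupRule,
    DockConstraint,
    filter_candidates,
    realize_candidate,
    rigid_dock,
    stack_to_dodecamer,
    symmetrize_c3,
)
from .peptides import (
    FluctuationSpec,
    build_abeta_core_monomer,
    build_abeta_monomer,
    build_dodecamer_fixture,
    default_sigma_profile,
    graft_helical_nterm,
    simulate_trajectory,
)
from .sasa import SasaParams, _reference_sasa, _res_letter, shrake_rupley
from .structures import (
    RegionSpec,
    Structure,
    Trajectory,
    parse_pdb,
    select,
    write_pdb,
)
from .trajectory_stats import (
    bfactor_profile,
    convergence_stats,
    distance_series,
    radius_of_gyration,
    rmsd_series,
)

__all__ = ["RunConfig", "PipelineError", "run_build", "run_analyze", "run_fixture"]

REGIONS = {
    "nterm": (1, 17),
    "central": (18, 30),
    "cterm": (31, 42),
    "core": (17, 42),
}


class PipelineError(RuntimeError):
    """Raised when a pipeline stage produces no viable candidates."""


@dataclass
class RunConfig:
    """Declarative configuration for the pipeline stages.

    Defaults run the whole workflow on synthetic fixtures at desk scale;
    any structure/trajectory produced elsewhere can be substituted through
    the ``*_pdb`` paths.
    """

    mode: str = "full"
    output_dir: str = "runs"
    seed: int = 0
    # inputs (analyze mode); None -> synthetic fixtures
    structure_pdb: str | None = None
    trajectory_pdb: str | None = None
    monomer_pdb: str | None = None
    # docking
    contact_cutoff: float = 5.0
    clash_cutoff: float = 2.5
    min_required_contacts: int = 1
    rot_step: float = 90.0
    trans_step: float = 3.0
    top_k: int = 5
    charged_min_rsasa: float = 0.10
    add_nterm_helices: bool = True
    # SASA
    probe_radius: float = 1.4
    n_points: int = 960
    # trajectory generation
    sigma_core: float = 0.4
    sigma_nterm: float = 1.2
    n_frames: int = 200
    frame_interval: float = 10.0
    unwind_nterm: bool = True
    # analysis
    protection_threshold: float = 0.10
    noe_tolerance: float = 7.5
    ace_cutoff: float = 6.0
    bfactor_window_ps: float = 500.0
    packing_mc_samples: int = 10_000

    def __post_init__(self) -> None:
        if self.mode not in ("build", "analyze", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze":
            for p in (self.structure_pdb, self.trajectory_pdb):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sasa_params(self) -> SasaParams:
        return SasaParams(probe_radius=self.probe_radius, n_points=self.n_points)

    def dock_constraint(self) -> DockConstraint:
        return DockConstraint(
            required_contact_region=RegionSpec("cterm", [REGIONS["cterm"]], "heavy"),
            contact_cutoff=self.contact_cutoff,
            clash_cutoff=self.clash_cutoff,
            min_required_contacts=self.min_required_contacts,
        )

    def fluctuation_spec(self) -> FluctuationSpec:
        return FluctuationSpec(
            per_residue_sigma=default_sigma_profile(self.sigma_core, self.sigma_nterm),
            n_frames=self.n_frames,
            frame_interval=self.frame_interval,
            unwind_nterm=self.unwind_nterm,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output location does not
        change what is computed)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _region_spec(name: str, atom_filter: str = "all") -> RegionSpec:
    return RegionSpec(name, [REGIONS[name]], atom_filter)


def _write_candidate_tsv(path: Path, stage: str, candidates) -> None:
    lines = ["candidate\tstage\tn_contacts\tn_clashes\tscore\tfilters"]
    for i, cand in enumerate(candidates):
        filters = ";".join(f"{k}={'pass' if v else 'fail'}" for k, v in cand.filter_report.items())
        lines.append(f"{i}\t{stage}\t{cand.n_contacts}\t{cand.n_clashes}\t{cand.score}\t{filters}")
    path.write_text("\n".join(lines) + "\n")


def _write_models(path: Path, structures: list[Structure]) -> None:
    if len(structures) == 1:
        path.write_text(write_pdb(structures[0]))
        return
    topo = structures[0]
    traj = Trajectory(topo, [s.coords for s in structures], frame_interval=1.0)
    path.write_text(write_pdb(traj))


def run_build(config: RunConfig) -> dict:
    """Monomer -> dimers -> C3 hexamers -> stacked dodecamers.

    Writes ranked candidate models (multi-model PDB) and filter-report
    TSVs per stage under ``output_dir``; raises :class:`PipelineError`
    naming the stage and filter whenever no candidate survives.
    Deterministic for a fixed config and seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    constraint = config.dock_constraint()
    rule = ChargedGroupRule(min_rsasa=config.charged_min_rsasa)
    sasa_p = config.sasa_params()
    if config.monomer_pdb:
        monomer = parse_pdb(Path(config.monomer_pdb).read_text())
        if isinstance(monomer, Trajectory):
            raise ValueError("monomer input must be a single-model PDB")
    else:
        monomer = build_abeta_core_monomer()
    log: dict = {"stages": {}}

    dimer_cands = rigid_dock(
        monomer, monomer, constraint,
        rot_step=config.rot_step, trans_step=config.trans_step,
        top_k=max(50 * config.top_k, 200),
    )
    if not dimer_cands:
        raise PipelineError("dimer stage: no candidates met required_region_contacts")
    dimer_cands = filter_candidates(
        dimer_cands, monomer, rule, mobile=monomer, sasa_params=sasa_p,
        max_passing=config.top_k,
    )
    if not dimer_cands:
        raise PipelineError("dimer stage: all candidates failed charged_groups_exposed")
    _write_candidate_tsv(out / "dimer_candidates.tsv", "dimer", dimer_cands)
    dimers = [realize_candidate(cd, monomer, monomer) for cd in dimer_cands]
    _write_models(out / "dimers.pdb", dimers)
    dimer = dimers[0]
    log["stages"]["dimer"] = {"n_candidates": len(dimer_cands), "best_score": dimer_cands[0].score}

    hex_cands = symmetrize_c3(
        dimer, constraint, AxisGrid(offset_step=3.0, offset_max=15.0),
        top_k=10 * config.top_k,
    )
    if not hex_cands:
        raise PipelineError("hexamer stage: no axis met required_region_contacts")
    hex_cands = filter_candidates(
        hex_cands, dimer, rule, sasa_params=sasa_p, max_passing=config.top_k
    )
    if not hex_cands:
        raise PipelineError("hexamer stage: all candidates failed charged_groups_exposed")
    _write_candidate_tsv(out / "hexamer_candidates.tsv", "hexamer", hex_cands)
    hexamers = [realize_candidate(cd, dimer) for cd in hex_cands]
    _write_models(out / "hexamers.pdb", hexamers)
    hexamer = hexamers[0]
    log["stages"]["hexamer"] = {"n_candidates": len(hex_cands), "best_score": hex_cands[0].score}

    dode_cands = stack_to_dodecamer(hexamer, constraint, top_k=10 * config.top_k)
    if not dode_cands:
        raise PipelineError("dodecamer stage: no stacking met required_region_contacts")
    dode_cands = filter_candidates(
        dode_cands, hexamer, rule, sasa_params=sasa_p, max_passing=config.top_k
    )
    if not dode_cands:
        raise PipelineError("dodecamer stage: all candidates failed charged_groups_exposed")
    _write_candidate_tsv(out / "dodecamer_candidates.tsv", "dodecamer", dode_cands)
    dodecamers = [realize_candidate(cd, hexamer) for cd in dode_cands]
    if config.add_nterm_helices:
        dodecamers = [graft_helical_nterm(d) for d in dodecamers]
    _write_models(out / "dodecamers.pdb", dodecamers)
    log["stages"]["dodecamer"] = {
        "n_candidates": len(dode_cands),
        "best_score": dode_cands[0].score,
        "n_chains": len(dodecamers[0].chains),
    }
    log["provenance"] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "build_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return log


def _amide_exposure(
    t: Trajectory | Structure,
    sasa_p: SasaParams,
    extra_targets: list[tuple[int, str]] | None = None,
) -> tuple[dict, dict]:
    """One SASA pass per frame for all backbone amide protons plus any
    extra (resnum, atom) targets; returns ({atom index: mean area},
    {atom index: (chain, resnum, name)})."""
    topo = t.topology if isinstance(t, Trajectory) else t
    keys = topo.atom_keys()
    spec = RegionSpec("all", [(-(10**6), 10**6)], "amide_proton")
    idx = list(select(topo, spec))
    for resnum, name in extra_targets or []:
        idx.extend(i for i, (ch, rn, an) in enumerate(keys) if rn == resnum and an == name)
    idx = sorted(set(idx))
    if isinstance(t, Trajectory):
        acc = {i: 0.0 for i in idx}
        work = topo.copy()
        for frame in t.frames:
            work.set_coords(frame)
            res = shrake_rupley(work, sasa_p, subset=idx)
            for k, v in res.per_atom.items():
                acc[k] += v
        areas = {k: v / t.n_frames for k, v in acc.items()}
    else:
        areas = shrake_rupley(t, sasa_p, subset=idx).per_atom
    return areas, {i: keys[i] for i in idx}


def _protection_from_areas(
    areas: dict, keys: dict, resnames: dict, region: tuple[int, int],
    sasa_p: SasaParams, threshold: float,
) -> float:
    sel = [
        i for i, (ch, rn, an) in keys.items()
        if an == "H" and region[0] <= rn <= region[1]
    ]
    if not sel:
        raise ValueError(f"no amide protons in region {region}")
    protected = 0
    for i in sel:
        ch, rn, an = keys[i]
        ref = _reference_sasa(_res_letter(resnames[(ch, rn)]), "H", "A", sasa_p)
        if areas[i] / ref < threshold:
            protected += 1
    return protected / len(sel)


def _windowed(t: Trajectory, lo_frac: float, hi_frac: float) -> Trajectory:
    n = t.n_frames
    lo = int(np.floor(lo_frac * n))
    hi = max(int(np.ceil(hi_frac * n)), lo + 1)
    return Trajectory(t.topology, t.frames[lo:hi], frame_interval=t.frame_interval)


def run_analyze(
    config: RunConfig,
    structure: Structure | None = None,
    trajectory: Trajectory | None = None,
) -> dict:
    """Compute the full ensemble report; returns the report dict and
    writes JSON + TSV profiles under ``output_dir``.

    Inputs resolve in order: explicit arguments, configured PDB paths,
    synthetic fixtures (standard dodecamer + simulated trajectory).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sasa_p = config.sasa_params()
    if structure is None:
        if config.structure_pdb:
            structure = parse_pdb(Path(config.structure_pdb).read_text())
        else:
            structure = build_dodecamer_fixture()
    if trajectory is None:
        if config.trajectory_pdb:
            parsed = parse_pdb(
                Path(config.trajectory_pdb).read_text(),
                frame_interval=config.frame_interval,
            )
            if isinstance(parsed, Structure):
                parsed = Trajectory(parsed, [parsed.coords], frame_interval=config.frame_interval)
            trajectory = parsed
        else:
            trajectory = simulate_trajectory(structure, config.fluctuation_spec())
    topo = trajectory.topology
    if topo.atom_keys() != structure.atom_keys():
        raise ValueError("trajectory topology does not match reference structure")
    has_hydrogens = any(a.is_hydrogen for _, _, a in topo.iter_atoms())
    if not has_hydrogens:
        raise ValueError(
            "input has no hydrogens, so amide-proton rSASA cannot be computed; "
            "generate fixtures with the built-in peptide builder or protonate "
            "the structure first"
        )
    resnames = {(c.chain_id, r.resnum): r.resname for c in topo.chains for r in c.residues}
    report: dict = {}

    # RMSD (fit selection == report selection), reference = input structure
    core = _region_spec("core", "calpha")
    total = RegionSpec("total", [(-(10**6), 10**6)], "calpha")
    series = rmsd_series(trajectory, structure, core, total)
    np.savetxt(
        out / "rmsd.tsv",
        np.column_stack([series.times, series.core, series.total]),
        header="time_ps\tcore_A\ttotal_A", comments="", delimiter="\t", fmt="%.4f",
    )
    report["rmsd"] = {
        "core_mean": float(series.core.mean()),
        "total_mean": float(series.total.mean()),
        "core_final": float(series.core[-1]),
        "total_final": float(series.total[-1]),
    }

    # radii of gyration: ensemble means over frames
    rg_total = []
    rg_core = []
    work = topo.copy()
    for frame in trajectory.frames:
        work.set_coords(frame)
        rg_total.append(radius_of_gyration(work))
        rg_core.append(radius_of_gyration(work, _region_spec("core", "heavy")))
    rg_total = np.array(rg_total)
    rg_core = np.array(rg_core)
    report["rg"] = {"total_mean": float(rg_total.mean()), "core_mean": float(rg_core.mean())}

    # B-factors over the trailing window
    t_end = float(trajectory.times[-1])
    window = (max(0.0, t_end - config.bfactor_window_ps), t_end)
    if trajectory.n_frames >= 2:
        prof = bfactor_profile(trajectory, window)
        np.savetxt(
            out / "bfactors.tsv",
            np.array(sorted(prof.per_residue.items())),
            header="resnum\tB_A2", comments="", delimiter="\t", fmt="%.4f",
        )
        b = prof.per_residue
        report["bfactor"] = {
            "nterm_mean": float(np.mean([v for r, v in b.items() if r <= 16])),
            "core_mean": float(np.mean([v for r, v in b.items() if 17 <= r <= 42])),
            "cterm_mean": float(np.mean([v for r, v in b.items() if 31 <= r <= 42])),
            "window_ps": list(window),
        }

    # amide rSASA profile + protection fractions (time-averaged).  The K28
    # sidechain amine is scored as a group (NZ + its protons summed in both
    # numerator and reference): the nitrogen alone is shadowed by its own
    # hydrogens, so the atomic ratio would be a quotient of near-zero areas.
    amine_names = ("NZ", "HZ1", "HZ2", "HZ3")
    areas, keymap = _amide_exposure(
        trajectory, sasa_p, extra_targets=[(28, n) for n in amine_names]
    )
    per_resnum: dict[int, list[float]] = {}
    amine_by_chain: dict[str, float] = {}
    for i, (ch, rn, an) in keymap.items():
        if an == "H":
            ref = _reference_sasa(_res_letter(resnames[(ch, rn)]), "H", "A", sasa_p)
            per_resnum.setdefault(rn, []).append(areas[i] / ref)
        elif rn == 28 and an in amine_names:
            amine_by_chain[ch] = amine_by_chain.get(ch, 0.0) + areas[i]
    amine_ref = sum(_reference_sasa("K", n, "A", sasa_p) for n in amine_names)
    k28 = [v / amine_ref for v in amine_by_chain.values()]
    rows = [(rn, float(np.mean(v)), float(np.std(v))) for rn, v in sorted(per_resnum.items())]
    np.savetxt(
        out / "amide_rsasa.tsv", np.array(rows),
        header="resnum\trsasa_mean\trsasa_sd", comments="", delimiter="\t", fmt="%.4f",
    )
    h_keys = {i: k for i, k in keymap.items() if k[2] == "H"}
    protection = {
        name: _protection_from_areas(
            areas, h_keys, resnames, REGIONS[name], sasa_p, config.protection_threshold
        )
        for name in ("nterm", "central", "cterm")
    }
    protection["total"] = _protection_from_areas(
        areas, h_keys, resnames, (-(10**6), 10**6), sasa_p, config.protection_threshold
    )
    report["protection"] = protection
    if k28:
        report["rsasa_k28_nz"] = float(np.mean(k28))

    # protection decline: first vs last quarter of the trajectory
    if trajectory.n_frames >= 8:
        for label, lo, hi in (("start", 0.0, 0.25), ("end", 0.75, 1.0)):
            win = _windowed(trajectory, lo, hi)
            a_w, k_w = _amide_exposure(win, sasa_p)
            h_w = {i: k for i, k in k_w.items() if k[2] == "H"}
            report.setdefault("protection_windows", {})[label] = _protection_from_areas(
                a_w, h_w, resnames, (-(10**6), 10**6), sasa_p, config.protection_threshold
            )

    # F19-L34 NOE monitor
    dist = distance_series(trajectory, 19, 34)
    report["distance_f19_l34"] = {
        "mean": dist.mean,
        "fraction_under_tolerance": dist.fraction_under(config.noe_tolerance),
        "tolerance": config.noe_tolerance,
    }

    # per-residue ACE for the C-terminal region, on the final frame
    final = trajectory.frame_structure(trajectory.n_frames - 1)
    profile = residue_ace_profile(final, load_default_ace_table(), cutoff=config.ace_cutoff)
    ct = profile.region_values(30, 42)
    lines = ["chain\tresnum\tace_kcal_mol"]
    for (ch, rn), v in sorted(ct.items()):
        lines.append(f"{ch}\t{rn}\t{v:.4f}")
    (out / "ace_cterm.tsv").write_text("\n".join(lines) + "\n")
    by_pos: dict[int, list[float]] = {}
    for (ch, rn), v in ct.items():
        by_pos.setdefault(rn, []).append(v)
    report["ace_cterm_mean_per_residue"] = {
        str(rn): float(np.mean(v)) for rn, v in sorted(by_pos.items())
    }

    # packing density on the final frame
    packing = packing_density(
        final, mc_samples=config.packing_mc_samples, seed=config.seed
    )
    report["packing_density"] = {
        "mean": packing.mean,
        "n_buried": len(packing.per_atom),
    }

    # convergence on the Rg series
    if trajectory.n_frames >= 3:
        conv = convergence_stats(rg_total, trajectory.times)
        report["convergence_rg"] = {"cv": conv.cv, "slope_per_ns": conv.slope}

    report["provenance"] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_frames": trajectory.n_frames,
        "frame_interval_ps": trajectory.frame_interval,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def run_fixture(config: RunConfig, kind: str = "dodecamer") -> Path:
    """Write a synthetic fixture PDB (monomer, dodecamer or trajectory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "monomer":
        path = out / "monomer.pdb"
        path.write_text(write_pdb(build_abeta_monomer()))
    elif kind == "dodecamer":
        path = out / "dodecamer.pdb"
        path.write_text(write_pdb(build_dodecamer_fixture()))
    elif kind == "trajectory":
        s = build_dodecamer_fixture()
        t = simulate_trajectory(s, config.fluctuation_spec())
        path = out / "trajectory.pdb"
        path.write_text(write_pdb(t))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path
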