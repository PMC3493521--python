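"""Trajectory statistics: superposition, RMSD, Rg, B-factors, monitors."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from globulomer.peptides import (
    ConformationSpec,
    FluctuationSpec,
    build_peptide,
    simulate_trajectory,
)
from globulomer.structures import RegionSpec, Structure, Trajectory, TransformOp
from globulomer.trajectory_stats import (
    bfactor_profile,
    convergence_stats,
    distance_series,
    kabsch_superpose,
    radius_of_gyration,
    rmsd_series,
)

from conftest import toy_structure


def numerical_rmsd_oracle(mobile, reference):
    """Minimum RMSD by direct numerical minimization over rotation vectors
    and translations, independent of the closed-form path."""

    def cost(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        moved = mobile @ rot.T + x[3:]
        return np.sqrt(((moved - reference) ** 2).sum(1).mean())

    best = np.inf
    for seed_rot in (np.zeros(3), np.array([1.0, 0.5, -0.5]), np.array([-2.0, 1.0, 2.0])):
        res = minimize(cost, np.concatenate([seed_rot, np.zeros(3)]), method="Nelder-Mead",
                       options={"maxiter": 6000, "xatol": 1e-10, "fatol": 1e-14})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_superposes_exactly(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        moved = pts @ rot.T + rng.normal(size=3)
        _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-9

    def test_matches_numerical_minimizer(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(scale=3, size=(4, 3))
        mob = ref + rng.normal(scale=0.3, size=(4, 3))
        _, rmsd = kabsch_superpose(mob, ref)
        oracle = numerical_rmsd_oracle(mob, ref)
        assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_symmetry_of_the_fit(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=0.2, size=(6, 3))
        _, r_ab = kabsch_superpose(a, b)
        _, r_ba = kabsch_superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(pts, pts)

    def test_cross_check_against_mdanalysis(self):
        mda_align = pytest.importorskip("MDAnalysis.analysis.align")
        rng = np.random.default_rng(4)
        ref = rng.normal(scale=4, size=(10, 3))
        mob = ref + rng.normal(scale=0.5, size=(10, 3))
        _, rmsd = kabsch_superpose(mob, ref)
        _, their_rmsd = mda_align.rotation_matrix(
            mob - mob.mean(0), ref - ref.mean(0)
        )
        assert rmsd == pytest.approx(their_rmsd, abs=1e-6)


def _calpha_chain(n=6, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=4, size=(n, 3))
    return toy_structure(coords, names=["CA"] * n, resnums=list(range(1, n + 1)))


class TestRmsdSeries:
    def test_reference_frame_gives_zero(self):
        s = _calpha_chain()
        t = Trajectory(s, [s.coords, s.coords + 0.1], frame_interval=10.0)
        spec = RegionSpec("all", [(1, 6)], "calpha")
        series = rmsd_series(t, s, spec, spec)
        assert series.core[0] == pytest.approx(0.0, abs=1e-9)
        assert series.total[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_body_motion_removed(self):
        s = _calpha_chain()
        frames = []
        rng = np.random.default_rng(9)
        for _ in range(4):
            rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
            frames.append(s.coords @ rot.T + rng.normal(size=3))
        t = Trajectory(s, frames, frame_interval=10.0)
        spec = RegionSpec("all", [(1, 6)], "calpha")
        series = rmsd_series(t, s, spec, spec)
        assert np.all(series.total < 1e-9)

    def test_mobile_tail_raises_total_above_core(self):
        s = build_peptide("A" * 12, ConformationSpec("extended"))
        sigma = {r: (0.05 if r <= 6 else 1.0) for r in range(1, 13)}
        t = simulate_trajectory(s, FluctuationSpec(sigma, n_frames=30, seed=5))
        core = RegionSpec("core", [(1, 6)], "calpha")
        total = RegionSpec("total", [(1, 12)], "calpha")
        series = rmsd_series(t, s, core, total)
        assert series.total.mean() > series.core.mean()

    def test_selection_mismatch_rejected(self):
        s = _calpha_chain(6)
        ref = _calpha_chain(5)
        t = Trajectory(s, [s.coords], frame_interval=10.0)
        spec = RegionSpec("all", [(1, 6)], "calpha")
        with pytest.raises(ValueError, match="does not match"):
            rmsd_series(t, ref, spec, spec)


class TestRadiusOfGyration:
    def test_two_unit_masses_two_angstroms_apart(self):
        s = toy_structure([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(s, mass_weighted=False) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        s = _calpha_chain(8, seed=3)
        rg0 = radius_of_gyration(s)
        t = TransformOp.rotation_about_axis(np.array([1.0, 1.0, 0.0]), 73.0,
                                            center=np.array([5.0, -2.0, 1.0]))
        from globulomer.structures import apply_transform

        assert radius_of_gyration(apply_transform(s, t)) == pytest.approx(rg0, abs=1e-9)

    def test_hydrogens_excluded(self):
        s = toy_structure(
            [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [50.0, 0.0, 0.0]],
            names=["C1", "C2", "H1"], elements=["C", "C", "H"],
        )
        assert radius_of_gyration(s, mass_weighted=False) == pytest.approx(1.0)


class TestBfactors:
    def test_static_trajectory_all_zero(self):
        s = _calpha_chain()
        t = Trajectory(s, [s.coords] * 5, frame_interval=10.0)
        prof = bfactor_profile(t, (0.0, 40.0))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in prof.per_residue.values())

    def test_isotropic_sigma_recovers_closed_form(self):
        s = toy_structure(
            np.random.default_rng(0).normal(scale=10, size=(4, 3)),
            names=["CA"] * 4, resnums=[1, 2, 3, 4],
        )
        sigma = 0.5
        t = simulate_trajectory(
            s, FluctuationSpec({r: sigma for r in range(1, 5)}, n_frames=2000, seed=8)
        )
        prof = bfactor_profile(t, (0.0, t.times[-1]))
        expected = 8.0 * np.pi**2 * sigma**2
        for v in prof.per_residue.values():
            assert abs(v - expected) / expected < 0.05

    def test_empty_window_rejected(self):
        s = _calpha_chain()
        t = Trajectory(s, [s.coords] * 3, frame_interval=10.0)
        with pytest.raises(ValueError):
            bfactor_profile(t, (100.0, 200.0))

    def test_mobile_nterm_ordering(self, unwind_trajectory):
        prof = bfactor_profile(
            unwind_trajectory, (0.0, float(unwind_trajectory.times[-1]))
        )
        b = prof.per_residue
        b_nterm = np.mean([v for r, v in b.items() if r <= 16])
        b_cterm = np.mean([v for r, v in b.items() if 31 <= r <= 42])
        assert b_nterm > b_cterm


class TestDistanceSeries:
    def test_known_sidechain_separation(self):
        # two "sidechains" (CB atoms) placed exactly 5.8 A apart
        s = toy_structure(
            [[0.0, 0.0, 0.0], [0.0, 0.0, 1.0], [5.8, 0.0, 1.0], [5.8, 0.0, 0.0]],
            names=["CA", "CB", "CB", "CA"], resnums=[1, 1, 2, 2],
        )
        d = distance_series(s, 1, 2)
        assert d.mean == pytest.approx(5.8)
        assert d.fraction_under(7.5) == 1.0

    def test_coincident_sidechains_zero(self):
        s = toy_structure(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
            names=["CA", "CB", "CB", "CA"], resnums=[1, 1, 2, 2],
        )
        assert distance_series(s, 1, 2).mean == 0.0

    def test_glycine_rejected(self):
        s = build_peptide("AGA", ConformationSpec("extended"))
        with pytest.raises(ValueError, match="sidechain"):
            distance_series(s, 1, 2)

    def test_f19_l34_on_dodecamer_ensemble(self, unwind_trajectory):
        d = distance_series(unwind_trajectory, 19, 34)
        assert d.mean < 7.5
        assert d.fraction_under(7.5) == 1.0


class TestConvergence:
    def test_constant_series(self):
        t = np.arange(10.0)
        rep = convergence_stats(np.full(10, 3.0), t)
        assert rep.cv == 0.0 and rep.slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_series_slope_recovered(self):
        t = np.arange(20.0)  # ps
        rep = convergence_stats(2.0 * t + 1.0, t)
        assert rep.slope == pytest.approx(2000.0, rel=1e-12)  # per ns

    def test_noise_cv_close_to_relative_sd(self):
        rng = np.random.default_rng(12)
        mean = 100.0
        y = mean + rng.normal(scale=1.0, size=4000)
        rep = convergence_stats(y, np.arange(4000.0))
        assert rep.cv == pytest.approx(0.01, rel=0.1)

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            convergence_stats(np.array([-1.0, 0.0, 1.0]), np.arange(3.0))
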