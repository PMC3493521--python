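"""Constrained rigid docking, C3 symmetrization, stacking and filters."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from globulomer.docking import (
    AxisGrid,
    ChargedGroupRule,
    DockCandidate,
    DockConstraint,
    filter_candidates,
    realize_candidate,
    rigid_dock,
    stack_to_dodecamer,
    symmetrize_c3,
    translation_grid,
)
from globulomer.peptides import ConformationSpec, build_cn_assembly, build_peptide
from globulomer.structures import RegionSpec, TransformOp
from globulomer.trajectory_stats import kabsch_superpose, radius_of_gyration

from conftest import toy_structure


def all_region(hi=99):
    return RegionSpec("all", [(1, hi)], "heavy")


def brute_force_dock(fixed, mobile, c, rot_step, trans_step):
    """Independent exhaustive enumeration with naive O(n^2) counting and
    strict < thresholds, replicating the documented grid definition."""
    fh = fixed.coords[fixed.heavy_mask()]
    mh = mobile.coords[mobile.heavy_mask()]
    fixed_keys = [k for k, m in zip(fixed.atom_keys(), fixed.heavy_mask()) if m]
    mobile_keys = [k for k, m in zip(mobile.atom_keys(), mobile.heavy_mask()) if m]
    freg = np.array([c.required_contact_region.contains(k[1]) for k in fixed_keys])
    mreg = np.array([c.required_contact_region.contains(k[1]) for k in mobile_keys])
    c_fix, c_mob = fh.mean(0), mh.mean(0)
    trans = translation_grid(fh, mh, c.contact_cutoff, trans_step)
    results = []
    grid_index = 0
    for a in np.arange(0.0, 360.0, rot_step):
        for b in np.arange(0.0, 180.0 + 1e-9, rot_step):
            for g in np.arange(0.0, 360.0, rot_step):
                rmat = Rotation.from_euler("zyz", [a, b, g], degrees=True).as_matrix()
                rot_mh = (mh - c_mob) @ rmat.T
                for t in trans:
                    grid_index += 1
                    placed = rot_mh + c_fix + t
                    d = np.linalg.norm(fh[:, None] - placed[None, :], axis=2)
                    nc = int((d < c.contact_cutoff).sum())
                    nx = int((d < c.clash_cutoff).sum())
                    nreg = int((d[freg][:, mreg] < c.contact_cutoff).sum())
                    if nreg < c.min_required_contacts:
                        continue
                    results.append(
                        {
                            "score": nc - 10 * nx,
                            "n_contacts": nc,
                            "n_clashes": nx,
                            "grid_index": grid_index,
                            "rotation": rmat,
                            "translation": c_fix + t - rmat @ c_mob,
                        }
                    )
    results.sort(key=lambda r: (-r["score"], r["n_clashes"], r["grid_index"]))
    return results


class TestRigidDockOracle:
    @pytest.mark.parametrize("n_fixed,n_mobile,seed", [(1, 1, 0), (3, 2, 1), (5, 4, 2)])
    def test_full_ranked_list_matches_enumeration(self, n_fixed, n_mobile, seed):
        """On tiny subunits the ranked candidate list equals independent
        brute-force enumeration exactly (scores, counts, order, placements)."""
        rng = np.random.default_rng(seed)
        fixed = toy_structure(rng.uniform(-2, 2, (n_fixed, 3)),
                              names=[f"C{i}" for i in range(n_fixed)])
        mobile = toy_structure(rng.uniform(-2, 2, (n_mobile, 3)),
                               names=[f"C{i}" for i in range(n_mobile)])
        c = DockConstraint(all_region(), contact_cutoff=5.0, clash_cutoff=2.5)
        got = rigid_dock(fixed, mobile, c, rot_step=120.0, trans_step=2.0, top_k=10**9)
        expected = brute_force_dock(fixed, mobile, c, 120.0, 2.0)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert (g.score, g.n_contacts, g.n_clashes, g.grid_index) == (
                e["score"], e["n_contacts"], e["n_clashes"], e["grid_index"]
            )
            np.testing.assert_allclose(g.placement.rotation, e["rotation"], atol=1e-12)
            np.testing.assert_allclose(g.placement.translation, e["translation"], atol=1e-9)

    def test_empty_required_region_returns_nothing(self):
        fixed = toy_structure([[0.0, 0.0, 0.0]])
        mobile = toy_structure([[0.0, 0.0, 0.0]])
        c = DockConstraint(RegionSpec("none", [(50, 60)], "heavy"))
        assert rigid_dock(fixed, mobile, c, rot_step=120.0, trans_step=3.0) == []

    def test_clash_penalty_is_ten_per_pair(self):
        fixed = toy_structure([[0.0, 0.0, 0.0]])
        mobile = toy_structure([[0.0, 0.0, 0.0]])
        c = DockConstraint(all_region(), min_required_contacts=0)
        cands = rigid_dock(fixed, mobile, c, rot_step=360.0, trans_step=1.0, top_k=10**9)
        for cand in cands:
            assert cand.score == cand.n_contacts - 10 * cand.n_clashes
        clashing = [cd for cd in cands if cd.n_clashes == 1]
        assert clashing and all(cd.score == -9 for cd in clashing)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        fixed = toy_structure(rng.uniform(-2, 2, (3, 3)), names=["C0", "C1", "C2"])
        mobile = toy_structure(rng.uniform(-2, 2, (3, 3)), names=["C0", "C1", "C2"])
        c = DockConstraint(all_region())
        a = rigid_dock(fixed, mobile, c, rot_step=120.0, trans_step=2.0)
        b = rigid_dock(fixed, mobile, c, rot_step=120.0, trans_step=2.0)
        assert [
            (x.score, x.grid_index, x.placement.translation.tolist()) for x in a
        ] == [(x.score, x.grid_index, x.placement.translation.tolist()) for x in b]


class TestSymmetrizeC3:
    @pytest.fixture()
    def dimer(self):
        s = build_peptide("AK", ConformationSpec("extended"), chain_id="A")
        m = build_peptide("AK", ConformationSpec("extended"), chain_id="B")
        m.set_coords(m.coords + np.array([0.0, 4.0, 0.0]))
        from globulomer.peptides import _merge

        out = _merge([s, m])
        out.set_coords(out.coords + np.array([8.0, 0.0, 0.0]))  # off-axis
        return out

    def test_output_has_exact_threefold_symmetry(self, dimer):
        c = DockConstraint(all_region(), min_required_contacts=1)
        cands = symmetrize_c3(dimer, c, AxisGrid(offset_step=4.0, offset_max=8.0))
        assert cands
        hexamer = realize_candidate(cands[0], dimer)
        assert len(hexamer.chains) == 6
        n = dimer.n_atoms
        first = hexamer.coords[:n]
        second = hexamer.coords[n : 2 * n]
        _, rmsd = kabsch_superpose(cands[0].placement.apply(first), second)
        assert rmsd < 1e-9

    def test_outward_facing_region_yields_nothing(self, dimer):
        # required region restricted to residue numbers not present
        c = DockConstraint(RegionSpec("none", [(90, 99)], "heavy"))
        assert symmetrize_c3(dimer, c, AxisGrid()) == []

    def test_toy_axis_choice_matches_exhaustive_enumeration(self):
        """Two-atom 'dimer': the retained axis maximizes inter-copy
        contacts, matching direct enumeration over the same axis grid."""
        dimer = toy_structure(
            [[4.0, 0.0, 0.0], [4.0, 2.0, 0.0]],
            names=["C0", "C1"], chain_ids=["A", "B"],
        )
        c = DockConstraint(all_region(), min_required_contacts=1)
        grid = AxisGrid(offset_step=2.0, offset_max=4.0)
        cands = symmetrize_c3(dimer, c, grid, top_k=10**9)
        assert cands
        # oracle: enumerate the same axes directly
        heavy = dimer.coords
        centroid = heavy.mean(0)
        best = None
        n1d = int(4.0 / 2.0)
        offsets = np.arange(-n1d, n1d + 1) * 2.0
        for ox in offsets:
            for oy in offsets:
                point = centroid + np.array([ox, oy, 0.0])
                gen = TransformOp.rotation_about_axis(np.array([0.0, 0.0, 1.0]), 120.0, center=point)
                c2 = gen.apply(heavy)
                c3 = gen.apply(c2)
                d01 = np.linalg.norm(heavy[:, None] - c2[None, :], axis=2)
                d02 = np.linalg.norm(heavy[:, None] - c3[None, :], axis=2)
                d12 = np.linalg.norm(c2[:, None] - c3[None, :], axis=2)
                nc = int((d01 < 5.0).sum() + (d02 < 5.0).sum() + (d12 < 5.0).sum())
                nx = int((d01 < 2.5).sum() + (d02 < 2.5).sum() + (d12 < 2.5).sum())
                score = nc - 10 * nx
                if nc >= 1 and (best is None or score > best):
                    best = score
        assert cands[0].score == best


@pytest.fixture(scope="module")
def hexamer():
    sub = build_peptide("AKW", ConformationSpec("extended"), chain_id="A")
    m2 = build_peptide("AKW", ConformationSpec("extended"), chain_id="B")
    m2.set_coords(m2.coords + np.array([0.0, 5.0, 0.0]))
    from globulomer.peptides import _merge

    dimer = _merge([sub, m2])
    return build_cn_assembly(dimer, 3, np.array([0.0, 0.0, 1.0]), 12.0)


class TestStacking:
    def test_every_model_has_twelve_chains(self, hexamer):
        c = DockConstraint(all_region(), min_required_contacts=1)
        cands = stack_to_dodecamer(hexamer, c, angle_step=60.0, axial_step=3.0, top_k=4)
        assert cands
        for cand in cands:
            assert len(realize_candidate(cand, hexamer).chains) == 12

    def test_dodecamer_rg_not_smaller_than_hexamer(self, hexamer):
        c = DockConstraint(all_region(), min_required_contacts=1)
        cands = stack_to_dodecamer(hexamer, c, angle_step=60.0, axial_step=3.0, top_k=4)
        rg_hex = radius_of_gyration(hexamer)
        for cand in cands:
            assert radius_of_gyration(realize_candidate(cand, hexamer)) >= rg_hex - 1e-9

    def test_region_requirement_enforced(self, hexamer):
        c = DockConstraint(RegionSpec("none", [(90, 99)], "heavy"))
        assert stack_to_dodecamer(hexamer, c, angle_step=90.0, axial_step=4.0) == []


class TestChargedFilter:
    def _candidate(self, score=0, contacts=0, clashes=0):
        return DockCandidate(TransformOp.identity(), contacts, clashes,
                             contacts - 10 * clashes, kind="dock")

    def test_burying_placement_rejected_exposed_retained(self):
        """A placement that cages the lysine amine is rejected; the same
        partner far away is retained."""
        host = build_peptide("AKA", ConformationSpec("extended"))
        nz = host.chains[0].residue(2).atom("NZ").coords
        golden = (1 + 5**0.5) / 2
        shell = []
        for i in range(60):
            z = 1 - 2 * (i + 0.5) / 60
            r = np.sqrt(1 - z * z)
            th = 2 * np.pi * i / golden
            shell.append(nz + 4.5 * np.array([r * np.cos(th), r * np.sin(th), z]))
        cage = toy_structure(shell, names=[f"C{i}" for i in range(60)])
        near = DockCandidate(TransformOp.identity(), 0, 0, 0, kind="dock", grid_index=0)
        far = DockCandidate(
            TransformOp(np.eye(3), np.array([200.0, 0.0, 0.0])), 0, 0, 0,
            kind="dock", grid_index=1,
        )
        passed = filter_candidates([near, far], host, ChargedGroupRule(), mobile=cage)
        assert near.filter_report["charged_groups_exposed"] is False
        assert far.filter_report["charged_groups_exposed"] is True
        assert passed == [far]

    def test_tightening_min_rsasa_never_admits_more(self):
        mono = build_peptide("KK", ConformationSpec("extended"))
        c = DockConstraint(RegionSpec("all", [(1, 2)], "heavy"), min_required_contacts=1)
        cands = rigid_dock(mono, mono, c, rot_step=180.0, trans_step=2.0, top_k=60)
        counts = []
        for thr in (0.02, 0.10, 0.30):
            passed = filter_candidates(list(cands), mono, ChargedGroupRule(min_rsasa=thr),
                                       mobile=mono)
            counts.append(len(passed))
        assert counts[0] >= counts[1] >= counts[2]

    def test_rank_order_preserved(self):
        mono = build_peptide("KK", ConformationSpec("extended"))
        c = DockConstraint(RegionSpec("all", [(1, 2)], "heavy"), min_required_contacts=1)
        cands = rigid_dock(mono, mono, c, rot_step=180.0, trans_step=2.0, top_k=40)
        passed = filter_candidates(list(cands), mono, ChargedGroupRule(), mobile=mono)
        indices = [next(i for i, c in enumerate(cands) if c is cd) for cd in passed]
        assert indices == sorted(indices)

    def test_invalid_min_rsasa_rejected(self):
        with pytest.raises(ValueError):
            ChargedGroupRule(min_rsasa=1.5)

    def test_score_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            DockCandidate(TransformOp.identity(), 3, 0, 5.0)
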