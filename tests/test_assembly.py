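import itertools
import math

import numpy as np
import pytest

from ssrna_fragdock.assembly import (
    Chain, ChainGraph, OverlapParams, build_graph, count_chains,
    enumerate_chains, iterative_assembly, overlap_energy, propensity_filter,
)
from ssrna_fragdock.cg import CGStructure, RigidTransform
from ssrna_fragdock.docking import DockingPool, Pose

from conftest import make_cg_chain


# ---------------------------------------------------------------------------
# helpers


def one_bead_conformer(positions, roles=("phosphate", "phosphate", "phosphate")):
    """3-residue conformer with one bead per nucleotide."""
    positions = np.asarray(positions, dtype=float)
    return CGStructure(
        positions, [1, 1, 1], [0.0] * 3, [1, 2, 3],
        np.array(["X"] * 3, dtype=object), np.array(list(roles), dtype=object),
        np.array(["PHO"] * 3, dtype=object),
        [("X", 1, "U"), ("X", 2, "U"), ("X", 3, "U")],
    )


def pose_at(conformer, pose_id, offset=(0.0, 0.0, 0.0), energy=0.0, cid=1):
    t = RigidTransform(np.eye(3), offset)
    return Pose(pose_id=pose_id, conformer_id=cid, transform=t,
                energy=energy, coords=t.apply(conformer.coords))


def continuation_poses(step=4.0, shift_third=0.0):
    """Two 1-bead/nt poses where pose_j exactly continues pose_i except for
    an optional displacement of the last paired bead."""
    conf = one_bead_conformer([(0, 0, 0), (step, 0, 0), (2 * step, 0, 0)])
    pose_i = pose_at(conf, 1)
    pose_j = pose_at(conf, 2, offset=(step, 0, 0))
    if shift_third:
        coords = pose_j.coords.copy()
        coords[1] += (0, shift_third, 0)  # nt2 of pose_j pairs with nt3 of i
        pose_j.coords = coords
    return pose_i, pose_j, conf


def graph_from_edges(nodes, edges, mode="single_pool", n_pools=1, pool_of=None):
    succ = {v: [] for v in nodes}
    for i, j in edges:
        succ[i].append((j, 0.0))
    for lst in succ.values():
        lst.sort()
    return ChainGraph(node_ids=sorted(nodes),
                      pool_of=pool_of or {v: 0 for v in nodes},
                      succ=succ, mode=mode, n_pools=n_pools)


def brute_force_walks(graph, N):
    """Oracle: enumerate all N-node walks by explicit recursion."""
    if graph.mode == "position_specific":
        starts = [v for v in graph.node_ids if graph.pool_of[v] == 0]
        valid_end = lambda v: graph.pool_of[v] == graph.n_pools - 1
    else:
        starts = list(graph.node_ids)
        valid_end = lambda v: True
    walks = []

    def rec(path):
        if len(path) == N:
            if valid_end(path[-1]):
                walks.append(tuple(path))
            return
        for j, _ in graph.succ[path[-1]]:
            rec(path + [j])

    for s in starts:
        rec([s])
    return walks


# ---------------------------------------------------------------------------


class TestOverlapParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            OverlapParams(margin_backbone=0.0)
        with pytest.raises(ValueError):
            OverlapParams(k=0.0)
        with pytest.raises(ValueError):
            OverlapParams(max_violation=-1.0)

    def test_hard_mode_budget(self):
        assert OverlapParams(hard_mode=True).budget == 0.0
        assert OverlapParams(max_violation=2.0).budget == 2.0


class TestOverlapEnergy:
    def test_exact_continuation_is_zero(self):
        pose_i, pose_j, conf = continuation_poses()
        assert overlap_energy(pose_i, pose_j, conf, conf,
                              OverlapParams()) == 0.0

    def test_planted_chain_junctions_zero(self, scenario):
        params = OverlapParams()
        poses = scenario.planted_poses
        for i in range(len(poses) - 1):
            e = overlap_energy(poses[i], poses[i + 1],
                               scenario.planted_conformers[i + 1],
                               scenario.planted_conformers[i + 2], params)
            assert e == 0.0

    def test_single_pair_tenth_angstrom_over_margin(self):
        params = OverlapParams(margin_backbone=2.3, k=100.0)
        pose_i, pose_j, conf = continuation_poses(shift_third=2.3 + 0.1)
        # exactly one bead pair at margin + 0.1: 100 * 0.01 = 1.0
        assert overlap_energy(pose_i, pose_j, conf, conf,
                              params) == pytest.approx(1.0)

    def test_margin_plus_015_violates_budget(self):
        params = OverlapParams(margin_backbone=2.3, k=100.0, max_violation=2.0)
        pose_i, pose_j, conf = continuation_poses(shift_third=2.3 + 0.15)
        e = overlap_energy(pose_i, pose_j, conf, conf, params)
        assert e == pytest.approx(2.25)
        assert e > params.max_violation

    def test_base_margin_applies_to_base_beads(self):
        conf = one_bead_conformer([(0, 0, 0), (4, 0, 0), (8, 0, 0)],
                                  roles=("base", "base", "base"))
        pose_i = pose_at(conf, 1)
        pose_j = pose_at(conf, 2, offset=(4, 0, 0))
        coords = pose_j.coords.copy()
        coords[1] += (0, 2.8 + 0.1, 0)
        pose_j.coords = coords
        params = OverlapParams(margin_backbone=2.3, margin_base=2.8, k=100.0)
        assert overlap_energy(pose_i, pose_j, conf, conf,
                              params) == pytest.approx(1.0)

    def test_role_mismatch_errors(self):
        conf_a = one_bead_conformer([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        conf_b = one_bead_conformer([(0, 0, 0), (4, 0, 0), (8, 0, 0)],
                                    roles=("base", "base", "base"))
        pa = pose_at(conf_a, 1)
        pb = pose_at(conf_b, 2, offset=(4, 0, 0))
        with pytest.raises(ValueError, match="role"):
            overlap_energy(pa, pb, conf_a, conf_b, OverlapParams())


class TestBuildGraph:
    def test_perfect_continuation_single_edge(self):
        pose_i, pose_j, conf = continuation_poses()
        pool = DockingPool(poses=[pose_i, pose_j], conformers={1: conf})
        g = build_graph(pool, OverlapParams(), mode="single_pool")
        assert g.n_edges() == 1
        assert g.succ[1] == [(2, 0.0)]

    def test_all_overlapping_complete_digraph(self):
        conf = one_bead_conformer([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        # all poses nearly identical: every ordered pair connects? no --
        # identical poses do NOT overlap as continuations (nt1_j sits on
        # nt1_i, 4 A from nt2_i); use poses shifted by the nucleotide step
        poses = [pose_at(conf, k, offset=(4.0 * k, 0, 0)) for k in range(4)]
        pool = DockingPool(poses=poses, conformers={1: conf})
        g = build_graph(pool, OverlapParams(), mode="single_pool")
        expected = {(k, k + 1) for k in range(3)}
        assert {(i, j) for i, j, _ in g.edges()} == expected

    def test_single_pool_identical_poses_n_times_n_minus_one(self):
        # degenerate conformer with all three nucleotides at one point:
        # every pose continues every other
        conf = one_bead_conformer([(0, 0, 0), (0, 0, 0), (0, 0, 0)])
        poses = [pose_at(conf, k) for k in range(4)]
        pool = DockingPool(poses=poses, conformers={1: conf})
        g = build_graph(pool, OverlapParams(), mode="single_pool")
        assert g.n_edges() == 4 * 3

    def test_prefilter_matches_brute_force(self, scenario):
        from conftest import random_pose_pool

        rng = np.random.default_rng(12)
        pool = random_pose_pool(rng, scenario, n=40, radius=12.0)
        params = OverlapParams(margin_backbone=4.0, margin_base=4.5,
                               max_violation=50.0)
        g_fast = build_graph(pool, params, mode="single_pool",
                             spatial_prefilter=True)
        g_slow = build_graph(pool, params, mode="single_pool",
                             spatial_prefilter=False)
        fast = {(i, j): e for i, j, e in g_fast.edges()}
        slow = {(i, j): e for i, j, e in g_slow.edges()}
        assert fast.keys() == slow.keys()
        for key, e in fast.items():
            assert e == pytest.approx(slow[key], abs=1e-9)

    def test_position_specific_edges_cross_pools_only(self):
        conf = one_bead_conformer([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        pools = []
        for p in range(3):
            poses = [pose_at(conf, 10 * p + k, offset=(4.0 * p, 0, 0))
                     for k in range(2)]
            pools.append(DockingPool(poses=poses, conformers={1: conf}))
        g = build_graph(pools, OverlapParams(), mode="position_specific")
        for i, j, _ in g.edges():
            assert g.pool_of[j] == g.pool_of[i] + 1


class TestCountChains:
    def test_three_pool_worked_example(self):
        # pools {a1,a2} -> {b1} -> {c1,c2}; edges a1->b1, a2->b1, b1->c1
        nodes = [1, 2, 3, 4, 5]  # a1 a2 b1 c1 c2
        pool_of = {1: 0, 2: 0, 3: 1, 4: 2, 5: 2}
        g = graph_from_edges(nodes, [(1, 3), (2, 3), (3, 4)],
                             mode="position_specific", n_pools=3,
                             pool_of=pool_of)
        res = count_chains(g, 3)
        assert res.total_chains == 2
        assert res.propensity(3) == 1.0
        assert res.propensity(5) == 0.0
        assert res.propensity(1) == 0.5

    def test_complete_tripartite_2x2x2(self):
        nodes = list(range(6))
        pool_of = {0: 0, 1: 0, 2: 1, 3: 1, 4: 2, 5: 2}
        edges = [(a, b) for a in (0, 1) for b in (2, 3)] + \
                [(b, c) for b in (2, 3) for c in (4, 5)]
        g = graph_from_edges(nodes, edges, mode="position_specific",
                             n_pools=3, pool_of=pool_of)
        res = count_chains(g, 3)
        assert res.total_chains == 8
        for v in nodes:
            assert res.propensity(v) == 0.5

    def test_requires_n_at_least_two(self):
        g = graph_from_edges([1], [])
        with pytest.raises(ValueError):
            count_chains(g, 1)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_walk_enumeration_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 13))
        nodes = list(range(n))
        edges = [(i, j) for i in nodes for j in nodes
                 if i != j and rng.random() < 0.25]
        g = graph_from_edges(nodes, edges)
        N = int(rng.integers(2, 7))
        res = count_chains(g, N)
        walks = brute_force_walks(g, N)
        assert res.total_chains == len(walks)
        from collections import Counter

        occ = Counter()
        for w in walks:
            occ.update(w)  # once per position occupied
        for v in nodes:
            assert res.counts.get(v, 0) == occ.get(v, 0)

    def test_positional_accounting_identity(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            nodes = list(range(n))
            edges = [(i, j) for i in nodes for j in nodes
                     if i != j and rng.random() < 0.3]
            g = graph_from_edges(nodes, edges)
            N = int(rng.integers(2, 6))
            res = count_chains(g, N)
            assert sum(res.counts.values()) == N * res.total_chains


class TestEnumerate:
    def test_three_pool_example_chains(self):
        nodes = [1, 2, 3, 4, 5]
        pool_of = {1: 0, 2: 0, 3: 1, 4: 2, 5: 2}
        g = graph_from_edges(nodes, [(1, 3), (2, 3), (3, 4)],
                             mode="position_specific", n_pools=3,
                             pool_of=pool_of)
        chains = enumerate_chains(g, 3)
        assert [c.pose_ids for c in chains] == [(1, 3, 4), (2, 3, 4)]

    def test_empty_graph(self):
        g = graph_from_edges([], [])
        assert enumerate_chains(g, 3) == []

    @pytest.mark.parametrize("trial", range(10))
    def test_count_equals_enumeration_on_dags(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(4, 11))
        nodes = list(range(n))
        # forward-only edges -> DAG, so walks cannot repeat poses
        edges = [(i, j) for i in nodes for j in nodes
                 if i < j and rng.random() < 0.3]
        g = graph_from_edges(nodes, edges)
        N = int(rng.integers(2, 5))
        res = count_chains(g, N)
        chains = enumerate_chains(g, N, cap=10_000_000)
        assert len(chains) == res.total_chains

    def test_cap_overflow(self):
        # dense cyclic graph: huge walk count
        nodes = list(range(6))
        edges = [(i, j) for i in nodes for j in nodes if i != j]
        g = graph_from_edges(nodes, edges)
        with pytest.raises(OverflowError, match="propensity_filter"):
            enumerate_chains(g, 6, cap=10)

    def test_junction_energies_recorded(self):
        pose_i, pose_j, conf = continuation_poses(shift_third=2.3 + 0.1)
        pool = DockingPool(poses=[pose_i, pose_j], conformers={1: conf})
        g = build_graph(pool, OverlapParams(), mode="single_pool")
        chains = enumerate_chains(g, 2)
        assert len(chains) == 1
        assert chains[0].junction_energies[0] == pytest.approx(1.0)
        assert chains[0].total_overlap == pytest.approx(1.0)


def _pool_of_poses(poses, conformers):
    pool = DockingPool(poses=list(poses), conformers=dict(conformers))
    pool.poses.sort(key=lambda p: (p.energy, p.pose_id))
    for i, p in enumerate(pool.poses, start=1):
        p.rank = i
    return pool


class TestPropensityFilter:
    def test_zero_count_removed(self):
        pose_i, pose_j, conf = continuation_poses()
        lone = pose_at(conf, 99, offset=(500, 0, 0))
        pool = _pool_of_poses([pose_i, pose_j, lone], {1: conf})
        g = build_graph(pool, OverlapParams(), mode="single_pool")
        counts = count_chains(g, 2)
        out = propensity_filter(pool, counts, threshold=1e-4)
        assert {p.pose_id for p in out.poses} == {1, 2}

    def test_threshold_arithmetic(self):
        counts_obj = count_chains(
            graph_from_edges([0, 1], [(0, 1)]), 2)
        # synthetic: T = 20000, c_v = 2 kept at 1/10000
        from ssrna_fragdock.assembly import ChainCountResult

        counts = ChainCountResult(chain_length=2, total_chains=20000,
                                  counts={7: 2, 8: 1})
        conf = one_bead_conformer([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        pool = _pool_of_poses([pose_at(conf, 7), pose_at(conf, 8)], {1: conf})
        out = propensity_filter(pool, counts, threshold=1e-4)
        assert {p.pose_id for p in out.poses} == {7}

    def test_no_chains_returns_empty_and_logs(self, caplog):
        import logging

        conf = one_bead_conformer([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        pool = _pool_of_poses([pose_at(conf, 1)], {1: conf})
        g = build_graph(pool, OverlapParams(), mode="single_pool")
        counts = count_chains(g, 2)
        assert counts.total_chains == 0
        with caplog.at_level(logging.WARNING):
            out = propensity_filter(pool, counts)
        assert len(out.poses) == 0
        assert any("no chains" in r.message for r in caplog.records)

    def test_planted_kept_decoys_removed(self, scenario, planted_pool):
        poses = list(planted_pool.poses) + [
            Pose(pose_id=d.pose_id, conformer_id=d.conformer_id,
                 transform=d.transform, energy=d.energy, coords=d.coords)
            for d in scenario.decoy_poses]
        pool = _pool_of_poses(poses, scenario.planted_conformers)
        g = build_graph(pool, OverlapParams(), mode="single_pool")
        counts = count_chains(g, 6)
        out = propensity_filter(pool, counts, threshold=1e-4)
        kept = {p.pose_id for p in out.poses}
        assert kept == {1, 2, 3, 4, 5, 6}

    def test_never_removes_chain_member_at_one_over_T(self):
        rng = np.random.default_rng(77)
        nodes = list(range(8))
        edges = [(i, j) for i in nodes for j in nodes
                 if i < j and rng.random() < 0.4]
        g = graph_from_edges(nodes, edges)
        N = 3
        counts = count_chains(g, N)
        if counts.total_chains == 0:
            pytest.skip("no chains in this random draw")
        chains = enumerate_chains(g, N)
        member_ids = {pid for c in chains for pid in c.pose_ids}
        cut = counts.total_chains * (1.0 / counts.total_chains)
        for v in member_ids:
            assert counts.counts[v] >= cut

    def test_monotone_in_threshold_and_violation(self, scenario, planted_pool):
        rng = np.random.default_rng(13)
        from conftest import random_pose_pool

        pool = random_pose_pool(rng, scenario, n=30, radius=10.0)
        loose = OverlapParams(margin_backbone=4.0, margin_base=4.0,
                              max_violation=20.0)
        tight = OverlapParams(margin_backbone=4.0, margin_base=4.0,
                              max_violation=2.0)
        g_loose = build_graph(pool, loose, mode="single_pool")
        g_tight = build_graph(pool, tight, mode="single_pool")
        assert set(g_tight.edges()) <= set(
            (i, j, e) for i, j, e in g_loose.edges())
        counts = count_chains(g_loose, 3)
        hi = propensity_filter(pool, counts, threshold=1e-2)
        lo = propensity_filter(pool, counts, threshold=1e-6)
        assert {p.pose_id for p in hi.poses} <= {p.pose_id for p in lo.poses}


class TestIterativeAssembly:
    def test_degenerate_schedule_equals_single_filter(self, scenario,
                                                      planted_pool):
        params = OverlapParams()
        out, log = iterative_assembly(planted_pool, params, N=6,
                                      schedule=(1.0,), threshold=1e-4)
        g = build_graph(planted_pool, params, mode="single_pool")
        counts = count_chains(g, 6)
        direct = propensity_filter(planted_pool, counts, threshold=1e-4)
        assert {p.pose_id for p in out.poses} == \
            {p.pose_id for p in direct.poses}
        assert len(log) == 1

    def test_planted_top_ranked_survive_all_stages(self, scenario,
                                                   planted_pool):
        # planted poses rank 1-6 (best energies); decoys fill the tail
        poses = list(planted_pool.poses)
        for k, d in enumerate(scenario.decoy_poses[:100]):
            poses.append(Pose(pose_id=d.pose_id, conformer_id=d.conformer_id,
                              transform=d.transform, energy=10.0 + k,
                              coords=d.coords))
        pool = _pool_of_poses(poses, scenario.planted_conformers)
        out, log = iterative_assembly(
            pool, OverlapParams(), N=6,
            schedule=(0.06, 0.12, 0.5, 1.0), threshold=1e-4)
        assert {1, 2, 3, 4, 5, 6} <= {p.pose_id for p in out.poses}

    def test_remote_pose_never_added(self, scenario, planted_pool):
        poses = list(planted_pool.poses)
        conf = scenario.planted_conformers[1]
        t = RigidTransform(np.eye(3), scenario.receptor.com + (200, 0, 0))
        remote = Pose(pose_id=777, conformer_id=1, transform=t, energy=5.0,
                      coords=t.apply(conf.coords))
        poses.append(remote)
        pool = _pool_of_poses(poses, scenario.planted_conformers)
        out, _ = iterative_assembly(pool, OverlapParams(), N=6,
                                    schedule=(0.9, 1.0), radius=5.0,
                                    threshold=1e-4)
        assert 777 not in {p.pose_id for p in out.poses}

    def test_schedule_must_increase(self, planted_pool):
        with pytest.raises(ValueError, match="increasing"):
            iterative_assembly(planted_pool, OverlapParams(), N=6,
                               schedule=(0.05, 0.05))
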