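"""RMSD-based pose clustering and coarse-to-fine overlap assembly.

Greedy leader clustering in rank order; a multi-radius hierarchy built by
re-clustering representatives; and a hierarchical assembly that screens
cluster representatives with loose overlap margins before refining candidate
pairs down to pose-level edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import Chain, ChainGraph, OverlapParams, build_graph, \
    count_chains, enumerate_chains, overlap_energy, propensity_filter
from .docking import DockingPool, Pose, pose_rmsd

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """Poses within ``radius`` ligand-RMSD of the best-ranked member."""

    cluster_id: int
    representative: int  # pose_id
    members: list[int]
    radius: float


@dataclass
class ClusterHierarchy:
    """Ordered clustering levels at strictly increasing radii.

    ``levels[l]`` is the cluster list at ``radii[l]``; level l+1 clusters the
    representatives of level l.  ``parent_of[l][cluster_id]`` maps a level-l
    cluster to its parent at level l+1.
    """

    radii: list[float]
    levels: list[list[Cluster]]
    parent_of: list[dict[int, int]] = field(default_factory=list)

    def sizes(self) -> list[int]:
        return [len(level) for level in self.levels]


def cluster_poses(pool: DockingPool, radius: float) -> list[Cluster]:
    """Greedy leader clustering in rank order.

    Each pose joins the first existing cluster whose representative lies
    within ``radius``; otherwise it founds a new cluster.  Deterministic
    because ranks are unique.
    """
    if radius <= 0:
        raise ValueError("cluster radius must be positive")
    pool.check_sorted()
    clusters: list[Cluster] = []
    reps: list[Pose] = []
    for pose in pool.poses:
        placed = False
        for c, rep in zip(clusters, reps):
            if pose_rmsd(pose, rep) <= radius:
                c.members.append(pose.pose_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(cluster_id=len(clusters),
                                    representative=pose.pose_id,
                                    members=[pose.pose_id], radius=radius))
            reps.append(pose)
    return clusters


def _rep_pool(pool: DockingPool, clusters: list[Cluster]) -> DockingPool:
    rep_ids = {c.representative for c in clusters}
    kept = [p for p in pool.poses if p.pose_id in rep_ids]
    out = DockingPool(poses=kept, conformers=pool.conformers,
                      provenance=dict(pool.provenance))
    out.poses.sort(key=lambda p: (p.energy, p.pose_id))
    return out


def sequential_cluster(pool: DockingPool,
                       radii: list[float] = (2.0, 3.0, 4.0)) -> ClusterHierarchy:
    """Cluster poses at radii[0], then representatives at each larger radius."""
    radii = list(radii)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    levels: list[list[Cluster]] = []
    parent_of: list[dict[int, int]] = []
    current = pool
    for r in radii:
        clusters = cluster_poses(current, r)
        levels.append(clusters)
        current = _rep_pool(current, clusters)
    for l in range(len(levels) - 1):
        rep_to_parent = {}
        for parent in levels[l + 1]:
            for member_pose in parent.members:
                rep_to_parent[member_pose] = parent.cluster_id
        parent_of.append({c.cluster_id: rep_to_parent[c.representative]
                          for c in levels[l]})
    return ClusterHierarchy(radii=radii, levels=levels, parent_of=parent_of)


def hierarchical_assembly(
    pool: DockingPool,
    hierarchy: ClusterHierarchy,
    params_schedule: list[OverlapParams],
    N: int,
    cap: int = 1_000_000,
) -> tuple[list[Chain], ChainGraph]:
    """Coarse-to-fine chain building over a cluster hierarchy.

    ``params_schedule`` has one entry per hierarchy level plus a final entry
    for the pose level, ordered finest-first (pose level first); margins must
    be non-increasing toward the finest level.  Top-level representative
    pairs passing the loose overlap test are refined child-pair by child-pair
    down to pose-level edges; chains are enumerated from the surviving edges.
    """
    n_levels = len(hierarchy.levels)
    if len(params_schedule) != n_levels + 1:
        raise ValueError("need one OverlapParams per level plus the pose level")
    for fine, coarse in zip(params_schedule, params_schedule[1:]):
        if fine.margin_backbone > coarse.margin_backbone or \
           fine.margin_base > coarse.margin_base:
            raise ValueError("margins must be non-increasing toward finer levels")
    if not hierarchy.levels or not hierarchy.levels[-1]:
        return [], ChainGraph(node_ids=[], pool_of={}, succ={},
                              mode="single_pool", n_pools=1)

    pose_of = {p.pose_id: p for p in pool.poses}
    conf_of = {p.pose_id: pool.conformers[p.conformer_id] for p in pool.poses}

    # children[l][cluster_id] -> list of level l-1 cluster ids (or pose ids at l=0)
    def children_of(level: int, cluster: Cluster) -> list[int]:
        if level == 0:
            return list(cluster.members)  # pose ids
        rep_to_child = {c.representative: c.cluster_id
                        for c in hierarchy.levels[level - 1]}
        return [rep_to_child[m] for m in cluster.members]

    def rep_pose(level: int, cluster_id: int) -> Pose:
        return pose_of[hierarchy.levels[level][cluster_id].representative]

    top = n_levels - 1
    top_params = params_schedule[top + 1]
    candidates = []
    top_clusters = hierarchy.levels[top]
    for a in top_clusters:
        for b in top_clusters:
            pa, pb = pose_of[a.representative], pose_of[b.representative]
            if pa.pose_id == pb.pose_id:
                continue
            e = overlap_energy(pa, pb, conf_of[pa.pose_id], conf_of[pb.pose_id],
                               top_params)
            ok = (e == 0.0) if top_params.hard_mode else (e <= top_params.max_violation)
            if ok:
                candidates.append((top, a.cluster_id, b.cluster_id))

    pose_edges: dict[int, list[tuple[int, float]]] = {p.pose_id: []
                                                      for p in pool.poses}
    cluster_by_id = [
        {c.cluster_id: c for c in level} for level in hierarchy.levels
    ]
    stack = candidates
    while stack:
        level, ca, cb = stack.pop()
        params = params_schedule[level]  # next finer level's params
        ch_a = children_of(level, cluster_by_id[level][ca])
        ch_b = children_of(level, cluster_by_id[level][cb])
        for xa in ch_a:
            for xb in ch_b:
                if level == 0:
                    pa, pb = pose_of[xa], pose_of[xb]
                    if pa.pose_id == pb.pose_id:
                        continue
                    e = overlap_energy(pa, pb, conf_of[xa], conf_of[xb], params)
                    ok = (e == 0.0) if params.hard_mode \
                        else (e <= params.max_violation)
                    if ok and all(j != xb for j, _ in pose_edges[xa]):
                        pose_edges[xa].append((xb, e))
                else:
                    pa = rep_pose(level - 1, xa)
                    pb = rep_pose(level - 1, xb)
                    if pa.pose_id == pb.pose_id:
                        continue
                    e = overlap_energy(pa, pb, conf_of[pa.pose_id],
                                       conf_of[pb.pose_id], params)
                    ok = (e == 0.0) if params.hard_mode \
                        else (e <= params.max_violation)
                    if ok:
                        stack.append((level - 1, xa, xb))
    for lst in pose_edges.values():
        lst.sort(key=lambda t: t[0])
    graph = ChainGraph(node_ids=sorted(pose_edges),
                       pool_of={i: 0 for i in pose_edges},
                       succ=pose_edges, mode="single_pool", n_pools=1)
    chains = enumerate_chains(graph, N, cap=cap)
    return chains, graph


def assemble_clustered(
    pool: DockingPool,
    N: int,
    cluster_radius: float = 3.0,
    loose_margin: float = 5.0,
    hard_mode: bool = True,
    propensity_threshold: float = 1e-4,
    cap: int = 1_000_000,
) -> tuple[list[Chain], DockingPool]:
    """Cluster a filtered pool and assemble representatives with loose margins.

    Clusters at ``cluster_radius``, keeps the best-ranked pose per cluster,
    builds a single-pool graph with uniform ``loose_margin`` restraints (no
    violation allowed in hard mode), propensity-filters, and enumerates the
    resulting chains.
    """
    clusters = cluster_poses(pool, cluster_radius)
    reps = _rep_pool(pool, clusters)
    params = OverlapParams(margin_backbone=loose_margin, margin_base=loose_margin,
                           k=100.0, max_violation=0.0 if hard_mode else 2.0,
                           hard_mode=hard_mode)
    graph = build_graph(reps, params, mode="single_pool")
    counts = count_chains(graph, N)
    filtered = propensity_filter(reps, counts, threshold=propensity_threshold)
    if not filtered.poses:
        return [], filtered
    graph2 = build_graph(filtered, params, mode="single_pool")
    chains = enumerate_chains(graph2, N, cap=cap)
    return chains, filtered
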