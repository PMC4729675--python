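"""Overlap evaluation, chain graphs, chain counting, and the propensity filter.

Two consecutive poses are connectable when the flat-bottom harmonic penalty
between the shared nucleotides (2nd/3rd of the upstream pose against 1st/2nd
of the downstream pose) stays below a violation budget.  Chain counting uses
a forward/backward dynamic program over the resulting directed graph; the
per-pose chain-participation count feeds the propensity filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cg import BACKBONE_LIKE, CGStructure
from .docking import DockingPool, Pose, pose_rmsd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapParams:
    """Flat-bottom restraint parameters for the overlap criterion."""

    margin_backbone: float = 2.3
    margin_base: float = 2.8
    k: float = 100.0  # kcal/mol/A^2
    max_violation: float = 2.0  # kcal/mol
    hard_mode: bool = False

    def __post_init__(self):
        if self.margin_backbone <= 0 or self.margin_base <= 0:
            raise ValueError("margins must be positive")
        if self.k <= 0:
            raise ValueError("harmonic constant must be positive")
        if self.max_violation < 0:
            raise ValueError("violation budget must be >= 0")

    @property
    def budget(self) -> float:
        return 0.0 if self.hard_mode else self.max_violation


def _residue_order(conformer: CGStructure) -> list[tuple[str, int]]:
    seen, order = set(), []
    for c, r in zip(conformer.chain_ids, conformer.residue_indices):
        key = (c, int(r))
        if key not in seen:
            seen.add(key)
            order.append(key)
    return order


def _nucleotide_slices(conformer: CGStructure) -> list[np.ndarray]:
    """Bead index arrays for the 1st, 2nd, 3rd nucleotide, in chain order."""
    order = _residue_order(conformer)
    return [
        np.flatnonzero([(c, int(r)) == key for c, r in
                        zip(conformer.chain_ids, conformer.residue_indices)])
        for key in order
    ]


def overlap_energy(pose_i: Pose, pose_j: Pose,
                   conformer_i: CGStructure, conformer_j: CGStructure,
                   params: OverlapParams) -> float:
    """Total flat-bottom violation energy for pose_j continuing pose_i.

    Beads of nucleotides 2 and 3 of pose_i pair with beads of nucleotides 1
    and 2 of pose_j; each pair at distance d contributes k*(d - m)^2 when
    d exceeds its margin m (backbone/sugar/phosphate vs base margins).
    """
    sl_i = _nucleotide_slices(conformer_i)
    sl_j = _nucleotide_slices(conformer_j)
    total = 0.0
    for a, b in ((sl_i[1], sl_j[0]), (sl_i[2], sl_j[1])):
        if len(a) != len(b):
            raise ValueError("paired nucleotides have different bead counts")
        roles_a = conformer_i.roles[a]
        roles_b = conformer_j.roles[b]
        if any(ra != rb for ra, rb in zip(roles_a, roles_b)):
            raise ValueError("bead role mismatch between paired nucleotides")
        d = np.linalg.norm(pose_i.coords[a] - pose_j.coords[b], axis=1)
        m = np.where([r in BACKBONE_LIKE for r in roles_a],
                     params.margin_backbone, params.margin_base)
        excess = np.maximum(0.0, d - m)
        total += params.k * float((excess ** 2).sum())
    return total


@dataclass
class ChainGraph:
    """Directed pose-connectivity graph.

    ``mode`` is ``position_specific`` (edges only pool p -> p+1) or
    ``single_pool`` (all ordered pairs tested).  ``succ[i]`` lists
    ``(j, overlap_energy)``.
    """

    node_ids: list[int]
    pool_of: dict[int, int]
    succ: dict[int, list[tuple[int, float]]]
    mode: str
    n_pools: int

    def edges(self) -> list[tuple[int, int, float]]:
        return [(i, j, e) for i, lst in self.succ.items() for j, e in lst]

    def n_edges(self) -> int:
        return sum(len(v) for v in self.succ.values())


def _max_extent(pool: DockingPool) -> float:
    ext = 0.0
    for conf in pool.conformers.values():
        centred = conf.coords - conf.coords.mean(axis=0)
        ext = max(ext, float(np.linalg.norm(centred, axis=1).max(initial=0.0)))
    return ext


def build_graph(pools: DockingPool | list[DockingPool],
                params: OverlapParams,
                mode: str = "single_pool",
                spatial_prefilter: bool = True) -> ChainGraph:
    """Edge i->j iff overlap_energy(i, j) <= budget (0 in hard mode).

    A conservative COM-distance bound may prune candidate pairs; it cannot
    remove true edges (a connecting pair keeps every matched bead within
    margin + sqrt(budget/k), so pose COMs stay within twice the maximal
    conformer extent plus that reach).
    """
    if mode not in ("single_pool", "position_specific"):
        raise ValueError(f"unknown graph mode {mode!r}")
    if mode == "single_pool":
        if isinstance(pools, list):
            if len(pools) != 1:
                raise ValueError("single_pool mode takes exactly one pool")
            pools = pools[0]
        pool_list = [pools]
    else:
        if not isinstance(pools, list) or len(pools) < 2:
            raise ValueError("position_specific mode needs a list of >= 2 pools")
        pool_list = pools

    node_ids, pool_of, pose_of, conf_of = [], {}, {}, {}
    for p_idx, pool in enumerate(pool_list):
        for pose in pool.poses:
            if pose.pose_id in pool_of:
                raise ValueError(f"duplicate pose id {pose.pose_id} across pools")
            node_ids.append(pose.pose_id)
            pool_of[pose.pose_id] = p_idx
            pose_of[pose.pose_id] = pose
            conf_of[pose.pose_id] = pool.conformers[pose.conformer_id]

    reach = (max(params.margin_backbone, params.margin_base)
             + math.sqrt(params.budget / params.k) if params.budget > 0
             else max(params.margin_backbone, params.margin_base))
    bound = 2.0 * max(_max_extent(p) for p in pool_list) + reach

    succ: dict[int, list[tuple[int, float]]] = {i: [] for i in node_ids}

    def add_pairs_batched(a_poses, b_poses, skip_self=False):
        """Vectorised overlap evaluation of KDTree-prefiltered pose pairs."""
        if not a_poses or not b_poses:
            return
        tb = cKDTree(np.array([p.com for p in b_poses]))
        ta = np.array([p.com for p in a_poses])
        pair_ia, pair_ib = [], []
        for ia, hits in enumerate(tb.query_ball_point(ta, bound)):
            for ib in hits:
                if skip_self and a_poses[ia].pose_id == b_poses[ib].pose_id:
                    continue
                pair_ia.append(ia)
                pair_ib.append(ib)
        if not pair_ia:
            return
        pair_ia = np.asarray(pair_ia)
        pair_ib = np.asarray(pair_ib)
        # group by conformer pair so bead layouts line up
        conf_a = np.array([a_poses[i].conformer_id for i in pair_ia])
        conf_b = np.array([b_poses[i].conformer_id for i in pair_ib])
        layout_cache: dict = {}
        for ca, cb in {(int(x), int(y)) for x, y in zip(conf_a, conf_b)}:
            sel = (conf_a == ca) & (conf_b == cb)
            ka = conf_of[a_poses[pair_ia[np.argmax(sel)]].pose_id]
            kb = conf_of[b_poses[pair_ib[np.argmax(sel)]].pose_id]
            key = (ca, cb)
            if key not in layout_cache:
                sl_a = _nucleotide_slices(ka)
                sl_b = _nucleotide_slices(kb)
                idx_a = np.concatenate([sl_a[1], sl_a[2]])
                idx_b = np.concatenate([sl_b[0], sl_b[1]])
                if len(idx_a) != len(idx_b):
                    raise ValueError(
                        "paired nucleotides have different bead counts")
                roles_a = ka.roles[idx_a]
                roles_b = kb.roles[idx_b]
                if any(ra != rb for ra, rb in zip(roles_a, roles_b)):
                    raise ValueError(
                        "bead role mismatch between paired nucleotides")
                margins = np.where([r in BACKBONE_LIKE for r in roles_a],
                                   params.margin_backbone, params.margin_base)
                layout_cache[key] = (idx_a, idx_b, margins)
            idx_a, idx_b, margins = layout_cache[key]
            ii = np.flatnonzero(sel)
            ca_coords = np.stack([a_poses[pair_ia[i]].coords[idx_a]
                                  for i in ii])
            cb_coords = np.stack([b_poses[pair_ib[i]].coords[idx_b]
                                  for i in ii])
            d = np.sqrt(((ca_coords - cb_coords) ** 2).sum(axis=-1))
            excess = np.maximum(0.0, d - margins[None, :])
            e = params.k * (excess ** 2).sum(axis=1)
            ok = (e == 0.0) if params.hard_mode else (e <= params.max_violation)
            for i, keep, ei in zip(ii, ok, e):
                if keep:
                    succ[a_poses[pair_ia[i]].pose_id].append(
                        (b_poses[pair_ib[i]].pose_id, float(ei)))

    def add_pairs_exhaustive(a_poses, b_poses, skip_self=False):
        """Reference path: one overlap_energy call per ordered pair."""
        for pa in a_poses:
            for pb in b_poses:
                if skip_self and pa.pose_id == pb.pose_id:
                    continue
                e = overlap_energy(pa, pb, conf_of[pa.pose_id],
                                   conf_of[pb.pose_id], params)
                ok = (e == 0.0) if params.hard_mode \
                    else (e <= params.max_violation)
                if ok:
                    succ[pa.pose_id].append((pb.pose_id, e))

    add_pairs = add_pairs_batched if spatial_prefilter else add_pairs_exhaustive
    if mode == "position_specific":
        for p_idx in range(len(pool_list) - 1):
            add_pairs(pool_list[p_idx].poses, pool_list[p_idx + 1].poses)
    else:
        poses = pool_list[0].poses
        add_pairs(poses, poses, skip_self=True)

    for lst in succ.values():
        lst.sort(key=lambda t: t[0])
    return ChainGraph(node_ids=sorted(node_ids), pool_of=pool_of, succ=succ,
                      mode=mode, n_pools=len(pool_list))


@dataclass
class ChainCountResult:
    """Chain-participation counts from the forward/backward DP."""

    chain_length: int
    total_chains: int
    counts: dict[int, int]

    def propensity(self, pose_id: int) -> float:
        if self.total_chains == 0:
            return 0.0
        # each chain touches a pose once per position it occupies
        return self.counts.get(pose_id, 0) / self.total_chains


def count_chains(graph: ChainGraph, N: int) -> ChainCountResult:
    """Number of N-pose chains each pose participates in.

    Forward pass: f_k(v) = number of k-node walks ending at v; backward pass
    symmetric.  c_v = sum_k f_k(v) * b_{N-k+1}(v) counts v once per chain
    position, so sum_v c_v = N * T.  In position-specific mode walks are
    anchored at the first/last pool (and are automatically simple); in
    single-pool mode walks may revisit poses.
    """
    if N < 2:
        raise ValueError("chain length must be >= 2")
    nodes = graph.node_ids
    pred: dict[int, list[int]] = {v: [] for v in nodes}
    for i, lst in graph.succ.items():
        for j, _ in lst:
            pred[j].append(i)

    if graph.mode == "position_specific":
        if graph.n_pools != N:
            raise ValueError(
                f"position_specific counting needs N ({N}) pools, "
                f"got {graph.n_pools}")
        f1 = {v: 1 if graph.pool_of[v] == 0 else 0 for v in nodes}
        b1 = {v: 1 if graph.pool_of[v] == graph.n_pools - 1 else 0 for v in nodes}
    else:
        f1 = {v: 1 for v in nodes}
        b1 = {v: 1 for v in nodes}

    f = [f1]
    for _ in range(N - 1):
        prev = f[-1]
        f.append({v: sum(prev[u] for u in pred[v]) for v in nodes})
    b = [b1]
    for _ in range(N - 1):
        prev = b[-1]
        b.append({v: sum(prev[w] for w, _ in graph.succ[v]) for v in nodes})

    T = sum(f[N - 1].values()) if graph.mode != "position_specific" else \
        sum(f[N - 1][v] for v in nodes if graph.pool_of[v] == graph.n_pools - 1)
    counts = {v: sum(f[k][v] * b[N - 1 - k][v] for k in range(N)) for v in nodes}
    assert sum(counts.values()) == N * T, "positional accounting identity violated"
    return ChainCountResult(chain_length=N, total_chains=T, counts=counts)


def propensity_filter(
    pools: DockingPool | list[DockingPool],
    counts: ChainCountResult,
    threshold: float = 1e-4,
):
    """Keep poses participating in at least ``threshold`` of all chains."""
    single = isinstance(pools, DockingPool)
    pool_list = [pools] if single else pools
    if counts.total_chains == 0:
        logger.warning("no chains formed: propensity filter returns empty pool(s)")
        empty = [DockingPool(conformers=p.conformers,
                             provenance=dict(p.provenance)) for p in pool_list]
        return empty[0] if single else empty
    cut = threshold * counts.total_chains
    out = []
    for p in pool_list:
        kept = [pose for pose in p.poses if counts.counts.get(pose.pose_id, 0) >= cut]
        q = DockingPool(poses=kept, conformers=p.conformers,
                        provenance=dict(p.provenance))
        q.provenance["propensity_threshold"] = threshold
        q.poses.sort(key=lambda x: (x.energy, x.pose_id))
        out.append(q)
    return out[0] if single else out


@dataclass
class Chain:
    """An ordered run of N connectable poses."""

    pose_ids: tuple[int, ...]
    junction_energies: tuple[float, ...]
    fragment_rmsds: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.junction_energies) != len(self.pose_ids) - 1:
            raise ValueError("need exactly N-1 junction energies")

    @property
    def total_overlap(self) -> float:
        return float(sum(self.junction_energies))


def enumerate_chains(graph: ChainGraph, N: int,
                     cap: int = 1_000_000) -> list[Chain]:
    """All N-pose chains, depth-first, lexicographic in pose id.

    In single-pool mode, walks revisiting a pose are dropped before
    reporting (the DP counts them; the discrepancy is logged).  Raises when
    the walk count exceeds ``cap``.
    """
    counts = count_chains(graph, N)
    if counts.total_chains > cap:
        raise OverflowError(
            f"{counts.total_chains} chains exceed cap {cap}; "
            "apply propensity_filter first")
    energy_of = {(i, j): e for i, lst in graph.succ.items() for j, e in lst}
    if graph.mode == "position_specific":
        starts = [v for v in graph.node_ids if graph.pool_of[v] == 0]
    else:
        starts = list(graph.node_ids)
    chains: list[Chain] = []
    dropped = 0

    def dfs(path: list[int]):
        nonlocal dropped
        if len(path) == N:
            if graph.mode == "single_pool" and len(set(path)) != N:
                dropped += 1
                return
            es = tuple(energy_of[(path[i], path[i + 1])] for i in range(N - 1))
            chains.append(Chain(pose_ids=tuple(path), junction_energies=es))
            return
        for j, _ in graph.succ[path[-1]]:
            path.append(j)
            dfs(path)
            path.pop()

    for s in sorted(starts):
        dfs([s])
    if dropped:
        logger.info("enumerate_chains: dropped %d pose-repeating walks", dropped)
    return chains


def iterative_assembly(
    pool: DockingPool,
    params: OverlapParams,
    N: int = 5,
    schedule: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05),
    radius: float = 5.0,
    threshold: float = 1e-4,
) -> tuple[DockingPool, list[dict]]:
    """Staged propensity filtering of a ranked pool.

    Stage 1 propensity-filters the first rank fraction; each later stage
    adds poses from its fraction that lie within ``radius`` ligand-RMSD of a
    previously selected pose, then re-filters.  Returns the final pool and a
    per-stage audit log.
    """
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule fractions must be strictly increasing")
    pool.check_sorted()
    ranked = pool.poses
    log: list[dict] = []
    selected: list[Pose] = []
    proximity_active = True
    prev_cut = 0

    def filter_poses(poses: list[Pose]) -> list[Pose]:
        sub = DockingPool(poses=list(poses), conformers=pool.conformers)
        sub.poses.sort(key=lambda x: (x.energy, x.pose_id))
        graph = build_graph(sub, params, mode="single_pool")
        counts = count_chains(graph, N)
        filtered = propensity_filter(sub, counts, threshold=threshold)
        return filtered.poses

    for stage, fraction in enumerate(schedule, start=1):
        cut = math.ceil(fraction * len(ranked))
        new_poses = ranked[prev_cut:cut]
        prev_cut = cut
        if stage == 1 or not proximity_active:
            added = list(new_poses)
        else:
            sel_coords = [p for p in selected]
            added = [p for p in new_poses
                     if any(pose_rmsd(p, s) <= radius for s in sel_coords)]
        candidate = selected + added
        selected = filter_poses(candidate)
        if stage == 1 and not selected:
            logger.warning("iterative_assembly: empty first stage; "
                           "proximity seeding disabled")
            proximity_active = False
            selected = list(added)
        log.append({"stage": stage, "fraction": fraction,
                    "candidates": len(candidate), "added": len(added),
                    "selected": len(selected)})
    out = DockingPool(poses=list(selected), conformers=pool.conformers,
                      provenance=dict(pool.provenance))
    out.poses.sort(key=lambda x: (x.energy, x.pose_id))
    return out, log
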