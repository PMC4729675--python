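"""Pose and chain scoring, RMSD metrics, hit classification and statistics.

All RMSDs here are ligand-RMSDs: computed over CG beads in the fixed
receptor frame, without re-superposition.  Chain accuracy is the geometric
mean of per-position ligand-RMSDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assembly import Chain, ChainCountResult
from .cg import CGStructure
from .docking import DockingPool, Pose


@dataclass(frozen=True)
class HitThresholds:
    """Strict RMSD thresholds for hit / near-hit / close-hit classification."""

    hit: float = 2.0
    near_hit: float = 5.0
    close_hit: float = 6.0

    def __post_init__(self):
        if not self.hit < self.near_hit < self.close_hit:
            raise ValueError("thresholds must satisfy hit < near_hit < close_hit")


def ligand_rmsd(pose: Pose | np.ndarray, reference: CGStructure | np.ndarray) -> float:
    """RMSD over beads with no re-superposition (receptor frame fixed)."""
    a = pose.coords if isinstance(pose, Pose) else np.asarray(pose, float)
    b = reference.coords if isinstance(reference, CGStructure) else \
        np.asarray(reference, float)
    if a.shape != b.shape:
        raise ValueError(f"bead count mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


@dataclass
class HitReport:
    """Per-reference hit statistics for one pose pool."""

    per_reference: list[dict]
    total_poses: int
    thresholds: HitThresholds

    def totals(self) -> dict:
        return {
            "hits": sum(r["hits"] for r in self.per_reference),
            "near_hits": sum(r["near_hits"] for r in self.per_reference),
            "close_hits": sum(r["close_hits"] for r in self.per_reference),
        }


def classify_hits(pool: DockingPool, references: list[CGStructure],
                  thresholds: HitThresholds = HitThresholds()) -> HitReport:
    """Compare every pose to every reference fragment (pooled convention).

    For each reference: the minimum RMSD over the pool and the number of
    poses strictly below each threshold.
    """
    if not references:
        raise ValueError("references must be non-empty")
    per_ref = []
    for ref in references:
        rmsds = np.array([ligand_rmsd(p, ref) for p in pool.poses]) \
            if pool.poses else np.array([])
        per_ref.append({
            "min_rmsd": float(rmsds.min()) if len(rmsds) else math.inf,
            "hits": int((rmsds < thresholds.hit).sum()),
            "near_hits": int((rmsds < thresholds.near_hit).sum()),
            "close_hits": int((rmsds < thresholds.close_hit).sum()),
        })
    return HitReport(per_reference=per_ref, total_poses=len(pool.poses),
                     thresholds=thresholds)


def chain_rmsd(per_fragment_rmsds) -> float:
    """Geometric mean of per-position ligand-RMSDs (0 if any term is 0)."""
    vals = np.asarray(list(per_fragment_rmsds), dtype=float)
    if len(vals) == 0:
        raise ValueError("need at least one per-fragment RMSD")
    if np.any(vals < 0):
        raise ValueError("RMSDs must be non-negative")
    if np.any(vals == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def evaluate_chain(chain: Chain, pose_of: dict[int, Pose],
                   references: list[CGStructure]) -> float:
    """Geometric-mean RMSD of a chain against position-matched references."""
    if len(chain.pose_ids) != len(references):
        raise ValueError(
            f"chain length {len(chain.pose_ids)} != reference count "
            f"{len(references)}")
    vals = [ligand_rmsd(pose_of[pid], ref)
            for pid, ref in zip(chain.pose_ids, references)]
    return chain_rmsd(vals)


@dataclass
class ScoreRecord:
    item_id: int | tuple
    score: float
    components: dict = field(default_factory=dict)


def score_poses(pool: DockingPool, counts: ChainCountResult) -> list[ScoreRecord]:
    """Pose score ln(chain propensity) / rank, sorted descending.

    Larger is better (less negative log over a better rank); poses with zero
    propensity are excluded since the log is undefined.
    """
    records = []
    for pose in pool.poses:
        p = counts.propensity(pose.pose_id)
        if p <= 0:
            continue
        records.append(ScoreRecord(
            item_id=pose.pose_id,
            score=math.log(p) / pose.rank,
            components={"propensity": p, "rank": pose.rank},
        ))
    records.sort(key=lambda r: -r.score)
    return records


def score_chains(chains: list[Chain], rank_of: dict[int, int], N: int,
                 mode: str = "product") -> list[ScoreRecord]:
    """Chain score combining junction overlaps with member ranks.

    ``product`` (default): (sum of junction overlaps) * (sum of rank^2) / N,
    smaller is better — both factors are penalties.  ``ratio`` divides by the
    rank term instead.  Sorted ascending (best first).
    """
    if mode not in ("product", "ratio"):
        raise ValueError(f"unknown chain-score mode {mode!r}")
    records = []
    for chain in chains:
        overlap = chain.total_overlap
        rank_term = sum(rank_of[pid] ** 2 for pid in chain.pose_ids) / N
        score = overlap * rank_term if mode == "product" else \
            (overlap / rank_term if rank_term else math.inf)
        records.append(ScoreRecord(
            item_id=chain.pose_ids, score=score,
            components={"overlap": overlap, "rank_term": rank_term,
                        "mode": mode}))
    records.sort(key=lambda r: r.score)
    return records


def binding_site_stats(pool: DockingPool, references: list[CGStructure],
                       cutoffs=(10.0, 15.0)) -> dict:
    """Distance-to-binding-site summary of a filtered pool.

    For each pose the RMSD to its closest reference fragment; returns the
    fraction strictly below each cutoff and the maximum.
    """
    mins = []
    for pose in pool.poses:
        mins.append(min(ligand_rmsd(pose, ref) for ref in references))
    mins = np.asarray(mins)
    out = {"max": float(mins.max()) if len(mins) else math.nan}
    out["fractions"] = {float(c): float((mins < c).mean()) if len(mins) else math.nan
                        for c in cutoffs}
    return out


def fit_vs_dock_correlation(pairs) -> tuple[float, float]:
    """Pearson correlation between best-fit conformer RMSD and minimal
    docked-pose RMSD, with a two-sided t-test p-value (n-2 df)."""
    from scipy import stats

    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in one coordinate: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def enrichment(top_n: int, pool_size: int, hits_in_top: int,
               hits_total: int) -> float:
    """Hypergeometric upper tail P(X >= hits_in_top), by exact summation.

    Drawing ``top_n`` items from ``pool_size`` of which ``hits_total`` are
    successes.
    """
    if not (0 <= hits_total <= pool_size):
        raise ValueError("hits_total must be within pool_size")
    if not (0 <= top_n <= pool_size):
        raise ValueError("top_n must be within pool_size")
    if hits_in_top > min(top_n, hits_total):
        raise ValueError("hits_in_top exceeds min(top_n, hits_total)")
    from fractions import Fraction

    denom = math.comb(pool_size, top_n)
    total = Fraction(0)
    for x in range(hits_in_top, min(top_n, hits_total) + 1):
        total += Fraction(math.comb(hits_total, x)
                          * math.comb(pool_size - hits_total, top_n - x), denom)
    return float(total)
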