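"""Average-linkage clustering bounded at the species-level distance.

Clusters are grown agglomeratively: at each step the pair of clusters
with the smallest average inter-member distance (arithmetic mean over
all cross pairs) is merged, while that minimum is at most the bound
(default 0.05, the Mash distance corresponding to 95% ANI).  The bound
acts as a merge stopping criterion; for average linkage this yields the
same partition as cutting the full tree at the bound.  Each final
cluster's representative is its highest-quality member.

Average distances are maintained with the Lance-Williams update
    d(i∪j, m) = (n_i * d(i,m) + n_j * d(j,m)) / (n_i + n_j),
reading the input distances row-wise from the store's random-access
interface.  Merge ties break on the lowest (i, j) index pair, so the
partition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gutrefset.minhash import DistanceStore
from gutrefset.quality import QualityMetrics, quality_score

SPECIES_BOUND = 0.05


@dataclass(frozen=True)
class SpeciesCluster:
    cluster_id: int
    member_ids: tuple[str, ...]
    representative_id: str
    representative_score: float

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a cluster member")

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class Dendrogram:
    """Ordered merge steps: (left members, right members, average distance)."""

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = field(default_factory=list)

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def average_linkage_partition(store: DistanceStore, bound: float = SPECIES_BOUND):
    """Merge clusters while the minimal average distance is <= bound.

    Returns (partition, dendrogram) where partition is a list of tuples
    of genome ids, each sorted, the list ordered by first member's
    input index.
    """
    n = len(store)
    if n == 0:
        raise ValueError("empty distance store")
    ids = store.ids
    if n == 1:
        return [tuple(ids)], Dendrogram()
    # Working matrix of average distances between *active* clusters,
    # filled row-wise through the store's random-access contract.
    work = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        work[i] = store.row(i)
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n, dtype=np.int64)
    members: list[list[int] | None] = [[i] for i in range(n)]
    active = np.ones(n, dtype=bool)
    dendro = Dendrogram()
    while active.sum() > 1:
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)
        a_idx = np.flatnonzero(active)
        i_loc, j_loc = divmod(flat, sub.shape[1])
        if i_loc > j_loc:  # keep i < j in original index order
            i_loc, j_loc = j_loc, i_loc
        i, j = int(a_idx[i_loc]), int(a_idx[j_loc])
        d_min = work[i, j]
        if d_min > bound:
            break
        dendro.merges.append(
            (
                tuple(ids[m] for m in members[i]),
                tuple(ids[m] for m in members[j]),
                float(d_min),
            )
        )
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * work[i] + nj * work[j]) / (ni + nj)
        work[i], work[:, i] = new_row, new_row
        work[i, i] = np.inf
        work[j], work[:, j] = np.inf, np.inf
        sizes[i] = ni + nj
        members[i] = members[i] + members[j]  # type: ignore[operator]
        members[j] = None
        active[j] = False
    partition = [
        tuple(sorted(ids[m] for m in mem)) for mem in members if mem is not None
    ]
    return partition, dendro


def choose_representative(
    member_ids, metrics: dict[str, QualityMetrics]
) -> tuple[str, float]:
    """Highest quality-score member; score ties break on the smaller name."""
    if not member_ids:
        raise ValueError("empty cluster")
    best: tuple[float, str] | None = None
    for gid in member_ids:
        if gid not in metrics:
            raise ValueError(f"missing quality metrics for {gid!r}")
        score = quality_score(metrics[gid])
        if best is None or (-score, gid) < best:
            best = (-score, gid)
    return best[1], -best[0]


def average_linkage_cluster(
    store: DistanceStore,
    metrics: dict[str, QualityMetrics] | None = None,
    bound: float = SPECIES_BOUND,
) -> tuple[list[SpeciesCluster], Dendrogram]:
    """Cluster the store and pick a representative per cluster.

    Without metrics the representative defaults to the lexicographically
    smallest member (score NaN); pipeline runs always supply metrics.
    """
    partition, dendro = average_linkage_partition(store, bound)
    clusters = []
    for cid, mem in enumerate(partition):
        if metrics is not None:
            rep, score = choose_representative(mem, metrics)
        else:
            rep, score = min(mem), float("nan")
        clusters.append(SpeciesCluster(cid, tuple(mem), rep, score))
    return clusters, dendro


def cluster_summary(clusters: list[SpeciesCluster], store: DistanceStore) -> pd.DataFrame:
    """Per-cluster size, representative and intra-cluster distance stats."""
    rows = []
    for cl in clusters:
        if len(cl) > 1:
            dists = [
                store[a, b]
                for ai, a in enumerate(cl.member_ids)
                for b in cl.member_ids[ai + 1 :]
            ]
            dmin, dmean = float(np.min(dists)), float(np.mean(dists))
        else:
            dmin = dmean = 0.0
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "size": len(cl),
                "representative": cl.representative_id,
                "representative_score": cl.representative_score,
                "min_intra_distance": dmin,
                "mean_intra_distance": dmean,
            }
        )
    return pd.DataFrame(rows)
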