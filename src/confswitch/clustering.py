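"""Greedy neighbour-count conformational clustering (Daura algorithm).

Two snapshots are "neighbours" when their pairwise C-alpha RMSD is at or
below a distance cutoff (1.7 Angstrom by default).  The algorithm
repeatedly extracts the unassigned snapshot with the most unassigned
neighbours, forms a cluster of it plus those neighbours, and repeats until
every snapshot is assigned.  Each cluster's representative is its
lowest-potential-energy member.

The cutoff comparison is inclusive (``<=``) and neighbour-count ties are
broken by the lowest snapshot index, which makes the procedure fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .structures import RMSDMatrix

__all__ = ["ClusterResult", "daura_cluster", "cluster_representative"]


@dataclass
class ClusterResult:
    """Partition of snapshot indices into clusters ordered by decreasing size."""

    threshold: float
    clusters: list[list[int]]
    occupancy: np.ndarray
    representatives: list[int] | None = None

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        all_members = sorted(i for c in self.clusters for i in c)
        if all_members != list(range(len(all_members))):
            raise ValueError("clusters must partition 0..N-1 without overlap")
        if abs(self.occupancy.sum() - 1.0) > 1e-12:
            raise ValueError("occupancies must sum to 1")
        sizes = [len(c) for c in self.clusters]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("clusters must be ordered by decreasing size")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        """Per-snapshot cluster index (0 = largest cluster)."""
        n = sum(len(c) for c in self.clusters)
        lab = np.empty(n, dtype=int)
        for k, c in enumerate(self.clusters):
            lab[list(c)] = k
        return lab


def daura_cluster(m: RMSDMatrix, threshold: float = 1.7) -> ClusterResult:
    """Cluster snapshots by the greedy maximal-neighbour rule.

    Parameters
    ----------
    m
        Symmetric all-vs-all RMSD matrix (Angstrom).
    threshold
        Neighbour cutoff in Angstrom, compared inclusively.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    values = m.values
    n = m.n
    adj = values <= threshold
    np.fill_diagonal(adj, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    while unassigned.any():
        # neighbour counts restricted to unassigned snapshots
        counts = (adj[:, unassigned]).sum(axis=1)
        counts[~unassigned] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(adj[centre] & unassigned)[0].tolist()
        cluster = sorted([centre] + members)
        clusters.append(cluster)
        unassigned[cluster] = False
    # stable sort keeps extraction order among equal-sized clusters
    clusters.sort(key=len, reverse=True)
    occupancy = np.array([len(c) / n for c in clusters])
    return ClusterResult(threshold=threshold, clusters=clusters, occupancy=occupancy)


def cluster_representative(
    cluster: Sequence[int], energy: Mapping[int, float]
) -> int:
    """Return the cluster member with the lowest potential energy.

    Ties are broken by the lowest snapshot index.  ``energy`` maps snapshot
    index to potential energy in kcal/mol and must cover every member.
    """
    members = sorted(cluster)
    if not members:
        raise ValueError("cluster is empty")
    missing = [i for i in members if i not in energy]
    if missing:
        raise KeyError(f"no energy for snapshots {missing}")
    return min(members, key=lambda i: (energy[i], i))


def assign_representatives(
    result: ClusterResult, energy: Mapping[int, float]
) -> ClusterResult:
    """Fill ``result.representatives`` using per-snapshot potential energies."""
    result.representatives = [
        cluster_representative(c, energy) for c in result.clusters
    ]
    return result
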