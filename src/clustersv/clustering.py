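"""Density-based clustering of SV signatures in (start, end, length) space.

Each signature is embedded as the 3-D vector (B, E, L) = (first reference
coordinate, last reference coordinate, length).  Two signatures are
neighbors when the Euclidean distance

    m = sqrt((B_j - B_i)^2 + (E_j - E_i)^2 + (L_j - L_i)^2)

is strictly below epsilon; edges with m >= epsilon are removed.  DBSCAN
labels a point *core* when it has at least ``min_pts`` neighbors (the point
itself not counted) and grows clusters by breadth-first search through core
points.  A graph is built independently for each signature type and each
chromosome; every resulting cluster becomes one candidate SV.

Neighbor search uses a sliding window over signatures sorted by B: since
|B_j - B_i| <= m, pairs with |B_j - B_i| >= epsilon can never be neighbors,
so the windowed graph is identical to the complete-graph construction.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

from clustersv.signatures import Signature, _signature_sort_key


@dataclass
class SignatureCluster:
    """A DBSCAN cluster of same-type signatures on one chromosome."""

    sv_type: str
    chrom: str
    members: list[Signature]
    core_flags: list[bool]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_uids(self) -> set[int]:
        return {s.uid for s in self.members if s.uid is not None}

    @property
    def mean_first(self) -> float:
        return sum(s.first for s in self.members) / len(self.members)


def signature_distance(p: Signature, q: Signature) -> float:
    """Euclidean distance between two signatures' (B, E, L) vectors."""
    return math.sqrt(
        (q.first - p.first) ** 2 + (q.last - p.last) ** 2 + (q.length - p.length) ** 2
    )


def _neighbor_lists(points: list[Signature], epsilon: float) -> list[list[int]]:
    """Within-epsilon neighbor lists (self excluded) via a window on B.

    ``points`` must be sorted by ``first``.
    """
    n = len(points)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        pi = points[i]
        j = i + 1
        while j < n and points[j].first - pi.first < epsilon:
            if signature_distance(pi, points[j]) < epsilon:
                neighbors[i].append(j)
                neighbors[j].append(i)
            j += 1
    return neighbors


def dbscan(
    points: list[Signature], epsilon: float, min_pts: int
) -> tuple[list[SignatureCluster], list[Signature]]:
    """Cluster signatures with DBSCAN; returns (clusters, noise).

    A point is core iff it has >= ``min_pts`` neighbors at distance < epsilon.
    Clusters are the BFS closures of core points over within-epsilon core
    links; non-core points adjacent to a core join its cluster, with ties
    between clusters broken toward the core neighbor earliest in canonical
    (chrom, first, last, length, read_id) order.  Points reachable from no
    core point are noise.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    if not points:
        return [], []

    order = sorted(range(len(points)), key=lambda i: _signature_sort_key(points[i]))
    pts = [points[i] for i in order]
    neighbors = _neighbor_lists(pts, epsilon)
    core = [len(nb) >= min_pts for nb in neighbors]

    labels = [-1] * len(pts)
    n_clusters = 0
    for seed in range(len(pts)):
        if not core[seed] or labels[seed] != -1:
            continue
        cid = n_clusters
        n_clusters += 1
        labels[seed] = cid
        queue = deque([seed])
        while queue:
            i = queue.popleft()
            for j in neighbors[i]:
                if core[j] and labels[j] == -1:
                    labels[j] = cid
                    queue.append(j)

    # Border points: attach to the cluster of the canonically-first core
    # neighbor (pts is already in canonical order, so the smallest index wins).
    for i in range(len(pts)):
        if core[i] or labels[i] != -1:
            continue
        for j in neighbors[i]:
            if core[j]:
                labels[i] = labels[j]
                break

    clusters = []
    for cid in range(n_clusters):
        idx = [i for i in range(len(pts)) if labels[i] == cid]
        clusters.append(
            SignatureCluster(
                sv_type=pts[idx[0]].sv_type,
                chrom=pts[idx[0]].chrom,
                members=[pts[i] for i in idx],
                core_flags=[core[i] for i in idx],
            )
        )
    noise = [pts[i] for i in range(len(pts)) if labels[i] == -1]
    return clusters, noise


def cluster_signatures(
    by_type: dict[str, list[Signature]], epsilon: float = 250.0, min_pts: int = 5
) -> dict[str, list[SignatureCluster]]:
    """Run DBSCAN independently per (sv_type, chromosome).

    Input lists must be sorted by (chrom, first); per type, the returned
    clusters are sorted by mean first coordinate within chromosome order.
    """
    out: dict[str, list[SignatureCluster]] = {}
    for sv_type, sigs in by_type.items():
        clusters: list[SignatureCluster] = []
        start = 0
        for i in range(1, len(sigs) + 1):
            if i == len(sigs) or sigs[i].chrom != sigs[start].chrom:
                chrom_clusters, _ = dbscan(sigs[start:i], epsilon, min_pts)
                chrom_clusters.sort(key=lambda c: c.mean_first)
                clusters.extend(chrom_clusters)
                start = i
        out[sv_type] = clusters
    return out
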