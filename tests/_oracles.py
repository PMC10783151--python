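"""Independent reference implementations used only to check the package.

These deliberately re-derive results by the most direct route available
(full O(n^2) matrices, character-by-character CIGAR walks) and share no
code with the implementation under test.
"""

from __future__ import annotations

import math


def cigar_walk_oracle(pos: int, cigar: str, min_len: int) -> list[tuple]:
    """Deletion/insertion runs of a CIGAR by a direct character walk.

    Returns (sv_type, first, last, length) tuples, reference coordinates
    1-based, deletions half-open, insertions anchored at the preceding base.
    """
    events = []
    ref = pos
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "D":
            if n >= min_len:
                events.append(("DEL", ref, ref + n, n))
            ref += n
        elif ch == "I":
            if n >= min_len:
                events.append(("INS", max(ref - 1, 1), max(ref - 1, 1), n))
        elif ch in "MN=X":
            ref += n
        elif ch in "SHP":
            pass
        else:
            raise ValueError(f"unexpected CIGAR op {ch}")
    return events


def dbscan_oracle(points, epsilon: float, min_pts: int):
    """Density-reachability closure by brute force on the full matrix.

    ``points`` must already be in canonical order.  Returns
    (clusters, noise) where clusters is a list of sorted index lists and
    noise a sorted index list.  Core points: >= min_pts neighbors at
    strictly smaller distance than epsilon, self excluded.  Core points are
    grouped by connected components of the core-core epsilon graph; each
    non-core point joins the cluster of its smallest-index core neighbor.
    """
    n = len(points)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(
                (points[i].first, points[i].last, points[i].length),
                (points[j].first, points[j].last, points[j].length),
            )
            adj[i][j] = adj[j][i] = d < epsilon
    core = [sum(adj[i]) >= min_pts for i in range(n)]

    labels = [-1] * n
    n_clusters = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = n_clusters
        while stack:
            u = stack.pop()
            for v in range(n):
                if adj[u][v] and core[v] and labels[v] == -1:
                    labels[v] = n_clusters
                    stack.append(v)
        n_clusters += 1
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        for j in range(n):
            if adj[i][j] and core[j]:
                labels[i] = labels[j]
                break
    clusters = [sorted(k for k in range(n) if labels[k] == c) for c in range(n_clusters)]
    noise = sorted(k for k in range(n) if labels[k] == -1)
    return clusters, noise
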