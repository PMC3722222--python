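"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (loops,
enumeration, closed forms) and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def bh_reject_by_definition(pvalues, q):
    """Benjamini-Hochberg rejection set by exhaustive definition.

    Finds the largest k with p_(k) <= k*q/m and rejects every hypothesis
    whose p-value is at most p_(k).
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        threshold = p[order[k_star - 1]]
        reject = p <= threshold
    return reject


def modularity_by_definition(graph, partition):
    """Weighted modularity from the per-edge-pair definition:
    Q = (1/2W) * sum_ij (A_ij - s_i * s_j / 2W) [c_i == c_j]."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        A[idx[u], idx[v]] += w
        A[idx[v], idx[u]] += w
    two_w = A.sum()
    if two_w == 0:
        return 0.0
    s = A.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if partition[nodes[i]] == partition[nodes[j]]:
                q += A[i, j] - s[i] * s[j] / two_w
    return q / two_w


def set_partitions(items):
    """All partitions of a list (restricted-growth-string enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_partition_exhaustive(graph):
    """Maximum-modularity partition by enumeration over all partitions."""
    best_q, best_part = -np.inf, None
    for blocks in set_partitions(list(graph.nodes)):
        part = {v: i for i, block in enumerate(blocks) for v in block}
        q = modularity_by_definition(graph, part)
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    return best_q, best_part


def overlap_counts_by_loop(rsn_masks, unit_masks):
    """Shared-voxel matrix via an explicit per-voxel triple loop."""
    out = np.zeros((len(rsn_masks), len(unit_masks)), dtype=int)
    shape = rsn_masks[0].shape
    for i, r in enumerate(rsn_masks):
        for j, u in enumerate(unit_masks):
            c = 0
            for x in range(shape[0]):
                for y in range(shape[1]):
                    for z in range(shape[2]):
                        if r[x, y, z] and u[x, y, z]:
                            c += 1
            out[i, j] = c
    return out


def connected_components_bfs(mask, connectivity=6):
    """Connected-component count by explicit flood fill."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        n += 1
        stack = [start]
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and mask[nx, ny, nz]
                    and not seen[nx, ny, nz]
                ):
                    seen[nx, ny, nz] = True
                    stack.append((nx, ny, nz))
    return n


def endpoint_containment(points, mask, affine):
    """Per-point containment recheck: nearest voxel center via explicit math."""
    inv = np.linalg.inv(affine)
    out = []
    for p in np.atleast_2d(points):
        hom = inv @ np.array([p[0], p[1], p[2], 1.0])
        ijk = tuple(int(np.floor(c + 0.5)) for c in hom[:3])
        inside = all(0 <= ijk[a] < mask.shape[a] for a in range(3))
        out.append(bool(inside and mask[ijk]))
    return np.array(out)
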