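"""Independent cross-checks for the Eikonal engine.

A 26-neighbor Dijkstra shortest path on the voxel graph, built with
scipy.sparse.csgraph, approximates the same minimal-travel-time problem
from a completely different direction than the upwind Fast Marching
scheme, and serves as the reference the solver is validated against.
Edge travel time is edge length times the mean slowness of its endpoints.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .wiring import CostField


def _voxel_graph(cost: CostField):
    """Sparse 26-neighbor graph over speed>0 voxels.

    Returns (graph_times, graph_lengths, node_index_grid) where weights of
    the first are travel times and of the second geometric edge lengths.
    """
    speed = cost.speed
    inside = speed > 0
    n_nodes = int(inside.sum())
    node_id = -np.ones(speed.shape, dtype=np.int64)
    node_id[inside] = np.arange(n_nodes)
    vs = np.asarray(cost.voxel_size, dtype=float)

    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) > (0, 0, 0)  # half of the 26, graph is symmetric
    ]
    rows, cols, times, lengths = [], [], [], []
    inv = np.where(inside, 1.0 / np.where(inside, speed, 1.0), np.inf)
    for off in offsets:
        src = [slice(max(0, -o), speed.shape[i] - max(0, o)) for i, o in enumerate(off)]
        dst = [slice(max(0, o), speed.shape[i] + min(0, o) or None) for i, o in enumerate(off)]
        a = node_id[tuple(src)]
        b = node_id[tuple(dst)]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        elen = float(np.linalg.norm(vs * np.array(off)))
        slow = 0.5 * (inv[tuple(src)][ok] + inv[tuple(dst)][ok])
        rows.append(a[ok].ravel())
        cols.append(b[ok].ravel())
        times.append(elen * slow.ravel())
        lengths.append(np.full(int(ok.sum()), elen))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    tmat = coo_matrix((np.concatenate(times), (rows, cols)), shape=(n_nodes, n_nodes))
    lmat = coo_matrix((np.concatenate(lengths), (rows, cols)), shape=(n_nodes, n_nodes))
    return tmat.tocsr(), lmat.tocsr(), node_id


def _node_of(cost: CostField, point_mm, node_id) -> int:
    vs = np.asarray(cost.voxel_size)
    idx = np.rint((np.asarray(point_mm, dtype=float) - cost.origin) / vs).astype(int)
    nid = int(node_id[tuple(idx)])
    if nid < 0:
        raise ValueError("point lies outside the brain")
    return nid


def dijkstra_times(cost: CostField, seed_mm) -> np.ndarray:
    """Shortest travel time from the seed to every voxel (grid of +inf outside)."""
    tmat, _, node_id = _voxel_graph(cost)
    src = _node_of(cost, seed_mm, node_id)
    dist = _dijkstra(tmat, directed=False, indices=src)
    out = np.full(cost.speed.shape, np.inf)
    out[node_id >= 0] = dist[node_id[node_id >= 0]]
    return out


def dijkstra_path_length(cost: CostField, a_mm, b_mm) -> float:
    """Geometric length (mm) of the minimal-travel-time 26-neighbor path a->b."""
    tmat, lmat, node_id = _voxel_graph(cost)
    src = _node_of(cost, a_mm, node_id)
    dst = _node_of(cost, b_mm, node_id)
    _, pred = _dijkstra(tmat, directed=False, indices=src, return_predecessors=True)
    if pred[dst] < 0 and src != dst:
        return float("inf")
    length = 0.0
    cur = dst
    while cur != src:
        prev = pred[cur]
        length += lmat[min(prev, cur), max(prev, cur)]
        cur = prev
    return float(length)


def dijkstra_pairwise_lengths(cost: CostField, points_mm) -> np.ndarray:
    """Path-length matrix over a list of mm points (oracle for area matrices)."""
    pts = np.asarray(points_mm, dtype=float).reshape(-1, 3)
    tmat, lmat, node_id = _voxel_graph(cost)
    nodes = [_node_of(cost, p, node_id) for p in pts]
    n = len(nodes)
    out = np.zeros((n, n))
    for i in range(n):
        _, pred = _dijkstra(tmat, directed=False, indices=nodes[i],
                            return_predecessors=True)
        for j in range(n):
            if i == j:
                continue
            cur = nodes[j]
            if pred[cur] < 0 and cur != nodes[i]:
                out[i, j] = np.inf
                continue
            length = 0.0
            while cur != nodes[i]:
                prev = pred[cur]
                length += lmat[min(prev, cur), max(prev, cur)]
                cur = prev
            out[i, j] = length
    return 0.5 * (out + out.T)
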