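"""Brute-force oracles shared by the test suite: dense/looped reference
implementations of the graph aggregation layers."""

import numpy as np

from stenoshear.encoding import VesselGraph


def small_graph(n, seed):
    """Random undirected graph on n nodes in the VesselGraph container."""
    r = np.random.default_rng(seed)
    mask = np.triu(r.random((n, n)) < 0.5, k=1)
    edges = np.argwhere(mask).astype(np.int64)
    g = VesselGraph(
        n_axial=1, n_theta=n,
        grid_edges=edges,
        spatial_edges=np.empty((0, 2), dtype=np.int64),
        edge_weights=np.ones(len(edges)),
        node_xyz=np.zeros((n, 3)),
    )
    return g, edges


def dense_gcn_oracle(n, edges, h, w):
    """D^-1/2 (A + I) D^-1/2 H W computed with dense matrices."""
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    a += np.eye(n)
    dinv = np.diag(1.0 / np.sqrt(a.sum(axis=1)))
    return dinv @ a @ dinv @ h @ w


def loop_sage_oracle(n, edges, h, w1, w2):
    """Per-node explicit mean-aggregation loop."""
    neigh = {i: [] for i in range(n)}
    for i, j in edges:
        neigh[i].append(j)
        neigh[j].append(i)
    out = np.zeros((n, w1.shape[1]))
    for i in range(n):
        m = (np.mean([h[j] for j in neigh[i]], axis=0)
             if neigh[i] else np.zeros(h.shape[1]))
        out[i] = h[i] @ w1 + m @ w2
    return out
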