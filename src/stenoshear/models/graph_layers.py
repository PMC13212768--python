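"""Graph message-passing layers.

GCN (spectral, symmetric-normalized aggregation with self-loops):
``H' = sigma(D^-1/2 (A + I) D^-1/2 H W)`` — the linear map is applied after
the aggregation, the standard operator order.

GraphSAGE (mean aggregation, separate self/neighbor transforms):
``h_i' = sigma(W1 h_i + W2 mean_{j in N(i)} h_j)`` with a zero mean term for
isolated nodes.

Both rules aggregate over the plain neighbor sets (degree counts with
self-loops for GCN, an unweighted mean for GraphSAGE); the exponential
edge weights describe the graph geometry and remain available through the
weighted sparse operators.
"""

from __future__ import annotations

import numpy as np

from ..encoding import VesselGraph
from ..errors import ShapeError
from ..nn import Linear, Module, Tensor


def _check_rows(h, graph: VesselGraph):
    n = h.shape[0]
    if n != graph.n_nodes:
        raise ShapeError(
            f"feature rows ({n}) != graph nodes ({graph.n_nodes})"
        )


def gcn_layer(
    h: np.ndarray | Tensor,
    graph: VesselGraph,
    weight: np.ndarray,
    activation: bool = True,
    weighted: bool = False,
) -> np.ndarray:
    """Functional GCN layer on plain arrays (inference/oracle checks)."""
    h = h.data if isinstance(h, Tensor) else np.asarray(h, dtype=float)
    _check_rows(h, graph)
    weight = np.asarray(weight, dtype=float)
    if weight.shape[0] != h.shape[1]:
        raise ShapeError("weight input dim mismatch")
    out = (graph.gcn_operator(weighted) @ h) @ weight
    return np.maximum(out, 0.0) if activation else out


def sage_layer(
    h: np.ndarray | Tensor,
    graph: VesselGraph,
    w_self: np.ndarray,
    w_neigh: np.ndarray,
    activation: bool = True,
    weighted: bool = False,
) -> np.ndarray:
    """Functional GraphSAGE layer on plain arrays."""
    h = h.data if isinstance(h, Tensor) else np.asarray(h, dtype=float)
    _check_rows(h, graph)
    w_self = np.asarray(w_self, dtype=float)
    w_neigh = np.asarray(w_neigh, dtype=float)
    if w_self.shape[0] != h.shape[1] or w_neigh.shape[0] != h.shape[1]:
        raise ShapeError("weight input dim mismatch")
    out = h @ w_self + (graph.mean_operator(weighted) @ h) @ w_neigh
    return np.maximum(out, 0.0) if activation else out


class GCNLayer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin = Linear(in_dim, out_dim, rng)

    def forward(self, h: Tensor, graph: VesselGraph) -> Tensor:
        _check_rows(h.data, graph)
        return self.lin(h.spmm(graph.gcn_operator(weighted=False))).relu()


class SAGELayer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin_self = Linear(in_dim, out_dim, rng)
        self.lin_neigh = Linear(in_dim, out_dim, rng, bias=False)

    def forward(self, h: Tensor, graph: VesselGraph) -> Tensor:
        _check_rows(h.data, graph)
        return (
            self.lin_self(h) + self.lin_neigh(h.spmm(graph.mean_operator(weighted=False)))
        ).relu()
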