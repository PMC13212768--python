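"""Physics-informed graph neural network and its composite loss.

Architecture: an input projection (8 -> hidden), alternating GCN (even
index) and GraphSAGE (odd index) layers with identity residual connections
at matched width, and a linear output head (hidden -> 1 per node).

Loss: ``L = L_MSE + alpha L_gradient + beta L_continuity + gamma L_boundary``
with a curriculum on gamma (linear from 0.01 to 0.1 over 500 epochs): the
network first fits the data distribution, then progressively enforces the
physical constraints.

* ``L_gradient``: mean over edges of the squared difference between predicted
  and target edge-wise finite-difference gradients ``(y_j - y_i)/dist_ij``.
* ``L_continuity``: mean squared residual of the quasi-1D mass-conservation
  surrogate ``dy/ds + y (d ln R/ds + kappa cos(theta))`` along each
  circumferential strip (central differences, interior stations).
* ``L_boundary``: mean squared deviation of the inlet-ring prediction from
  the analytic Poiseuille value, optionally curvature-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..encoding import VesselGraph, WSSNormalizer
from ..errors import ShapeError, StateError, ValidationError
from ..nn import Linear, Module, Tensor
from ..oracle import FlowParams, carreau_viscosity, poiseuille_wss
from .graph_layers import GCNLayer, SAGELayer


@dataclass
class PhysicsLossConfig:
    alpha: float = 0.1
    beta: float = 0.05
    gamma_start: float = 0.01
    gamma_end: float = 0.1
    gamma_schedule_epochs: int = 500
    #: curvature adjustment gain of the inlet boundary value (1 + c*kappa*R)
    boundary_curvature_gain: float = 0.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma_start, self.gamma_end) < 0:
            raise ValidationError("loss weights must be >= 0")


def gamma_schedule(epoch: int, config: PhysicsLossConfig) -> float:
    """Linear ramp of the boundary weight, clamped at the end value."""
    if epoch < 0:
        raise ValidationError("epoch must be >= 0")
    frac = min(epoch / config.gamma_schedule_epochs, 1.0)
    return config.gamma_start + (config.gamma_end - config.gamma_start) * frac


def inlet_reference_wss(
    graph: VesselGraph, flow: FlowParams, config: PhysicsLossConfig
) -> float:
    """Analytic Poiseuille WSS on the inlet ring(s), curvature-adjusted.

    Returns one value per inlet node."""
    idx = _inlet_indices(graph)
    r_mm = np.asarray(graph.node_radius)[idx]
    kappa = np.asarray(graph.node_curvature)[idx]
    u = flow.mean_inlet_velocity
    if flow.newtonian_mu is not None:
        mu = np.full_like(r_mm, flow.newtonian_mu)
    else:
        mu = carreau_viscosity(4.0 * u / (r_mm * 1e-3), flow)
    tau = 4.0 * mu * u / (r_mm * 1e-3)
    return tau * (1.0 + config.boundary_curvature_gain * kappa * r_mm)


def _inlet_indices(graph) -> np.ndarray:
    """Node indices of the first axial ring of every sample in the batch."""
    b = getattr(graph, "batch", 1)
    per = graph.n_axial * graph.n_theta
    return (np.arange(b)[:, None] * per
            + np.arange(graph.n_theta)[None, :]).ravel()


def _continuity_residual(y: Tensor, graph) -> Tensor:
    """Residual of dy/ds + y*(dlnR/ds + kappa cos theta) at interior
    stations, all circumferential strips (batch-aware: differences never
    cross sample boundaries)."""
    b = getattr(graph, "batch", 1)
    n_ax, n_th = graph.n_axial, graph.n_theta
    yg = y.reshape(b, n_ax, n_th)
    s = graph.node_s.reshape(b, n_ax, n_th)[:, :, 0]
    r = graph.node_radius.reshape(b, n_ax, n_th)[:, :, 0]
    ds2 = (s[:, 2:] - s[:, :-2])[:, :, None]             # (b, n_ax-2, 1)
    dyds = (yg[:, 2:] - yg[:, :-2]) / ds2
    dlnr = (np.log(r[:, 2:]) - np.log(r[:, :-2]))[:, :, None] / ds2
    kct = (
        graph.node_curvature * np.cos(graph.node_theta)
    ).reshape(b, n_ax, n_th)[:, 1:-1]
    return dyds + yg[:, 1:-1] * Tensor(dlnr + kct)


def physics_loss(
    pred,
    target,
    graph: VesselGraph,
    config: PhysicsLossConfig,
    epoch: int = 0,
    flow: FlowParams | None = None,
    normalizer: WSSNormalizer | None = None,
):
    """Composite physics-informed loss.

    ``pred``/``target`` may be Tensors (training) or arrays (evaluation), on
    either the grid shape or flattened.  When a ``normalizer`` is given the
    inputs are taken to be on the normalized log scale: the MSE and gradient
    terms act on that scale while the continuity and boundary terms act on
    the back-transformed Pa scale (the physical constraints are statements
    about the physical field).  Returns ``(total, components)`` with
    components a dict of floats (L_mse, L_gradient, L_continuity,
    L_boundary, gamma).
    """
    if epoch < 0:
        raise ValidationError("epoch must be >= 0")
    pred_t = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, float))
    targ = target.data if isinstance(target, Tensor) else np.asarray(target, float)
    if pred_t.data.shape != targ.shape:
        raise ShapeError("pred/target shape mismatch")
    n = graph.n_nodes
    y = pred_t.reshape(n)
    t = targ.reshape(n)

    l_mse = ((y - Tensor(t)) ** 2).mean()

    edges = graph.edges
    dist = np.linalg.norm(
        graph.node_xyz[edges[:, 0]] - graph.node_xyz[edges[:, 1]], axis=1
    )
    inv_d = 1.0 / np.maximum(dist, 1e-12)
    gy = (y[edges[:, 1]] - y[edges[:, 0]]) * Tensor(inv_d)
    gt = (t[edges[:, 1]] - t[edges[:, 0]]) * inv_d
    l_grad = ((gy - Tensor(gt)) ** 2).mean()

    # physical-scale field for the physics terms, nondimensionalized by the
    # characteristic WSS (the training set's geometric mean) so that the
    # residuals are commensurate with the normalized data terms
    if normalizer is not None:
        scale = float(np.exp(normalizer.mean))
        y_pa = (y * normalizer.sd + normalizer.mean).exp()
    else:
        scale = 1.0
        y_pa = y
    l_cont = ((_continuity_residual(y_pa, graph) * (1.0 / scale)) ** 2).mean()

    if flow is not None:
        tau_ref = inlet_reference_wss(graph, flow, config)
        inlet = y_pa[_inlet_indices(graph)]
        l_bound = (((inlet - Tensor(tau_ref)) * (1.0 / scale)) ** 2).mean()
    else:
        l_bound = Tensor(0.0)

    gamma = gamma_schedule(epoch, config)
    total = (
        l_mse
        + config.alpha * l_grad
        + config.beta * l_cont
        + gamma * l_bound
    )
    components = {
        "L_mse": float(l_mse.data),
        "L_gradient": float(l_grad.data),
        "L_continuity": float(l_cont.data),
        "L_boundary": float(l_bound.data),
        "gamma": gamma,
    }
    return total, components


class GraphBatch:
    """Block-diagonal union of same-shape vessel graphs.

    Stacking the per-sample sparse operators lets one forward/backward pass
    process a whole mini-batch, amortizing the sparse and dense products.
    Exposes the subset of the VesselGraph interface the network layers and
    the physics loss consume.
    """

    def __init__(self, graphs: list[VesselGraph]):
        import scipy.sparse as sp

        g0 = graphs[0]
        if any((g.n_axial, g.n_theta) != (g0.n_axial, g0.n_theta)
               for g in graphs):
            raise ShapeError("all graphs in a batch must share the grid shape")
        self.batch = len(graphs)
        self.n_axial = g0.n_axial
        self.n_theta = g0.n_theta
        self.n_nodes = self.batch * g0.n_nodes
        self._gcn = sp.block_diag(
            [g.gcn_operator(weighted=False) for g in graphs], format="csr")
        self._mean = sp.block_diag(
            [g.mean_operator(weighted=False) for g in graphs], format="csr")
        offs = np.arange(self.batch) * g0.n_nodes
        self.edges = np.vstack([g.edges + o for g, o in zip(graphs, offs)])
        self.node_xyz = np.vstack([g.node_xyz for g in graphs])
        for attr in ("node_radius", "node_curvature", "node_s", "node_theta"):
            setattr(self, attr,
                    np.concatenate([getattr(g, attr) for g in graphs]))

    def gcn_operator(self, weighted: bool = False):
        return self._gcn

    def mean_operator(self, weighted: bool = False):
        return self._mean


class PIGNN(Module):
    """Alternating GCN/GraphSAGE network with residual connections.

    Optional feature batch normalization and dropout can be inserted after
    each message-passing layer (before the identity residual addition);
    both default off."""

    def __init__(self, hidden_dim: int = 256, n_layers: int = 4,
                 seed: int = 0, in_dim: int = 8, dropout: float = 0.0,
                 batchnorm: bool = False):
        super().__init__()
        from ..nn.layers import BatchNorm1d, Dropout

        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 1)
        self.proj = Linear(in_dim, hidden_dim, rng)
        self.layers = [
            GCNLayer(hidden_dim, hidden_dim, rng) if i % 2 == 0
            else SAGELayer(hidden_dim, hidden_dim, rng)
            for i in range(n_layers)
        ]
        self.norms = [
            BatchNorm1d(hidden_dim) if batchnorm else None
            for _ in range(n_layers)
        ]
        self.drops = [
            Dropout(dropout, drop_rng) if dropout > 0 else None
            for _ in range(n_layers)
        ]
        self.head = Linear(hidden_dim, 1, rng)

    def forward(self, features: Tensor, graph: VesselGraph) -> Tensor:
        """``features``: (N, 8) node features -> (N,) prediction."""
        h = self.proj(features).relu()
        for layer, norm, drop in zip(self.layers, self.norms, self.drops):
            out = layer(h, graph)
            if norm is not None:
                out = norm(out)
            if drop is not None:
                out = drop(out)
            h = out + h
        return self.head(h).reshape(graph.n_nodes)


def pignn_forward(
    features: np.ndarray, graph: VesselGraph, model: PIGNN
) -> np.ndarray:
    """Deterministic inference: (n_axial, n_theta) prediction grid."""
    if graph.node_features is None and features is None:
        raise StateError("graph has no node features")
    from ..nn import no_grad

    with no_grad():
        out = model(Tensor(features), graph)
    return out.data.reshape(graph.n_axial, graph.n_theta)
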