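"""Graph layers against brute-force oracles, the composite losses, the
autoencoder/PCA compression stage, and the shared training loop."""

import numpy as np
import pytest

from stenoshear.dataset import CaseSample, WSSDataset
from stenoshear.encoding import VesselGraph
from stenoshear.errors import ShapeError, ValidationError
from stenoshear.models import (
    PIGNN,
    PhysicsLossConfig,
    TrainConfig,
    UNet,
    UNetLossConfig,
    fit_wss_autoencoder,
    gamma_schedule,
    gcn_layer,
    pca_baseline,
    physics_loss,
    sage_layer,
    train_surrogate,
    unet_loss,
)
from stenoshear.models.mlp import MLPSurrogate, mlp_forward, reconstruction_nmae
from stenoshear.nn import Tensor, no_grad
from stenoshear.oracle import FlowParams, WSSField, poiseuille_wss


def make_graph(n_nodes, edges, xyz=None, **node_arrays):
    """Arbitrary small graph wrapped in the VesselGraph container."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    xyz = np.zeros((n_nodes, 3)) if xyz is None else xyz
    return VesselGraph(
        n_axial=1, n_theta=n_nodes,
        grid_edges=edges,
        spatial_edges=np.empty((0, 2), dtype=np.int64),
        edge_weights=np.ones(len(edges)),
        node_xyz=xyz,
        **node_arrays,
    )


def lattice_graph(n_ax, n_th, radius, s=None, curvature=None, theta=None):
    """Structured lattice graph with explicit station geometry."""
    from stenoshear.encoding import grid_edge_list

    s = np.linspace(0.0, 10.0, n_ax) if s is None else s
    radius = np.broadcast_to(radius, (n_ax,)).astype(float)
    phi = 2 * np.pi * np.arange(n_th) / n_th
    xyz = np.zeros((n_ax, n_th, 3))
    xyz[..., 0] = radius[:, None] * np.cos(phi)
    xyz[..., 1] = radius[:, None] * np.sin(phi)
    xyz[..., 2] = s[:, None]
    e = grid_edge_list(n_ax, n_th)
    curvature = np.zeros(n_ax) if curvature is None else curvature
    theta = np.zeros((n_ax, n_th)) if theta is None else theta
    return VesselGraph(
        n_axial=n_ax, n_theta=n_th, grid_edges=e,
        spatial_edges=np.empty((0, 2), dtype=np.int64),
        edge_weights=np.ones(len(e)),
        node_xyz=xyz.reshape(-1, 3),
        node_radius=np.repeat(radius, n_th),
        node_curvature=np.repeat(curvature, n_th),
        node_s=np.repeat(s, n_th),
        node_theta=theta.reshape(-1),
    )


class TestGraphLayerOracles:
    def test_gcn_single_node_identity(self):
        g = make_graph(1, np.empty((0, 2)))
        h = np.array([[1.0, -2.0]])
        out = gcn_layer(h, g, np.eye(2), activation=False)
        assert np.allclose(out, h)

    def test_gcn_constant_on_ring_preserved(self):
        # ring of 6 nodes: every node has degree 2 + self-loop -> d_hat = 3
        edges = [(i, (i + 1) % 6) for i in range(6)]
        g = make_graph(6, edges)
        h = np.full((6, 3), 2.5)
        out = gcn_layer(h, g, np.eye(3), activation=False)
        assert np.allclose(out, 2.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gcn_matches_dense_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = 6
        mask = np.triu(r.random((n, n)) < 0.5, k=1)
        edges = np.argwhere(mask)
        g = make_graph(n, edges)
        h = r.standard_normal((n, 4))
        w = r.standard_normal((4, 3))
        # dense oracle: D^-1/2 (A + I) D^-1/2 H W
        a = np.zeros((n, n))
        for i, j in edges:
            a[i, j] = a[j, i] = 1.0
        a += np.eye(n)
        dinv = np.diag(1.0 / np.sqrt(a.sum(1)))
        expected = dinv @ a @ dinv @ h @ w
        got = gcn_layer(h, g, w, activation=False)
        assert np.allclose(got, expected, atol=1e-6)
        assert np.allclose(gcn_layer(h, g, w), np.maximum(expected, 0),
                           atol=1e-6)

    def test_sage_zero_neighbor_weight_reduces_to_linear(self):
        edges = [(0, 1), (1, 2)]
        g = make_graph(3, edges)
        h = np.random.default_rng(0).standard_normal((3, 2))
        w1 = np.random.default_rng(1).standard_normal((2, 2))
        out = sage_layer(h, g, w1, np.zeros((2, 2)), activation=False)
        assert np.allclose(out, h @ w1)

    def test_sage_constant_features_stay_constant(self):
        edges = [(i, (i + 1) % 5) for i in range(5)]
        g = make_graph(5, edges)
        h = np.full((5, 2), 3.0)
        out = sage_layer(h, g, np.eye(2), np.eye(2), activation=False)
        assert np.allclose(out, 6.0)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_sage_matches_per_node_loop(self, seed):
        r = np.random.default_rng(seed)
        n = 6
        mask = np.triu(r.random((n, n)) < 0.5, k=1)
        edges = np.argwhere(mask)
        g = make_graph(n, edges)
        h = r.standard_normal((n, 3))
        w1 = r.standard_normal((3, 2))
        w2 = r.standard_normal((3, 2))
        neigh = {i: [] for i in range(n)}
        for i, j in edges:
            neigh[i].append(j)
            neigh[j].append(i)
        expected = np.zeros((n, 2))
        for i in range(n):
            m = (np.mean([h[j] for j in neigh[i]], axis=0)
                 if neigh[i] else np.zeros(3))
            expected[i] = h[i] @ w1 + m @ w2
        got = sage_layer(h, g, w1, w2, activation=False)
        assert np.allclose(got, expected, atol=1e-6)

    def test_dimension_mismatch_raises(self):
        g = make_graph(3, [(0, 1)])
        with pytest.raises(ShapeError):
            gcn_layer(np.zeros((2, 4)), g, np.eye(4))
        with pytest.raises(ShapeError):
            sage_layer(np.zeros((3, 4)), g, np.eye(3), np.eye(3))


class TestPhysicsLoss:
    def test_perfect_poiseuille_prediction_all_components_zero(self):
        flow = FlowParams(newtonian_mu=0.0035)
        tau = poiseuille_wss(0.2, 1.5, 0.0035)
        g = lattice_graph(10, 8, radius=1.5)
        pred = np.full((10, 8), tau)
        total, comps = physics_loss(pred, pred.copy(), g,
                                    PhysicsLossConfig(), flow=flow)
        for key in ("L_mse", "L_gradient", "L_continuity", "L_boundary"):
            assert comps[key] == pytest.approx(0.0, abs=1e-12)
        assert float(total.data) == pytest.approx(0.0, abs=1e-12)

    def test_continuity_zero_for_inverse_radius_on_taper(self):
        # y(s) = c / R(s) solves dy/ds + y dlnR/ds = 0 exactly
        n_ax = 40
        s = np.linspace(0.0, 40.0, n_ax)
        radius = 1.5 - 0.005 * s
        g = lattice_graph(n_ax, 6, radius=radius, s=s)
        pred = np.broadcast_to((3.0 / radius)[:, None], (n_ax, 6)).copy()
        _, comps = physics_loss(pred, pred.copy(), g, PhysicsLossConfig())
        assert comps["L_continuity"] < 1e-6

    def test_gamma_schedule_values(self):
        cfg = PhysicsLossConfig()
        assert gamma_schedule(0, cfg) == pytest.approx(0.01)
        assert gamma_schedule(250, cfg) == pytest.approx(0.055)
        assert gamma_schedule(500, cfg) == pytest.approx(0.1)
        assert gamma_schedule(900, cfg) == pytest.approx(0.1)
        with pytest.raises(ValidationError):
            gamma_schedule(-1, cfg)

    def test_total_equals_weighted_component_sum(self, rng):
        flow = FlowParams(newtonian_mu=0.0035)
        g = lattice_graph(8, 6, radius=1.5)
        pred = rng.uniform(0.5, 4.0, (8, 6))
        target = rng.uniform(0.5, 4.0, (8, 6))
        cfg = PhysicsLossConfig()
        epoch = 123
        total, c = physics_loss(pred, target, g, cfg, epoch=epoch, flow=flow)
        expected = (c["L_mse"] + cfg.alpha * c["L_gradient"]
                    + cfg.beta * c["L_continuity"]
                    + gamma_schedule(epoch, cfg) * c["L_boundary"])
        assert float(total.data) == pytest.approx(expected, abs=1e-10)

    def test_shape_mismatch(self):
        g = lattice_graph(4, 4, radius=1.5)
        with pytest.raises(ShapeError):
            physics_loss(np.zeros((4, 4)), np.zeros((4, 3)), g,
                         PhysicsLossConfig())


class TestUNetLoss:
    def test_perfect_prediction_zero(self):
        x = np.full((4, 4), 3.0)
        total, comps = unet_loss(x, x.copy())
        assert comps["L_mse"] == 0.0
        assert comps["L_relative"] == 0.0
        # smoothness penalizes prediction gradients: uniform field -> 0
        assert comps["L_smoothness"] == 0.0
        assert float(total.data) == 0.0

    def test_zero_lambdas_reduce_to_mse(self, rng):
        p = rng.standard_normal((5, 8))
        t = rng.standard_normal((5, 8))
        total, _ = unet_loss(p, t, UNetLossConfig(lambda1=0, lambda2=0))
        assert float(total.data) == pytest.approx(np.mean((p - t) ** 2))

    def test_toy_grid_term_by_term(self):
        # independent term-by-term evaluation with explicit loops
        pred = np.array([[1.0, 2.0], [0.5, 3.0], [2.0, 2.0], [1.0, 0.0]])
        targ = np.array([[1.5, 1.0], [0.0, 2.0], [2.5, 2.5], [0.5, 1.0]])
        cfg = UNetLossConfig(lambda1=0.1, lambda2=0.05, eps_rel=1e-3)
        mse = sum((pred[i, j] - targ[i, j]) ** 2
                  for i in range(4) for j in range(2)) / 8
        rel = sum(abs(pred[i, j] - targ[i, j]) / (abs(targ[i, j]) + 1e-3)
                  for i in range(4) for j in range(2)) / 8
        gx = [(pred[i + 1, j] - pred[i, j]) ** 2
              for i in range(3) for j in range(2)]
        gy = [(pred[i, (j + 1) % 2] - pred[i, j]) ** 2
              for i in range(4) for j in range(2)]
        smooth = np.mean(gx) + np.mean(gy)
        expected = mse + 0.1 * rel + 0.05 * smooth
        total, _ = unet_loss(pred, targ, cfg)
        assert float(total.data) == pytest.approx(expected, abs=1e-8)


class TestForwardShapes:
    def test_unet_output_shape_and_determinism(self, rng):
        model = UNet(in_ch=8, base=4, depth=2, seed=0).eval()
        x = Tensor(rng.standard_normal((2, 8, 28, 8)))
        with no_grad():
            a = model(x).data
            b = model(x).data
        assert a.shape == (2, 1, 28, 8)
        assert np.array_equal(a, b)

    def test_unet_rejects_indivisible_grid(self, rng):
        model = UNet(in_ch=8, base=4, depth=3, seed=0)
        with pytest.raises(ShapeError):
            model(Tensor(rng.standard_normal((1, 8, 30, 8))))

    def test_pignn_output_per_node(self, tiny_cohort):
        sample = tiny_cohort.samples[0]
        n_ax, n_th = sample.grid_shape
        model = PIGNN(hidden_dim=16, n_layers=4, seed=0)
        feats = Tensor(sample.tensor.grid.reshape(-1, 8))
        with no_grad():
            out = model(feats, sample.graph)
        assert out.data.shape == (n_ax * n_th,)

    def test_pignn_zero_head_predicts_zero(self, tiny_cohort):
        sample = tiny_cohort.samples[0]
        model = PIGNN(hidden_dim=16, n_layers=2, seed=0)
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        with no_grad():
            out = model(Tensor(sample.tensor.grid.reshape(-1, 8)),
                        sample.graph)
        assert np.all(out.data == 0.0)

    def test_pignn_alternates_layer_kinds(self):
        from stenoshear.models.graph_layers import GCNLayer, SAGELayer

        model = PIGNN(hidden_dim=8, n_layers=4, seed=0)
        kinds = [type(l) for l in model.layers]
        assert kinds == [GCNLayer, SAGELayer, GCNLayer, SAGELayer]


class TestCompression:
    def test_pca_full_rank_recovers_exactly(self, rng):
        x = rng.standard_normal((10, 40))
        nmae = pca_baseline(x, n_components=9)
        assert nmae < 1e-10

    def test_pca_nmae_non_increasing(self, rng):
        # smooth synthetic fields: random low-frequency mixtures
        t = np.linspace(0, 1, 200)
        basis = np.stack([np.sin(2 * np.pi * (k + 1) * t) for k in range(30)])
        x = rng.standard_normal((50, 30)) @ basis + rng.normal(0, 0.05, (50, 200))
        errs = [pca_baseline(x, k) for k in (2, 4, 8, 16, 32)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_autoencoder_capacity_identity(self, rng):
        # bottleneck = data dimensionality can reach near-zero error
        x = rng.standard_normal((50, 12))
        with pytest.warns(UserWarning):
            _, nmae = fit_wss_autoencoder(x, bottleneck_dim=12, epochs=400,
                                          hidden=64, seed=0)
        assert nmae < 0.01

    def test_nmae_definition(self):
        x = np.array([[0.0, 2.0], [4.0, 0.0]])
        xhat = x + 0.5
        assert reconstruction_nmae(x, xhat) == pytest.approx(0.5 / 4.0)


class TestMLPComposition:
    def test_pipeline_equals_stagewise(self, rng):
        model = MLPSurrogate((28, 8), bottleneck=32, seed=1,
                             conv_channels=(4, 8), ae_hidden=32)
        model.fitted = True
        model.eval()
        grid = rng.standard_normal((28, 8, 8))
        out = mlp_forward(grid, model)
        x = Tensor(np.transpose(grid, (2, 0, 1))[None])
        with no_grad():
            z = model.input_ae.encode(x)
            z2 = model.mapper(z)
            manual = model.wss_ae.decode(z2).data.reshape(28, 8)
        assert np.allclose(out, manual, atol=1e-12)


class TestTraining:
    def test_standard_split_sizes(self):
        fields = [WSSField(values=np.random.default_rng(i).uniform(
            0.5, 2.0, (2, 2))) for i in range(1000)]
        ds = WSSDataset(samples=[
            CaseSample(tensor=None, graph=None, wss=f) for f in fields])
        ds.split(fractions=(0.8, 0.1, 0.1), seed=0)
        assert (len(ds.train_idx), len(ds.val_idx), len(ds.test_idx)) == (
            800, 100, 100)
        # disjoint and exhaustive
        allidx = np.concatenate([ds.train_idx, ds.val_idx, ds.test_idx])
        assert len(np.unique(allidx)) == 1000

    def test_same_seed_same_first_epoch_loss(self, tiny_cohort):
        cfg = TrainConfig(seed=5, max_epochs=1, split=(0.6, 0.2, 0.2),
                          model_kwargs=dict(hidden_dim=8, n_layers=2))
        a = train_surrogate(tiny_cohort, "pignn", cfg)
        b = train_surrogate(tiny_cohort, "pignn", cfg)
        assert a.history[0]["train_loss"] == b.history[0]["train_loss"]

    @pytest.mark.parametrize("kind,kwargs", [
        ("mlp", dict(bottleneck=16, conv_channels=(4, 8), ae_hidden=32)),
        ("unet", dict(base=4, depth=2)),
        ("pignn", dict(hidden_dim=16, n_layers=2)),
    ])
    def test_training_reduces_loss(self, tiny_cohort, kind, kwargs):
        cfg = TrainConfig(seed=3, max_epochs=8, split=(0.6, 0.2, 0.2),
                          ae_epochs=15, model_kwargs=kwargs)
        trained = train_surrogate(tiny_cohort, kind, cfg,
                                  flow=FlowParams())
        assert trained.history[-1]["train_loss"] < trained.history[0]["train_loss"]

    def test_invalid_kind_rejected(self, tiny_cohort):
        with pytest.raises(ValidationError):
            train_surrogate(tiny_cohort, "transformer")

    def test_prediction_has_physical_shape_and_sign(self, tiny_cohort):
        cfg = TrainConfig(seed=1, max_epochs=2, split=(0.6, 0.2, 0.2),
                          model_kwargs=dict(hidden_dim=8, n_layers=2))
        trained = train_surrogate(tiny_cohort, "pignn", cfg)
        sample = tiny_cohort.subset("test")[0]
        pred = trained.predict(sample)
        assert pred.shape == sample.grid_shape
        assert np.all(pred >= 0)
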