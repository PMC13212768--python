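"""Shared training loop for the three surrogates.

All kinds use Adam (initial learning rate 1e-3), learning-rate halving on a
validation plateau (factor 0.5, patience 10 epochs), early stopping
(patience 30 epochs, best weights restored), a maximum of 500 epochs and
batch size 4, over a seeded-shuffle 80/10/10 split.  The PI-GNN additionally
follows the gamma curriculum of its physics loss.  The validation metric is
the plain MSE on the normalized scale for every kind, so histories are
comparable across architectures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dataset import CaseSample, WSSDataset
from ..errors import ValidationError
from ..nn import Adam, Tensor, no_grad
from ..oracle import FlowParams
from .mlp import MLPSurrogate, _fit_autoencoder, mlp_forward
from .pignn import PIGNN, PhysicsLossConfig, gamma_schedule, physics_loss, pignn_forward
from .unet import UNet, UNetLossConfig, unet_loss

MODEL_KINDS = ("mlp", "unet", "pignn")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    early_stop_patience: int = 30
    max_epochs: int = 500
    batch_size: int = 4
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    #: stage-1 epochs for the MLP's two autoencoders
    ae_epochs: int = 150
    model_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")


class FeatureScaler:
    """Per-channel z-scoring of the 8 geometric features, statistics frozen
    on the training split."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray):
        self.mean = mean
        self.sd = np.where(sd > 0, sd, 1.0)

    @classmethod
    def fit(cls, grids: list[np.ndarray]) -> "FeatureScaler":
        stacked = np.stack(grids)  # (n, H, W, 8)
        return cls(stacked.mean(axis=(0, 1, 2)), stacked.std(axis=(0, 1, 2)))

    def transform(self, grid: np.ndarray) -> np.ndarray:
        return (grid - self.mean) / self.sd


@dataclass
class TrainedSurrogate:
    kind: str
    model: object
    dataset: WSSDataset
    scaler: FeatureScaler
    history: list[dict]
    physics_config: PhysicsLossConfig | None = None

    def predict_normalized(self, sample: CaseSample) -> np.ndarray:
        x = self.scaler.transform(sample.tensor.grid)
        if self.kind == "pignn":
            feats = x.reshape(-1, 8)
            return pignn_forward(feats, sample.graph, self.model)
        if self.kind == "unet":
            self.model.eval()
            xt = Tensor(np.transpose(x, (2, 0, 1))[None])
            with no_grad():
                out = self.model(xt).data[0, 0]
            return out
        return mlp_forward(x, self.model)

    def predict(self, sample: CaseSample) -> np.ndarray:
        """WSS prediction in Pa on the analysis grid."""
        z = self.predict_normalized(sample)
        return np.clip(self.dataset.normalizer.inverse(z), 0.0, None)


def _val_mse(predict, samples, targets_norm) -> float:
    errs = [
        float(np.mean((predict(s) - t) ** 2))
        for s, t in zip(samples, targets_norm)
    ]
    return float(np.mean(errs))


def train_surrogate(
    dataset: WSSDataset,
    model_kind: str,
    config: TrainConfig | None = None,
    flow: FlowParams | None = None,
    physics_config: PhysicsLossConfig | None = None,
    unet_loss_config: UNetLossConfig | None = None,
    verbose: bool = False,
) -> TrainedSurrogate:
    """Split, fit and early-stop one surrogate; returns the trained model
    with its per-epoch history (epoch, train_loss, val_loss, lr, gamma)."""
    config = config or TrainConfig()
    if model_kind not in MODEL_KINDS:
        raise ValidationError(f"model_kind must be one of {MODEL_KINDS}")
    if len(dataset) < 10:
        raise ValidationError("need at least 10 cases")
    dataset.split(fractions=config.split, seed=config.seed)
    if not len(dataset.train_idx) or not len(dataset.val_idx):
        raise ValidationError("empty train or validation split")

    train = dataset.subset("train")
    val = dataset.subset("val")
    scaler = FeatureScaler.fit([s.tensor.grid for s in train])
    x_train = [scaler.transform(s.tensor.grid) for s in train]
    y_train = dataset.targets_normalized("train")
    y_val = dataset.targets_normalized("val")
    grid_hw = train[0].grid_shape
    rng = np.random.default_rng(config.seed + 1)

    if model_kind == "pignn":
        kw = dict(hidden_dim=256, n_layers=4)
        kw.update(config.model_kwargs)
        model = PIGNN(seed=config.seed, **kw)
        pcfg = physics_config or PhysicsLossConfig()
        feats = [x.reshape(-1, 8) for x in x_train]
        from .pignn import GraphBatch

        def batch_loss(idx, epoch):
            gb = GraphBatch([train[i].graph for i in idx])
            fcat = np.concatenate([feats[i] for i in idx])
            tcat = np.concatenate([y_train[i].reshape(-1) for i in idx])
            pred = model(Tensor(fcat), gb)
            loss, _ = physics_loss(
                pred, tcat, gb, pcfg, epoch=epoch, flow=flow,
                normalizer=dataset.normalizer,
            )
            return loss

    elif model_kind == "unet":
        kw = dict(base=64, depth=3)
        kw.update(config.model_kwargs)
        model = UNet(in_ch=8, seed=config.seed, **kw)
        ucfg = unet_loss_config or UNetLossConfig()
        x_nchw = np.stack([np.transpose(x, (2, 0, 1)) for x in x_train])

        def batch_loss(idx, epoch):
            xb = Tensor(x_nchw[idx])
            pred = model(xb)
            b = len(idx)
            pred2 = pred.reshape(b, *grid_hw)
            loss, _ = unet_loss(pred2, y_train[idx], ucfg)
            return loss

    else:  # mlp
        kw = dict(bottleneck=128)
        kw.update(config.model_kwargs)
        model = MLPSurrogate(grid_hw, seed=config.seed, **kw)
        x_nchw = np.stack([np.transpose(x, (2, 0, 1)) for x in x_train])
        y_flat = y_train.reshape(len(train), -1)
        # stage 1: the two autoencoders
        _fit_autoencoder(model.input_ae, x_nchw, config.ae_epochs,
                         config.lr, max(config.batch_size, 8), config.seed + 3)
        _fit_autoencoder(model.wss_ae, y_flat, config.ae_epochs,
                         config.lr, max(config.batch_size, 8), config.seed + 4)
        model.fitted = True
        with no_grad():
            z_in = model.input_ae.encode(Tensor(x_nchw)).data
            z_out = model.wss_ae.encode(Tensor(y_flat)).data

        def batch_loss(idx, epoch):
            model.mapper.train()
            zhat = model.mapper(Tensor(z_in[idx]))
            return ((zhat - Tensor(z_out[idx])) ** 2).mean()

    # stage-2 / main loop
    if model_kind == "mlp":
        params = model.mapper.parameters()
    else:
        params = model.parameters()
    opt = Adam(params, lr=config.lr)

    trained = TrainedSurrogate(
        kind=model_kind, model=model, dataset=dataset, scaler=scaler,
        history=[], physics_config=physics_config,
    )
    best_val = np.inf
    best_state = None
    plateau_wait = 0
    stop_wait = 0
    n_train = len(train)
    for epoch in range(config.max_epochs):
        if hasattr(model, "train"):
            model.train()
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = batch_loss(idx, epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        model.eval()
        val_loss = _val_mse(trained.predict_normalized, val, y_val)
        gamma = gamma_schedule(
            epoch, physics_config or PhysicsLossConfig()
        ) if model_kind == "pignn" else float("nan")
        trained.history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "lr": opt.lr,
            "gamma": gamma,
        })
        if verbose:
            print(f"[{model_kind}] epoch {epoch}: "
                  f"train {np.mean(epoch_losses):.4f} val {val_loss:.4f}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            plateau_wait = 0
            stop_wait = 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                plateau_wait = 0
            if stop_wait >= config.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return trained
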