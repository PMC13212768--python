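"""Dual-autoencoder MLP surrogate and the PCA compression baseline.

The full grids are too high-dimensional for a plain fully connected network
(179,200 inputs / 22,400 outputs at full scale), so both sides are
compressed: a convolutional autoencoder for the 8-channel geometric input
and an MLP autoencoder for the WSS field, trained with the plain
reconstruction MSE.  A compact mapper (two hidden layers of 100 ReLU units,
dropout 0.2) connects the two latent spaces.

Reconstruction quality is reported as NMAE: mean absolute reconstruction
error normalized by the data range.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..errors import StateError
from ..nn import Adam, Conv2d, ConvTranspose2d, Dropout, Linear, Module, Tensor, no_grad

BOTTLENECK_CANDIDATES = (32, 64, 128, 256, 512)


def reconstruction_nmae(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean absolute error normalized by the data range."""
    rng = float(x.max() - x.min())
    return float(np.mean(np.abs(x - xhat)) / max(rng, 1e-300))


class WSSAutoencoder(Module):
    """Symmetric MLP autoencoder for flattened WSS fields."""

    def __init__(self, dim: int, bottleneck: int, hidden: int = 256,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.enc1 = Linear(dim, hidden, rng)
        self.enc2 = Linear(hidden, bottleneck, rng)
        self.dec1 = Linear(bottleneck, hidden, rng)
        self.dec2 = Linear(hidden, dim, rng)
        self.bottleneck = bottleneck

    def encode(self, x: Tensor) -> Tensor:
        return self.enc2(self.enc1(x).relu())

    def decode(self, z: Tensor) -> Tensor:
        return self.dec2(self.dec1(z).relu())

    def forward(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))


class ConvInputAutoencoder(Module):
    """Strided-convolution encoder (two 2x downsamplings) mirrored by a
    transpose-convolution decoder, for the (8, H, W) input tensor."""

    def __init__(self, grid_hw: tuple[int, int], bottleneck: int = 128,
                 channels: tuple[int, int] = (16, 32), in_ch: int = 8,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        h, w = grid_hw
        if h % 4 or w % 4:
            raise ValueError("grid must be divisible by 4")
        c1, c2 = channels
        self.conv1 = Conv2d(in_ch, c1, 3, rng, stride=2)
        self.conv2 = Conv2d(c1, c2, 3, rng, stride=2)
        self.h4, self.w4, self.c2 = h // 4, w // 4, c2
        flat = c2 * self.h4 * self.w4
        self.to_latent = Linear(flat, bottleneck, rng)
        self.from_latent = Linear(bottleneck, flat, rng)
        self.up1 = ConvTranspose2d(c2, c1, rng)
        self.up2 = ConvTranspose2d(c1, in_ch, rng)
        self.bottleneck = bottleneck

    def encode(self, x: Tensor) -> Tensor:
        b = x.shape[0]
        h = self.conv2(self.conv1(x).relu()).relu()
        return self.to_latent(h.reshape(b, self.c2 * self.h4 * self.w4))

    def decode(self, z: Tensor) -> Tensor:
        b = z.shape[0]
        h = self.from_latent(z).relu().reshape(b, self.c2, self.h4, self.w4)
        return self.up2(self.up1(h).relu())

    def forward(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))


class LatentMapper(Module):
    """Two hidden layers of 100 ReLU units with dropout 0.2."""

    def __init__(self, in_dim: int, out_dim: int, seed: int = 0,
                 hidden: int = 100, dropout: float = 0.2):
        super().__init__()
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 1)
        self.l1 = Linear(in_dim, hidden, rng)
        self.l2 = Linear(hidden, hidden, rng)
        self.l3 = Linear(hidden, out_dim, rng)
        self.d1 = Dropout(dropout, drop_rng)
        self.d2 = Dropout(dropout, drop_rng)

    def forward(self, z: Tensor) -> Tensor:
        h = self.d1(self.l1(z).relu())
        h = self.d2(self.l2(h).relu())
        return self.l3(h)


def _fit_autoencoder(model: Module, data: np.ndarray, epochs: int,
                     lr: float, batch_size: int, seed: int,
                     track_best: bool = False):
    """Minimize the reconstruction MSE (encoder/decoder jointly).

    With ``track_best``, evaluates the full-data reconstruction NMAE
    periodically and returns ``(best_nmae, best_state)``.
    """
    opt = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    best_nmae, best_state = np.inf, None

    def evaluate():
        model.eval()
        with no_grad():
            xhat = model(Tensor(data)).data
        model.train()
        return reconstruction_nmae(data, xhat)

    if track_best:
        best_nmae, best_state = evaluate(), model.state_dict()
    model.train()
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = Tensor(data[idx])
            loss = ((model(x) - x) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        if track_best and (epoch % 5 == 4 or epoch == epochs - 1):
            nmae = evaluate()
            if nmae < best_nmae:
                best_nmae, best_state = nmae, model.state_dict()
    model.eval()
    if track_best:
        return best_nmae, best_state
    return None


def fit_wss_autoencoder(
    fields: np.ndarray,
    bottleneck_dim: int,
    epochs: int = 200,
    lr: float = 1e-3,
    batch_size: int = 16,
    hidden: int = 256,
    seed: int = 0,
) -> tuple[WSSAutoencoder, float]:
    """Train the WSS-field autoencoder and report its reconstruction NMAE.

    ``fields``: (n_cases, ...) array (flattened internally).
    """
    if bottleneck_dim not in BOTTLENECK_CANDIDATES:
        warnings.warn(
            f"bottleneck {bottleneck_dim} outside the candidate set "
            f"{BOTTLENECK_CANDIDATES}", stacklevel=2,
        )
    x = np.asarray(fields, dtype=float).reshape(fields.shape[0], -1)
    model = WSSAutoencoder(x.shape[1], bottleneck_dim, hidden=hidden, seed=seed)
    _fit_autoencoder(model, x, epochs, lr, batch_size, seed + 1)
    with no_grad():
        xhat = model(Tensor(x)).data
    return model, reconstruction_nmae(x, xhat)


def widen_autoencoder(model: WSSAutoencoder, new_bottleneck: int,
                      seed: int = 0) -> WSSAutoencoder:
    """Grow the bottleneck, preserving the learned function exactly.

    The first ``model.bottleneck`` latent dimensions copy the old weights;
    the new encoder columns are freshly initialized while the corresponding
    decoder rows start at zero, so the widened model computes exactly the
    same reconstruction before further training.  Training a widened model
    can therefore only improve on the narrower one — the nested-capacity
    property of the bottleneck sweep holds by construction.
    """
    old_k = model.bottleneck
    if new_bottleneck < old_k:
        raise ValueError("can only widen the bottleneck")
    dim = model.dec2.weight.shape[1]
    hidden = model.enc1.weight.shape[1]
    rng = np.random.default_rng(seed)
    wide = WSSAutoencoder(dim, new_bottleneck, hidden=hidden, seed=seed)
    wide.enc1.weight.data = model.enc1.weight.data.copy()
    wide.enc1.bias.data = model.enc1.bias.data.copy()
    wide.enc2.weight.data[:, :old_k] = model.enc2.weight.data
    wide.enc2.bias.data[:old_k] = model.enc2.bias.data
    wide.dec1.weight.data[:] = 0.0
    wide.dec1.weight.data[:old_k] = model.dec1.weight.data
    wide.dec1.bias.data = model.dec1.bias.data.copy()
    wide.dec2.weight.data = model.dec2.weight.data.copy()
    wide.dec2.bias.data = model.dec2.bias.data.copy()
    return wide


def autoencoder_sweep(
    fields: np.ndarray,
    dims: tuple[int, ...] = BOTTLENECK_CANDIDATES,
    epochs: int = 120,
    lr: float = 1e-3,
    batch_size: int = 16,
    hidden: int = 256,
    seed: int = 0,
) -> dict[int, float]:
    """Reconstruction NMAE across bottleneck dimensions.

    Models are trained in ascending bottleneck order, each warm-started
    from the previous via :func:`widen_autoencoder`; the best-seen
    reconstruction during each fit is kept, so the reported curve reflects
    capacity rather than optimizer noise.
    """
    x = np.asarray(fields, dtype=float).reshape(fields.shape[0], -1)
    out: dict[int, float] = {}
    model = None
    for k in sorted(dims):
        if model is None:
            model = WSSAutoencoder(x.shape[1], k, hidden=hidden, seed=seed)
        else:
            model = widen_autoencoder(model, k, seed=seed + k)
        best_nmae, best_state = _fit_autoencoder(
            model, x, epochs, lr, batch_size, seed + 1 + k, track_best=True)
        model.load_state_dict(best_state)
        out[k] = best_nmae
    return out


def pca_baseline(fields: np.ndarray, n_components: int) -> float:
    """Reconstruction NMAE of an exact linear projection onto the top
    principal components (components capped at the data rank)."""
    from sklearn.decomposition import PCA

    x = np.asarray(fields, dtype=float).reshape(fields.shape[0], -1)
    k = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    z = pca.fit_transform(x)
    xhat = pca.inverse_transform(z)
    return reconstruction_nmae(x, xhat)


class MLPSurrogate(Module):
    """Input conv-AE -> latent MLP mapper -> WSS decoder pipeline."""

    def __init__(self, grid_hw: tuple[int, int], bottleneck: int = 128,
                 seed: int = 0, ae_hidden: int = 256,
                 conv_channels: tuple[int, int] = (16, 32)):
        super().__init__()
        h, w = grid_hw
        self.grid_hw = (h, w)
        self.input_ae = ConvInputAutoencoder(
            (h, w), bottleneck=bottleneck, channels=conv_channels, seed=seed
        )
        self.wss_ae = WSSAutoencoder(h * w, bottleneck, hidden=ae_hidden,
                                     seed=seed + 10)
        self.mapper = LatentMapper(bottleneck, bottleneck, seed=seed + 20)
        self.fitted = False

    def predict_batch(self, x: Tensor) -> Tensor:
        """(B, 8, H, W) scaled input -> (B, H*W) normalized WSS."""
        if not self.fitted:
            raise StateError("autoencoders/mapper not fitted")
        z = self.mapper(self.input_ae.encode(x))
        return self.wss_ae.decode(z)


def mlp_forward(input_grid: np.ndarray, model: MLPSurrogate) -> np.ndarray:
    """(H, W, 8) scaled input -> (H, W) normalized WSS prediction."""
    x = np.transpose(np.asarray(input_grid, float), (2, 0, 1))[None]
    model.eval()
    with no_grad():
        out = model.predict_batch(Tensor(x)).data
    return out.reshape(model.grid_hw)
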