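"""Image embedders behind the Fréchet-distance and PPL metrics.

Three kinds, mirroring the metric suite's contract:

* ``visual`` — a fixed-seed random-feature network standing in for a
  pretrained classifier embedding; deterministic, training-free.
* ``perceptual`` — the same construction with its own seed and width, used
  for perceptual distances along latent interpolation paths.
* ``histological`` — a small convolutional regressor trained to predict the
  Ki67 index from HE patches; its penultimate activations are the feature
  space of the Fréchet Histological Distance.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import F32

__all__ = ["RandomFeatureEmbedder", "ConvRegressor", "HistologicalEmbedder"]


def _to_float_batch(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8/float -> same layout, float32 in [0, 1]."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    x = images.astype(F32)
    if images.dtype == np.uint8 or x.max() > 1.5:
        x = x / 255.0
    return np.ascontiguousarray(x)


def _block_mean(x: np.ndarray, out_hw: int) -> np.ndarray:
    n, h, w, c = x.shape
    f = h // out_hw
    if f >= 1 and h % out_hw == 0:
        return x.reshape(n, out_hw, f, out_hw, f, c).mean(axis=(2, 4))
    from skimage.transform import resize
    return np.stack([
        resize(img, (out_hw, out_hw, c), preserve_range=True, anti_aliasing=True)
        for img in x]).astype(F32)


class RandomFeatureEmbedder:
    """Two-layer random-projection features on block-averaged images.

    Deterministic for a fixed seed; no training.  Distinct colour/texture
    populations map to distinct feature distributions, which is all the
    Fréchet machinery requires of a stand-in embedding.
    """

    def __init__(self, kind: str = "visual", d: int = 32, seed: int = 7,
                 grid: int = 16, hidden: int = 128):
        rng = np.random.default_rng(seed)
        self.kind = kind
        self.d = d
        self.grid = grid
        self.w1 = rng.standard_normal((3 * grid * grid, hidden)).astype(F32)
        self.w1 /= np.sqrt(3 * grid * grid)
        self.b1 = rng.uniform(-0.5, 0.5, hidden).astype(F32)
        self.w2 = rng.standard_normal((hidden, d)).astype(F32) / np.sqrt(hidden)

    def embed(self, images: np.ndarray) -> np.ndarray:
        x = _to_float_batch(images)
        x = _block_mean(x, self.grid).reshape(len(x), -1)
        h = x @ self.w1 + self.b1
        h = np.where(h >= 0, h, 0.2 * h)
        return (h @ self.w2).astype(np.float64)

    __call__ = embed


class ConvRegressor:
    """Small convolutional Ki67-index regressor (HE image -> index in [0, 1])."""

    def __init__(self, rng: np.random.Generator, embed_dim: int = 64,
                 channels: tuple = (8, 16, 24)):
        self.embed_dim = embed_dim
        ch = (3,) + tuple(channels)
        self.convs = [nn.Conv2d(cin, cout, 3, rng, stride=2)
                      for cin, cout in zip(ch[:-1], ch[1:])]
        self.acts = [nn.LeakyReLU() for _ in self.convs]
        self.fc1 = nn.Dense(ch[-1], embed_dim, rng)
        self.act_fc = nn.LeakyReLU()
        self.fc2 = nn.Dense(embed_dim, 1, rng)
        self.out = nn.Sigmoid()

    def params(self):
        ps = []
        for c in self.convs:
            ps += c.params()
        return ps + self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray, want_embedding: bool = False):
        for conv, act in zip(self.convs, self.acts):
            x = act.forward(conv.forward(x))
        self._pool_hw = x.shape[1] * x.shape[2]
        x = x.mean(axis=(1, 2))
        h = self.act_fc.forward(self.fc1.forward(x))
        y = self.out.forward(self.fc2.forward(h))[:, 0]
        return (y, h) if want_embedding else y

    def backward(self, dy: np.ndarray) -> None:
        dh = self.fc2.backward(self.out.backward(dy[:, None]))
        dpool = self.fc1.backward(self.act_fc.backward(dh))
        n, c = dpool.shape
        hw = int(np.sqrt(self._pool_hw))
        dx = np.broadcast_to(dpool[:, None, None, :] / self._pool_hw,
                             (n, hw, hw, c)).astype(F32)
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            dx = conv.backward(act.backward(dx))


class HistologicalEmbedder:
    """Trained Ki67 regressor exposing penultimate-layer features."""

    kind = "histological"

    def __init__(self, net: ConvRegressor):
        self.net = net
        self.d = net.embed_dim

    def embed(self, images: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(images), 128):
            x = _to_float_batch(images[start:start + 128])
            _, h = self.net.forward(x, want_embedding=True)
            out.append(h.astype(np.float64))
        return np.concatenate(out)

    def predict(self, images: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(images), 128):
            x = _to_float_batch(images[start:start + 128])
            out.append(self.net.forward(x).astype(np.float64))
        return np.concatenate(out)

    def weights_blob(self) -> bytes:
        """Concatenated parameter bytes (for determinism checks)."""
        return b"".join(p.data.tobytes() for p in self.net.params())

    __call__ = embed
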