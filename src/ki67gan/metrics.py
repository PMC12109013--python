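"""Generative-model evaluation metrics: FID, FHD and PPL.

All three reduce image sets to an embedding space and compare them there:

* FID / FHD — squared Fréchet distance between Gaussians fitted to embedded
  real and generated sets,
  ``||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^{1/2})``.
  FID uses a generic visual embedder; FHD swaps in a histological embedder
  trained to predict the Ki67 index from HE patches, so its feature space
  is sensitive to proliferation-related staining structure.
* PPL — mean squared perceptual distance per unit step between images
  generated at latent path positions t and t + epsilon; smaller values mean
  a perceptually smoother (less entangled) latent space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import embedders, nn
from .nn import F32

__all__ = [
    "GaussianStats",
    "PPLConfig",
    "fit_gaussian",
    "frechet",
    "fid",
    "fhd",
    "train_histological_embedder",
    "ppl",
    "ppl_for_generator",
    "slerp",
]


@dataclass
class GaussianStats:
    """Mean and covariance of an embedded image set."""

    mu: np.ndarray     # (d,)
    sigma: np.ndarray  # (d, d), symmetric
    n: int

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma shape inconsistent with mu")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")


@dataclass
class PPLConfig:
    epsilon: float = 1e-4
    n_pairs: int = 64
    space: str = "input-latent"      # or "intermediate-latent"
    label_value: float | None = None # fixed condition; None -> sample labels

    def validate(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.space not in ("input-latent", "intermediate-latent"):
            raise ValueError(f"unknown latent space {self.space!r}")


def fit_gaussian(features: np.ndarray) -> GaussianStats:
    """Sample mean and unbiased (n-1) sample covariance of an n x d matrix."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n = features.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to fit Gaussian statistics")
    mu = features.mean(axis=0)
    sigma = np.atleast_2d(np.cov(features, rowvar=False, ddof=1))
    return GaussianStats(mu=mu, sigma=sigma, n=n)


def frechet(a: GaussianStats, b: GaussianStats) -> float:
    """Squared Fréchet distance between two Gaussians (FID convention).

    The cross-term matrix square root (S_a S_b)^{1/2} is computed by Schur
    decomposition, retrying with a small diagonal jitter when the product is
    numerically singular; the result is clipped at zero.
    """
    if a.mu.size != b.mu.size:
        raise ValueError("dimension mismatch between Gaussian statistics")
    diff = a.mu - b.mu
    covmean = _sqrtm_product(a.sigma, b.sigma)
    val = float(diff @ diff + np.trace(a.sigma) + np.trace(b.sigma)
                - 2.0 * np.trace(covmean))
    if not np.isfinite(val):
        raise FloatingPointError("Fréchet distance is non-finite")
    return max(val, 0.0)


def _sqrtm_product(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    covmean = scipy.linalg.sqrtm(sa @ sb)
    if not np.isfinite(covmean).all():
        jitter = 1e-10 * np.eye(sa.shape[0])
        covmean = scipy.linalg.sqrtm((sa + jitter) @ (sb + jitter))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    return covmean


def fid(real_images: np.ndarray, gen_images: np.ndarray, embedder=None) -> float:
    """Fréchet distance between embedded real and generated image sets."""
    if embedder is None:
        embedder = embedders.RandomFeatureEmbedder(kind="visual", seed=7)
    if len(real_images) < 2 or len(gen_images) < 2:
        raise ValueError("both image sets need >= 2 images")
    try:
        fa = embedder.embed(real_images)
        fb = embedder.embed(gen_images)
    except Exception as exc:
        raise RuntimeError(f"embedder failed while computing FID: {exc}") from exc
    return frechet(fit_gaussian(fa), fit_gaussian(fb))


def fhd(real_images: np.ndarray, gen_images: np.ndarray,
        embedder: embedders.HistologicalEmbedder) -> float:
    """FID with the histological (Ki67-regressor) embedding space."""
    if getattr(embedder, "kind", None) != "histological":
        raise ValueError("fhd requires a histological embedder")
    return fid(real_images, gen_images, embedder)


def train_histological_embedder(data, seed: int = 0, epochs: int = 10,
                                batch_size: int = 64, lr: float = 2e-3,
                                embed_dim: int = 64,
                                ) -> embedders.HistologicalEmbedder:
    """Train the Ki67 regressor whose penultimate layer defines FHD features.

    ``data`` is a labelled manifest (DataFrame with he_path and ki67_index /
    true_index, rows with keep=False dropped) or a tuple (images, labels).
    Training is seeded and refuses fewer than 50 rows.
    """
    from . import synthdata

    if isinstance(data, tuple):
        images, labels = data
    else:
        df = data
        if "keep" in df.columns:
            df = df[df["keep"]]
        label_col = "ki67_index" if "ki67_index" in df.columns else "true_index"
        labels = df[label_col].to_numpy(dtype=np.float64)
        images = np.stack([synthdata.load_image(p) for p in df["he_path"]])
    labels = np.asarray(labels, dtype=np.float64)
    if len(labels) < 50:
        raise ValueError(
            f"histological embedder needs >= 50 training rows, got {len(labels)}")

    x_all = embedders._to_float_batch(images)
    rng = np.random.default_rng(seed)
    net = embedders.ConvRegressor(rng, embed_dim=embed_dim)
    opt = nn.Adam(net.params(), lr=lr, beta1=0.5)
    n = len(labels)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x, y = x_all[idx], labels[idx].astype(F32)
            opt.zero_grad()
            pred = net.forward(x)
            net.backward(2.0 * (pred - y) / len(idx))
            opt.step()
    return embedders.HistologicalEmbedder(net)


def slerp(a: np.ndarray, b: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Spherical interpolation between latent batches a and b at fractions t."""
    a_n = a / np.linalg.norm(a, axis=1, keepdims=True)
    b_n = b / np.linalg.norm(b, axis=1, keepdims=True)
    dot = np.clip((a_n * b_n).sum(axis=1, keepdims=True), -1.0, 1.0)
    omega = np.arccos(dot)
    so = np.sin(omega)
    t = np.asarray(t).reshape(-1, 1)
    near = so[:, 0] < 1e-6
    out = (np.sin((1.0 - t) * omega) / so) * a + (np.sin(t * omega) / so) * b
    if near.any():
        out[near] = (1.0 - t[near]) * a[near] + t[near] * b[near]
    return out.astype(F32)


def ppl(checkpoint, config: PPLConfig, rng: np.random.Generator,
        embedder=None, label_sampler=None,
        synth_fn=None, map_fn=None) -> float:
    """Perceptual path length of a conditional generator.

    Draws ``n_pairs`` latent endpoint pairs, interpolates (spherically in
    input-latent space, linearly in intermediate space), renders both path
    points t and t + epsilon, and averages squared perceptual distance over
    epsilon^2.  The condition is held fixed along each path — either
    ``config.label_value`` or one draw per pair from ``label_sampler``.

    ``synth_fn``/``map_fn``/``embedder`` are pluggable for testing against
    closed forms; defaults come from the checkpoint.
    """
    from . import cgan

    config.validate()
    gen = checkpoint.generator if isinstance(checkpoint, cgan.GeneratorCheckpoint) \
        else checkpoint
    if embedder is None:
        embedder = embedders.RandomFeatureEmbedder(kind="perceptual", seed=11)
    if map_fn is None:
        map_fn = lambda z, c: gen.mapping.forward(z, c)
    if synth_fn is None:
        synth_fn = lambda w: cgan.synthesize(gen, w)

    m = config.n_pairs
    z_dim = gen.spec.z_dim if hasattr(gen, "spec") else None
    z1 = rng.standard_normal((m, z_dim)).astype(F32)
    z2 = rng.standard_normal((m, z_dim)).astype(F32)
    t = rng.uniform(0.0, 1.0, size=m)
    if config.label_value is not None:
        c = np.full(m, float(config.label_value))
    elif label_sampler is not None:
        c = np.asarray(label_sampler(m), dtype=np.float64)
    else:
        raise ValueError("provide config.label_value or a label_sampler")

    eps = config.epsilon
    if config.space == "input-latent":
        wa = map_fn(slerp(z1, z2, t), c)
        wb = map_fn(slerp(z1, z2, t + eps), c)
    else:
        w1, w2 = map_fn(z1, c), map_fn(z2, c)
        tt = t.reshape(-1, 1)
        wa = (w1 + tt * (w2 - w1)).astype(F32)
        wb = (w1 + (tt + eps) * (w2 - w1)).astype(F32)

    ea = np.asarray(embedder.embed(synth_fn(wa)), dtype=np.float64)
    eb = np.asarray(embedder.embed(synth_fn(wb)), dtype=np.float64)
    d2 = np.square(ea - eb).sum(axis=1)
    return float(np.mean(d2) / (eps * eps))


# alias used by the training loop's metric logging
ppl_for_generator = ppl


def metric_report(name: str, value: float, n_real: int, n_gen: int,
                  embedder_kind: str, seed: int) -> dict:
    """JSON-serialisable metric report record."""
    return {"metric": name, "value": value, "n_real": n_real, "n_gen": n_gen,
            "embedder": embedder_kind, "seed": seed}
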