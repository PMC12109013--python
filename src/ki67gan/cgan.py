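"""Ki67-conditioned style-based GAN, compact enough to train on one CPU.

The conditioning contract lives in the mapping network: the scalar Ki67
index c is passed through a fully connected embedding producing a vector of
the intermediate-latent dimensionality, normalised the same way as the
input latent z (second-moment normalisation), concatenated with normalised
z, and pushed through two fully connected layers to yield w.  The synthesis
network is a small style-modulated convolutional stack (w injected per
block through a learned affine channel gain); the discriminator sees
(image, c) via projection conditioning.  Training uses the non-saturating
logistic loss with a lazy R1 gradient penalty weighted by gamma, and counts
progress in kimgs (thousands of real images shown to the discriminator).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nn
from .nn import F32

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorSpec",
    "TrainingConfig",
    "MappingNetwork",
    "SynthesisNetwork",
    "Discriminator",
    "Generator",
    "GeneratorCheckpoint",
    "map_latent",
    "synthesize",
    "train",
    "generate_conditional",
    "r1_penalty",
]


@dataclass
class GeneratorSpec:
    """Architecture hyper-parameters shared by mapping and synthesis."""

    z_dim: int = 64
    w_dim: int = 64
    label_dim: int = 1
    n_mapping_layers: int = 2
    img_size: int = 64
    syn_channels: tuple = (32, 24, 16, 8)   # const + one entry per conv block
    syn_upsample_tail: int = 1              # plain 2x upsamples after the stack
    disc_channels: tuple = (12, 20, 28, 40) # fromRGB + one entry per conv block
    disc_pool_first: bool = True            # 2x average pool after fromRGB

    def __post_init__(self):
        n_blocks = len(self.syn_channels) - 1
        if 4 * 2 ** (n_blocks + self.syn_upsample_tail) != self.img_size:
            raise ValueError("syn_channels/upsample tail inconsistent with img_size")
        d_in = self.img_size // (2 if self.disc_pool_first else 1)
        if d_in // 2 ** (len(self.disc_channels) - 1) != 4:
            raise ValueError("disc_channels inconsistent with img_size")


@dataclass
class TrainingConfig:
    gamma: float = 2.0               # R1 regularisation weight
    total_kimgs: float = 50.0        # thousands of images shown
    batch_size: int = 32
    lr: float = 1.5e-3
    metric_interval_kimgs: float = 10.0
    seed: int = 0
    r1_interval: int = 8             # lazy-regularisation cadence (iterations)
    ema_kimg: float = 10.0           # generator weight EMA half-life; 0 disables
    augment: bool = False            # fixed flip/90-degree-rotation augmentation
    spec: GeneratorSpec = field(default_factory=GeneratorSpec)

    def validate(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.total_kimgs < 0:
            raise ValueError("total_kimgs must be >= 0")


class MappingNetwork:
    """z, c -> w with the conditional-label embedding pathway."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        self.embed = nn.Dense(spec.label_dim, spec.w_dim, rng)
        self.norm_z = nn.PixelNorm()
        self.norm_e = nn.PixelNorm()
        self.fc1 = nn.Dense(spec.z_dim + spec.w_dim, spec.w_dim, rng)
        self.act1 = nn.LeakyReLU()
        self.fc2 = nn.Dense(spec.w_dim, spec.w_dim, rng)
        self.act2 = nn.LeakyReLU()

    def params(self):
        return (self.embed.params() + self.fc1.params() + self.fc2.params())

    def forward(self, z: np.ndarray, c: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=F32)
        c = np.asarray(c, dtype=F32).reshape(len(z), self.spec.label_dim)
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError("Ki67 condition c must lie in [0, 1]")
        e = self.embed.forward(c)
        zn = self.norm_z.forward(z)
        en = self.norm_e.forward(e)
        h = np.concatenate([zn, en], axis=1)
        return self.act2.forward(self.fc2.forward(
            self.act1.forward(self.fc1.forward(h))))

    def backward(self, dw: np.ndarray, accumulate: bool = True) -> None:
        dh = self.fc1.backward(
            self.act1.backward(self.fc2.backward(
                self.act2.backward(dw), accumulate)), accumulate)
        den = dh[:, self.spec.z_dim:]
        de = self.norm_e.backward(den)
        self.embed.backward(de, accumulate)


class SynthesisNetwork:
    """Learned-constant start, per-block: upsample, style gain, 3x3 conv."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        ch = spec.syn_channels
        self.const = nn.Param(rng.standard_normal((4, 4, ch[0])))
        self.blocks = []
        for cin, cout in zip(ch[:-1], ch[1:]):
            self.blocks.append({
                "up": nn.Upsample2x(),
                "affine": nn.Dense(spec.w_dim, cin, rng),
                "mod": nn.Modulate(),
                "conv": nn.Conv2d(cin, cout, 3, rng),
                "act": nn.LeakyReLU(),
            })
        self.tail = [nn.Upsample2x() for _ in range(spec.syn_upsample_tail)]
        self.to_rgb = nn.Conv2d(ch[-1], 3, 1, rng, pad=0)
        self.out = nn.Sigmoid()

    def params(self):
        ps = [self.const]
        for b in self.blocks:
            ps += b["affine"].params() + b["conv"].params()
        return ps + self.to_rgb.params()

    def forward(self, w: np.ndarray) -> np.ndarray:
        n = len(w)
        self._n = n
        x = np.broadcast_to(self.const.data, (n,) + self.const.data.shape).copy()
        for b in self.blocks:
            x = b["up"].forward(x)
            s = b["affine"].forward(w)
            x = b["mod"].forward(x, s)
            x = b["act"].forward(b["conv"].forward(x))
        for up in self.tail:
            x = up.forward(x)
        return self.out.forward(self.to_rgb.forward(x))

    def backward(self, dimg: np.ndarray, accumulate: bool = True) -> np.ndarray:
        dw = np.zeros((self._n, self.spec.w_dim), dtype=F32)
        dx = self.to_rgb.backward(self.out.backward(dimg), accumulate)
        for up in reversed(self.tail):
            dx = up.backward(dx)
        for b in reversed(self.blocks):
            dx = b["conv"].backward(b["act"].backward(dx), accumulate)
            dx, ds = b["mod"].backward(dx)
            dw += b["affine"].backward(ds, accumulate)
            dx = b["up"].backward(dx)
        if accumulate:
            self.const.grad += dx.sum(axis=0)
        return dw


class Generator:
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        self.mapping = MappingNetwork(spec, rng)
        self.synthesis = SynthesisNetwork(spec, rng)

    def params(self):
        return self.mapping.params() + self.synthesis.params()

    def forward(self, z: np.ndarray, c: np.ndarray) -> np.ndarray:
        return self.synthesis.forward(self.mapping.forward(z, c))

    def backward(self, dimg: np.ndarray) -> None:
        dw = self.synthesis.backward(dimg)
        self.mapping.backward(dw)


class Discriminator:
    """Strided conv stack with projection conditioning on the Ki67 index."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        ch = spec.disc_channels
        self.from_rgb = nn.Conv2d(3, ch[0], 1, rng, pad=0)
        self.act0 = nn.LeakyReLU()
        self.pool = nn.AvgPool2x() if spec.disc_pool_first else None
        self.blocks = []
        for cin, cout in zip(ch[:-1], ch[1:]):
            self.blocks.append({
                "conv": nn.Conv2d(cin, cout, 3, rng, stride=2),
                "act": nn.LeakyReLU(),
            })
        flat = ch[-1] * 4 * 4
        self.h_dim = 64
        self.fc = nn.Dense(flat, self.h_dim, rng)
        self.act_h = nn.LeakyReLU()
        self.out_lin = nn.Dense(self.h_dim, 1, rng)
        self.c_embed = nn.Dense(spec.label_dim, self.h_dim, rng)
        self.c_norm = nn.PixelNorm()
        self._proj_scale = F32(1.0 / np.sqrt(self.h_dim))

    def params(self):
        ps = self.from_rgb.params()
        for b in self.blocks:
            ps += b["conv"].params()
        return ps + self.fc.params() + self.out_lin.params() + self.c_embed.params()

    def forward(self, x: np.ndarray, c: np.ndarray) -> np.ndarray:
        n = len(x)
        c = np.asarray(c, dtype=F32).reshape(n, self.spec.label_dim)
        x = self.act0.forward(self.from_rgb.forward(np.asarray(x, dtype=F32)))
        if self.pool is not None:
            x = self.pool.forward(x)
        for b in self.blocks:
            x = b["act"].forward(b["conv"].forward(x))
        self._flat_shape = x.shape
        h = self.act_h.forward(self.fc.forward(x.reshape(n, -1)))
        ce = self.c_norm.forward(self.c_embed.forward(c))
        self._h, self._ce = h, ce
        out = self.out_lin.forward(h)[:, 0] + \
            (h * ce).sum(axis=1) * self._proj_scale
        return out

    def backward(self, dout: np.ndarray, accumulate: bool = True) -> np.ndarray:
        dout = np.asarray(dout, dtype=F32)[:, None]
        dh = self.out_lin.backward(dout, accumulate)
        dh = dh + dout * self._ce * self._proj_scale
        dce = dout * self._h * self._proj_scale
        self.c_embed.backward(self.c_norm.backward(dce), accumulate)
        dflat = self.fc.backward(self.act_h.backward(dh), accumulate)
        dx = dflat.reshape(self._flat_shape)
        for b in reversed(self.blocks):
            dx = b["conv"].backward(b["act"].backward(dx), accumulate)
        if self.pool is not None:
            dx = self.pool.backward(dx)
        return self.from_rgb.backward(self.act0.backward(dx), accumulate)


# ---------------------------------------------------------------------------
# checkpoints

@dataclass
class GeneratorCheckpoint:
    generator: Generator
    spec: GeneratorSpec
    kimgs: float
    seed: int

    def save(self, path: str | os.PathLike) -> None:
        meta = json.dumps({"spec": asdict(self.spec), "kimgs": self.kimgs,
                           "seed": self.seed})
        arrays = {f"p{i}": p.data for i, p in enumerate(self.generator.params())}
        np.savez(os.fspath(path), meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "GeneratorCheckpoint":
        with np.load(os.fspath(path)) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec_d = meta["spec"]
            spec_d["syn_channels"] = tuple(spec_d["syn_channels"])
            spec_d["disc_channels"] = tuple(spec_d["disc_channels"])
            spec = GeneratorSpec(**spec_d)
            gen = Generator(spec, np.random.default_rng(0))
            for i, p in enumerate(gen.params()):
                arr = data[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError("checkpoint/architecture shape mismatch")
                p.data = arr.astype(F32)
        return cls(gen, spec, meta["kimgs"], meta["seed"])


# ---------------------------------------------------------------------------
# spec'd operations

def map_latent(mapping: MappingNetwork, z: np.ndarray, c) -> np.ndarray:
    """Map latent z and Ki67 index c to the intermediate latent w."""
    z = np.atleast_2d(np.asarray(z, dtype=F32))
    c_arr = np.full((len(z), 1), np.nan, dtype=F32)
    c_arr[:, 0] = c
    return mapping.forward(z, c_arr)


def synthesize(gen: Generator | SynthesisNetwork, w: np.ndarray) -> np.ndarray:
    """Render w to an 8-bit RGB image batch (N, H, W, 3)."""
    syn = gen.synthesis if isinstance(gen, Generator) else gen
    w = np.atleast_2d(np.asarray(w, dtype=F32))
    if w.shape[1] != syn.spec.w_dim:
        raise ValueError(f"w has dimension {w.shape[1]}, expected {syn.spec.w_dim}")
    img = syn.forward(w)
    if not np.isfinite(img).all():
        raise FloatingPointError("synthesis produced non-finite pixels")
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def r1_penalty(disc: Discriminator, x: np.ndarray, c: np.ndarray,
               gamma: float) -> tuple[float, np.ndarray]:
    """R1 penalty value gamma/2 * E[||grad_x D||^2] and the image gradients.

    With gamma = 0 the term vanishes exactly.
    """
    disc.forward(np.asarray(x, dtype=F32), c)
    g = disc.backward(np.ones(len(x), dtype=F32), accumulate=False)
    sq = np.square(g.astype(np.float64)).sum(axis=(1, 2, 3)).mean()
    return float(0.5 * gamma * sq), g


def _apply_r1_grads(disc: Discriminator, x: np.ndarray, c: np.ndarray,
                    g: np.ndarray, weight: float) -> None:
    """Accumulate d/dtheta of the R1 penalty via a central-difference
    Hessian-vector product: d/d eps grad_theta sum_i D(x_i + eps g_i)."""
    params = disc.params()
    base = nn.collect(params)
    rms = float(np.sqrt(np.mean(np.square(g)))) + 1e-12
    eps = 1e-2 / rms
    for p in params:
        p.zero_grad()
    disc.forward(x + eps * g, c)
    disc.backward(np.ones(len(x), dtype=F32))
    plus = nn.collect(params)
    for p in params:
        p.zero_grad()
    disc.forward(x - eps * g, c)
    disc.backward(np.ones(len(x), dtype=F32))
    minus = nn.collect(params)
    scale = weight / (2.0 * eps)
    for p, b, gp, gm in zip(params, base, plus, minus):
        p.grad = b + scale * (gp - gm)


def _load_training_set(manifest: pd.DataFrame | str) -> tuple[np.ndarray, np.ndarray]:
    from . import synthdata

    if isinstance(manifest, str):
        manifest = synthdata.read_manifest(manifest)
    if "keep" in manifest.columns:
        manifest = manifest[manifest["keep"]]
    if len(manifest) == 0:
        raise ValueError("empty training manifest")
    label_col = "ki67_index" if "ki67_index" in manifest.columns else "true_index"
    labels = manifest[label_col].to_numpy(dtype=np.float64)
    images = np.stack([synthdata.load_image(p) for p in manifest["he_path"]])
    return images, labels


def train(data, config: TrainingConfig,
          checkpoint_dir: str | os.PathLike | None = None,
          ) -> tuple[GeneratorCheckpoint, pd.DataFrame]:
    """Adversarial training on labelled HE patches.

    ``data`` is a manifest (path or DataFrame with he_path and an index
    column) or a tuple ``(images uint8 NxHxWx3, labels)``.  Returns the
    final checkpoint and a metric log with columns (kimgs, fid, ppl),
    sampled every ``metric_interval_kimgs``.  Fully deterministic under a
    fixed seed.
    """
    from . import embedders, metrics

    config.validate()
    if isinstance(data, tuple):
        images, labels = data
    else:
        images, labels = _load_training_set(data)
    labels = np.asarray(labels, dtype=np.float64)
    if len(np.unique(np.round(labels, 6))) < 2:
        raise ValueError("training set must contain at least 2 distinct labels")

    spec = config.spec
    if images.shape[1] != spec.img_size:
        raise ValueError("image size does not match generator spec")
    x_all = np.ascontiguousarray(images.astype(F32) / 255.0)

    rng = np.random.default_rng(config.seed)
    gen = Generator(spec, rng)
    disc = Discriminator(spec, rng)
    opt_g = nn.Adam(gen.params(), lr=config.lr)
    opt_d = nn.Adam(disc.params(), lr=config.lr)

    # Evaluation uses an exponential moving average of the generator
    # weights, which smooths late-training oscillation.
    gen_ema = Generator(spec, np.random.default_rng(config.seed))
    for p_ema, p in zip(gen_ema.params(), gen.params()):
        p_ema.data = p.data.copy()
    ema_beta = 0.5 ** (config.batch_size / (config.ema_kimg * 1000.0)) \
        if config.ema_kimg > 0 else 0.0

    vis_embedder = embedders.RandomFeatureEmbedder(kind="visual", seed=7)
    perc_embedder = embedders.RandomFeatureEmbedder(kind="perceptual", seed=11)

    n = len(x_all)
    bs = config.batch_size
    total_imgs = int(config.total_kimgs * 1000)
    log_rows: list[dict] = []
    shown = 0
    next_log = config.metric_interval_kimgs
    it = 0

    def sample_labels(k: int) -> np.ndarray:
        return labels[rng.integers(0, n, size=k)]

    def augment_batch(x: np.ndarray) -> np.ndarray:
        # fixed-transform stand-in for adaptive discriminator augmentation:
        # a random 90-degree rotation and optional horizontal flip per batch
        k = int(rng.integers(0, 4))
        flip = bool(rng.integers(0, 2))
        if k:
            x = np.ascontiguousarray(np.rot90(x, k, axes=(1, 2)))
        if flip:
            x = np.ascontiguousarray(x[:, :, ::-1, :])
        return x

    def log_metrics() -> None:
        m = min(256, n)
        idx = rng.integers(0, n, size=m)
        z = rng.standard_normal((m, spec.z_dim)).astype(F32)
        c = sample_labels(m)
        fake = synthesize(gen_ema, gen_ema.mapping.forward(z, c))
        fid_val = metrics.fid(images[idx], fake, vis_embedder)
        ppl_val = metrics.ppl_for_generator(
            gen_ema, metrics.PPLConfig(n_pairs=32, epsilon=1e-2), rng,
            embedder=perc_embedder, label_sampler=sample_labels)
        log_rows.append({"kimgs": shown / 1000.0, "fid": fid_val, "ppl": ppl_val})
        logger.info("kimg %.1f  fid %.3f  ppl %.3f", shown / 1000.0, fid_val, ppl_val)

    while shown < total_imgs:
        it += 1
        # --- discriminator step
        ridx = rng.integers(0, n, size=bs)
        x_real, c_real = x_all[ridx], labels[ridx]
        z = rng.standard_normal((bs, spec.z_dim)).astype(F32)
        c_fake = sample_labels(bs)
        x_fake = gen.forward(z, c_fake)
        if config.augment:
            x_real, x_fake = augment_batch(x_real), augment_batch(x_fake)

        opt_d.zero_grad()
        d_real = disc.forward(x_real, c_real)
        disc.backward(-nn.sigmoid(-d_real) / bs)
        d_fake = disc.forward(x_fake, c_fake)
        disc.backward(nn.sigmoid(d_fake) / bs)
        loss_d = float(np.mean(nn.softplus(-d_real)) + np.mean(nn.softplus(d_fake)))
        if not np.isfinite(loss_d):
            raise RuntimeError(f"discriminator loss became non-finite at iter {it}")
        if it % config.r1_interval == 0:
            _, g = r1_penalty(disc, x_real, c_real, config.gamma)
            _apply_r1_grads(disc, x_real, c_real, g,
                            weight=config.gamma * config.r1_interval / bs)
        opt_d.step()

        # --- generator step
        z = rng.standard_normal((bs, spec.z_dim)).astype(F32)
        c = sample_labels(bs)
        x_fake = gen.forward(z, c)
        d_fake = disc.forward(x_fake, c)
        loss_g = float(np.mean(nn.softplus(-d_fake)))
        if not np.isfinite(loss_g):
            raise RuntimeError(f"generator loss became non-finite at iter {it}")
        opt_g.zero_grad()
        dx = disc.backward(-nn.sigmoid(-d_fake) / bs, accumulate=False)
        gen.backward(dx)
        opt_g.step()
        if ema_beta:
            for p_ema, p in zip(gen_ema.params(), gen.params()):
                p_ema.data += (1.0 - ema_beta) * (p.data - p_ema.data)
        else:
            gen_ema = gen

        shown += bs
        if shown / 1000.0 >= next_log and shown < total_imgs:
            log_metrics()
            next_log += config.metric_interval_kimgs
            if checkpoint_dir is not None:
                ck = GeneratorCheckpoint(gen_ema, spec, shown / 1000.0,
                                         config.seed)
                ck.save(os.path.join(os.fspath(checkpoint_dir),
                                     f"ckpt-{shown // 1000:05d}.npz"))

    if total_imgs > 0:
        log_metrics()
    ckpt = GeneratorCheckpoint(gen_ema, spec, shown / 1000.0, config.seed)
    if checkpoint_dir is not None:
        ckpt.save(os.path.join(os.fspath(checkpoint_dir), "ckpt-final.npz"))
    metric_log = pd.DataFrame(log_rows, columns=["kimgs", "fid", "ppl"])
    return ckpt, metric_log


def generate_conditional(checkpoint: GeneratorCheckpoint | Generator,
                         c, n: int, rng: np.random.Generator,
                         label_sampler=None) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n`` images from fresh z draws, conditioned on ``c``.

    ``c`` may be a scalar (shared condition) or ``label_sampler`` may supply
    per-image conditions.  Returns (images uint8 (n, H, W, 3), labels).
    """
    gen = checkpoint.generator if isinstance(checkpoint, GeneratorCheckpoint) \
        else checkpoint
    if n < 1:
        raise ValueError("n must be >= 1")
    if label_sampler is not None:
        labels = np.asarray(label_sampler(n), dtype=np.float64)
    else:
        labels = np.full(n, float(c))
    if np.any(labels < 0) or np.any(labels > 1):
        raise ValueError("Ki67 condition must lie in [0, 1]")
    z = rng.standard_normal((n, gen.spec.z_dim)).astype(F32)
    out = []
    for start in range(0, n, 64):
        zi = z[start:start + 64]
        ci = labels[start:start + 64]
        out.append(synthesize(gen, gen.mapping.forward(zi, ci)))
    return np.concatenate(out), labels
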