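"""Synthetic HE / Ki67 patch-pair generator.

Emulates the statistical structure of an annotated seminoma patch dataset:
adjacent-section HE and Ki67 (IHC) patches that share a nuclei layout, a
heavily imbalanced Ki67-index label distribution, and controllable quality
defects (blur, blank, tear, sparse tissue) for exercising the patch filter.

The Ki67 index of a pair is defined on *all* pixels of the patch: it is the
fraction of the patch area occupied by positively stained (DAB-brown) nuclei
pixels.  The renderer makes that fraction controllable: nuclei are placed
until their total coverage reaches ``NUCLEI_COVERAGE_BASE +
NUCLEI_COVERAGE_SLOPE * p`` of the patch, and a subset of nuclei pixels of
size ``round(p * H * W)`` is recoloured brown in the Ki67 image.  Because
HE nuclei coverage is an affine function of the index, downstream modules
can recover the index from the HE image alone, which closes the loop for
conditioning experiments.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import gaussian as gaussian_filter

logger = logging.getLogger(__name__)

__all__ = [
    "PatchPair",
    "LabelDistributionSpec",
    "sample_ki67_label",
    "render_patch_pair",
    "degrade",
    "write_dataset",
    "make_dataset",
    "read_manifest",
    "load_image",
]

# Affine calibration between the target Ki67 index p and the nuclei coverage
# of the patch.  coverage(p) >= p for every p in [0, 1] (equality at p = 1),
# so the requested brown fraction is geometrically achievable up to the
# packing limit of the nuclei placement.
NUCLEI_COVERAGE_BASE = 0.12
NUCLEI_COVERAGE_SLOPE = 0.88

# Reference palette (8-bit RGB).
HE_BACKGROUND = np.array([242, 200, 215], dtype=np.float64)   # eosin pink
HE_NUCLEUS = np.array([100, 60, 150], dtype=np.float64)       # hematoxylin purple
KI67_BACKGROUND = np.array([246, 246, 244], dtype=np.float64) # unstained
KI67_NEGATIVE = np.array([70, 90, 170], dtype=np.float64)     # hematoxylin blue
KI67_POSITIVE = np.array([140, 90, 40], dtype=np.float64)     # DAB brown

_PIXEL_NOISE_SIGMA = 2.5
_COLOUR_JITTER = 12.0

DEGRADE_MODES = ("blur", "blank", "tear", "sparse")


@dataclass
class PatchPair:
    """Co-located HE and Ki67 patch with ground-truth annotation masks."""

    he_image: np.ndarray      # H x W x 3 uint8
    ki67_image: np.ndarray    # H x W x 3 uint8
    true_index: float         # brown-pixel fraction of the whole patch
    nuclei_mask: np.ndarray   # H x W bool
    positive_mask: np.ndarray # H x W bool, subset of nuclei_mask
    patch_id: str

    def __post_init__(self) -> None:
        if self.he_image.shape != self.ki67_image.shape:
            raise ValueError("HE and Ki67 images must share a shape")


@dataclass
class LabelDistributionSpec:
    """Named Ki67-label distribution.

    ``paper-imbalanced`` mimics the real label imbalance: most labels below
    0.1 and roughly 2% above 0.5.  It is a Beta(1, 12) body with a small
    uniform tail on (0.4, 1).
    """

    name: str = "paper-imbalanced"
    params: Mapping[str, float] = field(default_factory=dict)

    _KNOWN = ("paper-imbalanced", "uniform", "point-mass")

    def validate(self) -> None:
        if self.name not in self._KNOWN:
            raise ValueError(
                f"unknown label distribution {self.name!r}; expected one of {self._KNOWN}"
            )
        if self.name == "point-mass":
            v = self.params.get("value")
            if v is None or not 0.0 <= float(v) <= 1.0:
                raise ValueError("point-mass requires params['value'] in [0, 1]")


# Mixture weight of the uniform(0.4, 1) tail.  With Beta(1, 12) body:
# P(label > 0.5) = w * 5/6 + (1 - w) * 0.5**12  ~  0.020 for w = 0.024.
_TAIL_WEIGHT = 0.024
_TAIL_LOW = 0.4
_BODY_A, _BODY_B = 1.0, 12.0


def sample_ki67_label(spec: LabelDistributionSpec, rng: np.random.Generator) -> float:
    """Draw one Ki67 index in [0, 1] from the named distribution."""
    return float(sample_ki67_labels(spec, 1, rng)[0])


def sample_ki67_labels(
    spec: LabelDistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised draw of ``n`` Ki67 indices."""
    spec.validate()
    if spec.name == "point-mass":
        return np.full(n, float(spec.params["value"]))
    if spec.name == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    # paper-imbalanced
    w = float(spec.params.get("tail_weight", _TAIL_WEIGHT))
    body = rng.beta(_BODY_A, _BODY_B, size=n)
    tail = rng.uniform(_TAIL_LOW, 1.0, size=n)
    take_tail = rng.uniform(0.0, 1.0, size=n) < w
    return np.where(take_tail, tail, body)


def _place_nuclei(
    size: int, target_coverage: float, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random sequential placement of elliptical nuclei.

    Ellipses may overlap already-placed ones by at most a small fraction of
    their own area; the tolerance grows with the target coverage so that
    dense layouts remain reachable beyond the hard-core jamming limit.
    Returns per-nucleus (rows, cols) pixel index arrays of the *new* pixels
    contributed by each nucleus.
    """
    occupied = np.zeros((size, size), dtype=bool)
    nuclei: list[tuple[np.ndarray, np.ndarray]] = []
    target_px = int(round(target_coverage * size * size))
    overlap_tol = min(0.6, max(0.08, 1.5 * (target_coverage - 0.40)))
    r_lo, r_hi = 0.025 * size, 0.055 * size
    max_attempts = 400 + int(60 * target_coverage * size)
    attempts = 0
    covered = 0
    while covered < target_px and attempts < max_attempts:
        attempts += 1
        a = rng.uniform(r_lo, r_hi)
        b = rng.uniform(r_lo, r_hi)
        theta = rng.uniform(0.0, np.pi)
        cy = rng.uniform(1, size - 2)
        cx = rng.uniform(1, size - 2)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(size, size), rotation=theta)
        if rr.size == 0:
            continue
        overlap = occupied[rr, cc]
        if overlap.sum() > overlap_tol * rr.size:
            continue
        new = ~overlap
        rr, cc = rr[new], cc[new]
        if rr.size == 0:
            continue
        occupied[rr, cc] = True
        nuclei.append((rr, cc))
        covered += rr.size
    return nuclei


def _paint(
    size: int,
    background: np.ndarray,
    nuclei: Sequence[tuple[np.ndarray, np.ndarray]],
    colours: Sequence[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = background
    for (rr, cc), col in zip(nuclei, colours):
        jitter = rng.uniform(-_COLOUR_JITTER, _COLOUR_JITTER, size=3)
        img[rr, cc] = col + jitter
    img += rng.normal(0.0, _PIXEL_NOISE_SIGMA, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_patch_pair(
    p: float,
    size: int = 64,
    rng: np.random.Generator | None = None,
    patch_id: str = "patch",
) -> PatchPair:
    """Render one HE/Ki67 pair whose brown-pixel fraction approximates ``p``.

    Raises ``ValueError`` for p outside [0, 1].  When ``p`` exceeds the
    achievable nuclei coverage, the realised index is clamped to the maximum
    coverage and a warning is logged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"Ki67 index must be in [0, 1], got {p}")
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng() if rng is None else rng

    coverage = min(1.0, NUCLEI_COVERAGE_BASE + NUCLEI_COVERAGE_SLOPE * p)
    nuclei = _place_nuclei(size, coverage, rng)

    total_px = size * size
    target_pos = int(round(p * total_px))
    order = rng.permutation(len(nuclei))
    pos_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    acquired = 0
    partial_split: dict[int, int] = {}
    for idx in order:
        if acquired >= target_pos:
            break
        rr, cc = nuclei[idx]
        need = target_pos - acquired
        if rr.size <= need:
            pos_pixels.append((rr, cc))
            acquired += rr.size
            partial_split[idx] = rr.size
        else:
            pos_pixels.append((rr[:need], cc[:need]))
            acquired += need
            partial_split[idx] = need

    if acquired < target_pos:
        logger.warning(
            "requested Ki67 index %.3f exceeds achievable nuclei coverage; "
            "clamped to %.3f", p, acquired / total_px,
        )

    nuclei_mask = np.zeros((size, size), dtype=bool)
    for rr, cc in nuclei:
        nuclei_mask[rr, cc] = True
    positive_mask = np.zeros((size, size), dtype=bool)
    for rr, cc in pos_pixels:
        positive_mask[rr, cc] = True

    he = _paint(size, HE_BACKGROUND, nuclei,
                [HE_NUCLEUS] * len(nuclei), rng)

    # Ki67 image: same layout; positive pixels brown, the rest blue.  A
    # nucleus can be split brown/blue when the exact pixel budget lands
    # inside it.
    ki67 = np.empty((size, size, 3), dtype=np.float64)
    ki67[:] = KI67_BACKGROUND
    for idx, (rr, cc) in enumerate(nuclei):
        k = partial_split.get(idx, 0)
        jn = rng.uniform(-_COLOUR_JITTER, _COLOUR_JITTER, size=3)
        jp = rng.uniform(-_COLOUR_JITTER, _COLOUR_JITTER, size=3)
        if k > 0:
            ki67[rr[:k], cc[:k]] = KI67_POSITIVE + jp
        if k < rr.size:
            ki67[rr[k:], cc[k:]] = KI67_NEGATIVE + jn
    ki67 += rng.normal(0.0, _PIXEL_NOISE_SIGMA, size=ki67.shape)
    ki67 = np.clip(ki67, 0, 255).astype(np.uint8)

    return PatchPair(
        he_image=he,
        ki67_image=ki67,
        true_index=float(positive_mask.sum()) / total_px,
        nuclei_mask=nuclei_mask,
        positive_mask=positive_mask,
        patch_id=patch_id,
    )


def degrade(
    pair: PatchPair,
    mode: str,
    rng: np.random.Generator | None = None,
    *,
    blur_sigma: float = 3.0,
    tear_fraction: float = 0.4,
) -> PatchPair:
    """Return a degraded copy of ``pair`` emulating a low-quality patch.

    Modes: ``blur`` (Gaussian smoothing), ``blank`` (near-uniform white),
    ``tear`` (inserted white band covering ``tear_fraction`` of the patch),
    ``sparse`` (re-render with too few nuclei).
    """
    if mode not in DEGRADE_MODES:
        raise ValueError(f"unknown degrade mode {mode!r}; expected one of {DEGRADE_MODES}")
    rng = np.random.default_rng() if rng is None else rng
    size = pair.he_image.shape[0]

    if mode == "blur":
        def blur(img: np.ndarray) -> np.ndarray:
            out = gaussian_filter(img.astype(np.float64), sigma=blur_sigma,
                                  channel_axis=-1, preserve_range=True)
            return np.clip(out, 0, 255).astype(np.uint8)
        return PatchPair(blur(pair.he_image), blur(pair.ki67_image),
                         pair.true_index, pair.nuclei_mask.copy(),
                         pair.positive_mask.copy(), pair.patch_id + "-blur")

    if mode == "blank":
        noise = rng.integers(-1, 2, size=(size, size, 3))
        img = np.clip(250 + noise, 0, 255).astype(np.uint8)
        empty = np.zeros((size, size), dtype=bool)
        return PatchPair(img, img.copy(), 0.0, empty, empty.copy(),
                         pair.patch_id + "-blank")

    if mode == "tear":
        n_rows = int(np.ceil(tear_fraction * size))
        start = int(rng.integers(0, size - n_rows + 1))
        def tear(img: np.ndarray) -> np.ndarray:
            out = img.copy()
            out[start:start + n_rows] = 253
            return out
        nm = pair.nuclei_mask.copy()
        pm = pair.positive_mask.copy()
        nm[start:start + n_rows] = False
        pm[start:start + n_rows] = False
        return PatchPair(tear(pair.he_image), tear(pair.ki67_image),
                         float(pm.sum()) / pm.size, nm, pm,
                         pair.patch_id + "-tear")

    # sparse: keep only a handful of nuclei worth of coverage
    sparse = render_patch_pair(0.0, size=size, rng=rng,
                               patch_id=pair.patch_id + "-sparse")
    keep = _sparsify(sparse, n_keep=4, rng=rng)
    return keep


def _sparsify(pair: PatchPair, n_keep: int, rng: np.random.Generator) -> PatchPair:
    """Blank out all but ``n_keep`` nuclei (connected components)."""
    from scipy import ndimage

    lab, n = ndimage.label(pair.nuclei_mask)
    keep_ids = rng.permutation(np.arange(1, n + 1))[:n_keep] if n > n_keep else \
        np.arange(1, n + 1)
    drop = ~np.isin(lab, keep_ids) & pair.nuclei_mask
    he = pair.he_image.copy()
    ki67 = pair.ki67_image.copy()
    he[drop] = np.clip(HE_BACKGROUND + rng.normal(0, _PIXEL_NOISE_SIGMA, 3), 0, 255)
    ki67[drop] = np.clip(KI67_BACKGROUND + rng.normal(0, _PIXEL_NOISE_SIGMA, 3), 0, 255)
    nm = pair.nuclei_mask & ~drop
    pm = pair.positive_mask & ~drop
    return PatchPair(he, ki67, float(pm.sum()) / pm.size, nm, pm, pair.patch_id)


def write_dataset(pairs: Sequence[PatchPair], directory: str | os.PathLike) -> str:
    """Write PNGs plus a CSV manifest; returns the manifest path.

    Manifest columns: patch_id, he_path, ki67_path, true_index.  Indices
    round-trip bit-identically through the CSV.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for pair in pairs:
        he_path = os.path.join(directory, f"{pair.patch_id}_he.png")
        ki_path = os.path.join(directory, f"{pair.patch_id}_ki67.png")
        try:
            Image.fromarray(pair.he_image).save(he_path)
            Image.fromarray(pair.ki67_image).save(ki_path)
        except OSError as exc:
            raise OSError(f"failed writing patch images under {he_path}: {exc}") from exc
        rows.append({
            "patch_id": pair.patch_id,
            "he_path": he_path,
            "ki67_path": ki_path,
            "true_index": float(pair.true_index),
        })
    manifest = os.path.join(directory, "manifest.csv")
    df = pd.DataFrame(rows, columns=["patch_id", "he_path", "ki67_path", "true_index"])
    df.to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def load_image(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def make_dataset(
    n: int,
    size: int = 64,
    spec: LabelDistributionSpec | None = None,
    seed: int = 0,
    degrade_fraction: float = 0.0,
    degrade_modes: Sequence[str] = DEGRADE_MODES,
) -> list[PatchPair]:
    """Render ``n`` pairs with labels drawn from ``spec`` (seeded).

    When ``degrade_fraction`` > 0, that share of pairs (the trailing ones)
    is degraded, cycling through ``degrade_modes``.
    """
    spec = spec or LabelDistributionSpec()
    rng = np.random.default_rng(seed)
    labels = sample_ki67_labels(spec, n, rng)
    pairs = []
    n_bad = int(round(degrade_fraction * n))
    for i, p in enumerate(labels):
        pair = render_patch_pair(float(p), size=size, rng=rng, patch_id=f"p{i:05d}")
        if i >= n - n_bad:
            pair = degrade(pair, degrade_modes[i % len(degrade_modes)], rng)
        pairs.append(pair)
    return pairs
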