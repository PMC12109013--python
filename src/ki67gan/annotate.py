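"""Semi-automated Ki67 annotation of HE/Ki67 patch pairs.

Three stages, mirroring the dataset-preparation pipeline the package
emulates:

1. colour-based k-means clustering of the Ki67 (IHC) patch into stain
   classes (DAB-brown positive, hematoxylin-blue negative, background);
2. Ki67-index quantification as the fraction of patch pixels falling in the
   brown (positive) cluster;
3. a quality filter on the HE patch combining blur, edge, blob, tissue and
   blank-region statistics to exclude low-information patches.

The brown rule classifies a cluster centroid as DAB-positive when its HSV
coordinates satisfy hue in [15, 50] degrees, saturation > 0.2 and value in
[0.15, 0.85]; this isolates brown chromogen from hematoxylin blue and from
the unstained background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from . import synthdata

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterMap",
    "FilterDecision",
    "DEFAULT_THRESHOLDS",
    "cluster_stain",
    "compute_ki67_index",
    "estimate_he_index",
    "quality_filter",
    "label_dataset",
]

BROWN_HUE_RANGE = (15.0 / 360.0, 50.0 / 360.0)
BROWN_MIN_SATURATION = 0.2
BROWN_VALUE_RANGE = (0.15, 0.85)

#: Default quality-filter thresholds (8-bit intensity scale).  ``min_``
#: thresholds are lower bounds a good patch must reach, ``max_`` upper
#: bounds it must stay below.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "min_laplacian_variance": 50.0,
    "min_edge_density": 0.02,
    "min_blob_count": 10,
    "min_tissue_fraction": 0.3,
    "min_intensity_std": 4.0,
    "max_white_blob_fraction": 0.2,
}


@dataclass
class ClusterMap:
    """Pixel-level colour clustering of a Ki67 patch."""

    labels: np.ndarray            # H x W int
    centroids: np.ndarray         # k x 3 mean RGB per cluster
    positive_cluster: int | None  # index of the DAB-brown cluster, if any


@dataclass
class FilterDecision:
    keep: bool
    reasons: list[str]
    metrics: dict[str, float] = field(default_factory=dict)


def _is_brown(centroid_rgb: np.ndarray) -> bool:
    hsv = rgb2hsv(centroid_rgb.reshape(1, 1, 3) / 255.0)[0, 0]
    h, s, v = float(hsv[0]), float(hsv[1]), float(hsv[2])
    return (BROWN_HUE_RANGE[0] <= h <= BROWN_HUE_RANGE[1]
            and s > BROWN_MIN_SATURATION
            and BROWN_VALUE_RANGE[0] <= v <= BROWN_VALUE_RANGE[1])


def cluster_stain(ki67_image: np.ndarray, k: int = 3, seed: int = 0) -> ClusterMap:
    """K-means colour clustering of a Ki67 patch; identifies the brown cluster.

    Runs k-means on RGB pixels.  If the image has fewer distinct colours
    than ``k``, falls back to one cluster per distinct colour.  Among
    clusters passing the brown rule, ties are broken by pixel count.
    """
    if ki67_image.ndim != 3 or ki67_image.shape[2] != 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    if k < 2:
        raise ValueError("k must be >= 2")
    h, w = ki67_image.shape[:2]
    pixels = ki67_image.reshape(-1, 3).astype(np.float64)

    distinct = np.unique(pixels, axis=0)
    if distinct.shape[0] < k:
        logger.warning("image has %d distinct colours < k=%d; using exact assignment",
                       distinct.shape[0], k)
        centroids = distinct
        dists = ((pixels[:, None, :] - centroids[None]) ** 2).sum(-1)
        labels = dists.argmin(1)
    else:
        km = KMeans(n_clusters=k, n_init=4, random_state=seed)
        labels = km.fit_predict(pixels)
        centroids = km.cluster_centers_

    counts = np.bincount(labels, minlength=centroids.shape[0])
    brown = [i for i in range(centroids.shape[0]) if _is_brown(centroids[i])]
    positive = max(brown, key=lambda i: counts[i]) if brown else None
    return ClusterMap(labels=labels.reshape(h, w), centroids=centroids,
                      positive_cluster=positive)


def compute_ki67_index(ki67_image: np.ndarray, k: int = 3, seed: int = 0,
                       tissue_only: bool = False) -> float:
    """Ki67 index of a Ki67-stained patch: brown-pixel share of the patch.

    The denominator is all patch pixels by default.  ``tissue_only=True``
    instead divides by the stained (non-background) pixel count, excluding
    the cluster with the brightest centroid.
    """
    cmap = cluster_stain(ki67_image, k=k, seed=seed)
    if cmap.positive_cluster is None:
        return 0.0
    pos = int((cmap.labels == cmap.positive_cluster).sum())
    if not tissue_only:
        return pos / cmap.labels.size
    background = int(np.argmax(cmap.centroids.sum(axis=1)))
    tissue = int((cmap.labels != background).sum())
    return pos / tissue if tissue else 0.0


# Luminance midpoint between the renderer's nucleus purple and eosin pink;
# generated HE patches inherit this palette from training data.
HE_NUCLEUS_LUMINANCE_THRESHOLD = 165.0


def estimate_he_index(he_image: np.ndarray,
                      luminance_threshold: float = HE_NUCLEUS_LUMINANCE_THRESHOLD) -> float:
    """Estimate the Ki67 index of an HE patch from its nuclei coverage.

    The synthetic renderer couples nuclei coverage to the index through an
    affine calibration (coverage = base + slope * index), so the index of an
    HE patch — real or generated — can be recovered by measuring the dark
    (hematoxylin) pixel fraction and inverting that calibration.  This is a
    synthetic-world proxy for a learned HE-side Ki67 regressor.
    """
    if he_image.ndim != 3 or he_image.shape[2] != 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    lum = he_image.astype(np.float64).mean(axis=2)
    coverage = float((lum < luminance_threshold).mean())
    est = (coverage - synthdata.NUCLEI_COVERAGE_BASE) / synthdata.NUCLEI_COVERAGE_SLOPE
    return float(np.clip(est, 0.0, 1.0))


def _filter_metrics(he_image: np.ndarray) -> dict[str, float]:
    gray = he_image.astype(np.float64).mean(axis=2)
    lap = ndimage.laplace(gray)
    lap_var = float(lap.var())

    edges = canny(gray / 255.0, sigma=1.0)
    edge_density = float(edges.mean())

    # dark blobs: nuclei-like connected components after Otsu thresholding
    spread = gray.max() - gray.min()
    if spread < 10:
        blob_count = 0
    else:
        dark = gray < threshold_otsu(gray)
        lab, n = ndimage.label(dark)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            blob_count = int((sizes >= 4).sum())
        else:
            blob_count = 0

    near_white = np.all(he_image.astype(np.int16) > 235, axis=2)
    tissue_fraction = float(1.0 - near_white.mean())
    if near_white.any():
        wlab, wn = ndimage.label(near_white)
        wsizes = np.bincount(wlab.ravel())[1:]
        white_blob_fraction = float(wsizes.max() / near_white.size) if wn else 0.0
    else:
        white_blob_fraction = 0.0

    return {
        "laplacian_variance": lap_var,
        "edge_density": edge_density,
        "blob_count": float(blob_count),
        "tissue_fraction": tissue_fraction,
        "intensity_std": float(gray.std()),
        "white_blob_fraction": white_blob_fraction,
    }


_REASON_RULES = [
    # (reason, metric, threshold key, comparator: True means metric must be >= threshold)
    ("blur", "laplacian_variance", "min_laplacian_variance", True),
    ("low-edge", "edge_density", "min_edge_density", True),
    ("low-blob-count", "blob_count", "min_blob_count", True),
    ("low-tissue", "tissue_fraction", "min_tissue_fraction", True),
    ("blank", "intensity_std", "min_intensity_std", True),
    ("blank", "white_blob_fraction", "max_white_blob_fraction", False),
]


def quality_filter(he_image: np.ndarray,
                   thresholds: Mapping[str, float] | None = None) -> FilterDecision:
    """Decide whether an HE patch carries enough clean tissue information.

    A patch is kept iff every metric passes its threshold.  Raises
    ``KeyError`` when a threshold key is missing from a custom config.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    else:
        missing = set(DEFAULT_THRESHOLDS) - set(thresholds)
        if missing:
            raise KeyError(f"missing filter threshold keys: {sorted(missing)}")
    metrics = _filter_metrics(he_image)
    reasons = []
    for reason, metric, key, is_min in _REASON_RULES:
        value, bound = metrics[metric], float(thresholds[key])
        failed = value < bound if is_min else value > bound
        if failed and reason not in reasons:
            reasons.append(reason)
    return FilterDecision(keep=not reasons, reasons=reasons, metrics=metrics)


def label_dataset(manifest: pd.DataFrame | str,
                  k: int = 3,
                  thresholds: Mapping[str, float] | None = None,
                  seed: int = 0,
                  tissue_only: bool = False) -> pd.DataFrame:
    """Annotate every manifest row with a computed Ki67 index and filter verdict.

    Adds columns ``ki67_index``, ``keep``, ``reasons`` and ``failed``
    (unreadable image), preserving row order.  Logs kept/excluded counts.
    """
    if isinstance(manifest, str):
        manifest = synthdata.read_manifest(manifest)
    out = manifest.copy()
    indices, keeps, reasons_col, failed = [], [], [], []
    for _, row in manifest.iterrows():
        try:
            ki = synthdata.load_image(row["ki67_path"])
            he = synthdata.load_image(row["he_path"])
        except OSError as exc:
            logger.warning("row %s unreadable: %s", row.get("patch_id", "?"), exc)
            indices.append(np.nan); keeps.append(False)
            reasons_col.append("failed"); failed.append(True)
            continue
        indices.append(compute_ki67_index(ki, k=k, seed=seed, tissue_only=tissue_only))
        decision = quality_filter(he, thresholds)
        keeps.append(decision.keep)
        reasons_col.append(";".join(decision.reasons))
        failed.append(False)
    out["ki67_index"] = indices
    out["keep"] = keeps
    out["reasons"] = reasons_col
    out["failed"] = failed
    n_kept = int(out["keep"].sum())
    counts = pd.Series([r for rs in reasons_col if rs for r in rs.split(";")])
    logger.info("label_dataset: kept %d / %d; exclusions per reason: %s",
                n_kept, len(out),
                dict(counts.value_counts()) if len(counts) else {})
    return out


def label_pairs(pairs, k: int = 3, thresholds=None, seed: int = 0) -> pd.DataFrame:
    """In-memory variant of :func:`label_dataset` operating on PatchPair objects."""
    rows = []
    for pair in pairs:
        idx = compute_ki67_index(pair.ki67_image, k=k, seed=seed)
        decision = quality_filter(pair.he_image, thresholds)
        rows.append({
            "patch_id": pair.patch_id,
            "true_index": pair.true_index,
            "ki67_index": idx,
            "keep": decision.keep,
            "reasons": ";".join(decision.reasons),
            "failed": False,
        })
    return pd.DataFrame(rows)
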