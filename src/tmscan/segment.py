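"""Image analysis: breast-area identification, tissue clustering, thresholds.

Three complementary segmentations of a reconstructed permittivity image:

* breast area — 2-means bipartition separating tissue from the air/uncovered
  background, keeping the largest connected component;
* tissue split — 2-means on the permittivity values inside the breast mask,
  separating fat (lower cluster) from glandular tissue and tumors (higher);
* threshold regions — fixed bands R1 (<=8), R2 (8-13], R3 (13-18], R4 (>18)
  applied uniformly to every subject, reported as fractions of breast area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .grid import GridSpec
from .recon import ReconImage

DEFAULT_THRESHOLDS = (8.0, 13.0, 18.0)


@dataclass(frozen=True)
class SegmentationConfig:
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    n_tissue_clusters: int = 2
    seed: int = 0
    max_iter: int = 100
    tol: float = 1e-8

    def __post_init__(self) -> None:
        t1, t2, t3 = self.thresholds
        if not 0 < t1 < t2 < t3:
            raise ValueError("thresholds must satisfy 0 < T1 < T2 < T3")


@dataclass
class SegmentationResult:
    breast_mask: np.ndarray  # bool grid
    tissue_labels: np.ndarray  # -1 outside mask, 0 = low (fat), 1 = high (glandular)
    cluster_means: tuple[float, float]  # (eps_low, eps_high)
    region_fractions: np.ndarray  # fR1..fR4, fractions of breast area
    breast_area_ratio: float
    config: SegmentationConfig = field(default_factory=SegmentationConfig)


def _kmeans_1d(values: np.ndarray, seed: int, max_iter: int, tol: float) -> np.ndarray:
    """Seeded 2-means (Lloyd, k-means++ init) on scalar values; returns the two
    cluster centres sorted ascending."""
    km = KMeans(n_clusters=2, n_init=10, random_state=seed, max_iter=max_iter, tol=tol)
    km.fit(values.reshape(-1, 1))
    return np.sort(km.cluster_centers_.ravel())


def _assign_two_centers(values: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-centre assignment; ties go to the lower-index (lower) centre."""
    d0 = np.abs(values - centers[0])
    d1 = np.abs(values - centers[1])
    return (d1 < d0).astype(int)


def segment_breast_mask(image: ReconImage, seed: int = 0) -> np.ndarray:
    """Identify the breast area by 2-means clustering of the image values.

    Clustering runs on log-permittivity so that the air/tissue boundary is the
    dominant bipartition regardless of breast density; the higher-mean cluster
    is taken as tissue and its largest connected component as the breast.
    """
    values = np.asarray(image.epsilon_map, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("image contains non-finite values")
    if np.ptp(values) == 0:
        raise ValueError("no breast detected: image is constant")
    logv = np.log(np.maximum(values, 1e-12)).ravel()
    centers = _kmeans_1d(logv, seed=seed, max_iter=100, tol=1e-8)
    labels = _assign_two_centers(logv, centers).reshape(values.shape)
    tissue = labels == 1
    if not tissue.any():
        raise ValueError("no breast detected")
    comp, n_comp = ndimage.label(tissue, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        tissue = comp == (1 + int(np.argmax(sizes)))
    return tissue


def kmeans_tissue_split(
    image: ReconImage,
    mask: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[np.ndarray, tuple[float, float]]:
    """Two-cluster fat/glandular split of the permittivity values in the mask.

    Returns (labels, (mean_low, mean_high)); labels are -1 outside the mask,
    0 for the lower-permittivity cluster and 1 for the higher.
    """
    if not mask.any():
        raise ValueError("empty breast mask")
    values = np.asarray(image.epsilon_map)[mask]
    if len(np.unique(values)) < 2:
        raise ValueError("need at least two distinct values to split tissues")
    centers = _kmeans_1d(values, config.seed, config.max_iter, config.tol)
    assign = _assign_two_centers(values, centers)
    labels = np.full(image.epsilon_map.shape, -1, dtype=int)
    labels[mask] = assign
    means = (float(values[assign == 0].mean()), float(values[assign == 1].mean()))
    return labels, means


def threshold_regions(
    image: ReconImage,
    mask: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Fractions of breast area in the four fixed permittivity bands.

    Band edges are closed on the upper side: a pixel exactly at T1 belongs to
    R1, at T2 to R2, at T3 to R3.
    """
    if not mask.any():
        raise ValueError("empty breast mask")
    values = np.asarray(image.epsilon_map)[mask]
    region = np.digitize(values, bins=np.asarray(config.thresholds), right=True)
    return np.bincount(region, minlength=4) / values.size


def breast_area_ratio(mask: np.ndarray, grid: GridSpec | None = None) -> float:
    """Breast pixels as a fraction of the whole imaging area."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum() / mask.size)


def segment_scan(
    image: ReconImage, config: SegmentationConfig = SegmentationConfig()
) -> SegmentationResult:
    """Run the full segmentation battery on one reconstructed image."""
    mask = segment_breast_mask(image, seed=config.seed)
    labels, means = kmeans_tissue_split(image, mask, config)
    fractions = threshold_regions(image, mask, config)
    return SegmentationResult(
        breast_mask=mask,
        tissue_labels=labels,
        cluster_means=means,
        region_fractions=fractions,
        breast_area_ratio=breast_area_ratio(mask),
        config=config,
    )
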