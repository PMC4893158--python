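"""Two-channel image co-localization and cluster geometry.

Pearson correlation with Costes auto-thresholding (the procedure behind
the ImageJ Coloc 2 plug-in): a symmetric line fit B = a*A + c (reduced
major axis) is made over the cell mask, then the channel-A threshold is
moved down the regression line until the pixels below both thresholds
are uncorrelated (Pearson <= 0).  The reported coefficient is computed
over mask pixels above threshold in either channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage import measure

from .clustermap import Cluster
from .io_formats import CellMask, PixelImage

__all__ = [
    "ColocResult",
    "CentroidDistances",
    "pearson_costes",
    "mean_intensity",
    "binarize_image_clusters",
    "centroid_distances",
]


@dataclass
class ColocResult:
    pearson_r: float
    costes_threshold_a: float
    costes_threshold_b: float
    n_pixels_used: int


@dataclass
class CentroidDistances:
    """Nearest-neighbour centroid distances from channel-A to channel-B clusters."""

    distances: np.ndarray  # nm, one per channel-A cluster
    nearest_index: np.ndarray  # index into channel-B cluster list

    @property
    def median(self) -> float:
        return float(np.median(self.distances))


def _masked(img: PixelImage, mask: CellMask) -> np.ndarray:
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if img.pixel_size != mask.pixel_size:
        raise ValueError("image and mask pixel sizes differ")
    return img.values[mask.mask].astype(float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson undefined: constant channel over the selected pixels")
    return float(np.corrcoef(a, b)[0, 1])


def pearson_costes(
    imgA: PixelImage,
    imgB: PixelImage,
    mask: CellMask,
    use_costes: bool = True,
    n_iter: int = 60,
) -> ColocResult:
    """Pearson coefficient with Costes auto-thresholds over the cell mask.

    With ``use_costes=False`` the coefficient is computed over all mask
    pixels and the thresholds are reported at the channel minima.
    """
    a = _masked(imgA, mask)
    b = _masked(imgB, mask)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson undefined: a channel is constant within the mask")

    if not use_costes:
        return ColocResult(
            pearson_r=_pearson(a, b),
            costes_threshold_a=float(a.min()),
            costes_threshold_b=float(b.min()),
            n_pixels_used=len(a),
        )

    # reduced-major-axis (geometric mean) regression of B on A: the
    # symmetric line fit used for auto-thresholding; equivariant under
    # affine rescaling of either channel, so the threshold search (and the
    # final coefficient) is invariant to gain/offset changes
    sab = np.cov(a, b)[0, 1]
    slope = np.sign(sab if sab != 0 else 1.0) * b.std() / a.std()
    intercept = b.mean() - slope * a.mean()

    def r_below(t_a: float) -> float:
        t_b = slope * t_a + intercept
        sel = (a < t_a) & (b < t_b)
        if sel.sum() < 2:
            return 0.0
        sa, sb = a[sel], b[sel]
        if sa.std() == 0 or sb.std() == 0:
            return 0.0
        return float(np.corrcoef(sa, sb)[0, 1])

    lo, hi = float(a.min()), float(a.max())
    if r_below(hi) <= 0:
        # channels uncorrelated (or anti-correlated) overall: thresholds
        # fall to the channel minima and every mask pixel is used
        t_a = lo
    else:
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            if r_below(mid) > 0:
                hi = mid
            else:
                lo = mid
        t_a = 0.5 * (lo + hi)
    t_b = float(np.clip(slope * t_a + intercept, b.min(), b.max()))

    above = (a > t_a) | (b > t_b)
    if above.sum() < 2 or a[above].std() == 0 or b[above].std() == 0:
        above = np.ones_like(a, dtype=bool)
    return ColocResult(
        pearson_r=_pearson(a[above], b[above]),
        costes_threshold_a=float(t_a),
        costes_threshold_b=t_b,
        n_pixels_used=int(above.sum()),
    )


def mean_intensity(img: PixelImage, mask: CellMask) -> float:
    """Arithmetic mean intensity per pixel over the cell mask."""
    vals = _masked(img, mask)
    if len(vals) == 0:
        raise ValueError("mask has no foreground pixels")
    return float(vals.mean())


def binarize_image_clusters(
    img: PixelImage,
    mask: CellMask,
    method: str = "otsu",
    threshold: float | None = None,
    min_area: float = 0.0,
    weighted_centroid: bool = True,
) -> list:
    """Binarize an image within the mask and label 8-connected clusters.

    ``method`` is ``"otsu"`` (threshold computed on mask pixels) or
    ``"absolute"`` (requires ``threshold``).  Areas are pixels x
    pixel_size^2 (nm^2); centroids are intensity-weighted unless
    ``weighted_centroid=False``.  An empty foreground yields ``[]``.
    """
    vals = _masked(img, mask)
    if method == "otsu":
        if vals.min() == vals.max():
            return []
        thr = float(threshold_otsu(vals))
    elif method == "absolute":
        if threshold is None:
            raise ValueError("absolute method requires threshold=")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")

    binary = (img.values > thr) & mask.mask
    labels = measure.label(binary, connectivity=2)
    ps = img.pixel_size
    clusters = []
    for region in measure.regionprops(labels, intensity_image=img.values):
        area = region.area * ps**2
        if area < min_area:
            continue
        if weighted_centroid:
            cy, cx = region.centroid_weighted
        else:
            cy, cx = region.centroid
        clusters.append(
            Cluster(
                id=len(clusters),
                pixels=np.array(region.coords),
                pixel_size=ps,
                area=float(area),
                centroid=((cx + 0.5) * ps, (cy + 0.5) * ps),
                total_intensity=float(region.image_intensity.sum()),
            )
        )
    return clusters


def centroid_distances(clustersA: list, clustersB: list) -> CentroidDistances:
    """Distance from each channel-A centroid to its nearest channel-B centroid."""
    if not clustersA:
        raise ValueError("no channel-A clusters: centroid distances undefined")
    if not clustersB:
        raise ValueError("no channel-B (partner) clusters: cannot measure distances")
    ca = np.array([c.centroid for c in clustersA], dtype=float)
    cb = np.array([c.centroid for c in clustersB], dtype=float)
    d, idx = cKDTree(cb).query(ca)
    return CentroidDistances(distances=np.atleast_1d(d), nearest_index=np.atleast_1d(idx))
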