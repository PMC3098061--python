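"""Automated histogram thresholding primitives shared by several detectors.

Histograms are built on ``[min, max]`` of the data with ``nbins``
equal-width bins; criterion ties break toward the lowest threshold (the
more conservative foreground).  All three routines are deterministic.
"""

from __future__ import annotations

import numpy as np

from .core_image import BinaryMask, GrayImage

__all__ = [
    "DegenerateHistogramError",
    "otsu_threshold",
    "kapur_entropy_threshold",
    "kmeans2_binarize",
]


class DegenerateHistogramError(ValueError):
    """Raised for constant images; callers decide the fallback."""


def _as_values(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels.ravel()
    return np.asarray(img, dtype=np.float64).ravel()


def _histogram(values: np.ndarray, nbins: int):
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateHistogramError("degenerate histogram: constant image")
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    return counts.astype(np.float64), edges


def otsu_threshold(img, nbins: int = 256) -> float:
    """Threshold maximizing the between-class variance.

    Returns the bin edge splitting the histogram; foreground is
    ``value > threshold``.
    """
    values = _as_values(img)
    counts, edges = _histogram(values, nbins)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(p)[:-1]              # background weight for cut after bin k
    w1 = 1.0 - w0
    cum_mu = np.cumsum(p * centers)[:-1]
    mu_total = float(np.sum(p * centers))

    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mu / w0
        mu1 = (mu_total - cum_mu) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    k = int(np.argmax(between))         # argmax takes the first (lowest) tie
    return float(edges[k + 1])


def kapur_entropy_threshold(img, nbins: int = 256) -> float:
    """Threshold maximizing the Kapur sum of partition entropies.

    Empty bins contribute zero entropy; ties resolve to the lowest
    maximizing bin edge.
    """
    values = _as_values(img)
    counts, edges = _histogram(values, nbins)
    p = counts / counts.sum()

    def entropy(prob, total):
        if total <= 0:
            return -np.inf
        q = prob[prob > 0] / total
        return float(-np.sum(q * np.log(q)))

    best_k, best_crit = None, -np.inf
    for k in range(nbins - 1):
        w0 = p[: k + 1].sum()
        w1 = 1.0 - w0
        crit = entropy(p[: k + 1], w0) + entropy(p[k + 1 :], w1)
        if crit > best_crit:
            best_crit, best_k = crit, k
    return float(edges[best_k + 1])


def kmeans2_binarize(img, max_iter: int = 300) -> BinaryMask:
    """Two-cluster 1-D k-means on intensities; brighter cluster becomes 1.

    Initialization is deterministic (centers at the intensity min and max,
    the farthest-apart pair) so downstream detectors are reproducible.
    A constant image yields an all-zero mask (no structures).
    """
    if isinstance(img, GrayImage):
        arr = img.pixels
    else:
        arr = np.asarray(img, dtype=np.float64)
    values = arr.ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return BinaryMask(np.zeros(arr.shape, dtype=bool))

    c0, c1 = lo, hi
    for _ in range(max_iter):
        boundary = 0.5 * (c0 + c1)
        high = values > boundary
        if not high.any() or high.all():
            break
        n0, n1 = float(np.mean(values[~high])), float(np.mean(values[high]))
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    boundary = 0.5 * (c0 + c1)
    return BinaryMask(arr > boundary)
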