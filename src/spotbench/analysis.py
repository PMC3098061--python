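"""Experiment drivers: object counting, dose–response summaries and
cross-method similarity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster import hierarchy

from .core_image import DetectionResult, GrayImage
from .thresholding import DegenerateHistogramError, otsu_threshold

__all__ = ["count_objects", "spots_per_cell", "count_cells",
           "method_similarity", "SimilarityResult"]

#: Default minimum nucleus size (pixels) for cell counting.
MIN_NUCLEUS_SIZE = 50


def count_objects(det: DetectionResult) -> int:
    """Object count: point count for point results, 8-connected component
    count for masks (deblended labels take precedence when present)."""
    if det.points is not None and det.mask is None:
        return det.points.count
    if det.labels is not None:
        return int(det.labels.max())
    _, n = ndimage.label(det.mask.pixels, structure=np.ones((3, 3), bool))
    return int(n)


def count_cells(nuclei_img: GrayImage,
                min_size: int = MIN_NUCLEUS_SIZE) -> int:
    """Cells = 8-connected components of the Otsu-binarized nuclei channel
    after a minimum-size filter."""
    try:
        th = otsu_threshold(nuclei_img)
    except DegenerateHistogramError:
        return 0
    labeled, n = ndimage.label(
        nuclei_img.pixels > th, structure=np.ones((3, 3), bool)
    )
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(
        np.ones(nuclei_img.shape), labeled, np.arange(1, n + 1)
    )
    return int(np.sum(sizes >= min_size))


def spots_per_cell(spot_count: int, nuclei_img: GrayImage,
                   min_size: int = MIN_NUCLEUS_SIZE) -> Optional[float]:
    """Spots divided by the nuclei-channel cell count.

    Zero cells yields ``None`` (a flagged missing value), never infinity.
    """
    cells = count_cells(nuclei_img, min_size=min_size)
    if cells == 0:
        return None
    return float(spot_count) / cells


@dataclass
class SimilarityResult:
    correlation: pd.DataFrame      # Pearson (or Spearman) matrix
    linkage: np.ndarray            # scipy linkage matrix, average linkage
    methods: list
    undefined: list                # methods with constant count vectors
    kind: str = "pearson"


def method_similarity(counts: dict, kind: str = "pearson") -> SimilarityResult:
    """Pairwise correlation of per-image object counts plus a dendrogram.

    Hierarchical clustering uses average linkage on the distance
    ``1 - correlation``.  Constant count vectors have undefined
    correlations; they are flagged and treated as maximally distant
    (distance 2) in the clustering.
    """
    if len(counts) < 2:
        raise ValueError("need at least two methods")
    frame = pd.DataFrame({k: np.asarray(v, float) for k, v in counts.items()})
    if len(frame) < 3:
        raise ValueError("need counts for at least three images")
    if kind == "spearman":
        corr = frame.corr(method="spearman")
    elif kind == "pearson":
        corr = frame.corr(method="pearson")
    else:
        raise ValueError("kind must be 'pearson' or 'spearman'")

    undefined = [m for m in frame.columns if frame[m].std() == 0]
    dist = 1.0 - corr.to_numpy()
    dist = np.where(np.isnan(dist), 2.0, dist)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(frame.columns), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return SimilarityResult(
        correlation=corr,
        linkage=Z,
        methods=list(frame.columns),
        undefined=undefined,
        kind=kind,
    )
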