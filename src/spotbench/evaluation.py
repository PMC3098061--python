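"""Object- and pixel-level scoring of detections against references, plus
count-distribution statistics.

Empty-denominator conventions (documented, since they matter for empty
frames): no detections with references present gives precision 0; no
references with detections present gives recall 0; both empty gives
precision = recall = F = 1 (an empty image correctly detected as empty is
a perfect result).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import linear_sum_assignment

from .core_image import BinaryMask, DetectionResult, PointList

__all__ = [
    "ReferenceAnnotation", "EvalReport", "CountComparison",
    "detection_centroids", "match_objects", "score", "pixel_score",
    "fscore_from_precision_recall", "compare_count_distributions",
]

#: Default matching radius (pixels) for point-mode references.
DEFAULT_MATCH_RADIUS = 4.0

_INFEASIBLE = 1e12


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Ground truth as either a pixel-accurate mask or a point list.

    Exactly one of ``mask``/``points`` is populated; in points mode a
    detection matches a reference when their centroids are within
    ``match_radius`` pixels.
    """

    mask: Optional[BinaryMask] = None
    points: Optional[PointList] = None
    match_radius: float = DEFAULT_MATCH_RADIUS

    def __post_init__(self):
        if (self.mask is None) == (self.points is None):
            raise ValueError("exactly one of mask/points must be populated")
        if self.points is not None and self.match_radius <= 0:
            raise ValueError("match_radius must be > 0 in points mode")

    @property
    def mode(self) -> str:
        return "mask" if self.mask is not None else "points"

    @property
    def n_objects(self) -> int:
        if self.points is not None:
            return self.points.count
        labeled, n = ndimage.label(
            self.mask.pixels, structure=np.ones((3, 3), dtype=bool)
        )
        return int(n)


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fscore: float
    level: str  # "object" or "pixel"


def detection_centroids(det: DetectionResult) -> np.ndarray:
    """Object centroids of a detection: points as-is, or component
    centroids of the mask (deblended labels take precedence when present)."""
    if det.points is not None:
        return det.points.points
    if det.labels is not None and det.labels.max() > 0:
        labeled = det.labels
        ids = np.unique(labeled)
        ids = ids[ids > 0]
    else:
        labeled, n = ndimage.label(
            det.mask.pixels, structure=np.ones((3, 3), dtype=bool)
        )
        ids = np.arange(1, n + 1)
    if len(ids) == 0:
        return np.empty((0, 2))
    return np.asarray(ndimage.center_of_mass(
        np.ones_like(labeled), labeled, ids
    ))


def _match_by_distance(det_pts, ref_pts, radius):
    nd, nr = len(det_pts), len(ref_pts)
    if nd == 0 or nr == 0:
        return 0
    dist = np.linalg.norm(det_pts[:, None, :] - ref_pts[None, :, :], axis=2)
    cost = np.where(dist <= radius, dist, _INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    return int(np.sum(cost[rows, cols] < _INFEASIBLE))


def _match_by_overlap(det, ref_mask):
    eight = np.ones((3, 3), dtype=bool)
    if det.labels is not None and det.labels.max() > 0:
        det_lab = det.labels
        nd = int(det_lab.max())
    else:
        det_lab, nd = ndimage.label(det.mask.pixels, structure=eight)
    ref_lab, nr = ndimage.label(ref_mask.pixels, structure=eight)
    if nd == 0 or nr == 0:
        return 0, nd, nr

    det_cent = np.asarray(ndimage.center_of_mass(
        np.ones_like(det_lab), det_lab, np.arange(1, nd + 1)
    ))
    ref_cent = np.asarray(ndimage.center_of_mass(
        np.ones_like(ref_lab), ref_lab, np.arange(1, nr + 1)
    ))
    overlap = np.zeros((nd, nr), dtype=bool)
    both = (det_lab > 0) & (ref_lab > 0)
    for d, r in zip(det_lab[both], ref_lab[both]):
        overlap[d - 1, r - 1] = True
    dist = np.linalg.norm(
        det_cent[:, None, :] - ref_cent[None, :, :], axis=2
    )
    cost = np.where(overlap, dist, _INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    tp = int(np.sum(cost[rows, cols] < _INFEASIBLE))
    return tp, nd, nr


def match_objects(det: DetectionResult, ref: ReferenceAnnotation):
    """One-to-one object matching; returns ``(tp, fp, fn)``.

    A pair is matchable iff the centroid distance is within
    ``match_radius`` (points mode) or the components overlap by at least
    one pixel (mask mode).  The assignment maximizes the number of matches
    and, among those, minimizes total centroid distance (Hungarian
    algorithm with infeasible pairs masked).
    """
    if ref.mode == "points":
        det_pts = detection_centroids(det)
        ref_pts = ref.points.points
        tp = _match_by_distance(det_pts, ref_pts, ref.match_radius)
        return tp, len(det_pts) - tp, len(ref_pts) - tp
    tp, nd, nr = _match_by_overlap(det, ref.mask)
    return tp, nd - tp, nr - tp


def score(tp: int, fp: int, fn: int, level: str = "object") -> EvalReport:
    """Precision, recall and their harmonic mean from raw counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        return EvalReport(0, 0, 0, 1.0, 1.0, 1.0, level)
    precision = tp / (tp + fp) if (tp + fp) > 0 else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if (tp + fn) > 0 else (1.0 if fp == 0 else 0.0)
    fscore = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EvalReport(int(tp), int(fp), int(fn), precision, recall, fscore, level)


def fscore_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of already-computed precision and recall values."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def pixel_score(det_mask: BinaryMask, ref_mask: BinaryMask) -> EvalReport:
    """Per-pixel TP/FP/FN scoring of two equal-shape masks."""
    if det_mask is None:
        raise ValueError(
            "pixel-level scoring needs a mask; point-output methods "
            "(FPD, SPL) are omitted from pixel-level comparison"
        )
    if det_mask.shape != ref_mask.shape:
        raise ValueError(
            f"shape mismatch: det {det_mask.shape} vs ref {ref_mask.shape}"
        )
    d, r = det_mask.pixels, ref_mask.pixels
    tp = int(np.sum(d & r))
    fp = int(np.sum(d & ~r))
    fn = int(np.sum(~d & r))
    return score(tp, fp, fn, level="pixel")


@dataclass(frozen=True)
class CountComparison:
    kruskal_h: float
    kruskal_p: float
    wilcoxon_p: pd.DataFrame  # symmetric matrix of pairwise rank-sum p-values


def _ranksum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for combined n <= 25, otherwise the normal
    approximation with midrank tie correction (both via the
    Mann-Whitney U equivalence).
    """
    method = "exact" if (len(x) + len(y)) <= 25 else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the corrected normal
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
    return float(res.pvalue)


def compare_count_distributions(counts: dict) -> CountComparison:
    """Kruskal-Wallis across methods plus pairwise Wilcoxon rank-sum tests.

    ``counts`` maps method id to a per-image object-count sequence.
    """
    if len(counts) < 2:
        raise ValueError("need counts for at least two methods")
    groups = {k: np.asarray(v, dtype=float) for k, v in counts.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each method needs counts for at least two images")

    values = list(groups.values())
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*values)

    names = list(groups)
    mat = pd.DataFrame(np.ones((len(names), len(names))),
                       index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
                pv = 1.0
            else:
                pv = _ranksum_p(groups[a], groups[b])
            mat.loc[a, b] = pv
            mat.loc[b, a] = pv
    return CountComparison(float(h), float(p), mat)
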