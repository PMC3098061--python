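"""Morphology-driven detectors: h-dome (HD) and granulometric morphometry
(MGI)."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import reconstruction

from .core_image import BinaryMask, DetectionResult, GrayImage, PointList

__all__ = [
    "HdParams", "MgiState", "ScaleSelectionError",
    "hdome_transform", "detect_hd",
    "granulometric_index", "granulometry", "detect_mgi", "disk_opening",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# HD


@dataclass(frozen=True)
class HdParams:
    """h-dome detector parameters.

    ``sigma_L`` is the LoG scale, ``h`` the dome height, ``s`` the
    sampling exponent, ``sigma_M`` the maximum accepted object scale, and
    ``n_samples`` the sampling budget.  ``seed`` makes the sampling and
    mean-shift clustering reproducible bit-for-bit.
    """

    sigma_L: float = 1.2
    h: float = 10.0
    s: float = 2.0
    sigma_M: float = 3.0
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.sigma_L <= 0:
            raise ValueError("sigma_L must be > 0")
        if self.h <= 0:
            raise ValueError("dome height h must be > 0")
        if self.s < 1:
            raise ValueError("sampling exponent s must be >= 1")
        if self.sigma_M <= 0:
            raise ValueError("sigma_M must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def hdome_transform(img, h: float) -> np.ndarray:
    """Dome image ``H = f - R(f; f - h)``.

    ``R`` is grayscale reconstruction by dilation of the marker ``f - h``
    under the mask ``f``; the result satisfies ``0 <= H <= h`` everywhere.
    Accepts a :class:`GrayImage` or a plain array (the detector feeds it a
    LoG-filtered image that can be negative).
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    f = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    if np.ptp(f) == 0:
        # a constant image holds no local structure; mapped to a zero dome
        # (the raw reconstruction identity would report a flat dome of h)
        return np.zeros_like(f)
    background = reconstruction(f - h, f, method="dilation")
    return f - background


def _mean_shift(samples: np.ndarray, bandwidth: float,
                tol: float = 1e-3, max_iter: int = 200):
    """Flat-kernel mean shift; returns (modes, labels).

    Modes closer than ``bandwidth / 2`` are merged.
    """
    pos = samples.astype(float).copy()
    for _ in range(max_iter):
        d2 = np.sum((pos[:, None, :] - samples[None, :, :]) ** 2, axis=2)
        within = d2 <= bandwidth**2
        new = np.array([
            samples[w].mean(axis=0) if w.any() else pos[i]
            for i, w in enumerate(within)
        ])
        shift = np.max(np.abs(new - pos))
        pos = new
        if shift < tol:
            break

    modes: list[np.ndarray] = []
    labels = np.empty(len(pos), dtype=int)
    for i, pt in enumerate(pos):
        for j, m in enumerate(modes):
            if np.hypot(*(pt - m)) <= bandwidth / 2:
                labels[i] = j
                break
        else:
            modes.append(pt)
            labels[i] = len(modes) - 1
    return np.asarray(modes), labels


def detect_hd(img: GrayImage, p: HdParams) -> DetectionResult:
    """LoG enhancement, h-dome, probabilistic sampling, mean-shift grouping.

    The dome image (raised to the power ``s``) is normalized into a
    probability map from which ``n_samples`` pixels are drawn; mean-shift
    with bandwidth ``sigma_M`` groups the samples, and clusters whose RMS
    sample spread exceeds ``sigma_M`` are rejected as structures larger
    than an object of interest.
    """
    # scale-normalized -LoG turns bright spots into positive peaks
    enhanced = -(p.sigma_L**2) * ndimage.gaussian_laplace(
        img.pixels, p.sigma_L, mode="reflect"
    )
    dome = hdome_transform(enhanced, p.h)
    dome = np.clip(dome, 0.0, None)
    prob = dome**p.s
    total = prob.sum()
    empty = DetectionResult(
        "HD",
        mask=BinaryMask(np.zeros(img.shape, dtype=bool)),
        points=PointList(np.empty((0, 2))),
        params=dataclasses.asdict(p),
    )
    if total <= 0:
        return empty
    prob = prob / total

    rng = np.random.Generator(np.random.Philox(p.seed))
    flat_idx = rng.choice(prob.size, size=p.n_samples, p=prob.ravel())
    samples = np.column_stack(np.unravel_index(flat_idx, img.shape)).astype(float)

    modes, labels = _mean_shift(samples, bandwidth=p.sigma_M)

    # bright objects reach the full dome height h; clusters must sit on a
    # strong-dome component, which also merges sampling clusters that
    # fragment one object
    eight = np.ones((3, 3), dtype=bool)
    comp, _ = ndimage.label(dome >= 0.5 * p.h, structure=eight)

    min_support = max(3, p.n_samples // 200)
    candidate_comps = set()
    for j in range(len(modes)):
        cluster = samples[labels == j]
        if len(cluster) < min_support:
            continue
        center = cluster.mean(axis=0)
        spread = float(np.sqrt(np.mean(np.sum((cluster - center) ** 2, axis=1))))
        if spread > p.sigma_M:
            continue
        r = min(max(int(round(center[0])), 0), img.shape[0] - 1)
        c = min(max(int(round(center[1])), 0), img.shape[1] - 1)
        if comp[r, c] > 0:
            candidate_comps.add(int(comp[r, c]))

    mask = np.zeros(img.shape, dtype=bool)
    points = []
    rr, cc = np.nonzero(comp > 0)
    for cid in sorted(candidate_comps):
        rows, cols = rr[comp[rr, cc] == cid], cc[comp[rr, cc] == cid]
        weights = dome[rows, cols]
        centroid = np.array([
            np.average(rows, weights=weights),
            np.average(cols, weights=weights),
        ])
        d2 = (rows - centroid[0]) ** 2 + (cols - centroid[1]) ** 2
        rms_radius = float(np.sqrt(np.average(d2, weights=weights)))
        if rms_radius > p.sigma_M:
            continue  # structure larger than an object of interest
        mask |= comp == cid
        points.append(centroid)
    if not points:
        return empty
    return DetectionResult(
        "HD",
        mask=BinaryMask(mask),
        points=PointList(np.asarray(points)),
        params=dataclasses.asdict(p),
    )


# ---------------------------------------------------------------------------
# MGI


class ScaleSelectionError(RuntimeError):
    """Raised when the granulometric index has fewer than two peaks."""


@dataclass
class MgiState:
    """Granulometric index over odd disc diameters plus the selected scales."""

    diameters: np.ndarray
    G: np.ndarray
    d_low: int
    d_high: int


def disk_opening(arr: np.ndarray, diameter: int) -> np.ndarray:
    """Grayscale opening with a discrete Euclidean disc of odd diameter."""
    if diameter % 2 == 0:
        raise ValueError("disc diameters must be odd")
    radius = (diameter - 1) // 2
    if radius == 0:
        return arr.copy()
    dr, dc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    footprint = (dr * dr + dc * dc) <= radius * radius
    return ndimage.grey_opening(arr, footprint=footprint, mode="reflect")


def granulometric_index(img: GrayImage, d_max: int = 21):
    """Size density over odd disc diameters: ``G(d)`` is the integrated
    intensity removed when the opening disc grows past diameter ``d``.

    Returns ``(diameters, G)``; ``sum(G)`` telescopes to the intensity
    removed by the largest opening.
    """
    if d_max < 3:
        raise ValueError("d_max must be >= 3")
    diameters = np.arange(1, d_max + 1, 2)
    sums = []
    for d in diameters:
        sums.append(float(disk_opening(img.pixels, int(d)).sum()))
    # one step beyond, so the last diameter has a defined loss
    beyond = float(disk_opening(img.pixels, int(diameters[-1]) + 2).sum())
    sums.append(beyond)
    G = np.array([sums[i] - sums[i + 1] for i in range(len(diameters))])
    return diameters, G


def granulometry(img: GrayImage, d_max: int = 21) -> MgiState:
    """Automatic two-peak scale pick from the granulometric index.

    The two highest local maxima of ``G`` give ``d_low < d_high``.
    """
    diameters, G = granulometric_index(img, d_max)
    peaks = [
        i for i in range(len(G))
        if G[i] > 0
        and (i == 0 or G[i] >= G[i - 1])
        and (i == len(G) - 1 or G[i] > G[i + 1])
    ]
    if len(peaks) < 2:
        raise ScaleSelectionError(
            f"scale selection failed: {len(peaks)} peak(s) in G(d)"
        )
    top_two = sorted(sorted(peaks, key=lambda i: -G[i])[:2])
    d_low, d_high = int(diameters[top_two[0]]), int(diameters[top_two[1]])
    return MgiState(diameters=diameters, G=G, d_low=d_low, d_high=d_high)


#: Fraction of cumulative masked intensity retained by integral thresholding.
MGI_INTEGRAL_FRACTION = 0.95


def detect_mgi(img: GrayImage, d_max: int = 21,
               integral_fraction: float = MGI_INTEGRAL_FRACTION) -> DetectionResult:
    """Parameter-free detection via granulometric scale selection.

    ``I_low - I_high`` (openings at the two selected scales) isolates
    structures of the small scale; a 2-means bright mask of the original
    image gates the result, and integral thresholding keeps the brightest
    difference pixels carrying ``integral_fraction`` of the gated
    intensity.  Scale-selection failure (e.g. near-empty images) yields an
    empty mask with a warning.
    """
    from .thresholding import kmeans2_binarize

    params = {"d_max": d_max, "integral_fraction": integral_fraction}
    try:
        state = granulometry(img, d_max=d_max)
    except ScaleSelectionError as exc:
        log.warning("MGI: %s; returning empty mask", exc)
        return DetectionResult(
            "MGI", mask=BinaryMask(np.zeros(img.shape, dtype=bool)),
            params=params,
        )

    i_low = disk_opening(img.pixels, state.d_low)
    i_high = disk_opening(img.pixels, state.d_high)
    diff = i_low - i_high

    bright = kmeans2_binarize(img).pixels
    gated = np.where(bright, diff, 0.0)
    positive = gated[gated > 0]
    if positive.size == 0:
        mask = np.zeros(img.shape, dtype=bool)
    else:
        order = np.sort(positive)[::-1]
        cum = np.cumsum(order)
        k = int(np.searchsorted(cum, integral_fraction * cum[-1]))
        threshold = order[min(k, len(order) - 1)]
        mask = bright & (diff >= threshold)
    params.update({"d_low": state.d_low, "d_high": state.d_high})
    return DetectionResult("MGI", mask=BinaryMask(mask), params=params)
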