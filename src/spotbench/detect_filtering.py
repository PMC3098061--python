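"""Filtering/enhancement detectors that output a segmentation mask.

Seven methods live here: band-pass filtering (BPF), kernel density
estimation (KDE), local comparison (LC), local enhancement filtering
(LEF), multiscale wavelet products (MW), source-extraction with blockwise
background clipping (SE), and top-hat filtering (THE).  Each follows the
same contract: a :class:`~spotbench.core_image.GrayImage` and a parameter
dataclass in, a :class:`~spotbench.core_image.DetectionResult` with a
binary mask out.  All detectors are deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core_image import BinaryMask, DetectionResult, GrayImage
from .thresholding import (
    DegenerateHistogramError,
    kapur_entropy_threshold,
    otsu_threshold,
)

__all__ = [
    "BpfParams", "KdeParams", "LcParams", "LefParams", "MwParams",
    "SeParams", "TheParams",
    "detect_bpf", "detect_kde", "detect_lc", "detect_lef", "detect_mw",
    "detect_se", "detect_the",
    "atrous_decompose", "se_estimate_background",
    "KDE_KERNELS",
]

#: Relative residual range under which a filtered image is treated as
#: "all near zero" and mapped to an empty mask instead of an arbitrary
#: histogram split.
_NEAR_ZERO_REL = 1e-3


def _mask_result(method_id, mask_arr, params, labels=None) -> DetectionResult:
    return DetectionResult(
        method_id=method_id,
        mask=BinaryMask(mask_arr),
        params=dataclasses.asdict(params),
        labels=labels,
    )


def _empty(method_id, shape, params) -> DetectionResult:
    return _mask_result(method_id, np.zeros(shape, dtype=bool), params)


def _disk_footprint(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= radius * radius


# ---------------------------------------------------------------------------
# BPF — band-pass filtering


@dataclass(frozen=True)
class BpfParams:
    """Four normalized cut-off frequencies (1 = Nyquist).

    The pass band is ``[w2, w3]``; ``[w1, w2]`` and ``[w3, w4]`` are the
    transition bands.
    """

    cutoffs: tuple = (0.02, 0.10, 0.45, 0.65)

    def __post_init__(self):
        c = tuple(float(x) for x in self.cutoffs)
        if len(c) != 4:
            raise ValueError("BPF needs exactly four cut-off frequencies")
        w1, w2, w3, w4 = c
        if not (0.0 <= w1 < w2 <= w3 < w4 <= 1.0):
            raise ValueError(
                f"cut-offs must satisfy 0 <= w1 < w2 <= w3 < w4 <= 1, got {c}"
            )
        object.__setattr__(self, "cutoffs", c)


def bpf_filter_taps(p: BpfParams) -> np.ndarray:
    """Design the 1-D linear-phase band-pass FIR (windowed-sinc, Hamming).

    The order is ``4 / (w2 - w1)`` rounded up to odd; the -6 dB edges sit
    at the transition-band midpoints.
    """
    w1, w2, w3, w4 = p.cutoffs
    ntaps = int(np.ceil(4.0 / (w2 - w1)))
    ntaps = max(ntaps, 9)
    if ntaps % 2 == 0:
        ntaps += 1
    lo = 0.5 * (w1 + w2)
    hi = 0.5 * (w3 + w4)
    hi = min(hi, 1.0 - 1e-6)
    return signal.firwin(ntaps, [lo, hi], pass_zero=False, window="hamming")


def bpf_filter_image(img: GrayImage, p: BpfParams) -> np.ndarray:
    """Apply the band-pass separably (rows then columns), reflective borders."""
    taps = bpf_filter_taps(p)
    out = ndimage.correlate1d(img.pixels, taps, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, taps, axis=1, mode="reflect")
    return out


def detect_bpf(img: GrayImage, p: BpfParams) -> DetectionResult:
    """Band-pass filter then binarize the response with Otsu's threshold."""
    filtered = bpf_filter_image(img, p)
    in_range = float(np.ptp(img.pixels))
    if np.ptp(filtered) <= max(_NEAR_ZERO_REL * in_range, 1e-12):
        return _empty("BPF", img.shape, p)
    try:
        th = otsu_threshold(filtered)
    except DegenerateHistogramError:
        return _empty("BPF", img.shape, p)
    return _mask_result("BPF", filtered > th, p)


# ---------------------------------------------------------------------------
# KDE — kernel density estimation (Parzen window smoothing)

KDE_KERNELS = {
    "uniform": lambda u: (np.abs(u) <= 1).astype(float),
    "gaussian": lambda u: np.exp(-0.5 * u * u),
    "epanechnikov": lambda u: 0.75 * np.clip(1 - u * u, 0, None),
    "triangle": lambda u: np.clip(1 - np.abs(u), 0, None),
    "quartic": lambda u: (15 / 16) * np.clip(1 - u * u, 0, None) ** 2,
    "triweight": lambda u: (35 / 32) * np.clip(1 - u * u, 0, None) ** 3,
    "cosine": lambda u: np.where(
        np.abs(u) <= 1, (np.pi / 4) * np.cos(np.pi * u / 2), 0.0
    ),
}


@dataclass(frozen=True)
class KdeParams:
    radius: int = 2
    h: float = 1.0
    kernel_name: str = "uniform"

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.h <= 0:
            raise ValueError("smoothing parameter h must be > 0")
        if self.kernel_name not in KDE_KERNELS:
            raise ValueError(
                f"unknown kernel {self.kernel_name!r}; "
                f"choose from {sorted(KDE_KERNELS)}"
            )


def kde_smooth(img: GrayImage, p: KdeParams) -> np.ndarray:
    """Kernel-weighted local average over a circular window of radius R.

    The kernel argument is the distance normalized by ``R * h``, so the
    uniform kernel at ``h = 1`` reduces to the plain windowed mean and
    ``h`` widens or narrows the kernel relative to the window.  The sum is
    normalized by the cardinality of the in-bounds window set, so border
    pixels average over fewer neighbors rather than over padded values.
    """
    R = p.radius
    if 2 * R + 1 > min(img.shape):
        raise ValueError("window radius exceeds half the image size")
    dr, dc = np.mgrid[-R : R + 1, -R : R + 1]
    dist = np.sqrt(dr * dr + dc * dc)
    inside = dist <= R
    weights = np.where(
        inside, KDE_KERNELS[p.kernel_name](dist / (R * p.h)), 0.0
    )
    num = ndimage.correlate(img.pixels, weights, mode="constant", cval=0.0)
    card = ndimage.correlate(
        np.ones(img.shape), inside.astype(float), mode="constant", cval=0.0
    )
    return num / card


def detect_kde(img: GrayImage, p: KdeParams) -> DetectionResult:
    smoothed = kde_smooth(img, p)
    try:
        th = otsu_threshold(smoothed)
    except DegenerateHistogramError:
        return _empty("KDE", img.shape, p)
    return _mask_result("KDE", smoothed > th, p)


# ---------------------------------------------------------------------------
# LC — local comparison between direction-specific filters


@dataclass(frozen=True)
class LcParams:
    radius: int = 3
    alpha: float = 1.0

    def __post_init__(self):
        if self.radius < 2:
            raise ValueError("radius must be >= 2 (quadrants empty otherwise)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def lc_direction_filters(radius: int) -> dict:
    """Quadrant mean filters (NE/NW/SW/SE) of a circular window.

    The center pixel is excluded; quadrant membership goes by the angle of
    ``(d_row, d_col)`` with on-axis ties assigned to the counter-clockwise
    quadrant.  Each filter is renormalized to unit sum.
    """
    R = radius
    dr, dc = np.mgrid[-R : R + 1, -R : R + 1]
    inside = (dr * dr + dc * dc <= R * R) & ~((dr == 0) & (dc == 0))
    # screen angle: rows grow downward, so up is -d_row
    theta = np.mod(np.arctan2(-dr, dc), 2 * np.pi)
    quadrant = np.floor(theta / (np.pi / 2)).astype(int) % 4
    names = ["NE", "NW", "SW", "SE"]
    filters = {}
    for q, name in enumerate(names):
        kern = ((quadrant == q) & inside).astype(float)
        total = kern.sum()
        if total == 0:
            raise ValueError("radius too small: empty quadrant filter")
        filters[name] = kern / total
    return filters


def detect_lc(img: GrayImage, p: LcParams) -> DetectionResult:
    """Pixel is an object iff ``alpha * f`` beats all four quadrant means."""
    filters = lc_direction_filters(p.radius)
    responses = [
        ndimage.correlate(img.pixels, k, mode="reflect")
        for k in filters.values()
    ]
    max_resp = np.maximum.reduce(responses)
    # tolerance keeps exact ties (e.g. constant images) out of the mask
    # despite rounding in the normalized filter weights
    guard = 1e-9 * (1.0 + np.abs(max_resp))
    return _mask_result("LC", p.alpha * img.pixels > max_resp + guard, p)


# ---------------------------------------------------------------------------
# LEF — local spot enhancement filtering


@dataclass(frozen=True)
class LefParams:
    th_s: float = 5.0
    kernel_size: int = 9
    inner_radius: float = 2.0
    target_mean: float = 100.0

    def __post_init__(self):
        if self.th_s <= 0:
            raise ValueError("th_s must be > 0")
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be an odd integer >= 3")
        if self.inner_radius < 1:
            raise ValueError("inner_radius must be >= 1")
        if self.inner_radius >= (self.kernel_size - 1) / 2:
            raise ValueError("inner circle must lie strictly inside the kernel")
        if self.target_mean <= 0:
            raise ValueError("target_mean must be > 0")


_LEF_EPS = 1e-6
_LEF_SD_FLOOR = 1e-9


def lef_likelihood(img: GrayImage, p: LefParams) -> np.ndarray:
    """Spot likelihood: inner-circle mean over outer-area mean.

    The image is first rescaled so its global mean equals ``target_mean``,
    removing global intensity differences; the ratio of area means makes
    the flat-field likelihood sit near 1.
    """
    mean = float(img.pixels.mean())
    if mean == 0:
        return np.zeros(img.shape)
    scaled = img.pixels * (p.target_mean / mean)

    half = (p.kernel_size - 1) // 2
    dr, dc = np.mgrid[-half : half + 1, -half : half + 1]
    inner = (dr * dr + dc * dc) <= p.inner_radius * p.inner_radius
    outer = ~inner
    inner_mean = ndimage.correlate(
        scaled, inner / inner.sum(), mode="reflect"
    )
    outer_mean = ndimage.correlate(
        scaled, outer / outer.sum(), mode="reflect"
    )
    return inner_mean / (outer_mean + _LEF_EPS)


def detect_lef(img: GrayImage, p: LefParams) -> DetectionResult:
    likelihood = lef_likelihood(img, p)
    sd = float(likelihood.std())
    if sd < _LEF_SD_FLOOR:
        return _empty("LEF", img.shape, p)
    return _mask_result("LEF", likelihood > p.th_s * sd, p)


# ---------------------------------------------------------------------------
# MW — multiscale product of à trous wavelet coefficients

_B3_KERNEL = np.array([1 / 16, 1 / 4, 3 / 8, 1 / 4, 1 / 16])


@dataclass(frozen=True)
class MwParams:
    J: int = 3
    l_d: float = 1.0

    def __post_init__(self):
        if self.J < 2:
            raise ValueError("J must be >= 2")
        if self.l_d <= 0:
            raise ValueError("detection level l_d must be > 0")


def atrous_kernel(scale: int) -> np.ndarray:
    """B3-spline kernel with ``2**(scale-1) - 1`` zeros between taps."""
    gap = 2 ** (scale - 1) - 1
    kern = np.zeros(4 * (gap + 1) + 1)
    kern[:: gap + 1] = _B3_KERNEL
    return kern


def atrous_decompose(arr: np.ndarray, J: int):
    """Separable à trous decomposition: returns ``([W_1..W_J], A_J)``.

    ``A_0 = A_J + sum(W_i)`` holds exactly (telescoping differences).
    """
    A = np.asarray(arr, dtype=np.float64)
    planes = []
    for i in range(1, J + 1):
        kern = atrous_kernel(i)
        if len(kern) > min(A.shape):
            raise ValueError(
                f"image too small for scale {i} (kernel support {len(kern)})"
            )
        nxt = ndimage.correlate1d(A, kern, axis=0, mode="reflect")
        nxt = ndimage.correlate1d(nxt, kern, axis=1, mode="reflect")
        planes.append(A - nxt)
        A = nxt
    return planes, A


def _mad_sigma(arr: np.ndarray) -> float:
    med = np.median(arr)
    return float(np.median(np.abs(arr - med)) / 0.67)


def detect_mw(img: GrayImage, p: MwParams) -> DetectionResult:
    """Hard-threshold each wavelet plane at 3 sigma (MAD/0.67 estimate),
    multiply the planes across scales, and keep product > l_d."""
    planes, _ = atrous_decompose(img.pixels, p.J)
    product = np.ones(img.shape)
    for W in planes:
        sigma = _mad_sigma(W)
        thresholded = np.where(np.abs(W) > 3.0 * sigma, W, 0.0)
        product = product * thresholded
    return _mask_result("MW", product > p.l_d, p)


# ---------------------------------------------------------------------------
# SE — blockwise background clipping, Gaussian matched filter, deblending


@dataclass(frozen=True)
class SeParams:
    block_size: int = 32
    th_detect: float = 3.0
    th_bg: float = 0.0
    gauss_sigma: float = 1.5
    deblend_nslices: int = 30
    deblend_min_contrast: float = 0.005

    def __post_init__(self):
        if self.block_size < 8:
            raise ValueError("block_size must be >= 8")
        if self.th_detect <= 0:
            raise ValueError("th_detect must be > 0")
        if self.th_bg < 0:
            raise ValueError("th_bg must be >= 0")
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be > 0")
        if not (0 < self.deblend_min_contrast < 1):
            raise ValueError("deblend_min_contrast must be in (0, 1)")


def _clip_block(values: np.ndarray) -> float:
    """Iterative 3-sigma clipping around the median of one block.

    If the standard deviation changed by less than 20% overall, the
    background is the clipped mean; otherwise ``2.5 * median - 1.5 * mean``
    of the clipped set.
    """
    retained = values.astype(np.float64)
    sigma0 = float(retained.std())
    if sigma0 == 0:
        return float(retained[0])
    for _ in range(100):
        med = np.median(retained)
        s = retained.std()
        if s == 0:
            break
        keep = np.abs(retained - med) <= 3.0 * s
        if keep.all():
            break
        retained = retained[keep]
    sigma_final = float(retained.std())
    if abs(sigma_final - sigma0) / sigma0 < 0.2:
        return float(retained.mean())
    return float(2.5 * np.median(retained) - 1.5 * retained.mean())


def se_estimate_background(img: GrayImage, block_size: int) -> GrayImage:
    """Blockwise sigma-clipped background, bilinearly interpolated to pixels.

    Edge blocks may be partial.  Negative blockwise estimates (possible
    under the median/mean branch) are clipped to zero in the returned
    image.
    """
    from scipy.interpolate import RegularGridInterpolator

    h, w = img.shape
    row_starts = list(range(0, h, block_size))
    col_starts = list(range(0, w, block_size))
    centers_r = [0.5 * (r0 + min(r0 + block_size, h) - 1) for r0 in row_starts]
    centers_c = [0.5 * (c0 + min(c0 + block_size, w) - 1) for c0 in col_starts]
    bg_grid = np.empty((len(row_starts), len(col_starts)))
    for bi, r0 in enumerate(row_starts):
        r1 = min(r0 + block_size, h)
        for bj, c0 in enumerate(col_starts):
            c1 = min(c0 + block_size, w)
            bg_grid[bi, bj] = _clip_block(img.pixels[r0:r1, c0:c1].ravel())

    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    if len(centers_r) == 1 and len(centers_c) == 1:
        bg = np.full((h, w), bg_grid[0, 0])
    elif len(centers_r) == 1:
        bg = np.tile(
            np.interp(cols, centers_c, bg_grid[0]), (h, 1)
        )
    elif len(centers_c) == 1:
        bg = np.tile(
            np.interp(rows, centers_r, bg_grid[:, 0])[:, None], (1, w)
        )
    else:
        interp = RegularGridInterpolator(
            (np.asarray(centers_r), np.asarray(centers_c)),
            bg_grid,
            method="linear",
            bounds_error=False,
            fill_value=None,
        )
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        bg = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(h, w)
    return GrayImage(np.clip(bg, 0.0, None), bit_origin=img.bit_origin)


def _deblend_component(values, comp_mask, base, nslices, min_contrast):
    """Split one connected component into branches by intensity slicing.

    Works top-down through ``nslices`` levels; a branch stays a separate
    object when its integrated intensity exceeds ``min_contrast`` of the
    component total.  Returns a label array over ``comp_mask`` and the
    number of objects.
    """
    total = float(np.sum((values - base)[comp_mask]))
    peak = float(values[comp_mask].max())
    if total <= 0 or peak <= base:
        return comp_mask.astype(int), 1

    levels = np.linspace(peak, base, nslices + 1)[1:]
    assign = np.zeros(values.shape, dtype=int)
    parent = {}  # union-find over branch ids

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    next_id = 1
    eight = np.ones((3, 3), dtype=bool)
    for level in levels:
        above = comp_mask & (values >= level)
        lab, n = ndimage.label(above, structure=eight)
        for region_idx in range(1, n + 1):
            region = lab == region_idx
            ids = np.unique(assign[region])
            ids = [find(i) for i in ids if i != 0]
            ids = sorted(set(ids))
            if not ids:
                parent[next_id] = next_id
                assign[region] = next_id
                next_id += 1
            elif len(ids) == 1:
                assign[region & (assign == 0)] = ids[0]
            else:
                strengths = {
                    i: float(np.sum((values - base)[assign == i]))
                    for i in ids
                }
                significant = [
                    i for i in ids
                    if strengths[i] > min_contrast * total
                ]
                dominant = max(ids, key=lambda i: strengths[i])
                if len(significant) >= 2:
                    # genuine branches stay separate; the merged shell
                    # joins the dominant branch
                    assign[region & (assign == 0)] = dominant
                else:
                    for i in ids:
                        parent[find(i)] = find(dominant)
                    assign[region & (assign == 0)] = dominant

    roots = sorted({find(i) for i in np.unique(assign) if i != 0})
    out = np.zeros(values.shape, dtype=int)
    for new_id, root in enumerate(roots, start=1):
        member = np.isin(assign, [i for i in parent if find(i) == root])
        out[member] = new_id
    out[comp_mask & (out == 0)] = 1  # safety: base level covers the component
    return out, max(len(roots), 1)


def detect_se(img: GrayImage, p: SeParams) -> DetectionResult:
    if p.block_size > min(img.shape):
        raise ValueError(
            f"block_size {p.block_size} exceeds image extent {min(img.shape)}"
        )
    bg = se_estimate_background(img, p.block_size).pixels
    sub = img.pixels - bg
    filtered = ndimage.gaussian_filter(sub, p.gauss_sigma, mode="reflect")
    sigma = float(sub.std())
    thresh_map = p.th_detect * sigma + p.th_bg * bg
    mask = filtered > thresh_map

    labels = np.zeros(img.shape, dtype=int)
    eight = np.ones((3, 3), dtype=bool)
    comp_labels, n_comp = ndimage.label(mask, structure=eight)
    next_label = 0
    for comp_id in range(1, n_comp + 1):
        comp = comp_labels == comp_id
        base = float(thresh_map[comp].min())
        local, n_obj = _deblend_component(
            filtered, comp, base, p.deblend_nslices, p.deblend_min_contrast
        )
        labels[comp] = local[comp] + next_label
        next_label += n_obj
    return _mask_result("SE", mask, p, labels=labels)


# ---------------------------------------------------------------------------
# THE — top-hat filtering with entropy-based thresholding


@dataclass(frozen=True)
class TheParams:
    r: int = 3

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("structuring element radius must be >= 1")


def tophat(img: GrayImage, r: int) -> np.ndarray:
    """Top-hat residual ``f - (f opened by a flat disk of radius r)``."""
    footprint = _disk_footprint(r)
    opened = ndimage.grey_opening(
        img.pixels, footprint=footprint, mode="reflect"
    )
    return img.pixels - opened


def detect_the(img: GrayImage, p: TheParams) -> DetectionResult:
    residual = tophat(img, p.r)
    try:
        th = kapur_entropy_threshold(residual)
    except DegenerateHistogramError:
        return _empty("THE", img.shape, p)
    return _mask_result("THE", residual > th, p)
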