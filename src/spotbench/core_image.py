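"""Image data model, grayscale conversion, file I/O and shared filtering helpers.

Conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based, with pixel centers at integer
  positions;
* filters pad with reflection ("symmetric") at the borders unless a method
  documents otherwise;
* images are promoted to ``float64`` on load and detectors never mutate
  their input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "BinaryMask",
    "PointList",
    "DetectionResult",
    "rgb_to_gray",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "load_points",
    "save_points",
    "lowpass_prefilter",
]

#: RGB → gray weights; kept exactly as printed (they sum to 0.9999, no
#: renormalization).
RGB_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass(frozen=True)
class GrayImage:
    """A 2-D real-valued intensity field.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (arbitrary linear
        units).
    bit_origin
        Provenance tag: ``"8"``, ``"16"`` or ``"float"``.
    """

    pixels: np.ndarray
    bit_origin: str = "float"

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must have height >= 1 and width >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("image intensities must be non-negative")
        if self.bit_origin not in ("8", "16", "float"):
            raise ValueError(f"unknown bit_origin {self.bit_origin!r}")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 1} image with the same shape as its source image."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", arr.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class PointList:
    """Sub-pixel object locations as ``(row, col)`` pairs."""

    points: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        object.__setattr__(self, "points", arr)

    @property
    def count(self) -> int:
        return int(self.points.shape[0])

    def __len__(self) -> int:
        return self.count


VALID_METHOD_IDS = (
    "BPF", "FPD", "HD", "KDE", "LC", "LEF", "MGI", "MW", "SE", "SPL", "THE",
)

#: Methods whose native output is a point list rather than a mask.
POINT_METHODS = ("FPD", "SPL")


@dataclass
class DetectionResult:
    """Common detector output: a mask and/or a point list.

    FPD and SPL carry points only; every other method carries a mask
    (points derivable as component centroids).  ``labels`` optionally
    carries a labelled image refining the mask into objects (used by SE
    deblending); when present it defines the object count.
    """

    method_id: str
    mask: Optional[BinaryMask] = None
    points: Optional[PointList] = None
    params: dict = field(default_factory=dict)
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.method_id not in VALID_METHOD_IDS:
            raise ValueError(f"unknown method id {self.method_id!r}")
        if self.mask is None and self.points is None:
            raise ValueError("detection result needs a mask or a point list")
        if self.method_id in POINT_METHODS and self.mask is not None:
            raise ValueError(f"{self.method_id} results carry points only")


def rgb_to_gray(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> GrayImage:
    """Convert three channels to gray as ``0.2989 R + 0.5870 G + 0.1140 B``.

    The coefficients are used exactly as printed; they sum to 0.9999 and are
    deliberately not renormalized.
    """
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if not (r.shape == g.shape == b.shape):
        raise ValueError(
            f"channel shape mismatch: R{r.shape}, G{g.shape}, B{b.shape}"
        )
    wr, wg, wb = RGB_WEIGHTS
    return GrayImage(wr * r + wg * g + wb * b)


def _read_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(str(path)))
    if suffix == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(str(path)))
    raise ValueError(f"unsupported image format: {path}")


def load_image(path) -> GrayImage:
    """Load a TIFF or PNG image as a :class:`GrayImage`.

    8/16-bit intensities are preserved exactly (no rescaling); RGB images
    are converted with :func:`rgb_to_gray`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_array(path)
    if arr.dtype == np.uint8:
        origin = "8"
    elif arr.dtype == np.uint16:
        origin = "16"
    else:
        origin = "float"
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            raise ValueError(f"cannot interpret {path} with shape {arr.shape}")
        gray = rgb_to_gray(arr[..., 0], arr[..., 1], arr[..., 2])
        return GrayImage(gray.pixels, bit_origin=origin)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret {path} with shape {arr.shape}")
    return GrayImage(arr, bit_origin=origin)


def save_image(img: GrayImage, path) -> None:
    """Write a grayscale image; 16-bit TIFF when values fit, else float TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    arr = img.pixels
    if suffix in (".tif", ".tiff"):
        import tifffile

        if np.allclose(arr, np.round(arr)) and arr.max(initial=0) <= 65535:
            tifffile.imwrite(str(path), np.round(arr).astype(np.uint16))
        else:
            tifffile.imwrite(str(path), arr.astype(np.float32))
    elif suffix == ".png":
        import imageio.v3 as iio

        if arr.max(initial=0) > 65535:
            raise ValueError("PNG cannot store intensities above 65535")
        dtype = np.uint8 if arr.max(initial=0) <= 255 else np.uint16
        iio.imwrite(str(path), np.round(arr).astype(dtype))
    else:
        raise ValueError(f"unsupported image format: {path}")


def save_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit {0, 255} PNG or TIFF."""
    path = Path(path)
    arr = (mask.pixels.astype(np.uint8)) * 255
    suffix = path.suffix.lower()
    if suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(str(path), arr)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        raise ValueError(f"unsupported mask format: {path}")


def load_mask(path) -> BinaryMask:
    """Load a binary mask (any non-zero pixel is foreground)."""
    arr = _read_array(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return BinaryMask(arr > 0)


def save_points(points: PointList, path) -> None:
    """Write a point list as CSV with header ``row,col``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col"])
        for row, col in points.points:
            writer.writerow([repr(float(row)), repr(float(col))])


def load_points(path) -> PointList:
    """Read a ``row,col`` CSV point list."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["row", "col"]:
            raise ValueError(f"expected a 'row,col' header in {path}")
        pts = [(float(r[0]), float(r[1])) for r in reader if r]
    return PointList(np.asarray(pts, dtype=np.float64).reshape(-1, 2))


def lowpass_prefilter(img: GrayImage, sigma: float) -> GrayImage:
    """Optional Gaussian noise-suppression prefilter.

    ``sigma = 0`` returns the input unchanged; borders are reflected.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img
    out = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="reflect")
    return GrayImage(np.clip(out, 0.0, None), bit_origin=img.bit_origin)
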