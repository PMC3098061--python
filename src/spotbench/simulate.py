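"""Synthetic benchmark scenes with exact ground truth.

Scenes are composed on three channels — cytoplasm on red, spots on green,
nuclei on blue — and converted for the detectors with the standard
RGB→gray weights, so spots end up slightly brighter than their
surroundings.  The ground truth is exact by construction: every truth
point is a generated spot center, and the truth mask is the union of the
above-half-maximum supports of the in-focus spots.

Randomness comes from a counter-based generator (Philox) keyed by the
config seed, so scenes are bit-identical across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_image import BinaryMask, GrayImage, PointList, rgb_to_gray

__all__ = ["SimConfig", "SimScene", "generate_scene", "generate_stack",
           "generate_doseplate"]

log = logging.getLogger(__name__)

#: Half-max radius → Gaussian sigma conversion.
_RADIUS_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))

#: Extra blur beyond this multiple of the nominal spot sigma marks a spot
#: out of focus (excluded from the truth).
IN_FOCUS_FACTOR = 1.5


@dataclass(frozen=True)
class SimConfig:
    size: int = 96
    n_cells: int = 3
    spots_per_cell: object = 4          # int, or (lo, hi) inclusive range
    spot_radius: tuple = (1.2, 1.7)     # half-max radius range, pixels
    spot_peak: float = 150.0
    cell_intensity: float = 35.0
    nucleus_intensity: float = 50.0
    background: float = 10.0
    noise_sd: float = 2.0
    texture_amplitude: float = 4.0
    blur_fraction: float = 0.0
    blur_sigma: float = 3.0
    empty_frame: bool = False
    seed: int = 0
    min_spot_separation: float = 7.0
    cell_radius: tuple = (11.0, 15.0)

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0 <= self.blur_fraction <= 1):
            raise ValueError("blur_fraction must be in [0, 1]")
        for name in ("spot_peak", "cell_intensity", "nucleus_intensity",
                     "background", "noise_sd", "texture_amplitude",
                     "blur_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimScene:
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    gray: GrayImage
    truth_mask: BinaryMask
    truth_points: PointList
    spots: list = field(default_factory=list)   # per-spot metadata dicts
    config: Optional[SimConfig] = None

    @property
    def nuclei(self) -> GrayImage:
        return GrayImage(self.blue)


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _draw_count(rng, spec) -> int:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _place_cells(cfg: SimConfig, rng) -> list:
    """Non-overlapping ellipses with bounded retries."""
    cells = []
    attempts = 0
    max_attempts = 200 * max(cfg.n_cells, 1)
    while len(cells) < cfg.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_cells} cells in a "
                f"{cfg.size}x{cfg.size} image"
            )
        ra = rng.uniform(*cfg.cell_radius)
        rb = rng.uniform(*cfg.cell_radius)
        big = max(ra, rb)
        r0 = rng.uniform(big + 1, cfg.size - big - 1)
        c0 = rng.uniform(big + 1, cfg.size - big - 1)
        theta = rng.uniform(0, np.pi)
        ok = all(
            np.hypot(r0 - c["row"], c0 - c["col"])
            > 0.9 * (big + max(c["ra"], c["rb"]))
            for c in cells
        )
        if ok:
            cells.append({"row": r0, "col": c0, "ra": ra, "rb": rb,
                          "theta": theta})
    return cells


def _ellipse_mask(shape, cell, scale=1.0) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - cell["row"]
    dc = cc - cell["col"]
    ct, st = np.cos(cell["theta"]), np.sin(cell["theta"])
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / (scale * cell["ra"])) ** 2 + (
        v / (scale * cell["rb"])
    ) ** 2 <= 1.0


def _place_spots(cfg: SimConfig, rng, cells, total: Optional[int] = None) -> list:
    """Spot layout inside cytoplasm with a minimum mutual separation."""
    spots = []

    def try_place(cell):
        for _ in range(200):
            # rejection sample inside the ellipse
            u = rng.uniform(-1, 1) * cell["ra"]
            v = rng.uniform(-1, 1) * cell["rb"]
            if (u / cell["ra"]) ** 2 + (v / cell["rb"]) ** 2 > 0.85:
                continue
            ct, st = np.cos(cell["theta"]), np.sin(cell["theta"])
            r = cell["row"] + u * ct - v * st
            c = cell["col"] + u * st + v * ct
            if any(
                np.hypot(r - s["row"], c - s["col"]) < cfg.min_spot_separation
                for s in spots
            ):
                continue
            radius = rng.uniform(*cfg.spot_radius)
            spots.append({
                "row": float(r), "col": float(c),
                "radius": float(radius),
                "sigma": float(radius * _RADIUS_TO_SIGMA),
                "peak": float(cfg.spot_peak),
                "blurred": bool(rng.uniform() < cfg.blur_fraction),
            })
            return True
        return False

    if total is None:
        for cell in cells:
            for _ in range(_draw_count(rng, cfg.spots_per_cell)):
                try_place(cell)
    else:
        placed = 0
        guard = 0
        while placed < total and cells:
            cell = cells[int(rng.integers(len(cells)))]
            if try_place(cell):
                placed += 1
            guard += 1
            if guard > 50 * max(total, 1):
                log.warning("spot placement gave up at %d/%d", placed, total)
                break
    return spots


def _render(cfg: SimConfig, rng, cells, spots,
            frame_blur: Optional[float] = None):
    """Compose the channels plus truth for one frame.

    ``frame_blur`` overrides per-spot blur flags with a single blur sigma
    applied to every spot (stack mode); ``None`` uses per-spot flags with
    ``cfg.blur_sigma``.
    """
    n = cfg.size
    shape = (n, n)
    red = np.full(shape, cfg.background, dtype=float)
    green = np.full(shape, cfg.background * 0.25, dtype=float)
    blue = np.full(shape, cfg.background * 0.25, dtype=float)

    texture = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, shape), 2.5, mode="reflect"
    )
    tex_sd = texture.std()
    if tex_sd > 0:
        texture *= cfg.texture_amplitude / tex_sd

    for cell in cells:
        body = _ellipse_mask(shape, cell)
        red[body] += cfg.cell_intensity + texture[body]
        nucleus = _ellipse_mask(shape, cell, scale=0.4)
        blue[nucleus] += cfg.nucleus_intensity

    truth_mask = np.zeros(shape, dtype=bool)
    truth_points = []
    rendered = []
    rr, cc = np.mgrid[0:n, 0:n]
    for spot in spots:
        sigma = spot["sigma"]
        if frame_blur is not None:
            extra = frame_blur
        else:
            extra = cfg.blur_sigma if spot["blurred"] else 0.0
        sigma_eff = float(np.hypot(sigma, extra))
        # energy-preserving defocus: amplitude drops as the profile widens
        amp = spot["peak"] * (sigma / sigma_eff) ** 2
        d2 = (rr - spot["row"]) ** 2 + (cc - spot["col"]) ** 2
        profile = amp * np.exp(-d2 / (2.0 * sigma_eff**2))
        green += profile
        in_focus = extra <= IN_FOCUS_FACTOR * sigma
        rendered.append({**spot, "blur_applied": extra, "in_focus": in_focus,
                         "amplitude": amp})
        if in_focus:
            truth_mask |= profile >= 0.5 * amp
            truth_points.append((spot["row"], spot["col"]))

    red = np.clip(red + rng.normal(0.0, cfg.noise_sd, shape), 0, None)
    green = np.clip(green + rng.normal(0.0, cfg.noise_sd, shape), 0, None)
    blue = np.clip(blue + rng.normal(0.0, cfg.noise_sd, shape), 0, None)

    n_truth = len(truth_points)
    if n_truth:
        _, n_comp = ndimage.label(truth_mask, structure=np.ones((3, 3), bool))
        if n_comp < n_truth:
            log.warning("truth mask: %d spots merged into %d components",
                        n_truth, n_comp)

    return SimScene(
        red=red, green=green, blue=blue,
        gray=rgb_to_gray(red, green, blue),
        truth_mask=BinaryMask(truth_mask),
        truth_points=PointList(
            np.asarray(truth_points, dtype=float).reshape(-1, 2)
        ),
        spots=rendered,
        config=cfg,
    )


def generate_scene(cfg: SimConfig) -> SimScene:
    """One scene: cells with textured cytoplasm and nuclei, Gaussian spots,
    optional per-spot defocus, additive noise — plus exact truth."""
    rng = _rng(cfg.seed)
    if cfg.empty_frame:
        return _render(cfg, rng, cells=[], spots=[])
    cells = _place_cells(cfg, rng)
    spots = _place_spots(cfg, rng, cells)
    return _render(cfg, rng, cells, spots)


def generate_stack(cfg: SimConfig, n_frames: int,
                   focus_profile: Sequence[float]) -> list:
    """A focal stack over one latent spot field.

    ``focus_profile`` gives the blur sigma applied to every spot in each
    frame; frames whose blur exceeds the in-focus criterion have empty
    truth, emulating scanning into and out of the objects' focal plane.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if len(focus_profile) != n_frames:
        raise ValueError("focus_profile must have one blur sigma per frame")
    rng = _rng(cfg.seed)
    cells = [] if cfg.empty_frame else _place_cells(cfg, rng)
    spots = [] if cfg.empty_frame else _place_spots(cfg, rng, cells)
    return [
        _render(cfg, rng, cells, spots, frame_blur=float(blur))
        for blur in focus_profile
    ]


def generate_doseplate(cfg: SimConfig, dose_levels: Sequence,
                       spots_per_cell_by_dose: Sequence[float],
                       images_per_dose: int = 2) -> list:
    """Images whose expected spots-per-cell follows a dose profile.

    Returns records ``{"dose", "image_index", "scene", "truth_count",
    "n_cells"}``; the nuclei channel is populated so downstream analysis
    can count cells.
    """
    if len(dose_levels) != len(spots_per_cell_by_dose):
        raise ValueError("dose_levels and profile must have equal length")
    records = []
    for d_idx, (dose, expected) in enumerate(
        zip(dose_levels, spots_per_cell_by_dose)
    ):
        for i in range(images_per_dose):
            seed = (cfg.seed, d_idx, i)
            rng = _rng(seed)
            sub = replace(cfg, empty_frame=False)
            cells = _place_cells(sub, rng)
            total = int(round(expected * len(cells)))
            spots = _place_spots(sub, rng, cells, total=total)
            scene = _render(sub, rng, cells, spots)
            records.append({
                "dose": dose,
                "image_index": i,
                "scene": scene,
                "truth_count": scene.truth_points.count,
                "n_cells": len(cells),
            })
    return records
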