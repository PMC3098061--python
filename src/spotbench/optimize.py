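"""Exhaustive grid-search tuning of detector parameters.

The objective is the micro-averaged F-score: tp/fp/fn are pooled over the
whole image set before scoring, because parameters must hold for the whole
screen rather than single images, and per-image F is ill-posed on empty
frames.  Tie-breaks are deterministic (first grid point in lexicographic
order of the axes as given).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .evaluation import ReferenceAnnotation, match_objects, pixel_score, score
from .methods import METHODS

__all__ = ["ParamGrid", "TuningResult", "grid_search", "sensitivity_surface",
           "default_grid"]


@dataclass(frozen=True)
class ParamGrid:
    """Per-parameter value lists for one method.

    Grid points violating a method's parameter invariants (e.g. the BPF
    cut-off ordering) are excluded before evaluation.
    """

    method_id: str
    axes: dict

    def __post_init__(self):
        if self.method_id.upper() not in METHODS:
            raise ValueError(f"unknown method {self.method_id!r}")
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("every grid axis needs at least one value")
        object.__setattr__(self, "method_id", self.method_id.upper())

    def points(self):
        """Feasible grid points, in lexicographic order of the given axes."""
        cls, _ = METHODS[self.method_id]
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            values = dict(zip(names, combo))
            try:
                params = cls(**values)
            except (ValueError, TypeError):
                continue
            yield values, params


@dataclass
class TuningResult:
    method_id: str
    level: str
    table: pd.DataFrame          # one row per grid point: params + counts + F
    best_params: dict = field(default_factory=dict)
    best_fscore: float = 0.0
    param_names: tuple = ()


def _evaluate_point(method_id, params, images, refs, level):
    _, detect = METHODS[method_id]
    tp = fp = fn = 0
    for img, ref in zip(images, refs):
        det = detect(img, params)
        if level == "object":
            t, f_, n = match_objects(det, ref)
        else:
            rep = pixel_score(det.mask, ref.mask)
            t, f_, n = rep.tp, rep.fp, rep.fn
        tp, fp, fn = tp + t, fp + f_, fn + n
    return tp, fp, fn, score(tp, fp, fn, level=level).fscore


def grid_search(images, refs, method_id, grid: ParamGrid,
                level: str = "object") -> TuningResult:
    """Evaluate every feasible grid point on the whole image set.

    Each grid point runs the detector with the same parameters on all
    images; counts are pooled and scored once.  Returns the arg-max with
    its full evaluation table.
    """
    if level not in ("object", "pixel"):
        raise ValueError("level must be 'object' or 'pixel'")
    images, refs = list(images), list(refs)
    if not images or len(images) != len(refs):
        raise ValueError("need equally many images and references (>= 1)")
    method_id = method_id.upper()
    if grid.method_id != method_id:
        raise ValueError("grid method does not match requested method")

    rows = []
    best = None
    for values, params in grid.points():
        tp, fp, fn, f = _evaluate_point(method_id, params, images, refs, level)
        rows.append({**values, "tp": tp, "fp": fp, "fn": fn, "fscore": f})
        if best is None or f > best[1]:
            best = (values, f)
    if best is None:
        raise ValueError("empty feasible grid")
    table = pd.DataFrame(rows)
    return TuningResult(
        method_id=method_id,
        level=level,
        table=table,
        best_params=best[0],
        best_fscore=best[1],
        param_names=tuple(grid.axes),
    )


def sensitivity_surface(result: TuningResult, param_x: str,
                        param_y: str | None = None) -> pd.DataFrame:
    """Profile-maximized F-score over one or two chosen parameters.

    For each value (pair) of the chosen parameter(s) the maximum F over
    all remaining parameters is reported — the heat-map view of a
    higher-dimensional grid.
    """
    for name in filter(None, (param_x, param_y)):
        if name not in result.param_names:
            raise ValueError(f"unknown parameter {name!r}")
    keys = [param_x] + ([param_y] if param_y else [])
    grouped = result.table.groupby(keys, sort=True)["fscore"].max()
    return grouped.reset_index()


#: Small default grids; ranges are this package's own choices, scaled for
#: desk-size images, and fully overridable from YAML configs.
_DEFAULT_AXES = {
    "BPF": {"cutoffs": [
        (0.01, 0.08, 0.35, 0.55),
        (0.02, 0.10, 0.45, 0.65),
        (0.05, 0.15, 0.55, 0.75),
        (0.02, 0.20, 0.60, 0.80),
    ]},
    "FPD": {"w": [2, 3], "r_pct": [5.0, 10.0, 25.0, 50.0], "T_s": [4.0]},
    "HD": {"sigma_L": [1.2], "h": [10.0, 25.0, 40.0],
           "sigma_M": [2.5, 3.5], "s": [2.0]},
    "KDE": {"radius": [1, 2], "h": [0.5, 1.0],
            "kernel_name": ["uniform", "gaussian"]},
    "LC": {"radius": [2, 3, 4], "alpha": [0.5, 0.6, 0.7, 0.85, 1.0]},
    "LEF": {"th_s": [2.0, 4.0, 8.0, 16.0, 32.0]},
    "MGI": {"d_max": [21]},
    "MW": {"J": [2, 3], "l_d": [0.5, 5.0, 50.0]},
    "SE": {"block_size": [32], "th_detect": [2.0, 4.0, 8.0],
           "th_bg": [0.0, 0.5], "gauss_sigma": [1.2]},
    "SPL": {"alpha": [1e-5, 1e-4, 1e-3, 1e-2]},
    "THE": {"r": [2, 3, 5]},
}


def default_grid(method_id: str) -> ParamGrid:
    method_id = method_id.upper()
    if method_id not in _DEFAULT_AXES:
        raise ValueError(f"no default grid for {method_id!r}")
    return ParamGrid(method_id, _DEFAULT_AXES[method_id])
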