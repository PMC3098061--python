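"""Registry mapping method ids to parameter types and detector callables."""

from __future__ import annotations

from .core_image import DetectionResult, GrayImage
from .detect_filtering import (
    BpfParams, KdeParams, LcParams, LefParams, MwParams, SeParams, TheParams,
    detect_bpf, detect_kde, detect_lc, detect_lef, detect_mw, detect_se,
    detect_the,
)
from .detect_morph import HdParams, detect_hd, detect_mgi
from .detect_point import FpdParams, SplParams, detect_fpd, detect_spl

__all__ = ["METHODS", "run_detector", "make_params"]


class _MgiParams:
    """Adapter giving parameter-free MGI the same constructor surface."""

    def __init__(self, d_max: int = 21, integral_fraction: float = 0.95):
        self.d_max = d_max
        self.integral_fraction = integral_fraction


def _run_mgi(img: GrayImage, p: _MgiParams) -> DetectionResult:
    return detect_mgi(img, d_max=p.d_max, integral_fraction=p.integral_fraction)


METHODS = {
    "BPF": (BpfParams, detect_bpf),
    "FPD": (FpdParams, detect_fpd),
    "HD": (HdParams, detect_hd),
    "KDE": (KdeParams, detect_kde),
    "LC": (LcParams, detect_lc),
    "LEF": (LefParams, detect_lef),
    "MGI": (_MgiParams, _run_mgi),
    "MW": (MwParams, detect_mw),
    "SE": (SeParams, detect_se),
    "SPL": (SplParams, detect_spl),
    "THE": (TheParams, detect_the),
}


def make_params(method_id: str, values: dict):
    """Build the parameter object for ``method_id`` from a name→value map."""
    method_id = method_id.upper()
    if method_id not in METHODS:
        raise ValueError(f"unknown method {method_id!r}")
    cls, _ = METHODS[method_id]
    return cls(**values)


def run_detector(img: GrayImage, method_id: str, params) -> DetectionResult:
    method_id = method_id.upper()
    if method_id not in METHODS:
        raise ValueError(f"unknown method {method_id!r}")
    cls, fn = METHODS[method_id]
    if isinstance(params, dict):
        params = cls(**params)
    return fn(img, params)
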