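"""Threshold triage: the cheap first stage of the hierarchical detector.

For each frame two scalars are extracted — v, the maximum tri-axial norm,
and w, the maximum horizontal-plane norm.  Four thresholds are learned from
the training distribution of (v, w):

* ``t_fall_xyz`` / ``t_fall_hori`` — the maximum v / w observed on ADL
  frames; exceeding both marks an *absolute fall*.
* ``t_adl_xyz`` / ``t_adl_hori`` — the minimum v / w observed on fall
  frames; staying below both marks an *absolute ADL*.

Everything else is *unidentified* and deferred to the knowledge-based
stage.  Inequalities are strict, so frames sitting exactly on a threshold
are deferred rather than decided.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Tuple

import numpy as np

from .preprocessing import frame_norms
from .signal_model import Frame

__all__ = ["FrameExtrema", "Thresholds", "TriageLabel", "frame_extrema", "fit_thresholds", "triage"]


class TriageLabel(Enum):
    FALL = "fall"
    ADL = "adl"
    UNIDENTIFIED = "unidentified"


@dataclass(frozen=True)
class FrameExtrema:
    """Frame maxima of the tri-axial (v) and horizontal (w) norms, in g."""

    v: float
    w: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v) and np.isfinite(self.w)):
            raise ValueError("frame extrema must be finite")
        if self.v < self.w - 1e-12 or self.w < 0:
            raise ValueError("extrema must satisfy v >= w >= 0")


@dataclass(frozen=True)
class Thresholds:
    """The four learned decision constants of the triage stage, in g."""

    t_fall_xyz: float
    t_fall_hori: float
    t_adl_xyz: float
    t_adl_hori: float

    def __post_init__(self) -> None:
        vals = (self.t_fall_xyz, self.t_fall_hori, self.t_adl_xyz, self.t_adl_hori)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("thresholds must be finite and non-negative")


def frame_extrema(frame: Frame) -> FrameExtrema:
    """Maximum tri-axial and horizontal norms over all 513 samples."""
    norms = frame_norms(frame)
    return FrameExtrema(v=float(norms.norm_xyz.max()), w=float(norms.norm_hori.max()))


def fit_thresholds(training: Iterable[Tuple[FrameExtrema, bool]]) -> Thresholds:
    """Learn the four thresholds from labeled training extrema.

    Parameters
    ----------
    training
        Pairs of (extrema, is_fall).  Both classes must be present.
    """
    fall_v, fall_w, adl_v, adl_w = [], [], [], []
    for ext, is_fall in training:
        (fall_v if is_fall else adl_v).append(ext.v)
        (fall_w if is_fall else adl_w).append(ext.w)
    if not fall_v:
        raise ValueError("cannot fit thresholds: no fall frames in training set")
    if not adl_v:
        raise ValueError("cannot fit thresholds: no ADL frames in training set")
    return Thresholds(
        t_fall_xyz=max(adl_v),
        t_fall_hori=max(adl_w),
        t_adl_xyz=min(fall_v),
        t_adl_hori=min(fall_w),
    )


def triage(extrema: FrameExtrema, thresholds: Thresholds) -> TriageLabel:
    """Three-way threshold classification of one frame (strict inequalities)."""
    if extrema.v > thresholds.t_fall_xyz and extrema.w > thresholds.t_fall_hori:
        return TriageLabel.FALL
    if extrema.v < thresholds.t_adl_xyz and extrema.w < thresholds.t_adl_hori:
        return TriageLabel.ADL
    return TriageLabel.UNIDENTIFIED
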