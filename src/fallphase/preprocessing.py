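"""Norm computation, critical-point location and fixed-window framing.

The classification unit is a 513-sample frame: the time index of the
record-wide maximum of the tri-axial Euclidean norm (the *critical point*)
plus 1.5 s (192 samples) of look-back and 2.5 s (320 samples) of look-ahead
at 128 Hz.  Three per-sample norms feed the later stages::

    norm_xyz   = sqrt(ax^2 + ay^2 + az^2)   total acceleration
    norm_hori  = sqrt(ay^2 + az^2)          horizontal (transverse) plane
    norm_verti = sqrt(ax^2 + ay^2)          coronal plane (configurable)

with x the vertical axis of a waist-worn sensor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .signal_model import (
    CRITICAL_INDEX,
    FRAME_LENGTH,
    POST_SAMPLES,
    PRE_SAMPLES,
    AccelRecord,
    Frame,
)

__all__ = [
    "NormSeries",
    "CriticalPoint",
    "compute_norms",
    "find_critical_point",
    "make_frame",
    "record_to_frame",
]

#: Default axis pair for the coronal-plane norm.
DEFAULT_CORONAL_PAIR: Tuple[str, str] = ("ax", "ay")


@dataclass(frozen=True)
class NormSeries:
    """Per-sample Euclidean norms of a record, in g."""

    norm_xyz: np.ndarray
    norm_hori: np.ndarray
    norm_verti: np.ndarray

    def __len__(self) -> int:
        return len(self.norm_xyz)


@dataclass(frozen=True)
class CriticalPoint:
    """Sample index of the record-wide maximum of ``norm_xyz``."""

    index: int
    value: float


def compute_norms(
    record: AccelRecord, coronal_pair: Tuple[str, str] = DEFAULT_CORONAL_PAIR
) -> NormSeries:
    """Compute the three per-sample Euclidean norms of a record."""
    comps = {"ax": record.ax, "ay": record.ay, "az": record.az}
    u, v = (comps[a] for a in coronal_pair)
    return NormSeries(
        norm_xyz=np.sqrt(record.ax**2 + record.ay**2 + record.az**2),
        norm_hori=np.sqrt(record.ay**2 + record.az**2),
        norm_verti=np.sqrt(u**2 + v**2),
    )


def find_critical_point(norms: NormSeries) -> CriticalPoint:
    """Locate the global maximum of ``norm_xyz``; ties break to the earliest index."""
    if len(norms) < 1:
        raise ValueError("cannot locate a critical point in an empty series")
    idx = int(np.argmax(norms.norm_xyz))  # np.argmax is first-wins on ties
    return CriticalPoint(index=idx, value=float(norms.norm_xyz[idx]))


def make_frame(
    record: AccelRecord,
    critical: CriticalPoint,
    pad_policy: str = "replicate",
) -> Frame:
    """Cut the 513-sample window around the critical point.

    The window spans record indices ``critical.index - 192`` through
    ``critical.index + 320`` inclusive.  Positions outside the record are
    filled by replicating the boundary sample (``pad_policy="replicate"``,
    pad counts recorded on the frame) or the call is rejected
    (``pad_policy="reject"``).
    """
    n = len(record)
    c = critical.index
    if not 0 <= c < n:
        raise ValueError(f"critical index {c} outside record of length {n}")
    start, stop = c - PRE_SAMPLES, c + POST_SAMPLES  # inclusive
    pad_left = max(0, -start)
    pad_right = max(0, stop - (n - 1))
    if pad_policy == "reject":
        if pad_left or pad_right:
            raise ValueError(
                f"window [{start}, {stop}] exceeds record bounds [0, {n - 1}] "
                "and pad_policy is 'reject'"
            )
    elif pad_policy != "replicate":
        raise ValueError(f"unknown pad_policy {pad_policy!r}")
    idx = np.clip(np.arange(start, stop + 1), 0, n - 1)
    return Frame(
        ax=record.ax[idx],
        ay=record.ay[idx],
        az=record.az[idx],
        sample_rate=record.sample_rate,
        pad_left=pad_left,
        pad_right=pad_right,
        source=record.subject_id,
        label=record.label,
    )


def record_to_frame(record: AccelRecord, pad_policy: str = "replicate") -> Frame:
    """Convenience: norms -> critical point -> frame, one frame per record."""
    return make_frame(record, find_critical_point(compute_norms(record)), pad_policy)


def frame_norms(
    frame: Frame, coronal_pair: Tuple[str, str] = DEFAULT_CORONAL_PAIR
) -> NormSeries:
    """Per-sample norms of a frame (same definitions as :func:`compute_norms`)."""
    comps = {"ax": frame.ax, "ay": frame.ay, "az": frame.az}
    u, v = (comps[a] for a in coronal_pair)
    return NormSeries(
        norm_xyz=np.sqrt(frame.ax**2 + frame.ay**2 + frame.az**2),
        norm_hori=np.sqrt(frame.ay**2 + frame.az**2),
        norm_verti=np.sqrt(u**2 + v**2),
    )
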