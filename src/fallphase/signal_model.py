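"""Domain types and on-disk formats for tri-axial accelerometer data.

A recording is a continuous tri-axial acceleration time series in units of
g (1 g = 9.81 m/s^2) at a fixed sampling rate (128 Hz by default, the rate
of waist-worn inertial sensors used in fall studies).  Records travel as
plain CSV files with a ``time,ax,ay,az`` header; ground-truth activity
labels live in a sidecar manifest (``path,label,subject``) so that one
record format serves labeled and unlabeled data alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "G_MS2",
    "FRAME_LENGTH",
    "CRITICAL_INDEX",
    "PRE_SAMPLES",
    "POST_SAMPLES",
    "FALL_ACTIVITIES",
    "ADL_ACTIVITIES",
    "AccelRecord",
    "ActivityLabel",
    "Frame",
    "ManifestEntry",
    "read_record",
    "write_record",
    "read_manifest",
    "write_manifest",
]

#: Standard gravity, m/s^2 per g.
G_MS2 = 9.81

#: Samples kept before the critical point (1.5 s at 128 Hz).
PRE_SAMPLES = 192
#: Samples kept after the critical point (2.5 s at 128 Hz).
POST_SAMPLES = 320
#: Classification window: PRE_SAMPLES + critical point + POST_SAMPLES.
FRAME_LENGTH = PRE_SAMPLES + 1 + POST_SAMPLES  # 513
#: 0-based position of the critical point inside a frame.
CRITICAL_INDEX = PRE_SAMPLES  # 192

#: Fall archetypes — named by the activity being performed when the fall
#: starts.  All map to the positive (fall) class.
FALL_ACTIVITIES = (
    "stand",
    "stand up",
    "sit down",
    "walk",
    "stoop",
    "jump",
    "walk backward",
)

#: Activities of daily living — the negative class.
ADL_ACTIVITIES = (
    "stand from sit",
    "stand from squat",
    "sit (normal)",
    "sit (fast)",
    "lie (normal)",
    "lie (fast)",
    "go upstairs",
    "go downstairs",
    "walk (normal)",
    "walk (fast)",
    "jump (ground)",
    "jump (bed)",
)

_TIMESTAMP_TOL = 1e-9


@dataclass(frozen=True)
class ActivityLabel:
    """An activity name with its ground-truth class.

    ``name`` is normally one of the registered fall/ADL vocabulary entries;
    unknown names are allowed but flagged ``custom`` and must carry an
    explicit ``is_fall``.
    """

    name: str
    is_fall: bool
    custom: bool = False

    @classmethod
    def from_name(cls, name: str, is_fall: Optional[bool] = None) -> "ActivityLabel":
        """Resolve ``name`` against the registered vocabulary.

        Unknown names produce a warning and a ``custom`` label; in that case
        ``is_fall`` defaults to False unless given.
        """
        key = name.strip().lower()
        if key in FALL_ACTIVITIES:
            return cls(key, True)
        if key in ADL_ACTIVITIES:
            return cls(key, False)
        warnings.warn(f"unknown activity name {name!r}; treating as custom label")
        return cls(name.strip(), bool(is_fall) if is_fall is not None else False, custom=True)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class AccelRecord:
    """A continuous tri-axial acceleration time series in g.

    Parameters
    ----------
    ax, ay, az
        Acceleration components in g, equal length >= 1.
    sample_rate
        Sampling rate in Hz (default 128).
    t
        Timestamps in seconds.  Synthesized as ``i / sample_rate`` when
        omitted; when given they must be uniform at the sampling interval.
    label
        Optional ground-truth activity label.
    subject_id
        Optional subject identifier.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float = 128.0
    t: Optional[np.ndarray] = None
    label: Optional[ActivityLabel] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.ax = _as_float_array(self.ax, "ax")
        self.ay = _as_float_array(self.ay, "ay")
        self.az = _as_float_array(self.az, "az")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = len(self.ax)
        if n < 1:
            raise ValueError("record must contain at least one sample")
        if not (len(self.ay) == len(self.az) == n):
            raise ValueError("ax, ay, az must have identical length")
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.t is None:
            self.t = np.arange(n) / self.sample_rate
        else:
            self.t = _as_float_array(self.t, "t")
            if len(self.t) != n:
                raise ValueError("t must match the acceleration length")
            if n > 1:
                dt = np.diff(self.t)
                if np.any(np.abs(dt - 1.0 / self.sample_rate) > _TIMESTAMP_TOL):
                    raise ValueError(
                        "timestamps are not uniform at 1/sample_rate "
                        f"(tolerance {_TIMESTAMP_TOL} s)"
                    )

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array of the acceleration components."""
        return np.column_stack([self.ax, self.ay, self.az])

    def equals(self, other: "AccelRecord", atol: float = 1e-12) -> bool:
        """Field-by-field equality of the signal content within ``atol`` g."""
        if len(self) != len(other) or self.sample_rate != other.sample_rate:
            return False
        return all(
            np.allclose(a, b, rtol=0.0, atol=atol)
            for a, b in ((self.ax, other.ax), (self.ay, other.ay), (self.az, other.az))
        )


@dataclass
class Frame:
    """A fixed 513-sample window around the critical point.

    The critical point (record-wide maximum of the tri-axial norm) always
    sits at local index 192; the window spans 192 samples before it and 320
    after.  ``pad_left``/``pad_right`` count boundary-replicated samples
    when the source record did not fully cover the window.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float = 128.0
    pad_left: int = 0
    pad_right: int = 0
    source: Optional[str] = None
    label: Optional[ActivityLabel] = None

    critical_index: int = field(default=CRITICAL_INDEX, init=False)

    def __post_init__(self) -> None:
        self.ax = _as_float_array(self.ax, "ax")
        self.ay = _as_float_array(self.ay, "ay")
        self.az = _as_float_array(self.az, "az")
        if not (len(self.ax) == len(self.ay) == len(self.az) == FRAME_LENGTH):
            raise ValueError(f"frame must contain exactly {FRAME_LENGTH} samples")
        if self.pad_left < 0 or self.pad_right < 0:
            raise ValueError("pad counts must be non-negative")

    def __len__(self) -> int:
        return FRAME_LENGTH

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    label: ActivityLabel
    subject_id: Optional[str] = None


def read_record(
    path: Union[str, Path],
    sample_rate: float = 128.0,
    units: str = "g",
    label: Optional[ActivityLabel] = None,
    subject_id: Optional[str] = None,
) -> AccelRecord:
    """Read a tri-axial record from CSV.

    The file must have a header naming ``ax``, ``ay`` and ``az`` columns
    (a ``time`` column is optional — timestamps are regenerated from
    ``sample_rate`` when absent).  ``units="ms2"`` converts m/s^2 inputs
    to g on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV: report file and cause
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [axis for axis in ("ax", "ay", "az") if axis not in cols]
    if missing:
        raise ValueError(f"{path}: missing axis column(s) {missing} in header {list(df.columns)}")
    scale = 1.0 / G_MS2 if units == "ms2" else 1.0
    if units not in ("g", "ms2"):
        raise ValueError(f"unknown units {units!r}; expected 'g' or 'ms2'")
    t = df[cols["time"]].to_numpy(dtype=float) if "time" in cols else None
    return AccelRecord(
        ax=df[cols["ax"]].to_numpy(dtype=float) * scale,
        ay=df[cols["ay"]].to_numpy(dtype=float) * scale,
        az=df[cols["az"]].to_numpy(dtype=float) * scale,
        sample_rate=sample_rate,
        t=t,
        label=label,
        subject_id=subject_id,
    )


def write_record(record: AccelRecord, path: Union[str, Path]) -> Path:
    """Write a record as ``time,ax,ay,az`` CSV; round-trips within 1e-12 g."""
    path = Path(path)
    df = pd.DataFrame(
        {"time": record.t, "ax": record.ax, "ay": record.ay, "az": record.az}
    )
    df.to_csv(path, index=False)  # default float repr preserves all digits
    return path


def read_manifest(path: Union[str, Path], check_files: bool = True) -> list[ManifestEntry]:
    """Read a ``path,label,subject`` manifest; paths resolve relative to it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("path", "label"):
        if required not in cols:
            raise ValueError(f"{path}: manifest lacks a {required!r} column")
    entries: list[ManifestEntry] = []
    for _, row in df.iterrows():
        rec_path = path.parent / str(row[cols["path"]])
        if check_files and not rec_path.exists():
            raise FileNotFoundError(f"manifest {path} references missing record {rec_path}")
        subject = None
        if "subject" in cols and not pd.isna(row[cols["subject"]]):
            subject = str(row[cols["subject"]])
        entries.append(
            ManifestEntry(rec_path, ActivityLabel.from_name(str(row[cols["label"]])), subject)
        )
    return entries


def write_manifest(entries: Sequence[ManifestEntry], path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "path": [str(Path(e.path).name) for e in entries],
            "label": [e.label.name for e in entries],
            "subject": [e.subject_id if e.subject_id is not None else "" for e in entries],
        }
    )
    df.to_csv(path, index=False)
    return path
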