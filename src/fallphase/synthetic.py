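"""Synthetic tri-axial accelerometer signals for falls and daily activities.

Real fall recordings are scarce and rarely shareable, so this module
generates labeled records that reproduce the *signal structure* the
detector relies on, with per-sample phase ground truth:

* a **fall** is pre-fall activity, then a free-fall dip of the norm toward
  0 g (durations reported across the fall literature span roughly
  0.12–0.8 s), then a sharp half-sine impact pulse (sub-second) at a
  configurable peak, then motionless rest at 1 g static in a lying
  orientation with a decaying ring-down;
* an **ADL** follows one of twelve archetypes — periodic gait near 1 g for
  walking and stairs, a single moderate transient for sit/stand/lie
  transitions, repeated bounces for jumping.

Severities are chosen so the two classes overlap: lie-on-the-bed (fast)
transients reach into the mild-fall peak band, so the threshold stage alone
cannot separate them and the knowledge-based stage is genuinely exercised.
The generator targets signal statistics, not biomechanical fidelity; all
shape parameters are exposed on :class:`SimConfig`.  Fixed seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

from .signal_model import (
    ADL_ACTIVITIES,
    FALL_ACTIVITIES,
    AccelRecord,
    ActivityLabel,
    ManifestEntry,
    write_manifest,
    write_record,
)

__all__ = [
    "SimConfig",
    "AnnotatedRecord",
    "gen_fall",
    "gen_adl",
    "gen_dataset",
    "save_dataset",
    "PHASE_TAGS",
]

#: Per-sample ground-truth phase tags.
PHASE_TAGS = ("PreFall", "FreeFall", "Impact", "Rest", "None")

#: Default fall impact-peak bands, in g: mild (below the 6 g severity
#: boundary) and severe (above it), alternated when no mix is given.
MILD_PEAK_BAND = (3.3, 5.5)
SEVERE_PEAK_BAND = (6.2, 8.0)

#: Free-fall durations reported for falls, in seconds.
FREE_FALL_BAND = (0.12, 0.8)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Durations are seconds, accelerations g.  ``None`` for
    ``free_fall_duration``, ``impact_peak`` or ``impact_duration`` means
    "draw from the default band" per record.
    """

    sample_rate: float = 128.0
    free_fall_duration: Optional[float] = None  # drawn from FREE_FALL_BAND
    impact_peak: Optional[float] = None  # drawn from the severity mix
    impact_duration: Optional[float] = None  # drawn from (0.1, 0.35)
    rest_duration: float = 3.0
    pre_fall_duration: float = 2.0
    noise_sd: float = 0.03
    orientation: Tuple[float, float, float] = (1.0, 0.0, 0.0)  # gravity, upright
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rest_duration", "pre_fall_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("free_fall_duration", "impact_duration", "impact_peak"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.impact_duration is not None and self.impact_duration >= 1.0:
            raise ValueError("impact_duration must be below one second")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class AnnotatedRecord:
    """A generated record with per-sample phase ground truth."""

    record: AccelRecord
    phase_truth: np.ndarray  # strings from PHASE_TAGS, one per sample
    label: ActivityLabel

    def __post_init__(self) -> None:
        self.phase_truth = np.asarray(self.phase_truth, dtype=object)
        if len(self.phase_truth) != len(self.record):
            raise ValueError("phase_truth must match the record length")


def _unit(vec: np.ndarray) -> np.ndarray:
    return vec / np.linalg.norm(vec)


def _direction(rng: np.random.Generator, hori_frac: float) -> np.ndarray:
    """Unit vector whose (y, z) horizontal component has norm ``hori_frac``."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    vert = np.sqrt(max(0.0, 1.0 - hori_frac**2))
    return np.array([vert, hori_frac * np.cos(phi), hori_frac * np.sin(phi)])


def _gait(
    n: int, fs: float, rng: np.random.Generator, grav: np.ndarray,
    amp: float, freq: float, noise_sd: float,
) -> np.ndarray:
    """Periodic locomotion: vertical bounce + harmonic + horizontal sway."""
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    vert = amp * np.sin(2 * np.pi * freq * t + phase) + 0.3 * amp * np.sin(
        4 * np.pi * freq * t + phase
    )
    sway = 0.15 * np.sin(2 * np.pi * freq / 2 * t + phase / 2)
    sig = np.outer(np.ones(n), grav)
    sig += np.outer(vert, grav)  # bounce along the gravity (vertical) axis
    sig[:, 1] += sway
    sig += rng.normal(0.0, noise_sd, size=(n, 3))
    return sig


def _static(
    n: int, rng: np.random.Generator, grav: np.ndarray, noise_sd: float, sway: float = 0.02
) -> np.ndarray:
    sig = np.outer(np.ones(n), grav)
    if n > 1:
        t = np.linspace(0.0, 1.0, n)
        sig[:, 0] += sway * np.sin(2 * np.pi * t * 0.7)
    sig += rng.normal(0.0, noise_sd, size=(n, 3))
    return sig


def _half_sine_pulse(n: int, peak: float, direction: np.ndarray) -> np.ndarray:
    """Pulse whose norm peaks exactly at ``peak`` at the center sample."""
    w = np.sin(np.pi * np.arange(n) / (n - 1))
    return np.outer(peak * w, direction)


def _prefall_segment(
    fall_type: str, n: int, fs: float, rng: np.random.Generator,
    grav: np.ndarray, noise_sd: float,
) -> np.ndarray:
    if fall_type in ("walk", "walk backward"):
        return _gait(n, fs, rng, grav, amp=0.3, freq=2.0, noise_sd=noise_sd)
    if fall_type == "jump":
        return _gait(n, fs, rng, grav, amp=0.6, freq=1.6, noise_sd=noise_sd)
    if fall_type in ("stand up", "sit down", "stoop"):
        return _static(n, rng, grav, noise_sd, sway=0.2)
    return _static(n, rng, grav, noise_sd)  # stand


def gen_fall(config: SimConfig = SimConfig(), fall_type: str = "stand") -> AnnotatedRecord:
    """Generate one fall record: pre-fall -> free fall -> impact -> rest."""
    if fall_type not in FALL_ACTIVITIES:
        raise ValueError(f"unknown fall archetype {fall_type!r}; choose from {FALL_ACTIVITIES}")
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    grav = _unit(np.asarray(config.orientation, dtype=float))

    dur_ff = config.free_fall_duration or rng.uniform(*FREE_FALL_BAND)
    peak = config.impact_peak or rng.uniform(*MILD_PEAK_BAND)
    dur_imp = config.impact_duration or rng.uniform(0.1, 0.35)

    n_pre = int(round(config.pre_fall_duration * fs))
    n_ff = max(4, int(round(dur_ff * fs)))
    n_imp = max(5, int(round(dur_imp * fs)))
    if n_imp % 2 == 0:
        n_imp += 1  # odd length so the half-sine peak lands on a sample
    n_rest = int(round(config.rest_duration * fs))

    pre = _prefall_segment(fall_type, n_pre, fs, rng, grav, config.noise_sd)

    # Free fall: the norm collapses quickly toward ~0.1 g and stays there.
    p = np.linspace(0.0, 1.0, n_ff)
    level = np.where(p < 0.15, 1.0 - p / 0.15 * 0.7, 0.3 - (p - 0.15) / 0.85 * 0.22)
    ff = np.outer(level, grav) + rng.normal(0.0, config.noise_sd, size=(n_ff, 3))

    # Impact: half-sine pulse along a direction with substantial horizontal
    # content (falls topple, they do not drop straight down).
    d_imp = _direction(rng, rng.uniform(0.35, 0.9))
    imp = _half_sine_pulse(n_imp, peak, d_imp)
    imp += rng.normal(0.0, config.noise_sd, size=(n_imp, 3))

    # Rest: static 1 g in a lying orientation plus a decaying ring-down.
    lying = _direction(rng, rng.uniform(0.9, 0.999))
    t_rest = np.arange(n_rest) / fs
    ring = min(1.2, 0.25 * peak) * np.exp(-t_rest / 0.25) * np.sin(2 * np.pi * 8.0 * t_rest)
    rest = np.outer(np.ones(n_rest), lying) + np.outer(ring, d_imp)
    rest += rng.normal(0.0, config.noise_sd, size=(n_rest, 3))

    sig = np.vstack([pre, ff, imp, rest])
    truth = np.concatenate(
        [
            np.repeat("PreFall", n_pre),
            np.repeat("FreeFall", n_ff),
            np.repeat("Impact", n_imp),
            np.repeat("Rest", n_rest),
        ]
    ).astype(object)
    label = ActivityLabel(fall_type, True)
    record = AccelRecord(
        ax=sig[:, 0], ay=sig[:, 1], az=sig[:, 2],
        sample_rate=fs, label=label,
    )
    return AnnotatedRecord(record=record, phase_truth=truth, label=label)


def _transient_adl(
    rng: np.random.Generator, fs: float, noise_sd: float, grav: np.ndarray,
    peak_band: Tuple[float, float], hori_band: Tuple[float, float],
    lying_after: bool, pre_s: float = 2.0, post_s: float = 2.8,
) -> np.ndarray:
    """Single moderate transition bump on a 1 g baseline (sit/stand/lie)."""
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n_tr = int(round(0.4 * fs))
    if n_tr % 2 == 0:
        n_tr += 1
    peak = rng.uniform(*peak_band)
    d = _direction(rng, rng.uniform(*hori_band))
    pre = _static(n_pre, rng, grav, noise_sd, sway=0.08)
    tr = np.outer(np.ones(n_tr), grav) + _half_sine_pulse(n_tr, peak - 1.0, d)
    tr += rng.normal(0.0, noise_sd, size=(n_tr, 3))
    grav_after = _direction(rng, rng.uniform(0.9, 0.999)) if lying_after else grav
    post = _static(n_post, rng, grav_after, noise_sd, sway=0.05)
    return np.vstack([pre, tr, post])


def _jump_adl(
    rng: np.random.Generator, fs: float, noise_sd: float, grav: np.ndarray,
    peak_band: Tuple[float, float], dip_level: float, total_s: float = 6.0,
) -> np.ndarray:
    """Repeated bounces: brief low-norm flight then a vertical landing spike."""
    n = int(round(total_s * fs))
    sig = _static(n, rng, grav, noise_sd, sway=0.1)
    period = int(round(fs / 1.6))
    n_dip = int(round(0.12 * fs))
    n_spk = int(round(0.1 * fs))
    if n_spk % 2 == 0:
        n_spk += 1
    start = int(round(0.8 * fs))
    while start + n_dip + n_spk < n - int(fs):
        sig[start : start + n_dip] = np.outer(
            np.full(n_dip, dip_level), grav
        ) + rng.normal(0.0, noise_sd, size=(n_dip, 3))
        peak = rng.uniform(*peak_band)
        d = _direction(rng, rng.uniform(0.05, 0.3))
        s = start + n_dip
        sig[s : s + n_spk] = _half_sine_pulse(n_spk, peak, d) + rng.normal(
            0.0, noise_sd, size=(n_spk, 3)
        )
        start += period
    return sig


def gen_adl(config: SimConfig = SimConfig(), adl_type: str = "walk (normal)") -> AnnotatedRecord:
    """Generate one ADL record matching the named archetype."""
    if adl_type not in ADL_ACTIVITIES:
        raise ValueError(f"unknown ADL archetype {adl_type!r}; choose from {ADL_ACTIVITIES}")
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    grav = _unit(np.asarray(config.orientation, dtype=float))
    noise = config.noise_sd

    if adl_type in ("walk (normal)", "walk (fast)", "go upstairs", "go downstairs"):
        amp, freq = {
            "walk (normal)": (0.35, 2.0),
            "walk (fast)": (0.5, 2.5),
            "go upstairs": (0.45, 1.8),
            "go downstairs": (0.5, 1.9),
        }[adl_type]
        sig = _gait(int(round(7.0 * fs)), fs, rng, grav, amp=amp, freq=freq, noise_sd=noise)
    elif adl_type in ("stand from sit", "stand from squat", "sit (normal)"):
        sig = _transient_adl(rng, fs, noise, grav, (1.4, 2.2), (0.05, 0.3), lying_after=False)
    elif adl_type == "sit (fast)":
        sig = _transient_adl(rng, fs, noise, grav, (2.0, 3.0), (0.05, 0.3), lying_after=False)
    elif adl_type == "lie (normal)":
        sig = _transient_adl(rng, fs, noise, grav, (1.8, 2.8), (0.3, 0.8), lying_after=True)
    elif adl_type == "lie (fast)":
        # The hardest negative: a brisk drop onto the bed reaches into the
        # mild-fall peak band and carries fall-like horizontal content.
        sig = _transient_adl(rng, fs, noise, grav, (2.5, 4.0), (0.3, 0.8), lying_after=True)
    elif adl_type == "jump (ground)":
        sig = _jump_adl(rng, fs, noise, grav, (2.0, 3.2), dip_level=0.6)
    else:  # jump (bed)
        sig = _jump_adl(rng, fs, noise, grav, (1.8, 2.6), dip_level=0.75)

    label = ActivityLabel(adl_type, False)
    record = AccelRecord(
        ax=sig[:, 0], ay=sig[:, 1], az=sig[:, 2], sample_rate=fs, label=label
    )
    truth = np.repeat("None", len(record)).astype(object)
    return AnnotatedRecord(record=record, phase_truth=truth, label=label)


SeverityMix = Union[None, Tuple[float, float], Sequence[float], Callable[[np.random.Generator], float]]


def _draw_peak(mix: SeverityMix, i: int, rng: np.random.Generator) -> float:
    if mix is None:
        # Alternate mild and severe so both impact-phase branches occur.
        return rng.uniform(*(MILD_PEAK_BAND if i % 2 == 0 else SEVERE_PEAK_BAND))
    if callable(mix):
        return float(mix(rng))
    if isinstance(mix, tuple) and len(mix) == 2:
        return float(rng.uniform(*mix))
    return float(mix[i % len(mix)])


def gen_dataset(
    n_falls: int,
    n_adls: int,
    severity_mix: SeverityMix = None,
    seed: int = 0,
    config: SimConfig = SimConfig(),
    n_subjects: int = 8,
) -> list[AnnotatedRecord]:
    """Generate a reproducible mixed dataset cycling over all archetypes.

    Fall impact peaks come from ``severity_mix``: ``None`` alternates the
    mild and severe default bands, a ``(lo, hi)`` tuple draws uniformly, a
    sequence is cycled, a callable is invoked with the RNG.
    """
    if n_falls < 0 or n_adls < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[AnnotatedRecord] = []
    for i in range(n_falls):
        child = replace(
            config,
            seed=int(rng.integers(2**31)),
            impact_peak=_draw_peak(severity_mix, i, rng),
        )
        ann = gen_fall(child, FALL_ACTIVITIES[i % len(FALL_ACTIVITIES)])
        ann.record.subject_id = f"sim{i % n_subjects + 1:02d}"
        records.append(ann)
    for i in range(n_adls):
        child = replace(config, seed=int(rng.integers(2**31)))
        ann = gen_adl(child, ADL_ACTIVITIES[i % len(ADL_ACTIVITIES)])
        ann.record.subject_id = f"sim{i % n_subjects + 1:02d}"
        records.append(ann)
    return records


def save_dataset(records: Sequence[AnnotatedRecord], out_dir: Union[str, Path]) -> Path:
    """Write records, per-sample annotations and the manifest to a directory.

    Returns the manifest path.  Layout: ``rec_NNNN.csv`` signal files,
    ``ann_NNNN.csv`` (index,phase) annotations, ``manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, ann in enumerate(records):
        rec_path = out_dir / f"rec_{i:04d}.csv"
        write_record(ann.record, rec_path)
        import pandas as pd

        pd.DataFrame(
            {"index": np.arange(len(ann.record)), "phase": ann.phase_truth}
        ).to_csv(out_dir / f"ann_{i:04d}.csv", index=False)
        entries.append(ManifestEntry(rec_path, ann.label, ann.record.subject_id))
    return write_manifest(entries, out_dir / "manifest.csv")
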