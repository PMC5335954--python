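"""Multiphase fall segmentation and time-domain feature extraction.

A fall frame decomposes into three semantic phases around the critical
point (local index 192):

* **free fall** — 32 samples immediately before the impact phase; the body
  accelerates toward the ground and the norm approaches 0 g;
* **impact** — the sharp pulse around the critical point.  Its length
  depends on severity: 21 samples (10 + critical + 10) when the frame's
  maximum norm exceeds 6 g, 31 samples (10 + critical + 20) otherwise —
  6 g is the full-scale range of the waist sensors this convention models,
  so a peak at or beyond it indicates saturation and the severe branch;
* **rest** — everything after the impact phase to the end of the frame;
  motionless lying near 1 g static.

From a whole frame or any phase, 54 time-domain statistics are extracted:
mean, standard deviation, variance, maximum, minimum, range, kurtosis and
skewness of the six signals (ax, ay, az and the tri-axial, coronal and
horizontal norms), plus the six pairwise correlation coefficients
(ax–ay, ax–az, ay–az, norm–coronal, norm–horizontal, coronal–horizontal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

import numpy as np
from scipy import stats

from .preprocessing import DEFAULT_CORONAL_PAIR, frame_norms
from .signal_model import CRITICAL_INDEX, FRAME_LENGTH, Frame

__all__ = [
    "SEVERITY_SPLIT_G",
    "IMPACT_BEFORE",
    "IMPACT_AFTER_SEVERE",
    "IMPACT_AFTER_MILD",
    "FREE_FALL_LENGTH",
    "N_FEATURES",
    "Severity",
    "PhaseName",
    "PhaseSegmentation",
    "FeatureConfig",
    "segment_phases",
    "extract_features",
    "featurize_frame",
    "featurize_phases",
    "feature_names",
]

#: Impact severity boundary on the frame's maximum tri-axial norm, in g.
SEVERITY_SPLIT_G = 6.0
#: Impact samples taken before the critical point.
IMPACT_BEFORE = 10
#: Impact samples taken after the critical point, by severity.
IMPACT_AFTER_SEVERE = 10  # total 21 = 10 + critical + 10
IMPACT_AFTER_MILD = 20  # total 31 = 10 + critical + 20
#: Free-fall phase length, immediately before the impact phase.
FREE_FALL_LENGTH = 32
#: Dimension of the time-domain feature vector.
N_FEATURES = 54


class Severity(Enum):
    SEVERE = "severe"  # max norm >= 6 g, 21-sample impact
    MILD = "mild"  # max norm < 6 g, 31-sample impact


class PhaseName(Enum):
    FREE_FALL = "FreeFall"
    IMPACT = "Impact"
    REST = "Rest"


Span = Tuple[int, int]  # inclusive (start, stop) local indices


@dataclass(frozen=True)
class PhaseSegmentation:
    """Contiguous free-fall / impact / rest index spans of one frame."""

    free_fall: Span
    impact: Span
    rest: Span
    situation: Severity

    def span(self, phase: PhaseName) -> Span:
        return {
            PhaseName.FREE_FALL: self.free_fall,
            PhaseName.IMPACT: self.impact,
            PhaseName.REST: self.rest,
        }[phase]

    @staticmethod
    def length(span: Span) -> int:
        return span[1] - span[0] + 1


def segment_phases(frame: Frame) -> PhaseSegmentation:
    """Partition a frame into free-fall, impact and rest phases.

    The impact phase straddles the critical point; its post-critical extent
    switches on whether the frame's maximum norm reaches 6 g (peaks exactly
    at 6 g take the severe branch).  The free-fall phase is the 32 samples
    before the impact phase; the rest phase runs from the sample after the
    impact phase to the end of the frame.
    """
    peak = float(frame_norms(frame).norm_xyz.max())
    severe = peak >= SEVERITY_SPLIT_G
    after = IMPACT_AFTER_SEVERE if severe else IMPACT_AFTER_MILD
    impact = (CRITICAL_INDEX - IMPACT_BEFORE, CRITICAL_INDEX + after)
    free_fall = (impact[0] - FREE_FALL_LENGTH, impact[0] - 1)
    rest = (impact[1] + 1, FRAME_LENGTH - 1)
    return PhaseSegmentation(
        free_fall=free_fall,
        impact=impact,
        rest=rest,
        situation=Severity.SEVERE if severe else Severity.MILD,
    )


@dataclass(frozen=True)
class FeatureConfig:
    """Estimator conventions for the statistical features.

    ddof
        Delta degrees of freedom of variance/std (1 = sample estimator).
    excess_kurtosis
        False (default) reports Pearson kurtosis (normal = 3); True
        subtracts 3.
    bias_corrected_moments
        Apply small-sample bias correction to skewness/kurtosis.
    coronal_pair
        Axis pair defining the coronal-plane norm.
    """

    ddof: int = 1
    excess_kurtosis: bool = False
    bias_corrected_moments: bool = False
    coronal_pair: Tuple[str, str] = DEFAULT_CORONAL_PAIR


def _signals(ax: np.ndarray, ay: np.ndarray, az: np.ndarray, config: FeatureConfig):
    comps = {"ax": ax, "ay": ay, "az": az}
    u, v = (comps[a] for a in config.coronal_pair)
    a_norm = np.sqrt(ax**2 + ay**2 + az**2)
    a_verti = np.sqrt(u**2 + v**2)
    a_hori = np.sqrt(ay**2 + az**2)
    return ax, ay, az, a_norm, a_verti, a_hori


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    # Zero-variance input (e.g. a motionless rest phase) yields 0 by
    # convention so downstream classifiers never see NaNs.
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _moment_or_zero(func, x: np.ndarray, **kw) -> float:
    if np.ptp(x) == 0.0:
        return 0.0  # degenerate: constant signal
    return float(func(x, **kw))


def extract_features(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Compute the 54 time-domain statistics of a tri-axial segment.

    Segments shorter than 2 samples are rejected (dispersion statistics are
    undefined).  Returns the features in canonical f1..f54 order.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    m = len(ax)
    if not (len(ay) == len(az) == m):
        raise ValueError("segment axes must have identical length")
    if m < 2:
        raise ValueError(f"segment too short for feature extraction (m={m} < 2)")
    sigs = _signals(ax, ay, az, config)
    feats: list[float] = []
    feats += [float(np.mean(s)) for s in sigs]
    feats += [float(np.std(s, ddof=config.ddof)) for s in sigs]
    feats += [float(np.var(s, ddof=config.ddof)) for s in sigs]
    feats += [float(np.max(s)) for s in sigs]
    feats += [float(np.min(s)) for s in sigs]
    feats += [float(np.ptp(s)) for s in sigs]
    feats += [
        _moment_or_zero(
            stats.kurtosis,
            s,
            fisher=config.excess_kurtosis,
            bias=not config.bias_corrected_moments,
        )
        for s in sigs
    ]
    feats += [
        _moment_or_zero(stats.skew, s, bias=not config.bias_corrected_moments)
        for s in sigs
    ]
    a_x, a_y, a_z, a_norm, a_verti, a_hori = sigs
    feats += [
        _corr(a_x, a_y),
        _corr(a_x, a_z),
        _corr(a_y, a_z),
        _corr(a_norm, a_verti),
        _corr(a_norm, a_hori),
        _corr(a_verti, a_hori),
    ]
    out = np.asarray(feats, dtype=float)
    assert out.shape == (N_FEATURES,)
    return out


def featurize_frame(frame: Frame, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Feature vector of the whole 513-sample frame (m = 513)."""
    return extract_features(frame.ax, frame.ay, frame.az, config)


def featurize_phases(
    frame: Frame,
    seg: PhaseSegmentation,
    config: FeatureConfig = FeatureConfig(),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One feature vector per phase, in order free-fall, impact, rest."""
    out = []
    for span in (seg.free_fall, seg.impact, seg.rest):
        sl = slice(span[0], span[1] + 1)
        out.append(extract_features(frame.ax[sl], frame.ay[sl], frame.az[sl], config))
    return tuple(out)


_STATS = ("mean", "std", "var", "max", "min", "range", "kurtosis", "skewness")
_SIGNAL_NAMES = ("ax", "ay", "az", "a_norm", "a_verti", "a_hori")
_CORR_NAMES = (
    "corr_ax_ay",
    "corr_ax_az",
    "corr_ay_az",
    "corr_norm_verti",
    "corr_norm_hori",
    "corr_verti_hori",
)


def feature_names(descriptive: bool = False) -> list[str]:
    """Column names f1..f54, or human-readable statistic/signal names."""
    if not descriptive:
        return [f"f{i}" for i in range(1, N_FEATURES + 1)]
    names = [f"{st}_{sig}" for st in _STATS for sig in _SIGNAL_NAMES]
    return names + list(_CORR_NAMES)
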