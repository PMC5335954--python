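"""Phase classification, the whole-frame baseline, and hierarchical detection.

The knowledge-based stage trains a 3-class linear support-vector machine
(one-versus-one, hence x(x-1)/2 = 3 binary classifiers) on the per-phase
feature vectors of training *fall* frames, labeled free-fall / impact /
rest.  At detection time a frame the threshold stage could not decide is
segmented, each phase is classified, and the frame is declared a fall
exactly when the predicted sequence is (FreeFall, Impact, Rest) in temporal
order.  Features are z-scored with training statistics before the margin
classifier — variances and kurtoses live on wildly different scales.

A whole-frame binary SVM on the same 54 features (no phase segmentation)
serves as the machine-learning baseline the multiphase model is compared
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .multiphase import (
    N_FEATURES,
    FeatureConfig,
    PhaseName,
    featurize_frame,
    featurize_phases,
    segment_phases,
)
from .signal_model import AccelRecord, Frame
from .threshold_stage import Thresholds, TriageLabel, frame_extrema, triage
from .preprocessing import record_to_frame

__all__ = [
    "PhaseModel",
    "BaselineModel",
    "PhasePrediction",
    "Decision",
    "train_phase_model",
    "predict_phases",
    "check_temporal_order",
    "train_baseline",
    "predict_baseline",
    "detect",
    "detect_frame",
    "save_model",
    "load_model",
]

_PHASE_ORDER = (PhaseName.FREE_FALL, PhaseName.IMPACT, PhaseName.REST)
_PHASE_TO_INT = {p: i for i, p in enumerate(_PHASE_ORDER)}
_INT_TO_PHASE = {i: p for p, i in _PHASE_TO_INT.items()}


@dataclass
class PhasePrediction:
    """Ordered (phase label, timestamp) tuples for the three frame segments.

    Timestamps are phase start times in seconds from the frame start; they
    are strictly increasing by construction of the segmentation.
    """

    sequence: List[Tuple[PhaseName, float]]

    def __post_init__(self) -> None:
        if len(self.sequence) != 3:
            raise ValueError("a phase prediction holds exactly 3 (label, time) tuples")
        times = [t for _, t in self.sequence]
        if not all(t1 < t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("phase timestamps must be strictly increasing")

    @property
    def labels(self) -> Tuple[PhaseName, PhaseName, PhaseName]:
        return tuple(s for s, _ in self.sequence)


@dataclass
class Decision:
    """Outcome of hierarchical detection with its provenance.

    ``stage`` records which stage decided: ``"threshold"`` (triage was
    conclusive; no phase prediction) or ``"knowledge"`` (phase classifier +
    temporal-order rule).
    """

    is_fall: bool
    stage: str
    prediction: Optional[PhasePrediction] = None

    def __post_init__(self) -> None:
        if self.stage not in ("threshold", "knowledge"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "threshold" and self.prediction is not None:
            raise ValueError("threshold-stage decisions carry no phase prediction")


@dataclass
class PhaseModel:
    """Trained multiphase classifier bundled with its triage thresholds."""

    scaler: StandardScaler
    svm: SVC
    thresholds: Thresholds
    config: FeatureConfig = field(default_factory=FeatureConfig)

    @property
    def n_binary_classifiers(self) -> int:
        k = len(self.svm.classes_)
        return k * (k - 1) // 2


@dataclass
class BaselineModel:
    """Whole-frame binary SVM on the same 54 features (no segmentation)."""

    scaler: StandardScaler
    svm: SVC
    config: FeatureConfig = field(default_factory=FeatureConfig)


def train_phase_model(
    fall_frames: Sequence[Frame],
    thresholds: Thresholds,
    config: FeatureConfig = FeatureConfig(),
    C: float = 1.0,
) -> PhaseModel:
    """Fit the 3-class one-vs-one linear phase classifier on fall frames.

    Each training fall frame contributes three labeled feature vectors —
    its free-fall, impact and rest phases.
    """
    if len(fall_frames) == 0:
        raise ValueError("cannot train the phase classifier on an empty set of fall frames")
    X, y = [], []
    for frame in fall_frames:
        seg = segment_phases(frame)
        for phase, feats in zip(_PHASE_ORDER, featurize_phases(frame, seg, config)):
            X.append(feats)
            y.append(_PHASE_TO_INT[phase])
    X = np.asarray(X)
    scaler = StandardScaler().fit(X)
    svm = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    svm.fit(scaler.transform(X), np.asarray(y))
    return PhaseModel(scaler=scaler, svm=svm, thresholds=thresholds, config=config)


def predict_phases(model: PhaseModel, frame: Frame) -> PhasePrediction:
    """Segment a frame and classify each phase segment."""
    seg = segment_phases(frame)
    feats = np.asarray(featurize_phases(frame, seg, model.config))
    pred = model.svm.predict(model.scaler.transform(feats))
    fs = frame.sample_rate
    spans = (seg.free_fall, seg.impact, seg.rest)
    return PhasePrediction(
        sequence=[(_INT_TO_PHASE[int(p)], span[0] / fs) for p, span in zip(pred, spans)]
    )


def check_temporal_order(prediction: PhasePrediction) -> bool:
    """True iff the predicted sequence is exactly (FreeFall, Impact, Rest)."""
    return prediction.labels == _PHASE_ORDER


def train_baseline(
    frames: Sequence[Frame],
    is_fall: Sequence[bool],
    config: FeatureConfig = FeatureConfig(),
    C: float = 1.0,
) -> BaselineModel:
    """Fit the whole-frame binary SVM baseline (fall vs ADL)."""
    if len(frames) != len(is_fall):
        raise ValueError("frames and labels must have equal length")
    y = np.asarray(is_fall, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("baseline training requires both fall and ADL frames")
    X = np.asarray([featurize_frame(f, config) for f in frames])
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES}-dimensional features, got {X.shape[1]}")
    scaler = StandardScaler().fit(X)
    svm = SVC(kernel="linear", C=C)
    svm.fit(scaler.transform(X), y)
    return BaselineModel(scaler=scaler, svm=svm, config=config)


def predict_baseline(model: BaselineModel, frame: Frame) -> bool:
    feats = featurize_frame(frame, model.config).reshape(1, -1)
    return bool(model.svm.predict(model.scaler.transform(feats))[0])


def detect_frame(frame: Frame, model: PhaseModel) -> Decision:
    """Hierarchical decision for one prepared frame.

    Triage with the bundled thresholds decides absolute falls and ADLs
    outright; only unidentified frames invoke the phase classifier and the
    temporal-order rule.
    """
    label = triage(frame_extrema(frame), model.thresholds)
    if label is TriageLabel.FALL:
        return Decision(is_fall=True, stage="threshold")
    if label is TriageLabel.ADL:
        return Decision(is_fall=False, stage="threshold")
    prediction = predict_phases(model, frame)
    return Decision(
        is_fall=check_temporal_order(prediction),
        stage="knowledge",
        prediction=prediction,
    )


def detect(record: AccelRecord, model: PhaseModel, pad_policy: str = "replicate") -> Decision:
    """End-to-end detection on a raw record: frame it, then decide."""
    return detect_frame(record_to_frame(record, pad_policy), model)


def save_model(model: Union[PhaseModel, BaselineModel], path: Union[str, Path]) -> Path:
    """Persist a model bundle (thresholds, scaler, SVM, config) as one archive."""
    path = Path(path)
    joblib.dump(model, path)
    return path


def load_model(path: Union[str, Path]) -> Union[PhaseModel, BaselineModel]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return joblib.load(path)
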