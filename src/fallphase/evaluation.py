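"""Binary-classification metrics, per-activity confusion tables and k-fold CV.

Falls are the positive condition.  From the confusion counts TP/FP/TN/FN:

    sensitivity = TP / (TP + FN)        specificity = TN / (FP + TN)
    precision   = TP / (TP + FP)        accuracy    = (TP + TN) / total

all reported as percentages.  A metric whose denominator is zero is
*undefined* (reported as NaN and excluded from averages, never coerced to
zero).  The evaluation protocol is stratified k-fold cross-validation
repeated over several independently shuffled rounds; per fold the full
detector — triage thresholds plus phase classifier — is refit on the
training portion and scored on the test portion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .multiphase import FeatureConfig
from .phase_classifier import Decision, PhaseModel, detect_frame, train_phase_model
from .signal_model import ActivityLabel, Frame
from .threshold_stage import fit_thresholds, frame_extrema

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVReport",
    "compute_metrics",
    "per_activity_confusion",
    "run_cross_validation",
    "hierarchical_detector_factory",
    "baseline_detector_factory",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with fall as the positive condition."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[bool, bool]]) -> "ConfusionCounts":
        """Build counts from (predicted_fall, truth_fall) pairs."""
        tp = fp = tn = fn = 0
        for pred, truth in pairs:
            if truth:
                tp, fn = tp + (pred), fn + (not pred)
            else:
                fp, tn = fp + (pred), tn + (not pred)
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class MetricSet:
    """The four metrics as percentages; NaN marks an undefined metric."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio_pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, precision and accuracy in percent."""
    return MetricSet(
        sensitivity=_ratio_pct(counts.tp, counts.tp + counts.fn),
        specificity=_ratio_pct(counts.tn, counts.fp + counts.tn),
        precision=_ratio_pct(counts.tp, counts.tp + counts.fp),
        accuracy=_ratio_pct(counts.tp + counts.tn, counts.total),
    )


def per_activity_confusion(
    decisions: Sequence[Tuple[object, ActivityLabel]]
) -> pd.DataFrame:
    """Per-activity confusion table.

    ``decisions`` pairs each prediction (a :class:`Decision` or a plain
    bool meaning predicted-fall) with its ground-truth label.  One row per
    activity name with predicted-fall / predicted-ADL counts, plus
    sensitivity and false-negative rate for fall activities and specificity
    and false-positive rate for ADLs (the complementary cells are NaN,
    mirroring the dashes of a published confusion table).
    """
    rows = {}
    for decision, label in decisions:
        pred_fall = decision.is_fall if isinstance(decision, Decision) else bool(decision)
        row = rows.setdefault(
            label.name, {"is_fall": label.is_fall, "pred_fall": 0, "pred_adl": 0}
        )
        row["pred_fall" if pred_fall else "pred_adl"] += 1
    records = []
    for name, row in rows.items():
        n = row["pred_fall"] + row["pred_adl"]
        if row["is_fall"]:
            sens = _ratio_pct(row["pred_fall"], n)
            records.append(
                dict(
                    activity=name,
                    is_fall=True,
                    n=n,
                    pred_fall=row["pred_fall"],
                    pred_adl=row["pred_adl"],
                    sensitivity=sens,
                    specificity=math.nan,
                    false_positive_rate=math.nan,
                    false_negative_rate=100.0 - sens if not math.isnan(sens) else math.nan,
                )
            )
        else:
            spec = _ratio_pct(row["pred_adl"], n)
            records.append(
                dict(
                    activity=name,
                    is_fall=False,
                    n=n,
                    pred_fall=row["pred_fall"],
                    pred_adl=row["pred_adl"],
                    sensitivity=math.nan,
                    specificity=spec,
                    false_positive_rate=100.0 - spec if not math.isnan(spec) else math.nan,
                    false_negative_rate=math.nan,
                )
            )
    return pd.DataFrame.from_records(records).set_index("activity")


# A detector factory maps (training frames, training labels) to a
# frame -> bool predictor, so the CV harness is agnostic to the detector.
DetectorFactory = Callable[[Sequence[Frame], Sequence[bool]], Callable[[Frame], bool]]


def hierarchical_detector_factory(
    config: FeatureConfig = FeatureConfig(), C: float = 1.0
) -> DetectorFactory:
    """Factory for the full hierarchical detector (triage + phase classifier)."""

    def build(train_frames: Sequence[Frame], train_is_fall: Sequence[bool]):
        extrema = [(frame_extrema(f), bool(y)) for f, y in zip(train_frames, train_is_fall)]
        thresholds = fit_thresholds(extrema)
        fall_frames = [f for f, y in zip(train_frames, train_is_fall) if y]
        model = train_phase_model(fall_frames, thresholds, config, C)
        return lambda frame: detect_frame(frame, model).is_fall

    return build


def baseline_detector_factory(
    config: FeatureConfig = FeatureConfig(), C: float = 1.0
) -> DetectorFactory:
    """Factory for the whole-frame machine-learning baseline."""
    from .phase_classifier import predict_baseline, train_baseline

    def build(train_frames: Sequence[Frame], train_is_fall: Sequence[bool]):
        model = train_baseline(train_frames, train_is_fall, config, C)
        return lambda frame: predict_baseline(model, frame)

    return build


@dataclass
class CVReport:
    """Cross-validation results at fold, round and overall granularity."""

    folds: pd.DataFrame  # columns: round, fold, tp, fp, tn, fn, 4 metrics
    decisions: List[Tuple[bool, ActivityLabel]]  # pooled (predicted, truth) pairs

    @property
    def round_summary(self) -> pd.DataFrame:
        """Per-round mean and std of each metric (undefined folds excluded)."""
        g = self.folds.groupby("round")[list(METRIC_NAMES)]
        mean, std = g.mean(), g.std(ddof=1)
        return pd.concat({"mean": mean, "std": std}, axis=1)

    @property
    def overall(self) -> pd.Series:
        """Mean of every fold-level metric across all rounds."""
        return self.folds[list(METRIC_NAMES)].mean()

    @property
    def pooled_counts(self) -> ConfusionCounts:
        s = self.folds[["tp", "fp", "tn", "fn"]].sum()
        return ConfusionCounts(tp=int(s.tp), fp=int(s.fp), tn=int(s.tn), fn=int(s.fn))

    def render_text(self) -> str:
        """Plain-text rendering in the round-by-round layout of a CV table."""
        lines = ["Round       " + "".join(f"{r:>10}" for r in sorted(self.folds["round"].unique())) + "      Mean"]
        summary = self.round_summary
        for metric in METRIC_NAMES:
            cells = [
                f"{summary[('mean', metric)][r]:6.2f} ({summary[('std', metric)][r]:.2f})"
                for r in summary.index
            ]
            lines.append(f"{metric.capitalize():<12}" + "".join(f"{c:>14}" for c in cells)
                         + f"{self.overall[metric]:10.2f}")
        return "\n".join(lines)


def run_cross_validation(
    frames: Sequence[Frame],
    labels: Sequence[ActivityLabel],
    detector_factory: Optional[DetectorFactory] = None,
    k: int = 5,
    rounds: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation repeated over shuffled rounds.

    Every frame appears in the test fold exactly once per round; folds are
    stratified by the fall/ADL class so each training split contains both
    classes.  A fixed ``seed`` makes the report reproducible.
    """
    if len(frames) != len(labels):
        raise ValueError("frames and labels must have equal length")
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(frames) < k:
        raise ValueError(f"dataset of {len(frames)} frames cannot be split into {k} folds")
    if detector_factory is None:
        detector_factory = hierarchical_detector_factory()
    y = np.asarray([lab.is_fall for lab in labels], dtype=int)
    rows = []
    decisions: List[Tuple[bool, ActivityLabel]] = []
    for rnd in range(1, rounds + 1):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rnd)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y), start=1):
            predictor = detector_factory(
                [frames[i] for i in train_idx], [bool(y[i]) for i in train_idx]
            )
            pairs = []
            for i in test_idx:
                pred = bool(predictor(frames[i]))
                pairs.append((pred, bool(y[i])))
                decisions.append((pred, labels[i]))
            counts = ConfusionCounts.from_pairs(pairs)
            metrics = compute_metrics(counts)
            rows.append(
                dict(round=rnd, fold=fold, tp=counts.tp, fp=counts.fp, tn=counts.tn,
                     fn=counts.fn, **metrics.as_dict())
            )
    return CVReport(folds=pd.DataFrame(rows), decisions=decisions)
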