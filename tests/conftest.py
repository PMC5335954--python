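import numpy as np
import pytest

import fallphase as fp


def build_frame(peak: float = 7.0, peak_axes=(0.0, 0.6, 0.8), baseline: float = 0.0):
    """Deterministic 513-sample frame with its norm maximum at index 192.

    The peak sample is ``peak * peak_axes`` (unit-norm axes by default), the
    remaining samples sit at ``baseline`` on the x axis.
    """
    ax = np.full(fp.FRAME_LENGTH, baseline)
    ay = np.zeros(fp.FRAME_LENGTH)
    az = np.zeros(fp.FRAME_LENGTH)
    ax[fp.CRITICAL_INDEX] = peak * peak_axes[0]
    ay[fp.CRITICAL_INDEX] = peak * peak_axes[1]
    az[fp.CRITICAL_INDEX] = peak * peak_axes[2]
    return fp.Frame(ax=ax, ay=ay, az=az)


@pytest.fixture(scope="session")
def small_dataset():
    """24 labeled synthetic records (12 falls, 12 ADLs), fixed seed."""
    return fp.gen_dataset(12, 12, seed=7)


@pytest.fixture(scope="session")
def small_frames(small_dataset):
    frames = [fp.record_to_frame(ann.record) for ann in small_dataset]
    labels = [ann.label for ann in small_dataset]
    return frames, labels


@pytest.fixture(scope="session")
def trained_model(small_frames):
    frames, labels = small_frames
    extrema = [(fp.frame_extrema(f), lab.is_fall) for f, lab in zip(frames, labels)]
    thresholds = fp.fit_thresholds(extrema)
    fall_frames = [f for f, lab in zip(frames, labels) if lab.is_fall]
    return fp.train_phase_model(fall_frames, thresholds)
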