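import math

import numpy as np
import pytest

import fallphase as fp
from fallphase.multiphase import FeatureConfig, Severity, extract_features, feature_names

from conftest import build_frame


class TestSegmentation:
    def test_severe_frame_spans(self):
        seg = fp.segment_phases(build_frame(peak=7.0))
        assert seg.situation is Severity.SEVERE
        assert seg.impact == (182, 202) and seg.length(seg.impact) == 21
        assert seg.free_fall == (150, 181) and seg.length(seg.free_fall) == 32
        assert seg.rest == (203, 512) and seg.length(seg.rest) == 310

    def test_mild_frame_spans(self):
        seg = fp.segment_phases(build_frame(peak=5.0))
        assert seg.situation is Severity.MILD
        assert seg.impact == (182, 212) and seg.length(seg.impact) == 31
        assert seg.free_fall == (150, 181) and seg.length(seg.free_fall) == 32
        assert seg.rest == (213, 512) and seg.length(seg.rest) == 300

    def test_exactly_6g_takes_severe_branch(self):
        seg = fp.segment_phases(build_frame(peak=6.0))
        assert seg.situation is Severity.SEVERE

    @pytest.mark.parametrize("peak", [3.0, 5.99, 6.0, 7.5])
    def test_phases_tile_150_to_512_without_gaps(self, peak):
        seg = fp.segment_phases(build_frame(peak=peak))
        assert seg.free_fall[0] == 150
        assert seg.free_fall[1] + 1 == seg.impact[0]
        assert seg.impact[1] + 1 == seg.rest[0]
        assert seg.rest[1] == 512


def oracle_features(ax, ay, az):
    """Direct-formula reference for the 54 features (pure-python loops)."""
    m = len(ax)
    norm = [math.sqrt(a * a + b * b + c * c) for a, b, c in zip(ax, ay, az)]
    verti = [math.hypot(a, b) for a, b in zip(ax, ay)]
    hori = [math.hypot(b, c) for b, c in zip(ay, az)]
    sigs = [list(ax), list(ay), list(az), norm, verti, hori]

    def mean(x):
        return sum(x) / len(x)

    def central(x, k):
        mu = mean(x)
        return sum((v - mu) ** k for v in x) / len(x)

    def var(x):  # sample estimator, n-1
        mu = mean(x)
        return sum((v - mu) ** 2 for v in x) / (len(x) - 1)

    def kurt(x):  # Pearson (non-excess), population moments
        m2 = central(x, 2)
        return central(x, 4) / m2**2 if m2 > 0 else 0.0

    def skew(x):
        m2 = central(x, 2)
        return central(x, 3) / m2**1.5 if m2 > 0 else 0.0

    def corr(x, y):
        sx, sy = central(x, 2), central(y, 2)
        if sx == 0 or sy == 0:
            return 0.0
        mx, my = mean(x), mean(y)
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
        return cov / math.sqrt(sx * sy)

    out = []
    out += [mean(s) for s in sigs]
    out += [math.sqrt(var(s)) for s in sigs]
    out += [var(s) for s in sigs]
    out += [max(s) for s in sigs]
    out += [min(s) for s in sigs]
    out += [max(s) - min(s) for s in sigs]
    out += [kurt(s) for s in sigs]
    out += [skew(s) for s in sigs]
    pairs = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
    out += [corr(sigs[i], sigs[j]) for i, j in pairs]
    return out


class TestExtractFeatures:
    def test_constant_segment_conventions(self):
        n = 20
        f = extract_features(np.ones(n), np.zeros(n), np.zeros(n))
        names = feature_names(descriptive=True)
        by = dict(zip(names, f))
        assert by["mean_ax"] == 1.0 and by["std_ax"] == 0.0 and by["range_ax"] == 0.0
        # degenerate correlations and moments use the 0 convention
        assert all(by[k] == 0.0 for k in names if k.startswith("corr_"))
        assert by["kurtosis_ax"] == 0.0 and by["skewness_ax"] == 0.0

    def test_small_segment_examples(self):
        f = extract_features(np.array([1.0, 2, 3]), np.zeros(3), np.zeros(3))
        by = dict(zip(feature_names(descriptive=True), f))
        assert by["max_ax"] == 3.0 and by["min_ax"] == 1.0 and by["range_ax"] == 2.0
        assert by["std_ax"] == pytest.approx(1.0)  # n-1 estimator
        assert by["var_ax"] == pytest.approx(1.0)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            extract_features(np.ones(1), np.ones(1), np.ones(1))

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = int(rng.integers(5, 80))
            ax, ay, az = rng.normal(0, 2, size=(3, m))
            got = extract_features(ax, ay, az)
            expected = oracle_features(ax, ay, az)
            np.testing.assert_allclose(got, expected, rtol=0, atol=1e-9)

    def test_internal_consistency_invariants(self):
        rng = np.random.default_rng(8)
        ax, ay, az = rng.normal(size=(3, 64))
        by = dict(zip(feature_names(descriptive=True), extract_features(ax, ay, az)))
        for sig in ("ax", "ay", "az", "a_norm", "a_verti", "a_hori"):
            assert by[f"range_{sig}"] == pytest.approx(by[f"max_{sig}"] - by[f"min_{sig}"])
            assert by[f"var_{sig}"] == pytest.approx(by[f"std_{sig}"] ** 2, abs=1e-9)
        for name, val in by.items():
            if name.startswith("corr_"):
                assert -1.0 - 1e-12 <= val <= 1.0 + 1e-12

    def test_estimator_configuration(self):
        x = np.array([1.0, 2, 3, 4])
        f_pop = extract_features(x, x[::-1], x, FeatureConfig(ddof=0))
        by = dict(zip(feature_names(descriptive=True), f_pop))
        assert by["var_ax"] == pytest.approx(np.var(x))  # population estimator
        f_exc = extract_features(x, x, x, FeatureConfig(excess_kurtosis=True))
        f_pear = extract_features(x, x, x, FeatureConfig(excess_kurtosis=False))
        by_exc = dict(zip(feature_names(descriptive=True), f_exc))
        by_pear = dict(zip(feature_names(descriptive=True), f_pear))
        assert by_pear["kurtosis_ax"] - by_exc["kurtosis_ax"] == pytest.approx(3.0)


class TestFrameAndPhaseFeatures:
    def test_zero_frame_means_and_stds(self):
        frame = fp.Frame(ax=np.zeros(513), ay=np.zeros(513), az=np.zeros(513))
        f = fp.featurize_frame(frame)
        by = dict(zip(feature_names(descriptive=True), f))
        assert all(by[f"mean_{s}"] == 0 for s in ("ax", "ay", "az"))
        assert all(by[f"std_{s}"] == 0 for s in ("ax", "ay", "az"))

    def test_feature_vector_length_and_peak_norm(self):
        frame = build_frame(peak=7.0)
        f = fp.featurize_frame(frame)
        assert f.shape == (54,)
        assert f[21] == pytest.approx(7.0)  # f22: max a_norm

    @pytest.mark.parametrize("peak, impact_m", [(7.0, 21), (5.0, 31)])
    def test_phase_vectors_use_phase_sample_counts(self, peak, impact_m):
        frame = build_frame(peak=peak)
        seg = fp.segment_phases(frame)
        ff, imp, rest = fp.featurize_phases(frame, seg)
        assert ff.shape == imp.shape == rest.shape == (54,)
        assert seg.length(seg.impact) == impact_m
        assert seg.length(seg.free_fall) == 32
        # the impact vector is computed on exactly the impact span
        sl = slice(seg.impact[0], seg.impact[1] + 1)
        np.testing.assert_allclose(
            imp, extract_features(frame.ax[sl], frame.ay[sl], frame.az[sl])
        )

    def test_csv_export_column_names(self):
        assert feature_names() == [f"f{i}" for i in range(1, 55)]
        assert len(set(feature_names(descriptive=True))) == 54
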