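import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import fallphase as fp
from fallphase.signal_model import G_MS2


def _random_record(seed, n=50):
    rng = np.random.default_rng(seed)
    return fp.AccelRecord(
        ax=rng.normal(size=n), ay=rng.normal(size=n), az=rng.normal(size=n)
    )


class TestAccelRecord:
    def test_timestamps_synthesized_from_sample_rate(self):
        rec = fp.AccelRecord(ax=np.zeros(4), ay=np.zeros(4), az=np.zeros(4), sample_rate=128)
        assert np.allclose(rec.t, np.arange(4) / 128.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(ax=np.zeros(3), ay=np.zeros(2), az=np.zeros(3)),  # length mismatch
            dict(ax=np.array([np.nan]), ay=np.zeros(1), az=np.zeros(1)),  # non-finite
            dict(ax=np.zeros(0), ay=np.zeros(0), az=np.zeros(0)),  # empty
            dict(ax=np.zeros(3), ay=np.zeros(3), az=np.zeros(3),
                 t=np.array([0.0, 0.5, 1.0])),  # non-uniform at 128 Hz
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fp.AccelRecord(**kwargs)


class TestRecordIO:
    def test_zero_csv_identity(self, tmp_path):
        p = tmp_path / "z.csv"
        p.write_text("time,ax,ay,az\n" + "".join(f"{i/128},0,0,0\n" for i in range(4)))
        rec = fp.read_record(p)
        assert len(rec) == 4
        assert np.all(rec.ax == 0) and np.all(rec.ay == 0) and np.all(rec.az == 0)

    def test_missing_axis_column_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time,ax,ay\n0,0,0\n")
        with pytest.raises(ValueError, match="az"):
            fp.read_record(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fp.read_record(tmp_path / "absent.csv")

    def test_write_has_header_and_one_row_per_sample(self, tmp_path):
        rec = fp.AccelRecord(ax=np.zeros(10), ay=np.zeros(10), az=np.zeros(10))
        path = fp.write_record(rec, tmp_path / "r.csv")
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "time,ax,ay,az"
        assert len(lines) == 11

    def test_round_trip_seed7(self, tmp_path):
        rec = _random_record(7)
        back = fp.read_record(fp.write_record(rec, tmp_path / "r.csv"))
        assert back.equals(rec, atol=1e-12)
        assert np.allclose(back.t, rec.t, atol=1e-12)

    def test_ms2_units_converted_on_read(self, tmp_path):
        rec = fp.AccelRecord(ax=np.full(5, G_MS2), ay=np.zeros(5), az=np.zeros(5))
        path = fp.write_record(rec, tmp_path / "r.csv")
        back = fp.read_record(path, units="ms2")
        assert np.allclose(back.ax, 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        data=hnp.arrays(
            np.float64,
            shape=st.tuples(st.integers(1, 40), st.just(3)),
            elements=st.floats(-16, 16, allow_nan=False, width=32),
        )
    )
    def test_round_trip_property(self, data, tmp_path_factory):
        rec = fp.AccelRecord(ax=data[:, 0], ay=data[:, 1], az=data[:, 2])
        path = tmp_path_factory.mktemp("rt") / "r.csv"
        assert fp.read_record(fp.write_record(rec, path)).equals(rec, atol=1e-12)


class TestLabelsAndManifest:
    def test_vocabulary_maps_each_name_to_one_class(self):
        for name in fp.FALL_ACTIVITIES:
            assert fp.ActivityLabel.from_name(name).is_fall
        for name in fp.ADL_ACTIVITIES:
            assert not fp.ActivityLabel.from_name(name).is_fall
        assert len(set(fp.FALL_ACTIVITIES) & set(fp.ADL_ACTIVITIES)) == 0

    def test_walk_backward_is_a_fall(self):
        assert fp.ActivityLabel.from_name("Walk backward").is_fall

    def test_unknown_name_warns_and_flags_custom(self):
        with pytest.warns(UserWarning, match="custom"):
            lab = fp.ActivityLabel.from_name("cartwheel")
        assert lab.custom and not lab.is_fall

    def test_manifest_round_trip_preserves_order(self, tmp_path):
        entries = []
        for i, name in enumerate(["stoop", "walk (normal)", "lie (fast)"]):
            rec = _random_record(i, n=5)
            path = fp.write_record(rec, tmp_path / f"r{i}.csv")
            entries.append(fp.ManifestEntry(path, fp.ActivityLabel.from_name(name), f"s{i}"))
        mpath = fp.write_manifest(entries, tmp_path / "manifest.csv")
        back = fp.read_manifest(mpath)
        assert [e.label.name for e in back] == ["stoop", "walk (normal)", "lie (fast)"]
        assert [e.label.is_fall for e in back] == [True, False, False]
        assert [e.subject_id for e in back] == ["s0", "s1", "s2"]

    def test_empty_manifest(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("path,label,subject\n")
        assert fp.read_manifest(p) == []

    def test_missing_record_file_is_lookup_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("path,label,subject\nghost.csv,stoop,s1\n")
        with pytest.raises(FileNotFoundError, match="ghost"):
            fp.read_manifest(p)
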