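"""FCS reading/writing and batch-directory classification."""

import datetime as dt
import struct

import numpy as np
import pandas as pd
import pytest

import cytogate as cg
from cytogate.errors import (
    ConfigurationError,
    FCSParseError,
    IntegrityError,
    InvalidInputError,
    UnsupportedFormatError,
)
from cytogate.fcs import EventTable, fcs_to_dataframe, read_fcs, write_fcs


def make_table(rng, n=1000, channels=("FSC-H", "SSC-H", "FSC-A", "SSC-A", "SSC-W", "Time")):
    vals = rng.uniform(0, 1e5, size=(n, len(channels))).astype(np.float32)
    return EventTable(pd.DataFrame(vals.astype(np.float64), columns=list(channels)))


def build_fcs_bytes(values, channels, total_events=None, version=b"FCS3.1"):
    """Independent byte-by-byte FCS assembly (little-endian float32)."""
    values = np.asarray(values, dtype=np.float64)
    n, p = values.shape
    total = n if total_events is None else total_events
    payload = b"".join(
        struct.pack("<f", v) for row in values for v in row
    )
    pairs = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%10d"), ("$ENDDATA", "%10d"),
        ("$NEXTDATA", "0"), ("$DATATYPE", "F"), ("$BYTEORD", "1,2,3,4"),
        ("$MODE", "L"), ("$PAR", str(p)), ("$TOT", str(total)),
        ("$BTIM", "10:00:00"), ("$ETIM", "10:02:00"), ("$DATE", "01-Mar-2021"),
    ]
    for i, ch in enumerate(channels, 1):
        pairs += [(f"$P{i}N", ch), (f"$P{i}B", "32"),
                  (f"$P{i}E", "0,0"), (f"$P{i}R", "262144")]

    body = "/" + "/".join(f"{k}/{v}" for k, v in pairs) + "/"
    text_len = len(body % (0, 0))
    data_begin = 58 + text_len
    data_end = data_begin + len(payload) - 1
    text = (body % (data_begin, data_end)).encode("ascii")
    header = (
        version + b"    "
        + str(58).rjust(8).encode()
        + str(58 + len(text) - 1).rjust(8).encode()
        + str(data_begin).rjust(8).encode()
        + str(data_end).rjust(8).encode()
        + b"       0" + b"       0"
    )
    return header + text + payload


class TestRoundTrip:
    def test_float32_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        table = make_table(rng)
        write_fcs(table, tmp_path / "t.fcs")
        back, meta = read_fcs(tmp_path / "t.fcs")
        assert back.channels == table.channels
        assert np.array_equal(
            back.values(), table.values().astype(np.float32).astype(np.float64)
        )
        assert meta.total_events == table.n_events
        assert meta.data_type == "float32"

    def test_integer_storage(self, tmp_path):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 2**20, size=(200, 3)).astype(np.float64)
        table = EventTable(pd.DataFrame(vals, columns=["A", "B", "C"]))
        write_fcs(table, tmp_path / "i.fcs", data_type="integer")
        back, meta = read_fcs(tmp_path / "i.fcs")
        assert meta.data_type == "integer"
        assert np.array_equal(back.values(), vals)

    def test_single_event_single_channel(self, tmp_path):
        table = EventTable(pd.DataFrame({"X": [0.0]}))
        write_fcs(table, tmp_path / "one.fcs")
        back, meta = read_fcs(tmp_path / "one.fcs")
        assert meta.total_events == 1
        assert back.values()[0, 0] == 0.0

    def test_channel_name_with_delimiter_escapes(self, tmp_path):
        table = EventTable(pd.DataFrame({"FL/1-A": [1.0, 2.0]}))
        write_fcs(table, tmp_path / "esc.fcs")
        back, _ = read_fcs(tmp_path / "esc.fcs")
        assert back.channels == ["FL/1-A"]

    def test_acquisition_times_survive(self, tmp_path):
        rng = np.random.default_rng(2)
        t0 = dt.datetime(2021, 3, 1, 9, 30, 0)
        write_fcs(make_table(rng, 10), tmp_path / "t.fcs",
                  acquisition_start=t0, acquisition_end=t0 + dt.timedelta(minutes=2))
        _, meta = read_fcs(tmp_path / "t.fcs")
        assert meta.acquisition_start == t0
        assert meta.acquisition_end == t0 + dt.timedelta(minutes=2)


class TestReaderOracle:
    """The reader against an independently hand-assembled byte layout."""

    def test_hand_built_fixture_values(self, tmp_path):
        values = [(1.0, 10.0), (2.0, 20.0), (3.0, 30.0)]
        blob = build_fcs_bytes(values, ["CH1", "CH2"])
        path = tmp_path / "fixture.fcs"
        path.write_bytes(blob)
        table, meta = read_fcs(path)
        assert table.channels == ["CH1", "CH2"]
        assert np.array_equal(table.values(), np.array(values))
        assert meta.total_events == 3

    def test_declared_count_exceeds_data(self, tmp_path):
        blob = build_fcs_bytes([(1.0, 2.0)] * 99, ["A", "B"], total_events=100)
        path = tmp_path / "short.fcs"
        path.write_bytes(blob)
        with pytest.raises(IntegrityError, match="expected .* found"):
            read_fcs(path)

    def test_unsupported_version(self, tmp_path):
        blob = build_fcs_bytes([(1.0, 2.0)], ["A", "B"], version=b"FCS2.0")
        path = tmp_path / "old.fcs"
        path.write_bytes(blob)
        with pytest.raises(UnsupportedFormatError, match="FCS"):
            read_fcs(path)

    def test_missing_mandatory_keyword(self, tmp_path):
        blob = build_fcs_bytes([(1.0, 2.0)], ["A", "B"])
        blob = blob.replace(b"$TOT", b"$XOT")
        path = tmp_path / "nok.fcs"
        path.write_bytes(blob)
        with pytest.raises(FCSParseError, match=r"\$TOT"):
            read_fcs(path)


class TestWriterValidation:
    def test_empty_table_rejected(self, tmp_path):
        table = EventTable(pd.DataFrame({"A": []}))
        with pytest.raises(InvalidInputError):
            write_fcs(table, tmp_path / "e.fcs")

    def test_duplicate_channels_rejected(self):
        df = pd.DataFrame(np.ones((3, 2)))
        df.columns = ["A", "A"]
        with pytest.raises(InvalidInputError):
            EventTable(df)


def _write_sample(path, rng, start):
    write_fcs(make_table(rng, 50), path, acquisition_start=start)


class TestClassifyBatch:
    def test_blank_selection_by_timestamp(self, tmp_path):
        rng = np.random.default_rng(3)
        t = dt.datetime(2021, 3, 1, 9, 0)

        _write_sample(tmp_path / "a_blank.fcs", rng, t)
        _write_sample(tmp_path / "b_blank.fcs", rng, t + dt.timedelta(minutes=1))
        _write_sample(tmp_path / "s1.fcs", rng, t + dt.timedelta(minutes=2))
        _write_sample(tmp_path / "beads.fcs", rng, t + dt.timedelta(minutes=3))
        m = cg.classify_batch(tmp_path)
        assert m.blank_file.name == "b_blank.fcs"
        assert [p.name for p in m.sample_files] == ["s1.fcs"]
        assert [p.name for p in m.bead_files] == ["beads.fcs"]

    def test_blank_after_samples_falls_back_to_latest(self, tmp_path):
        rng = np.random.default_rng(4)
        t = dt.datetime(2021, 3, 1, 9, 0)
        _write_sample(tmp_path / "s1.fcs", rng, t)
        _write_sample(tmp_path / "late_blank.fcs", rng, t + dt.timedelta(minutes=5))
        _write_sample(tmp_path / "later_blank.fcs", rng, t + dt.timedelta(minutes=9))
        m = cg.classify_batch(tmp_path)
        assert m.blank_file.name == "later_blank.fcs"

    def test_explicit_blank_override(self, tmp_path):
        rng = np.random.default_rng(5)
        t = dt.datetime(2021, 3, 1, 9, 0)
        _write_sample(tmp_path / "a_blank.fcs", rng, t)
        _write_sample(tmp_path / "b_blank.fcs", rng, t + dt.timedelta(minutes=1))
        _write_sample(tmp_path / "s1.fcs", rng, t + dt.timedelta(minutes=2))
        m = cg.classify_batch(tmp_path, blank_file="a_blank.fcs")
        assert m.blank_file.name == "a_blank.fcs"

    def test_no_samples_is_config_error(self, tmp_path):
        rng = np.random.default_rng(6)
        _write_sample(tmp_path / "beads.fcs", rng, dt.datetime(2021, 3, 1))
        with pytest.raises(ConfigurationError):
            cg.classify_batch(tmp_path)

    def test_no_blank_is_config_error(self, tmp_path):
        rng = np.random.default_rng(7)
        _write_sample(tmp_path / "s1.fcs", rng, dt.datetime(2021, 3, 1))
        with pytest.raises(ConfigurationError):
            cg.classify_batch(tmp_path)


class TestBatchConversion:
    def test_records_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        t = dt.datetime(2021, 3, 1, 9, 0)
        _write_sample(tmp_path / "blank.fcs", rng, t)
        _write_sample(tmp_path / "s1.fcs", rng, t + dt.timedelta(minutes=1))
        _write_sample(tmp_path / "beads.fcs", rng, t + dt.timedelta(minutes=2))
        records = fcs_to_dataframe(tmp_path)
        assert len(records) == 3
        for rec in records:
            table, meta = rec.load()
            original, _ = read_fcs(rec.source)
            assert np.allclose(table.values(), original.values())
            assert meta["format"] == "cytogate-record-1"

    def test_sample_filter(self, tmp_path):
        rng = np.random.default_rng(9)
        t = dt.datetime(2021, 3, 1, 9, 0)
        _write_sample(tmp_path / "blank.fcs", rng, t)
        _write_sample(tmp_path / "s1.fcs", rng, t + dt.timedelta(minutes=1))
        _write_sample(tmp_path / "s2.fcs", rng, t + dt.timedelta(minutes=2))
        records = fcs_to_dataframe(tmp_path, samples=["s1"])
        names = sorted(r.source.name for r in records)
        assert names == ["blank.fcs", "s1.fcs"]

    def test_corrupt_file_skipped(self, tmp_path, capsys):
        rng = np.random.default_rng(10)
        t = dt.datetime(2021, 3, 1, 9, 0)
        _write_sample(tmp_path / "blank.fcs", rng, t)
        _write_sample(tmp_path / "good.fcs", rng, t + dt.timedelta(minutes=1))
        (tmp_path / "bad_sample.fcs").write_bytes(b"not an fcs file at all")
        records = fcs_to_dataframe(tmp_path)
        assert sorted(r.source.name for r in records) == ["blank.fcs", "good.fcs"]
        assert "bad_sample.fcs" in capsys.readouterr().err
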