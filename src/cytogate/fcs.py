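"""Reading, writing and batch organisation of Flow Cytometry Standard files.

Supports FCS 3.0 and 3.1, list-mode DATA segments with DATATYPE F (32-bit
float) or I (unsigned integer, masked to the declared ``$PnB`` bit width).
ANALYSIS segments, DATATYPE A/D and multi-dataset files are rejected.

A batch is a directory of ``.fcs`` files where filename substrings tag the
role of each file: a file with ``"blank"`` in its name is a buffer blank,
``"bead"`` marks calibration-bead samples, and everything else is a cell
sample.  Matching is case-insensitive.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    CytogateError,
    DataError,
    FCSParseError,
    IntegrityError,
    InvalidInputError,
    UnsupportedFormatError,
)

RECORD_FORMAT_VERSION = "cytogate-record-1"

_HEADER_LEN = 58
_DELIM = "/"

_MANDATORY_KEYWORDS = ("$DATATYPE", "$BYTEORD", "$MODE", "$PAR", "$TOT")


@dataclass
class ChannelDescriptor:
    short_name: str
    long_name: str
    bits: int
    range: float


@dataclass
class FCSMetadata:
    """Metadata carried alongside each event table."""

    acquisition_start: _dt.datetime | None
    acquisition_end: _dt.datetime | None
    total_events: int
    channel_descriptors: list[ChannelDescriptor]
    data_type: str  # "float32" | "integer"
    byte_order: str  # "little" | "big"
    source_path: str

    def __post_init__(self) -> None:
        if self.total_events < 0:
            raise InvalidInputError("total_events must be >= 0")
        if self.data_type not in ("float32", "integer"):
            raise InvalidInputError(f"unknown data_type {self.data_type!r}")
        if self.byte_order not in ("little", "big"):
            raise InvalidInputError(f"unknown byte_order {self.byte_order!r}")


@dataclass
class EventTable:
    """Per-event channel measurements; one row per event.

    The universal currency between pipeline stages.  ``data`` is a pandas
    DataFrame whose columns are the channel short names (e.g. ``FSC-H``).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            raise InvalidInputError("channel names must be unique")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.channels == other.channels and np.array_equal(
            self.values(), other.values()
        )


@dataclass
class BatchManifest:
    """Role assignment for every FCS file in a batch directory."""

    blank_file: Path
    bead_files: list[Path]
    sample_files: list[Path]
    data_directory: Path


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    text = raw.decode("ascii", errors="replace")
    if not text:
        raise FCSParseError("empty TEXT segment")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Doubled delimiters escape a literal delimiter inside a value; they
    # show up as empty strings after splitting and are re-joined here.
    parts = body.split(delim)
    merged: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        j = i + 1
        # "a<d><d>b" splits to ["a", "", "b"]: a literal delimiter inside a token
        while j + 1 < len(parts) and parts[j] == "":
            tok = tok + delim + parts[j + 1]
            j += 2
        merged.append(tok)
        i = j
    if len(merged) % 2 != 0:
        raise FCSParseError("TEXT segment has an odd number of tokens")
    kw: dict[str, str] = {}
    for key, value in zip(merged[::2], merged[1::2]):
        kw[key.strip().upper()] = value
    return kw


def _require(kw: dict[str, str], key: str) -> str:
    if key not in kw:
        raise FCSParseError(f"mandatory keyword {key} missing from TEXT segment")
    return kw[key]


def _parse_timestamp(kw: dict[str, str], time_key: str) -> _dt.datetime | None:
    date_s = kw.get("$DATE")
    time_s = kw.get(time_key)
    if not time_s:
        return None
    time_s = time_s.split(".")[0].split(":")
    try:
        h, m, s = (int(x) for x in time_s[:3])
        t = _dt.time(h, m, s)
    except (ValueError, TypeError):
        return None
    day = _dt.date(1970, 1, 1)
    if date_s:
        for fmt in ("%d-%b-%Y", "%d-%B-%Y", "%Y-%b-%d", "%d-%b-%y"):
            try:
                day = _dt.datetime.strptime(date_s.strip(), fmt).date()
                break
            except ValueError:
                continue
    return _dt.datetime.combine(day, t)


def _read_header_and_text(fh) -> tuple[dict[str, str], int, int]:
    header = fh.read(_HEADER_LEN)
    if len(header) < _HEADER_LEN:
        raise FCSParseError("file shorter than the 58-byte FCS header")
    version = header[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedFormatError(
            f"unsupported FCS version {version!r}; only FCS 3.0 / 3.1 are handled"
        )

    def _offset(a: int, b: int) -> int:
        s = header[a:b].decode("ascii", errors="replace").strip()
        return int(s) if s else 0

    text_begin = _offset(10, 18)
    text_end = _offset(18, 26)
    data_begin = _offset(26, 34)
    data_end = _offset(34, 42)
    fh.seek(text_begin)
    raw = fh.read(text_end - text_begin + 1)
    kw = _parse_text_segment(raw)
    if data_begin == 0:
        data_begin = int(_require(kw, "$BEGINDATA"))
        data_end = int(_require(kw, "$ENDDATA"))
    return kw, data_begin, data_end


def _metadata_from_keywords(
    kw: dict[str, str], path: Path
) -> tuple[FCSMetadata, list[int]]:
    mode = _require(kw, "$MODE").strip().upper()
    if mode != "L":
        raise UnsupportedFormatError(f"only list-mode DATA supported, got $MODE={mode}")
    dtype_code = _require(kw, "$DATATYPE").strip().upper()
    if dtype_code == "F":
        data_type = "float32"
    elif dtype_code == "I":
        data_type = "integer"
    else:
        raise UnsupportedFormatError(
            f"$DATATYPE {dtype_code} not supported (only F and I)"
        )
    byteord = _require(kw, "$BYTEORD").strip()
    if byteord.startswith("1"):
        byte_order = "little"
    elif byteord.startswith("4") or byteord.startswith("2"):
        byte_order = "big"
    else:
        raise UnsupportedFormatError(f"unrecognised $BYTEORD {byteord!r}")
    n_par = int(_require(kw, "$PAR"))
    total = int(_require(kw, "$TOT"))
    descriptors: list[ChannelDescriptor] = []
    bits: list[int] = []
    for i in range(1, n_par + 1):
        name = _require(kw, f"$P{i}N")
        b = int(_require(kw, f"$P{i}B"))
        rng = float(kw.get(f"$P{i}R", "0") or 0)
        descriptors.append(
            ChannelDescriptor(
                short_name=name,
                long_name=kw.get(f"$P{i}S", name),
                bits=b,
                range=rng,
            )
        )
        bits.append(b)
    meta = FCSMetadata(
        acquisition_start=_parse_timestamp(kw, "$BTIM"),
        acquisition_end=_parse_timestamp(kw, "$ETIM"),
        total_events=total,
        channel_descriptors=descriptors,
        data_type=data_type,
        byte_order=byte_order,
        source_path=str(path),
    )
    return meta, bits


def read_fcs_metadata(path: str | Path) -> FCSMetadata:
    """Parse only the HEADER and TEXT segments (fast role/timestamp lookup)."""
    path = Path(path)
    with open(path, "rb") as fh:
        kw, _, _ = _read_header_and_text(fh)
    meta, _ = _metadata_from_keywords(kw, path)
    return meta


def read_fcs(path: str | Path) -> tuple[EventTable, FCSMetadata]:
    """Read an FCS 3.0/3.1 file into an event table plus metadata.

    Raises
    ------
    UnsupportedFormatError
        For FCS versions other than 3.0/3.1 or data layouts outside
        list-mode F/I storage.
    IntegrityError
        When the DATA segment holds fewer bytes than ``$TOT`` events require.
    FCSParseError
        When a mandatory keyword is absent.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        kw, data_begin, data_end = _read_header_and_text(fh)
        meta, bits = _metadata_from_keywords(kw, path)
        n_par = len(bits)
        total = meta.total_events
        expected_bytes = total * sum(bits) // 8
        fh.seek(data_begin)
        raw = fh.read(data_end - data_begin + 1)
    if len(raw) < expected_bytes:
        raise IntegrityError(
            f"{path.name}: DATA segment truncated: expected {expected_bytes} bytes "
            f"for {total} events, found {len(raw)}"
        )
    raw = raw[:expected_bytes]
    order = "<" if meta.byte_order == "little" else ">"
    names = [d.short_name for d in meta.channel_descriptors]
    if meta.data_type == "float32":
        if any(b != 32 for b in bits):
            raise UnsupportedFormatError("$DATATYPE F requires $PnB=32 for all channels")
        arr = np.frombuffer(raw, dtype=np.dtype(order + "f4"))
        arr = arr.reshape(total, n_par).astype(np.float64)
    else:
        if len(set(bits)) == 1:
            width = bits[0]
            if width not in (8, 16, 32, 64):
                raise UnsupportedFormatError(f"unsupported integer width {width}")
            code = {8: "u1", 16: "u2", 32: "u4", 64: "u8"}[width]
            ints = np.frombuffer(raw, dtype=np.dtype(order + code)).reshape(
                total, n_par
            )
            arr = ints.astype(np.float64)
        else:
            fields = [(f"f{i}", order + {8: "u1", 16: "u2", 32: "u4", 64: "u8"}[b])
                      for i, b in enumerate(bits)]
            rec = np.frombuffer(raw, dtype=np.dtype(fields))
            arr = np.column_stack([rec[f"f{i}"] for i in range(n_par)]).astype(
                np.float64
            )
        # mask to the declared bit width (identity for full-width storage)
        for i, b in enumerate(bits):
            if b < 64:
                arr[:, i] = np.mod(arr[:, i], float(2**b))
    table = EventTable(pd.DataFrame(arr, columns=names))
    return table, table_meta_check(table, meta)


def table_meta_check(table: EventTable, meta: FCSMetadata) -> FCSMetadata:
    if table.n_events != meta.total_events:
        raise IntegrityError(
            f"decoded {table.n_events} events but $TOT declares {meta.total_events}"
        )
    return meta


def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM + _DELIM)


def write_fcs(
    table: EventTable,
    path: str | Path,
    data_type: str = "float32",
    acquisition_start: _dt.datetime | None = None,
    acquisition_end: _dt.datetime | None = None,
) -> Path:
    """Write an event table as a list-mode FCS 3.1 file.

    ``data_type`` is ``"float32"`` (DATATYPE F) or ``"integer"`` (DATATYPE I,
    32-bit unsigned).  The written file round-trips through :func:`read_fcs`.
    """
    path = Path(path)
    if table.n_events == 0:
        raise InvalidInputError("cannot write an empty event table")
    for name in table.channels:
        if not name or not name.isascii():
            raise InvalidInputError(f"channel name {name!r} must be non-empty ASCII")
    if data_type not in ("float32", "integer"):
        raise InvalidInputError(f"unsupported storage type {data_type!r}")

    values = table.values()
    n_events, n_par = values.shape
    if data_type == "float32":
        payload = values.astype("<f4").tobytes(order="C")
        dt_code, bits = "F", 32
        ranges = [float(np.max(np.abs(values[:, i]))) + 1 for i in range(n_par)]
    else:
        ints = np.clip(np.round(values), 0, 2**32 - 1).astype("<u4")
        payload = ints.tobytes(order="C")
        dt_code, bits = "I", 32
        ranges = [float(ints[:, i].max()) + 1 for i in range(n_par)]

    start = acquisition_start or _dt.datetime(1970, 1, 1, 0, 0, 0)
    end = acquisition_end or start

    def build_text(data_begin: int, data_end: int) -> bytes:
        pairs: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", f"{data_begin:>10d}"),
            ("$ENDDATA", f"{data_end:>10d}"),
            ("$NEXTDATA", "0"),
            ("$DATATYPE", dt_code),
            ("$BYTEORD", "1,2,3,4"),
            ("$MODE", "L"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_events)),
            ("$BTIM", start.strftime("%H:%M:%S")),
            ("$ETIM", end.strftime("%H:%M:%S")),
            ("$DATE", start.strftime("%d-%b-%Y")),
        ]
        for i, name in enumerate(table.channels, start=1):
            pairs += [
                (f"$P{i}N", name),  # escaping happens once, in the join below
                (f"$P{i}B", str(bits)),
                (f"$P{i}E", "0,0"),
                (f"$P{i}R", f"{ranges[i - 1]:.0f}"),
            ]
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{_escape(v)}" for k, v in pairs) + _DELIM
        return body.encode("ascii")

    # Offsets depend on TEXT length; fixed-width offset fields make one
    # re-measure pass sufficient.
    text = build_text(0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(payload) - 1
    text = build_text(data_begin, data_end)
    assert text_end == text_begin + len(text) - 1

    def fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            s = "0"
        return s.rjust(8).encode("ascii")

    hdr_data_begin = data_begin if data_begin <= 99_999_999 else 0
    hdr_data_end = data_end if data_end <= 99_999_999 else 0
    header = (
        b"FCS3.1    "
        + fmt(text_begin)
        + fmt(text_end)
        + fmt(hdr_data_begin)
        + fmt(hdr_data_end)
        + fmt(0)
        + fmt(0)
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)
    return path


# ---------------------------------------------------------------------------
# Batch classification and conversion
# ---------------------------------------------------------------------------


def _role(name: str) -> str:
    low = name.lower()
    if "blank" in low:
        return "blank"
    if "bead" in low:
        return "bead"
    return "sample"


def classify_batch(
    data_directory: str | Path,
    blank_file: str | Path | None = None,
    samples: list[str] | None = None,
    exclude: list[str] | None = None,
) -> BatchManifest:
    """Assign a role to every ``.fcs`` file in a batch directory.

    The blank is auto-selected as the last blank-named file acquired before
    the earliest cell sample (falling back to the latest blank overall when
    none precedes the samples), unless ``blank_file`` overrides it.
    ``samples``/``exclude`` filter the cell-sample list by filename substring.
    """
    data_directory = Path(data_directory)
    files = sorted(p for p in data_directory.glob("*.fcs"))
    by_role: dict[str, list[Path]] = {"blank": [], "bead": [], "sample": []}
    for p in files:
        by_role[_role(p.name)].append(p)

    sample_files = by_role["sample"]
    if samples is not None:
        sample_files = [p for p in sample_files if any(s in p.name for s in samples)]
    if exclude:
        sample_files = [p for p in sample_files if not any(s in p.name for s in exclude)]
    if not sample_files:
        raise ConfigurationError(
            f"no cell-sample .fcs files in {data_directory} "
            "(a sample file name contains neither 'blank' nor 'bead')"
        )

    if blank_file is not None:
        blank = Path(blank_file)
        if not blank.is_absolute():
            blank = data_directory / blank
        if not blank.exists():
            raise ConfigurationError(f"specified blank file {blank} does not exist")
    else:
        blanks = by_role["blank"]
        if not blanks:
            raise ConfigurationError(
                f"no file with 'blank' in its name found in {data_directory}; "
                "supply blank_file explicitly"
            )

        def start_time(p: Path) -> _dt.datetime:
            # unreadable metadata must not break classification; conversion
            # reports such files later
            try:
                t = read_fcs_metadata(p).acquisition_start
            except (CytogateError, OSError, ValueError):
                t = None
            return t if t is not None else _dt.datetime.min

        sample_starts = [start_time(p) for p in sample_files]
        earliest_sample = min(sample_starts)
        timed = sorted(blanks, key=lambda p: (start_time(p), p.name))
        before = [p for p in timed if start_time(p) <= earliest_sample]
        blank = before[-1] if before else timed[-1]

    return BatchManifest(
        blank_file=blank,
        bead_files=by_role["bead"],
        sample_files=sample_files,
        data_directory=data_directory,
    )


def _meta_to_json(meta: FCSMetadata) -> dict:
    return {
        "format": RECORD_FORMAT_VERSION,
        "acquisition_start": meta.acquisition_start.isoformat()
        if meta.acquisition_start
        else None,
        "acquisition_end": meta.acquisition_end.isoformat()
        if meta.acquisition_end
        else None,
        "total_events": meta.total_events,
        "data_type": meta.data_type,
        "byte_order": meta.byte_order,
        "source_path": meta.source_path,
        "channels": [
            {
                "short_name": d.short_name,
                "long_name": d.long_name,
                "bits": d.bits,
                "range": d.range,
            }
            for d in meta.channel_descriptors
        ],
    }


@dataclass
class ConvertedRecord:
    """Pointer to one serialized event-table record on disk."""

    source: Path
    role: str
    events_csv: Path
    meta_json: Path

    def load(self) -> tuple[EventTable, dict]:
        table = EventTable(pd.read_csv(self.events_csv))
        meta = json.loads(self.meta_json.read_text())
        return table, meta


def records_directory(data_directory: str | Path) -> Path:
    return Path(data_directory) / "event_tables"


def fcs_to_dataframe(
    data_directory: str | Path,
    blank_file: str | Path | None = None,
    samples: list[str] | None = None,
    exclude: list[str] | None = None,
) -> list[ConvertedRecord]:
    """Convert every FCS file in a batch to its serialized record.

    Records are CSV event matrices plus JSON metadata sidecars, written to an
    ``event_tables`` sub-directory alongside the raw files.  Conversion is
    fail-soft per file: an unreadable file is reported (stderr) and skipped,
    but an empty result is an error.
    """
    manifest = classify_batch(data_directory, blank_file, samples, exclude)
    out_dir = records_directory(manifest.data_directory)
    out_dir.mkdir(exist_ok=True)
    todo = [(manifest.blank_file, "blank")]
    todo += [(p, "bead") for p in manifest.bead_files]
    todo += [(p, "sample") for p in manifest.sample_files]
    records: list[ConvertedRecord] = []
    failures: list[str] = []
    for path, role in todo:
        try:
            table, meta = read_fcs(path)
        except (CytogateError, OSError, ValueError) as exc:
            failures.append(f"{path.name}: {exc}")
            continue
        stem = path.stem
        events_csv = out_dir / f"{stem}.events.csv"
        meta_json = out_dir / f"{stem}.meta.json"
        table.data.to_csv(events_csv, index=False)
        doc = _meta_to_json(meta)
        doc["role"] = role
        meta_json.write_text(json.dumps(doc, indent=1))
        records.append(ConvertedRecord(path, role, events_csv, meta_json))
    if failures:
        import sys

        for msg in failures:
            print(f"cytogate: skipped {msg}", file=sys.stderr)
    if not records:
        raise DataError(
            "no FCS file in the batch could be converted: " + "; ".join(failures)
        )
    return records
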