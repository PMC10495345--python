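"""Reading, validating and writing FP-In flux-met files.

An FP-In file is a comma-delimited table with one row per half-hour (or
hour), paired ``TIMESTAMP_START`` / ``TIMESTAMP_END`` columns in
``YYYYMMDDHHMM`` local standard time, variable labels in the header, and
``-9999`` as the missing-value sentinel.  This module provides the
:class:`FPTable` container every check consumes, the variable-label
grammar (:func:`parse_variable_name`), and a reader/writer pair with a
lossless round-trip contract.

Missing values are represented internally as NaN; the sentinel never
survives as data after a read and is the only serialized form on write.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .registry import VariableRegistry

MISSING_SENTINEL = -9999.0
TIMESTAMP_START = "TIMESTAMP_START"
TIMESTAMP_END = "TIMESTAMP_END"
TIMESTAMP_FORMAT = "%Y%m%d%H%M"

#: closed set of recognized general (non-positional) variable qualifiers
GENERAL_QUALIFIERS = ("PI", "F", "QC", "SD", "N")


class TimestampFormatError(ValueError):
    """Raised for a timestamp token that is not 12 digits."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"malformed timestamp {token!r}: expected 12 digits YYYYMMDDHHMM")


class TimestampCalendarError(ValueError):
    """Raised for a well-formed token that is not a valid calendar instant."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"timestamp {token!r} is not a valid calendar instant")


def parse_timestamp(s: str) -> tuple[int, int, int, int, int]:
    """Parse ``YYYYMMDDHHMM`` into ``(year, month, day, hour, minute)``.

    Inverse of :func:`format_timestamp`.  Timestamps are local standard
    time; no time zone or daylight-saving semantics are attached here.
    """
    if not isinstance(s, str) or len(s) != 12 or not s.isdigit():
        raise TimestampFormatError(str(s))
    year, month, day = int(s[0:4]), int(s[4:6]), int(s[6:8])
    hour, minute = int(s[8:10]), int(s[10:12])
    try:
        _dt.datetime(year, month, day, hour, minute)
    except ValueError as exc:
        raise TimestampCalendarError(s) from exc
    return (year, month, day, hour, minute)


def format_timestamp(t: Union[tuple, _dt.datetime, np.datetime64, pd.Timestamp]) -> str:
    """Format a calendar instant as the 12-digit ``YYYYMMDDHHMM`` string."""
    if isinstance(t, tuple):
        t = _dt.datetime(*t)
    ts = pd.Timestamp(t)
    return f"{ts.year:04d}{ts.month:02d}{ts.day:02d}{ts.hour:02d}{ts.minute:02d}"


_INT_RE = re.compile(r"^[1-9]\d*$")
_LABEL_RE = re.compile(r"^[A-Za-z0-9_]+$")


@dataclass(frozen=True)
class FPVariable:
    """A parsed variable label: base + positional triple + general qualifiers.

    The positional grammar is a trailing ``_<h>_<v>_<r>`` triple of positive
    integers (all three or none).  General qualifiers come from the closed
    set :data:`GENERAL_QUALIFIERS` and sit between the base and the triple.
    """

    base: str
    h_index: Optional[int] = None
    v_index: Optional[int] = None
    r_index: Optional[int] = None
    general_qualifiers: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        indices = (self.h_index, self.v_index, self.r_index)
        if any(i is not None for i in indices) and not all(i is not None for i in indices):
            raise ValueError("positional indices must be all present or all absent")
        if not self.base:
            raise ValueError("variable base must be non-empty")

    @property
    def has_position(self) -> bool:
        return self.h_index is not None

    @property
    def label(self) -> str:
        parts = [self.base, *self.general_qualifiers]
        if self.has_position:
            parts += [str(self.h_index), str(self.v_index), str(self.r_index)]
        return "_".join(parts)


def parse_variable_name(label: str) -> FPVariable:
    """Parse a column label into an :class:`FPVariable`.

    Unknown bases are allowed (flagged downstream); a *partial* positional
    triple (e.g. ``TA_1_1``) parses with the digits folded into the base
    plus a naming warning, because guessing the missing index would be
    unsafe.
    """
    if not label:
        raise ValueError("empty variable label")
    warnings: list[str] = []
    if not _LABEL_RE.match(label):
        raise ValueError(f"variable label {label!r} contains illegal characters")
    tokens = label.split("_")
    if any(t == "" for t in tokens):
        raise ValueError(f"variable label {label!r} has empty components")

    h = v = r = None
    if len(tokens) >= 4 and all(_INT_RE.match(t) for t in tokens[-3:]):
        h, v, r = (int(t) for t in tokens[-3:])
        tokens = tokens[:-3]

    quals: list[str] = []
    while tokens and tokens[-1].upper() in GENERAL_QUALIFIERS and len(tokens) > 1:
        quals.insert(0, tokens.pop().upper())

    base = "_".join(tokens)
    trailing_ints = [t for t in tokens if _INT_RE.match(t)]
    if trailing_ints:
        warnings.append(
            f"label {label!r}: numeric components {trailing_ints} do not form a "
            "complete _H_V_R positional triple"
        )
    if base != base.upper():
        warnings.append(f"label {label!r}: base {base!r} is not upper-case")
    return FPVariable(
        base=base, h_index=h, v_index=v, r_index=r,
        general_qualifiers=tuple(quals), warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class SiteMetadata:
    """Minimal site record: identity, location, and standard-time offset."""

    site_id: str
    lat_deg: float
    lon_deg: float
    utc_offset_hours: float
    igbp: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat_deg <= 90.0:
            raise ValueError(f"latitude {self.lat_deg} out of range")
        if not -180.0 <= self.lon_deg <= 180.0:
            raise ValueError(f"longitude {self.lon_deg} out of range")
        if not -12.0 <= self.utc_offset_hours <= 14.0:
            raise ValueError(f"UTC offset {self.utc_offset_hours} out of range")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SiteMetadata":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            site_id=d["site_id"], lat_deg=float(d["lat_deg"]),
            lon_deg=float(d["lon_deg"]),
            utc_offset_hours=float(d["utc_offset_hours"]),
            igbp=d.get("igbp", ""),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        d = {
            "site_id": self.site_id, "lat_deg": self.lat_deg,
            "lon_deg": self.lon_deg, "utc_offset_hours": self.utc_offset_hours,
            "igbp": self.igbp,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass(frozen=True)
class ParseDiagnostic:
    """One non-conforming cell/row/file condition found while reading."""

    code: str  # WRONG_DELIMITER | BAD_TIMESTAMP_FORMAT | NON_NUMERIC_CELL | NO_TIMESTAMP_COLUMNS | EMPTY_FILE | DUPLICATE_COLUMN
    message: str
    row: Optional[int] = None  # 0-based data-row index (header excluded)
    column: Optional[str] = None
    fatal: bool = False


class FPTable:
    """Regular flux-met time-series table with paired start/end timestamps.

    Data columns are float64 with NaN for missing.  ``start``/``end`` are
    naive local-standard-time instants.  A freshly parsed table may violate
    the regular-axis invariants; violations are diagnosable via
    :meth:`validate` and repaired by the format-QA/QC autocorrection.
    """

    def __init__(
        self,
        start: Sequence,
        end: Sequence,
        data: pd.DataFrame,
        resolution_minutes: int,
        site_id: str = "",
    ) -> None:
        def _index(seq) -> pd.DatetimeIndex:
            if isinstance(seq, pd.DatetimeIndex):
                return seq.copy()
            return pd.DatetimeIndex(pd.to_datetime(list(seq)))

        self.start = _index(start)
        self.end = _index(end)
        if len(self.start) != len(self.end):
            raise ValueError("start and end timestamp sequences differ in length")
        if len(data) != len(self.start):
            raise ValueError("data length does not match timestamps")
        self.data = data.reset_index(drop=True).astype(float)
        self.resolution_minutes = int(resolution_minutes)
        self.site_id = site_id

    # -- container basics -------------------------------------------------
    def __len__(self) -> int:
        return len(self.start)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.data[label].to_numpy()

    def __setitem__(self, label: str, values) -> None:
        self.data[label] = np.asarray(values, dtype=float)

    def copy(self) -> "FPTable":
        return FPTable(self.start.copy(), self.end.copy(), self.data.copy(),
                       self.resolution_minutes, self.site_id)

    def equals(self, other: "FPTable") -> bool:
        if len(self) != len(other) or self.resolution_minutes != other.resolution_minutes:
            return False
        if self.columns != other.columns:
            return False
        if not (self.start.equals(other.start) and self.end.equals(other.end)):
            return False
        a, b = self.data.to_numpy(), other.data.to_numpy()
        return bool(np.array_equal(a, b, equal_nan=True))

    # -- invariants --------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when conforming)."""
        problems: list[str] = []
        if self.resolution_minutes not in (30, 60):
            problems.append(f"unsupported resolution {self.resolution_minutes} min")
        if self.start.hasnans or self.end.hasnans:
            problems.append("unparseable timestamps present")
            return problems
        step = pd.Timedelta(minutes=self.resolution_minutes)
        if not ((self.end - self.start) == step).all():
            problems.append("end - start != resolution for some rows")
        if len(self) > 1:
            diffs = np.diff(self.start.asi8)
            if not (diffs > 0).all():
                problems.append("start timestamps not strictly increasing")
            elif not (diffs == step.value).all():
                problems.append("start timestamps not on a constant step")
        return problems

    def digest(self) -> str:
        """Stable content hash used for report provenance."""
        h = hashlib.sha256()
        h.update(self.site_id.encode())
        h.update(str(self.resolution_minutes).encode())
        h.update(self.start.asi8.tobytes())
        h.update(self.end.asi8.tobytes())
        for c in self.columns:
            h.update(c.encode())
            h.update(np.ascontiguousarray(self.data[c].to_numpy()).tobytes())
        return h.hexdigest()


def infer_resolution(start: Sequence) -> int:
    """Modal step (minutes) of consecutive start timestamps; must be 30 or 60.

    Depends only on the multiset of steps; isolated gaps are missing-row
    diagnostics, not a resolution change.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(list(start))).dropna()
    if len(idx) < 2:
        raise ValueError("need at least 2 timestamps to infer resolution")
    steps = np.diff(idx.asi8) // (60 * 10**9)
    values, counts = np.unique(steps, return_counts=True)
    modal = int(values[np.argmax(counts)])
    if modal not in (30, 60):
        raise ValueError(f"unsupported resolution: modal step {modal} minutes")
    return modal


def _sniff_delimiter(header_line: str) -> str:
    candidates = {",": header_line.count(","), ";": header_line.count(";"),
                  "\t": header_line.count("\t")}
    return max(candidates, key=lambda k: candidates[k])


_SENTINEL_RE = re.compile(r"^-9999(\.0*)?$")


def read_fp_file(
    path: Union[str, Path],
    registry: Optional[VariableRegistry] = None,
    site_id: str = "",
) -> tuple[Optional[FPTable], list[ParseDiagnostic]]:
    """Read an FP-In file, mapping sentinels to missing and logging every
    non-conforming cell.  Data are never silently dropped: rows with
    unparseable timestamps are kept (as NaT) and reported.

    Returns ``(table, diagnostics)``; ``table`` is ``None`` only when no
    rows parse at all.
    """
    diags: list[ParseDiagnostic] = []
    path = Path(path)
    try:
        raw_text = path.read_text(encoding="utf-8-sig")
    except OSError as exc:
        return None, [ParseDiagnostic("UNREADABLE", str(exc), fatal=True)]
    lines = raw_text.splitlines()
    if not lines or not raw_text.strip():
        return None, [ParseDiagnostic("EMPTY_FILE", "file has no content", fatal=True)]

    delim = _sniff_delimiter(lines[0])
    if delim != ",":
        diags.append(ParseDiagnostic(
            "WRONG_DELIMITER",
            f"delimiter {delim!r} inferred; FP-In requires comma", fatal=False))

    header = [h.strip().strip('"') for h in lines[0].split(delim)]
    seen: set[str] = set()
    for h in header:
        if h in seen:
            diags.append(ParseDiagnostic("DUPLICATE_COLUMN", f"duplicate column {h!r}",
                                         column=h))
        seen.add(h)

    cells = [ln.split(delim) for ln in lines[1:] if ln.strip() != ""]
    ncol = len(header)
    norm_rows = []
    for i, row in enumerate(cells):
        if len(row) != ncol:
            diags.append(ParseDiagnostic(
                "NON_NUMERIC_CELL", f"row has {len(row)} fields, expected {ncol}", row=i))
            row = (row + [""] * ncol)[:ncol]
        norm_rows.append([c.strip().strip('"') for c in row])
    frame = pd.DataFrame(norm_rows, columns=header, dtype=str)

    has_start = TIMESTAMP_START in header
    has_end = TIMESTAMP_END in header
    if not (has_start and has_end):
        diags.append(ParseDiagnostic(
            "NO_TIMESTAMP_COLUMNS",
            "TIMESTAMP_START and TIMESTAMP_END are both required", fatal=True))
        return None, diags

    def _parse_ts_column(col: str) -> pd.DatetimeIndex:
        out = []
        for i, token in enumerate(frame[col]):
            try:
                parse_timestamp(token)
                out.append(pd.Timestamp(_dt.datetime.strptime(token, TIMESTAMP_FORMAT)))
            except (TimestampFormatError, TimestampCalendarError) as exc:
                diags.append(ParseDiagnostic("BAD_TIMESTAMP_FORMAT", str(exc),
                                             row=i, column=col))
                out.append(pd.NaT)
        return pd.DatetimeIndex(out)

    start = _parse_ts_column(TIMESTAMP_START)
    end = _parse_ts_column(TIMESTAMP_END)

    data_cols = [c for c in header if c not in (TIMESTAMP_START, TIMESTAMP_END)]
    data = pd.DataFrame(index=frame.index)
    for col in data_cols:
        raw = frame[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        # re-parse valid cells with the correctly rounded scalar parser so
        # that read(write(t)) is bit-stable
        ok = ~numeric.isna()
        if ok.any():
            exact = np.full(len(raw), np.nan)
            exact[ok.to_numpy()] = [float(s) for s in raw[ok]]
            numeric = pd.Series(exact, index=raw.index)
        bad = numeric.isna() & ~raw.str.fullmatch(r"\s*") & (raw != "")
        for i in frame.index[bad]:
            diags.append(ParseDiagnostic(
                "NON_NUMERIC_CELL", f"non-numeric cell {raw[i]!r}", row=int(i), column=col))
        empty = raw.str.fullmatch(r"\s*") | (raw == "")
        for i in frame.index[empty]:
            diags.append(ParseDiagnostic(
                "NON_NUMERIC_CELL", "empty cell", row=int(i), column=col))
        numeric = numeric.mask(numeric == MISSING_SENTINEL)
        data[col] = numeric.astype(float)

    try:
        resolution = infer_resolution(start)
    except ValueError:
        # fall back: try the end-start difference, else refuse
        valid = (~start.isna()) & (~end.isna())
        if valid.any():
            delta = (end[valid][0] - start[valid][0]).total_seconds() / 60
            resolution = int(delta) if delta in (30, 60) else 30
        else:
            resolution = 30
        diags.append(ParseDiagnostic(
            "BAD_TIMESTAMP_FORMAT",
            f"could not infer a supported resolution; assuming {resolution} min"))

    table = FPTable(start, end, data, resolution, site_id=site_id)
    return table, diags


def _format_value(v: float) -> str:
    if np.isnan(v):
        return "-9999"
    return repr(float(v))  # shortest decimal that round-trips bit-stably


def write_fp_file(table: FPTable, path: Union[str, Path]) -> None:
    """Write an FP-In file: comma-delimited, ``YYYYMMDDHHMM`` timestamps,
    missing written exactly as ``-9999``, no quoting, newline-terminated.

    Refuses to write a table that violates the FPTable invariants.
    """
    problems = table.validate()
    if problems:
        raise ValueError("refusing to write non-conforming table: " + "; ".join(problems))
    cols = table.columns
    lines = [",".join([TIMESTAMP_START, TIMESTAMP_END] + cols)]
    data = table.data.to_numpy()
    starts = [format_timestamp(t) for t in table.start]
    ends = [format_timestamp(t) for t in table.end]
    for i in range(len(table)):
        row = [starts[i], ends[i]]
        row.extend(_format_value(v) for v in data[i])
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def make_time_axis(start: Union[str, _dt.datetime], n: int, resolution_minutes: int
                   ) -> tuple[pd.DatetimeIndex, pd.DatetimeIndex]:
    """Regular (start, end) axes of ``n`` intervals from a first instant."""
    t0 = pd.Timestamp(start)
    step = pd.Timedelta(minutes=resolution_minutes)
    starts = pd.date_range(t0, periods=n, freq=step)
    return starts, starts + step
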