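"""Delimited-text file formats for measurement series and fit reports.

A series file is plain CSV with a YAML front-matter block in ``#``-prefixed
header lines declaring the format version, the units the columns are written
in, the source table and free-form metadata::

    # deadtime-series: 1
    # units:
    #   time: s
    #   activity: Bq
    # sources:
    # - source_id: s1
    #   reference_activity: 125000000.0
    #   reference_time: 0.0
    #   half_life: 21636.0
    # metadata:
    #   seed: 7
    detector_id,window,t_start,duration,counts,source_ids
    det1,OW,0.0,300.0,612,
    det1,OW,360.0,60.0,5262110,s1;s2

Counts are integers; ``source_ids`` is a ``;``-joined list, empty for
background frames.  Times may be declared in seconds or hours and activities
in Bq or MBq; everything is converted to the internal units (s, Bq) on read.
With the default dialect (s, Bq) a write/read round trip reproduces the
series exactly.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass

import yaml

from .core import RadioactiveSource
from .estimation import CountMeasurement, MeasurementSeries

__all__ = ["SeriesFileDialect", "SeriesFormatError", "read_series", "write_series"]

_TIME_UNITS = {"s": 1.0, "h": 3600.0}
_ACTIVITY_UNITS = {"Bq": 1.0, "MBq": 1e6}
_COLUMNS = ["detector_id", "window", "t_start", "duration", "counts", "source_ids"]
_FORMAT_KEY = "deadtime-series"
_FORMAT_VERSION = 1


class SeriesFormatError(ValueError):
    """A series file does not conform to the documented dialect."""


@dataclass(frozen=True)
class SeriesFileDialect:
    """Delimiter and unit declarations for a series file."""

    delimiter: str = ","
    time_unit: str = "s"
    activity_unit: str = "Bq"

    def __post_init__(self) -> None:
        if self.time_unit not in _TIME_UNITS:
            raise SeriesFormatError(f"unknown time unit {self.time_unit!r}")
        if self.activity_unit not in _ACTIVITY_UNITS:
            raise SeriesFormatError(f"unknown activity unit {self.activity_unit!r}")

    @property
    def time_scale(self) -> float:
        return _TIME_UNITS[self.time_unit]

    @property
    def activity_scale(self) -> float:
        return _ACTIVITY_UNITS[self.activity_unit]


DEFAULT_DIALECT = SeriesFileDialect()


def write_series(
    series: MeasurementSeries, path, dialect: SeriesFileDialect = DEFAULT_DIALECT
) -> None:
    """Write a measurement series to ``path`` in the documented dialect."""
    header = {
        _FORMAT_KEY: _FORMAT_VERSION,
        "units": {"time": dialect.time_unit, "activity": dialect.activity_unit},
        "sources": [
            {
                "source_id": s.source_id,
                "reference_activity": s.reference_activity / dialect.activity_scale,
                "reference_time": s.reference_time / dialect.time_scale,
                "half_life": s.half_life / dialect.time_scale,
            }
            for s in series.sources
        ],
        "metadata": series.metadata,
    }
    buf = _io.StringIO()
    yaml.safe_dump(header, buf, sort_keys=False)
    with open(path, "w", newline="") as fh:
        for line in buf.getvalue().splitlines():
            fh.write(f"# {line}\n" if line else "#\n")
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(_COLUMNS)
        for m in series.measurements:
            writer.writerow(
                [
                    m.detector_id,
                    m.window,
                    repr(m.t_start / dialect.time_scale),
                    repr(m.duration / dialect.time_scale),
                    m.counts,
                    ";".join(sorted(m.source_ids)),
                ]
            )


def _parse_int(value: str, lineno: int, column: str) -> int:
    try:
        out = int(value)
    except ValueError:
        raise SeriesFormatError(
            f"line {lineno}: column {column!r} must be an integer, got {value!r}"
        ) from None
    return out


def _parse_float(value: str, lineno: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise SeriesFormatError(
            f"line {lineno}: column {column!r} must be a number, got {value!r}"
        ) from None


def read_series(path) -> MeasurementSeries:
    """Read a series file, converting declared units to internal s/Bq."""
    header_lines: list[str] = []
    body_lines: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if stripped.startswith("#"):
                if body_lines:
                    raise SeriesFormatError(
                        f"line {lineno}: header line after the start of the table"
                    )
                # strip "# " but keep YAML indentation intact
                header_lines.append(stripped[2:] if stripped.startswith("# ") else stripped[1:])
            elif stripped.strip():
                body_lines.append((lineno, stripped))
    try:
        header = yaml.safe_load("\n".join(header_lines)) or {}
    except yaml.YAMLError as exc:
        raise SeriesFormatError(f"malformed YAML front matter: {exc}") from None
    if header.get(_FORMAT_KEY) != _FORMAT_VERSION:
        raise SeriesFormatError(
            f"missing or unsupported '{_FORMAT_KEY}' format declaration"
        )
    units = header.get("units", {})
    dialect = SeriesFileDialect(
        time_unit=units.get("time", "s"), activity_unit=units.get("activity", "Bq")
    )
    sources = [
        RadioactiveSource(
            source_id=str(rec["source_id"]),
            reference_activity=float(rec["reference_activity"]) * dialect.activity_scale,
            reference_time=float(rec["reference_time"]) * dialect.time_scale,
            half_life=float(rec["half_life"]) * dialect.time_scale,
        )
        for rec in header.get("sources", [])
    ]

    if not body_lines:
        raise SeriesFormatError("no table found after the header")
    first_lineno, first = body_lines[0]
    reader = csv.reader([first], delimiter=dialect.delimiter)
    columns = next(reader)
    if columns != _COLUMNS:
        raise SeriesFormatError(
            f"line {first_lineno}: expected columns {_COLUMNS}, got {columns}"
        )
    measurements = []
    for lineno, raw in body_lines[1:]:
        row = next(csv.reader([raw], delimiter=dialect.delimiter))
        if len(row) != len(_COLUMNS):
            raise SeriesFormatError(
                f"line {lineno}: expected {len(_COLUMNS)} fields, got {len(row)}"
            )
        rec = dict(zip(_COLUMNS, row))
        counts = _parse_int(rec["counts"], lineno, "counts")
        if counts < 0:
            raise SeriesFormatError(f"line {lineno}: negative counts {counts}")
        duration = _parse_float(rec["duration"], lineno, "duration") * dialect.time_scale
        if duration <= 0:
            raise SeriesFormatError(f"line {lineno}: duration must be > 0")
        source_ids = frozenset(s for s in rec["source_ids"].split(";") if s)
        try:
            measurements.append(
                CountMeasurement(
                    detector_id=rec["detector_id"],
                    window=rec["window"],
                    t_start=_parse_float(rec["t_start"], lineno, "t_start")
                    * dialect.time_scale,
                    duration=duration,
                    counts=counts,
                    source_ids=source_ids,
                )
            )
        except ValueError as exc:
            raise SeriesFormatError(f"line {lineno}: {exc}") from None
    try:
        return MeasurementSeries(
            measurements=measurements,
            sources=sources,
            metadata=header.get("metadata") or {},
        )
    except ValueError as exc:
        raise SeriesFormatError(str(exc)) from None
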