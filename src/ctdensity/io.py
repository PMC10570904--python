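"""Reading and validating camera-trap survey data.

Two delimited-text inputs drive every downstream analysis:

* a *sequence* table — one row per annotated sequence of consecutive
  photos (one triggering episode), carrying the species label, the
  individual count, and the optional distance-sampling observables
  (entry radius/angle) and speed observables (path length, duration);
* a *deployment* table — one row per camera placement, with planar
  coordinates (km), the active interval and a year index.

Rows that fail type coercion are collected and reported, never silently
dropped; a missing required column raises :class:`SchemaError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SequenceRecord",
    "Deployment",
    "RowRejection",
    "ReadResult",
    "SchemaError",
    "read_sequences",
    "read_deployments",
    "write_sequences",
    "write_deployments",
    "SEQUENCE_COLUMNS",
    "DEPLOYMENT_COLUMNS",
]

#: canonical column names for the sequence table
SEQUENCE_COLUMNS = (
    "species",
    "camera_id",
    "start_time",
    "n_individuals",
    "entry_radius_m",
    "entry_angle_rad",
    "path_length_m",
    "duration_s",
    "behaviour",
)

#: canonical column names for the deployment table
DEPLOYMENT_COLUMNS = ("camera_id", "x_km", "y_km", "start", "end", "year_index")

_SEQUENCE_REQUIRED = ("species", "camera_id", "start_time", "n_individuals")
_SEQUENCE_OPTIONAL = (
    "entry_radius_m",
    "entry_angle_rad",
    "path_length_m",
    "duration_s",
    "behaviour",
)


class SchemaError(ValueError):
    """A required column is missing or the header cannot be mapped."""


@dataclass(frozen=True)
class SequenceRecord:
    """One annotated photo sequence (one passage through a viewshed)."""

    species: str
    camera_id: str
    start_time: pd.Timestamp
    n_individuals: int
    entry_radius_m: float | None = None
    entry_angle_rad: float | None = None
    path_length_m: float | None = None
    duration_s: float | None = None
    behaviour: str | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1 for a stored record")
        if self.entry_radius_m is not None and self.entry_radius_m <= 0:
            raise ValueError("entry_radius_m must be positive when present")
        if self.entry_angle_rad is not None and not (
            -math.pi <= self.entry_angle_rad <= math.pi
        ):
            raise ValueError("entry_angle_rad must lie in [-pi, pi]")
        if self.path_length_m is not None and self.duration_s is None:
            raise ValueError("path_length_m requires duration_s (speed computable)")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be positive when present")

    @property
    def speed_km_day(self) -> float | None:
        """Traversal speed in km/day, or None when unobserved."""
        if self.path_length_m is None or self.duration_s is None:
            return None
        return (self.path_length_m / 1000.0) / (self.duration_s / 86400.0)


@dataclass(frozen=True)
class Deployment:
    """One camera placement with its active interval."""

    camera_id: str
    x_km: float
    y_km: float
    start: pd.Timestamp
    end: pd.Timestamp
    year_index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"deployment {self.camera_id}: end must be after start")

    @property
    def effort_days(self) -> float:
        return (self.end - self.start) / pd.Timedelta(days=1)


@dataclass(frozen=True)
class RowRejection:
    """A row that failed coercion, with enough context to fix the file."""

    line_number: int
    reason: str


@dataclass
class ReadResult:
    """Successfully parsed records plus the rejected-row report."""

    records: list
    rejections: list[RowRejection] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing required column(s): {missing}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_sequences(path: str | Path, schema: dict[str, str] | None = None) -> ReadResult:
    """Read the sequence table from a delimited UTF-8 text file.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical column name (``SEQUENCE_COLUMNS``)
        to the column name used in the file.

    Returns
    -------
    ReadResult
        Iterable of :class:`SequenceRecord`; rows failing coercion are in
        ``.rejections`` with their 1-based line numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _check_columns(df, _SEQUENCE_REQUIRED, "sequence")

    records: list[SequenceRecord] = []
    rejections: list[RowRejection] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header on line 1
        d = dict(zip(df.columns, row))
        try:
            ts = pd.Timestamp(d["start_time"])
            if pd.isna(ts):
                raise ValueError("empty timestamp")
            behaviour = d.get("behaviour") or None
            records.append(
                SequenceRecord(
                    species=str(d["species"]),
                    camera_id=str(d["camera_id"]),
                    start_time=ts,
                    n_individuals=int(d["n_individuals"]),
                    entry_radius_m=_opt_float(d.get("entry_radius_m")),
                    entry_angle_rad=_opt_float(d.get("entry_angle_rad")),
                    path_length_m=_opt_float(d.get("path_length_m")),
                    duration_s=_opt_float(d.get("duration_s")),
                    behaviour=behaviour,
                )
            )
        except (ValueError, TypeError) as exc:
            rejections.append(RowRejection(line_number=line, reason=str(exc)))
    return ReadResult(records=records, rejections=rejections)


def read_deployments(path: str | Path, schema: dict[str, str] | None = None) -> ReadResult:
    """Read the deployment table; same contract as :func:`read_sequences`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _check_columns(df, DEPLOYMENT_COLUMNS, "deployment")

    records: list[Deployment] = []
    rejections: list[RowRejection] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2
        d = dict(zip(df.columns, row))
        try:
            start, end = pd.Timestamp(d["start"]), pd.Timestamp(d["end"])
            if pd.isna(start) or pd.isna(end):
                raise ValueError("empty timestamp")
            records.append(
                Deployment(
                    camera_id=str(d["camera_id"]),
                    x_km=float(d["x_km"]),
                    y_km=float(d["y_km"]),
                    start=start,
                    end=end,
                    year_index=int(d["year_index"]),
                )
            )
        except (ValueError, TypeError) as exc:
            rejections.append(RowRejection(line_number=line, reason=str(exc)))
    return ReadResult(records=records, rejections=rejections)


def _records_frame(records: Sequence, columns: Sequence[str]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in columns} for r in records]
    return pd.DataFrame(rows, columns=list(columns))


def write_sequences(records: Sequence[SequenceRecord], path: str | Path) -> None:
    _records_frame(records, SEQUENCE_COLUMNS).to_csv(path, index=False)


def write_deployments(records: Sequence[Deployment], path: str | Path) -> None:
    _records_frame(records, DEPLOYMENT_COLUMNS).to_csv(path, index=False)


def total_effort_days(deployments: Sequence[Deployment]) -> float:
    """Survey effort t: summed active durations across cameras, in days."""
    return float(sum(d.effort_days for d in deployments))
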