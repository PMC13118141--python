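"""Flow-metadata I/O and time binning.

Traffic metadata arrives as one record per 10-second window per destination
hostname: participant ID, window start timestamp (with an explicit UTC
offset), upload/download byte and packet counts.  This module parses and
validates such logs (JSONL or CSV), and aggregates a participant's records
into contiguous, non-overlapping within-day bins (10-minute bins for rhythm
analysis, 60-minute bins for coverage analysis).

Local time is the record timestamp shifted by a fixed per-participant UTC
offset; daylight-saving transitions are deliberately not modeled (the
analyses assume participants remain in one time zone).  Days are local
calendar days, day index 0 being the first day with any traffic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd

WINDOW_SECONDS = 10

#: Column order of the on-disk flow-log schema (CSV header / JSONL keys).
FLOW_COLUMNS = (
    "participant_id",
    "window_start",
    "duration_s",
    "hostname",
    "bytes_up",
    "bytes_down",
    "packets_up",
    "packets_down",
)


class FlowLogError(ValueError):
    """Raised for malformed flow-log input; the message names the line."""


@dataclass(frozen=True)
class FlowRecord:
    """One 10-second traffic-metadata window.

    ``window_start`` is timezone-aware (explicit UTC offset).  Byte and
    packet counts are non-negative; ``duration_s`` is fixed at 10.
    """

    participant_id: str
    window_start: datetime
    hostname: str
    bytes_up: int
    bytes_down: int
    packets_up: int = 0
    packets_down: int = 0
    duration_s: int = WINDOW_SECONDS

    def __post_init__(self) -> None:
        if self.duration_s != WINDOW_SECONDS:
            raise FlowLogError(f"duration_s must be {WINDOW_SECONDS}, got {self.duration_s}")
        if self.window_start.tzinfo is None:
            raise FlowLogError("window_start must carry an explicit UTC offset")
        if not self.hostname:
            raise FlowLogError("hostname must be non-empty")
        for name in ("bytes_up", "bytes_down", "packets_up", "packets_down"):
            if getattr(self, name) < 0:
                raise FlowLogError(f"{name} must be non-negative, got {getattr(self, name)}")


@dataclass
class BinnedSeries:
    """Per-participant dense grid of binned traffic volumes.

    ``up`` and ``down`` are (D, T) arrays of byte totals, one row per local
    calendar day starting at ``first_day``, with T = 1440 / ``bin_width``
    within-day bins.  The dense representation guarantees the bins are
    contiguous and non-overlapping over the covered span; bins with no
    traffic hold 0.
    """

    participant_id: str
    bin_width: int  # minutes
    first_day: date
    tz_offset_minutes: int
    up: np.ndarray
    down: np.ndarray

    @property
    def n_days(self) -> int:
        return self.up.shape[0]

    @property
    def bins_per_day(self) -> int:
        return 1440 // self.bin_width

    def total(self) -> np.ndarray:
        """Elementwise up + down byte totals."""
        return self.up + self.down

    def day_dates(self) -> list[date]:
        return [self.first_day + timedelta(days=int(d)) for d in range(self.n_days)]

    def rebin(self, bin_width: int) -> "BinnedSeries":
        """Aggregate to a coarser bin width (must be a multiple of the current one)."""
        if bin_width % self.bin_width != 0:
            raise ValueError(
                f"target bin width {bin_width} is not a multiple of {self.bin_width}"
            )
        k = bin_width // self.bin_width
        T = self.bins_per_day // k
        up = self.up.reshape(self.n_days, T, k).sum(axis=2)
        down = self.down.reshape(self.n_days, T, k).sum(axis=2)
        return BinnedSeries(
            participant_id=self.participant_id,
            bin_width=bin_width,
            first_day=self.first_day,
            tz_offset_minutes=self.tz_offset_minutes,
            up=up,
            down=down,
        )


def _parse_offset(tz: Union[int, str, timezone]) -> timezone:
    """Accept a fixed offset as minutes, '+05:30'-style string, or tzinfo."""
    if isinstance(tz, timezone):
        return tz
    if isinstance(tz, int):
        return timezone(timedelta(minutes=tz))
    s = tz.strip()
    sign = -1 if s.startswith("-") else 1
    s = s.lstrip("+-")
    hh, _, mm = s.partition(":")
    return timezone(sign * timedelta(hours=int(hh), minutes=int(mm or 0)))


def _coerce_record(raw: dict, lineno: int) -> FlowRecord:
    missing = [c for c in FLOW_COLUMNS if c not in raw or raw[c] in (None, "")]
    # packets default to 0 when absent, duration to 10
    missing = [m for m in missing if m not in ("packets_up", "packets_down", "duration_s")]
    if missing:
        raise FlowLogError(f"line {lineno}: missing required field(s) {missing}")
    try:
        ts = datetime.fromisoformat(str(raw["window_start"]))
    except ValueError as exc:
        raise FlowLogError(f"line {lineno}: unparseable window_start: {exc}") from exc
    if ts.tzinfo is None:
        raise FlowLogError(f"line {lineno}: window_start lacks a UTC offset")
    try:
        return FlowRecord(
            participant_id=str(raw["participant_id"]),
            window_start=ts,
            hostname=str(raw["hostname"]),
            bytes_up=int(raw["bytes_up"]),
            bytes_down=int(raw["bytes_down"]),
            packets_up=int(raw.get("packets_up") or 0),
            packets_down=int(raw.get("packets_down") or 0),
            duration_s=int(raw.get("duration_s") or WINDOW_SECONDS),
        )
    except FlowLogError as exc:
        raise FlowLogError(f"line {lineno}: {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise FlowLogError(f"line {lineno}: malformed field: {exc}") from exc


def _iter_raw(path: Path, format: str) -> Iterator[tuple[int, dict]]:
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    yield lineno, json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FlowLogError(f"line {lineno}: invalid JSON: {exc}") from exc
    elif format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):  # line 1 is the header
                yield lineno, row
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")


def read_flow_log(path: Union[str, Path], format: str | None = None) -> list[FlowRecord]:
    """Read and validate a flow log, returning records in timestamp order.

    Parameters
    ----------
    path
        JSONL (one object per line) or CSV (RFC 4180, header row) file.
    format
        ``'jsonl'`` or ``'csv'``; inferred from the file suffix when omitted.

    Raises
    ------
    FlowLogError
        On a missing required field, negative count, or unparseable
        timestamp — the message names the offending line.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    records = [_coerce_record(raw, lineno) for lineno, raw in _iter_raw(path, format)]
    records.sort(key=lambda r: (r.participant_id, r.window_start))
    return records


def write_flow_log(
    records: Union[Sequence[FlowRecord], pd.DataFrame],
    path: Union[str, Path],
    format: str | None = None,
) -> None:
    """Write records (or an equivalent DataFrame) to JSONL or CSV."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out = frame.copy()
    out["window_start"] = [ts.isoformat() for ts in out["window_start"]]
    out = out[list(FLOW_COLUMNS)]
    if format == "csv":
        out.to_csv(path, index=False)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in out.itertuples(index=False):
                fh.write(json.dumps(dict(zip(FLOW_COLUMNS, row))) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def records_to_frame(records: Iterable[FlowRecord]) -> pd.DataFrame:
    """Convert FlowRecords to the canonical DataFrame layout."""
    rows = [
        (
            r.participant_id,
            r.window_start,
            r.duration_s,
            r.hostname,
            r.bytes_up,
            r.bytes_down,
            r.packets_up,
            r.packets_down,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(FLOW_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[FlowRecord]:
    return [
        FlowRecord(
            participant_id=str(row.participant_id),
            window_start=row.window_start.to_pydatetime()
            if isinstance(row.window_start, pd.Timestamp)
            else row.window_start,
            hostname=row.hostname,
            bytes_up=int(row.bytes_up),
            bytes_down=int(row.bytes_down),
            packets_up=int(row.packets_up),
            packets_down=int(row.packets_down),
        )
        for row in frame.itertuples(index=False)
    ]


def bin_traffic(
    records: Union[Sequence[FlowRecord], pd.DataFrame],
    bin_width: int,
    tz: Union[int, str, timezone],
) -> BinnedSeries:
    """Aggregate one participant's flow records into within-day bins.

    Each record's bytes are added to exactly one bin, determined by the
    local time of its ``window_start`` (10-second windows never meaningfully
    straddle a bin boundary).  The returned grid spans the first through the
    last local calendar day with traffic; bins without traffic hold 0, so
    total bytes are conserved per direction.

    Parameters
    ----------
    records
        Flow records or an equivalent DataFrame; all must share one
        participant.
    bin_width
        Bin width in minutes; must divide 1440.
    tz
        The participant's fixed UTC offset (minutes, ``'+HH:MM'`` string,
        or a fixed-offset ``timezone``).
    """
    if 1440 % bin_width != 0:
        raise ValueError(f"bin_width {bin_width} does not divide 1440")
    tzinfo = _parse_offset(tz)
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("cannot bin an empty record sequence")
    pids = frame["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"records mix participants: {sorted(map(str, pids))}")

    ts = pd.DatetimeIndex(frame["window_start"])
    local = ts.tz_convert(tzinfo)
    # naive local timestamps -> day ordinal + within-day bin index
    naive = local.tz_localize(None)
    day_ord = naive.normalize().asi8 // 86_400_000_000_000
    minute_of_day = naive.hour * 60 + naive.minute
    bin_idx = (minute_of_day // bin_width).to_numpy()

    d0, d1 = int(day_ord.min()), int(day_ord.max())
    n_days = d1 - d0 + 1
    T = 1440 // bin_width
    flat = (day_ord - d0) * T + bin_idx
    up = np.bincount(flat, weights=frame["bytes_up"].to_numpy(dtype=np.float64), minlength=n_days * T)
    down = np.bincount(flat, weights=frame["bytes_down"].to_numpy(dtype=np.float64), minlength=n_days * T)

    first_day = (datetime(1970, 1, 1) + timedelta(days=d0)).date()
    offset_minutes = int(tzinfo.utcoffset(None).total_seconds() // 60)
    return BinnedSeries(
        participant_id=str(pids[0]),
        bin_width=bin_width,
        first_day=first_day,
        tz_offset_minutes=offset_minutes,
        up=up.reshape(n_days, T),
        down=down.reshape(n_days, T),
    )


def split_by_participant(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a cohort flow frame into per-participant frames."""
    return {str(pid): grp.reset_index(drop=True) for pid, grp in frame.groupby("participant_id", sort=True)}
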