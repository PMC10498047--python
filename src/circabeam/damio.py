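"""Reading, writing, binning and day-slicing of DAM-style locomotor recordings.

Drosophila Activity Monitors (Trikinetics) record infrared beam crossings per
fly at a 1-minute cadence and archive them as tab-delimited monitor files with
one row per reading: a reading index, date, time, a status code, six auxiliary
fields and 32 channel counts (42 columns in all).  This module parses that
dialect into :class:`ActivityTable`, writes it back losslessly, re-bins counts
and splits ZT-aligned recordings into day-by-day matrices for actograms and
daily profiles.

ZT (Zeitgeber Time) alignment is metadata: ``zt0_offset`` gives the number of
minutes from the start of the recording to the first ZT00 (lights-on of the
entraining cycle) and is supplied by the caller, never inferred from the data.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
N_FILE_CHANNELS = 32
N_FILE_COLUMNS = 42
OK_STATUS = 1
#: status code written for rows that were flagged on read (any non-OK code
#: in the source file is preserved in ``ActivityTable.flagged`` but rewritten
#: with this single marker).
FLAG_STATUS = 51

_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"


class MonitorParseError(ValueError):
    """A monitor file row could not be parsed (message names the line)."""


class MonitorIntegrityError(ValueError):
    """Timestamps in a monitor file are not strictly increasing."""


@dataclass
class ActivityTable:
    """Per-fly beam-crossing counts on a uniform time grid.

    Parameters
    ----------
    timestamps
        Minutes since recording start, strictly increasing with constant
        spacing equal to ``bin_minutes``.
    counts
        Mapping channel number -> integer count array, one entry per
        timestamp.
    bin_minutes
        Width of each bin in minutes (native DAM cadence is 1).
    zt0_offset
        Minutes from recording start to the first ZT00.
    flagged
        Row indices whose status code was not the OK code on read.
    """

    timestamps: np.ndarray
    counts: dict[int, np.ndarray]
    bin_minutes: int = 1
    zt0_offset: int = 0
    flagged: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        if self.bin_minutes <= 0:
            raise ValueError("bin_minutes must be positive")
        n = len(self.timestamps)
        if n > 1:
            diffs = np.diff(self.timestamps)
            if not np.all(diffs == self.bin_minutes):
                raise MonitorIntegrityError(
                    "timestamps must be strictly increasing with spacing "
                    f"{self.bin_minutes} min"
                )
        clean: dict[int, np.ndarray] = {}
        for ch, arr in self.counts.items():
            arr = np.asarray(arr)
            if len(arr) != n:
                raise ValueError(f"channel {ch}: {len(arr)} counts for {n} timestamps")
            if np.issubdtype(arr.dtype, np.floating):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"channel {ch}: counts must be integers")
                arr = np.round(arr)
            arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise ValueError(f"channel {ch}: counts must be >= 0")
            clean[ch] = arr
        self.counts = clean

    # -- convenience accessors -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.timestamps)

    @property
    def channels(self) -> list[int]:
        return sorted(self.counts)

    @property
    def duration_minutes(self) -> int:
        return self.n_bins * self.bin_minutes

    def channel(self, ch: int | None = None) -> np.ndarray:
        """Counts for one channel; default is the only channel present."""
        if ch is None:
            if len(self.counts) != 1:
                raise ValueError("table holds several channels; specify one")
            return next(iter(self.counts.values()))
        return self.counts[ch]

    def zt_minutes(self) -> np.ndarray:
        """ZT of each bin start, in minutes within [0, 1440)."""
        return (self.timestamps - self.zt0_offset) % MINUTES_PER_DAY


@dataclass
class DayMatrix:
    """Counts reshaped day-by-row over complete 24 h cycles."""

    values: np.ndarray  # shape (n_days, 1440 // bin_minutes)
    bin_minutes: int
    channel: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("DayMatrix values must be 2-D")
        if self.values.shape[0] and self.values.shape[1] * self.bin_minutes != MINUTES_PER_DAY:
            raise ValueError("columns x bin_minutes must equal 1440")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]


# -- monitor file I/O ----------------------------------------------------------


def read_monitor_file(
    path,
    channels: list[int] | None = None,
    zt0_offset: int = 0,
) -> ActivityTable:
    """Parse a classic 42-column Trikinetics monitor file.

    Rows whose status column differs from the OK code are flagged and their
    counts replaced with zeros (with a warning); they are never silently
    dropped, so the row grid stays uniform.
    """
    wanted = list(range(1, N_FILE_CHANNELS + 1)) if channels is None else list(channels)
    times: list[_dt.datetime] = []
    rows: list[list[int]] = []
    flagged: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != N_FILE_COLUMNS:
                raise MonitorParseError(
                    f"line {lineno}: expected {N_FILE_COLUMNS} tab-delimited "
                    f"fields, found {len(fields)}"
                )
            try:
                stamp = _dt.datetime.strptime(
                    f"{fields[1]} {fields[2]}", f"{_DATE_FMT} {_TIME_FMT}"
                )
                status = int(fields[3])
                counts = [int(v) for v in fields[10:]]
            except ValueError as exc:
                raise MonitorParseError(f"line {lineno}: {exc}") from exc
            if status != OK_STATUS:
                flagged.append(len(rows))
                counts = [0] * N_FILE_CHANNELS
            times.append(stamp)
            rows.append(counts)
    if not rows:
        raise MonitorParseError(f"{path}: empty monitor file")
    minutes = np.array(
        [round((t - times[0]).total_seconds() / 60.0) for t in times], dtype=np.int64
    )
    if np.any(np.diff(minutes) <= 0):
        raise MonitorIntegrityError(f"{path}: timestamps are not strictly increasing")
    if flagged:
        warnings.warn(
            f"{path}: {len(flagged)} rows carried a non-OK status; their counts "
            "were zeroed and the rows flagged",
            stacklevel=2,
        )
    mat = np.asarray(rows, dtype=np.int64)
    counts = {ch: mat[:, ch - 1] for ch in wanted}
    return ActivityTable(
        timestamps=minutes,
        counts=counts,
        bin_minutes=1,
        zt0_offset=zt0_offset,
        flagged=tuple(flagged),
    )


def write_monitor_file(
    table: ActivityTable,
    path,
    start: _dt.datetime | None = None,
) -> None:
    """Serialize a table back to the 42-column Trikinetics dialect.

    Channels absent from the table are written as zeros; flagged rows are
    written with :data:`FLAG_STATUS`.
    """
    start = start or _dt.datetime(2023, 1, 2, 0, 0, 0)
    flagged = set(table.flagged)
    n = table.n_bins
    mat = np.zeros((n, N_FILE_CHANNELS), dtype=np.int64)
    for ch, arr in table.counts.items():
        if not 1 <= ch <= N_FILE_CHANNELS:
            raise ValueError(f"channel {ch} outside the 32-channel dialect")
        mat[:, ch - 1] = arr
    with open(path, "w") as fh:
        for i in range(n):
            stamp = start + _dt.timedelta(minutes=int(table.timestamps[i]))
            status = FLAG_STATUS if i in flagged else OK_STATUS
            meta = [
                str(i + 1),
                stamp.strftime(_DATE_FMT).lstrip("0"),
                stamp.strftime(_TIME_FMT),
                str(status),
            ] + ["0"] * 6
            fh.write("\t".join(meta + [str(int(v)) for v in mat[i]]) + "\n")


# -- binning and slicing -------------------------------------------------------


def bin_activity(table: ActivityTable, bin_minutes: int) -> ActivityTable:
    """Sum counts into coarser bins; the grand total is conserved exactly."""
    if bin_minutes % table.bin_minutes != 0:
        raise ValueError(
            f"bin_minutes={bin_minutes} is not a multiple of the table's "
            f"{table.bin_minutes}-min bins"
        )
    if MINUTES_PER_DAY % bin_minutes != 0:
        raise ValueError(f"bin_minutes={bin_minutes} does not divide 1440")
    factor = bin_minutes // table.bin_minutes
    if factor == 1:
        return table
    n = table.n_bins
    if n % factor != 0:
        raise ValueError(
            f"table length {n} is not a whole number of {bin_minutes}-min bins"
        )
    counts = {
        ch: arr.reshape(-1, factor).sum(axis=1) for ch, arr in table.counts.items()
    }
    return ActivityTable(
        timestamps=table.timestamps[::factor],
        counts=counts,
        bin_minutes=bin_minutes,
        zt0_offset=table.zt0_offset,
    )


def split_days(table: ActivityTable, ch: int | None = None) -> DayMatrix:
    """Reshape one channel into complete ZT-aligned 24 h rows.

    Leading data before the first ZT00 and any trailing partial day are
    excluded.  With less than one complete day the matrix is empty (with a
    warning).
    """
    series = table.channel(ch)
    values, _ = _split_series(
        series, table.bin_minutes, table.zt0_offset, int(table.timestamps[0])
    )
    if values.shape[0] == 0:
        warnings.warn("fewer than one complete ZT day of data", stacklevel=2)
    return DayMatrix(values=values, bin_minutes=table.bin_minutes, channel=ch)


def _split_series(
    series: np.ndarray, bin_minutes: int, zt0_offset: int, t0: int = 0
) -> tuple[np.ndarray, int]:
    """Day-split any per-bin series; returns (matrix, start index of first day)."""
    series = np.asarray(series)
    per_day = MINUTES_PER_DAY // bin_minutes
    lead = (zt0_offset - t0) % MINUTES_PER_DAY
    if lead % bin_minutes != 0:
        raise ValueError("zt0_offset is not aligned to the bin grid")
    i0 = lead // bin_minutes
    n_days = max(0, (len(series) - i0) // per_day)
    mat = series[i0 : i0 + n_days * per_day].reshape(n_days, per_day)
    return mat, i0


def to_csv(table: ActivityTable, path) -> None:
    """Long-format CSV export (zt_min, channel, count)."""
    zt = table.zt_minutes()
    frames = [
        pd.DataFrame({"zt_min": zt, "channel": ch, "count": arr})
        for ch, arr in sorted(table.counts.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
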