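"""Reading, validation and writing of TriKinetics DAM activity-monitor files.

A DAM monitor records, once per minute, the number of infrared beam breaks
for each of 32 tube channels.  The on-disk dialect handled here is the
DAMSystem3 tab-delimited layout with 42 fields per line:

====  =======================================
field  content
====  =======================================
1      reading index
2      date, ``d MMM yy`` (e.g. ``7 Jan 20``)
3      time, ``HH:MM:SS``
4      monitor status code
5-9    device metadata (ignored on read)
10     light-sensor flag
11-42  beam-break counts for channels 1-32
====  =======================================

Light/dark *phase* is protocol-defined (see :mod:`dsprsleep.sleepmetrics`);
the hardware light-sensor flag in field 10 is retained for QC only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

N_CHANNELS = 32
N_FIELDS = 42
_MINUTE = timedelta(minutes=1)


class DamError(ValueError):
    """Base class for DAM file problems."""


class DamFormatError(DamError):
    """A line could not be parsed; the message names the line number."""


class DamGapError(DamError):
    """The minute sequence has gaps (or runs backwards)."""


@dataclass
class ActivityMatrix:
    """Minute-binned beam-break counts for one 32-channel monitor.

    ``counts`` has shape ``(n_minutes, 32)``; ``light`` and ``status`` are
    per-minute vectors.  ``flagged`` marks records whose status code was not
    accepted by the reader (they are kept, never silently dropped).
    """

    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    light: np.ndarray
    status: np.ndarray
    monitor: str = "M001"
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.light = np.asarray(self.light, dtype=np.int64)
        self.status = np.asarray(self.status, dtype=np.int64)
        if self.flagged is None:
            self.flagged = np.zeros(len(self.timestamps), dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.timestamps)
        if self.counts.shape != (n, N_CHANNELS):
            raise DamError(
                f"counts shape {self.counts.shape} != ({n}, {N_CHANNELS})"
            )
        if self.light.shape != (n,) or self.status.shape != (n,):
            raise DamError("light/status length mismatch")
        if np.any(self.counts < 0):
            raise DamError("negative beam-break counts")
        if n > 1:
            steps = np.diff(self.timestamps.asi8)
            if np.any(steps <= 0):
                raise DamGapError("timestamps not strictly increasing")
            if np.any(steps != 60_000_000_000):
                bad = int(np.argmax(steps != 60_000_000_000))
                raise DamGapError(
                    f"non 1-min step after {self.timestamps[bad]}"
                )

    def __len__(self) -> int:
        return len(self.timestamps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivityMatrix):
            return NotImplemented
        return (
            self.timestamps.equals(other.timestamps)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.light, other.light)
            and np.array_equal(self.status, other.status)
        )

    def channel(self, channel: int) -> np.ndarray:
        """Counts for one 1-based channel."""
        if not 1 <= channel <= N_CHANNELS:
            raise DamError(f"channel {channel} outside 1..{N_CHANNELS}")
        return self.counts[:, channel - 1]


def empty_matrix(monitor: str = "M001") -> ActivityMatrix:
    return ActivityMatrix(
        timestamps=pd.DatetimeIndex([]),
        counts=np.zeros((0, N_CHANNELS), dtype=np.int64),
        light=np.zeros(0, dtype=np.int64),
        status=np.zeros(0, dtype=np.int64),
        monitor=monitor,
    )


def _parse_line(line: str, lineno: int) -> tuple[datetime, int, int, np.ndarray]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < N_FIELDS:
        raise DamFormatError(
            f"line {lineno}: expected >= {N_FIELDS} fields, got {len(fields)}"
        )
    try:
        ts = datetime.strptime(f"{fields[1]} {fields[2]}", "%d %b %y %H:%M:%S")
    except ValueError as exc:
        raise DamFormatError(f"line {lineno}: bad date/time: {exc}") from exc
    try:
        status = int(fields[3])
        light = int(fields[9])
        counts = np.array([int(x) for x in fields[10:42]], dtype=np.int64)
    except ValueError as exc:
        raise DamFormatError(f"line {lineno}: bad integer field: {exc}") from exc
    return ts, status, light, counts


def read_dam_file(
    path: str | Path,
    valid_status_codes: tuple[int, ...] = (1,),
    monitor: str | None = None,
    max_gap_fill: int | None = None,
) -> ActivityMatrix:
    """Read one DAM monitor file.

    Records whose status code is not in ``valid_status_codes`` are flagged in
    :attr:`ActivityMatrix.flagged`, not dropped.  Gaps in the minute sequence
    raise :class:`DamGapError`; if ``max_gap_fill`` is given, gaps of at most
    that many minutes are zero-filled (filled rows get status 0 and are
    flagged).  Filling fabricates inactivity, so the default is a hard error.
    """
    path = Path(path)
    name = monitor or path.stem
    rows: list[tuple[datetime, int, int, np.ndarray]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rows.append(_parse_line(line, lineno))
    if not rows:
        warnings.warn(f"{path}: empty DAM file", stacklevel=2)
        return empty_matrix(name)

    ts = [r[0] for r in rows]
    for a, b in zip(ts, ts[1:]):
        if b <= a:
            raise DamGapError(f"{path}: non-monotone timestamps at {b}")

    out_ts: list[datetime] = []
    out_status: list[int] = []
    out_light: list[int] = []
    out_counts: list[np.ndarray] = []
    out_fill: list[bool] = []
    zero = np.zeros(N_CHANNELS, dtype=np.int64)
    prev: datetime | None = None
    for t, status, light, counts in rows:
        if prev is not None:
            gap = int((t - prev) / _MINUTE) - 1
            if gap > 0:
                if max_gap_fill is None or gap > max_gap_fill:
                    raise DamGapError(
                        f"{path}: {gap}-min gap after {prev} (no fill allowed)"
                    )
                for k in range(1, gap + 1):
                    out_ts.append(prev + k * _MINUTE)
                    out_status.append(0)
                    out_light.append(light)
                    out_counts.append(zero)
                    out_fill.append(True)
        out_ts.append(t)
        out_status.append(status)
        out_light.append(light)
        out_counts.append(counts)
        out_fill.append(False)
        prev = t

    status_arr = np.array(out_status)
    flagged = ~np.isin(status_arr, np.asarray(valid_status_codes)) | np.array(out_fill)
    return ActivityMatrix(
        timestamps=pd.DatetimeIndex(out_ts),
        counts=np.vstack(out_counts),
        light=np.array(out_light),
        status=status_arr,
        monitor=name,
        flagged=flagged,
    )


def write_dam_file(matrix: ActivityMatrix, path: str | Path) -> Path:
    """Write ``matrix`` in the 42-field dialect; byte-stable for fixed input."""
    path = Path(path)
    lines = []
    for i, ts in enumerate(matrix.timestamps):
        fields = [
            str(i + 1),
            f"{ts.day} {ts.strftime('%b %y')}",
            ts.strftime("%H:%M:%S"),
            str(int(matrix.status[i])),
            "1", "0", "0", "0", "0",
            str(int(matrix.light[i])),
        ]
        fields.extend(str(int(c)) for c in matrix.counts[i])
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def clip_to_assay(
    matrix: ActivityMatrix, start_time: str = "08:00", n_days: int = 4
) -> ActivityMatrix:
    """Clip to exactly ``n_days`` x 1440 minutes starting at the first
    occurrence of ``start_time`` in the recording."""
    if n_days < 0:
        raise DamError("n_days must be >= 0")
    if n_days == 0:
        return empty_matrix(matrix.monitor)
    hh, mm = (int(x) for x in start_time.split(":"))
    target = hh * 60 + mm
    mod = matrix.timestamps.hour * 60 + matrix.timestamps.minute
    hits = np.flatnonzero(mod.to_numpy() == target)
    if hits.size == 0:
        raise DamError(f"start time {start_time} not present in recording")
    start = int(hits[0])
    stop = start + n_days * 1440
    if stop > len(matrix):
        raise DamError(
            f"assay window ({n_days} d from {matrix.timestamps[start]}) "
            "exceeds recording"
        )
    return ActivityMatrix(
        timestamps=matrix.timestamps[start:stop],
        counts=matrix.counts[start:stop],
        light=matrix.light[start:stop],
        status=matrix.status[start:stop],
        monitor=matrix.monitor,
        flagged=matrix.flagged[start:stop],
    )


@dataclass
class ChannelMap:
    """(monitor, channel) -> (genotype, fly) assignment table."""

    table: pd.DataFrame  # columns: monitor, channel, genotype, fly

    def __post_init__(self) -> None:
        required = {"monitor", "channel", "genotype", "fly"}
        missing = required - set(self.table.columns)
        if missing:
            raise DamError(f"channel map missing columns: {sorted(missing)}")
        if self.table.duplicated(["monitor", "channel"]).any():
            raise DamError("duplicate (monitor, channel) keys in channel map")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ChannelMap":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def __len__(self) -> int:
        return len(self.table)
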