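"""CSV interchange for sensor recordings.

One row per sample; columns ``subject_id, activity, bout, t, acc_x, acc_y,
acc_z, gyr_x, gyr_y, gyr_z`` (UTF-8, '.' decimal, mandatory header).  A
recording is a contiguous block of rows sharing (subject_id, activity, bout);
the sampling rate is recovered from the time column on read.  Floats are
written with ``repr`` precision so write -> read round-trips exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .simulate import ACTIVITIES, CHANNELS, SensorRecording

__all__ = ["CSV_COLUMNS", "ParseError", "write_csv", "read_csv"]

CSV_COLUMNS: Sequence[str] = ("subject_id", "activity", "bout", "t") + tuple(CHANNELS)


class ParseError(ValueError):
    """Malformed sensor-log CSV; message names the offending line."""


def write_csv(recordings: Iterable[SensorRecording], path) -> None:
    """Write recordings to ``path``, one sample per row."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in recordings:
            t = np.arange(rec.n_samples) / rec.sampling_rate
            chans = rec.channels()
            for i in range(rec.n_samples):
                writer.writerow(
                    [rec.subject_id, rec.activity, rec.bout, repr(float(t[i]))]
                    + [repr(float(v)) for v in chans[:, i]]
                )


def _finish_block(key, times, rows) -> SensorRecording:
    subject_id, activity, bout = key
    data = np.asarray(rows, dtype=float).T  # (6, N)
    t = np.asarray(times, dtype=float)
    if len(t) > 1:
        rate = (len(t) - 1) / (t[-1] - t[0])
    else:
        rate = 1.0
    return SensorRecording(
        subject_id=subject_id,
        activity=activity,
        sampling_rate=round(rate, 6),
        acc=data[:3],
        gyr=data[3:],
        bout=bout,
    )


def read_csv(path) -> list[SensorRecording]:
    """Read a sensor-log CSV back into recordings.

    Contiguous rows sharing (subject_id, activity, bout) form one recording,
    in file order.  Raises :class:`ParseError` (naming the 1-based line
    number) on a bad header, an unknown activity label, or non-numeric
    sample values.
    """
    path = Path(path)
    recordings: list[SensorRecording] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: line 1: empty file, expected header")
        if tuple(header) != tuple(CSV_COLUMNS):
            raise ParseError(
                f"{path}: line 1: bad header {header!r}, expected {list(CSV_COLUMNS)}"
            )

        key = None
        times: list[float] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(CSV_COLUMNS)} fields, got {len(row)}"
                )
            subject_id, activity = row[0], row[1]
            if activity not in ACTIVITIES:
                raise ParseError(
                    f"{path}: line {lineno}: unknown activity label {activity!r}"
                )
            try:
                bout = int(row[2])
                t = float(row[3])
                vals = [float(v) for v in row[4:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric value ({exc})")
            this_key = (subject_id, activity, bout)
            if this_key != key:
                if key is not None:
                    recordings.append(_finish_block(key, times, rows))
                key, times, rows = this_key, [], []
            times.append(t)
            rows.append(vals)
        if key is not None:
            recordings.append(_finish_block(key, times, rows))
    return recordings
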