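"""Reading, writing and windowed streaming of two-channel EOG recordings.

The canonical on-disk format is a UTF-8 CSV with header columns
``time_s, eog_h, eog_v`` ('.' decimal separator).  Record metadata
(sampling rate, units, free-form keys) travels in a JSON sidecar written
next to the CSV (``<path>.meta.json``); when the sidecar is absent the
sampling rate is inferred from the time column.  Event streams are stored
as JSON lines, one event per line.

All sample indexing is 0-based; event timestamps are sample indices,
convertible to seconds through the record's sampling rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "Event",
    "EventLog",
    "read_csv",
    "write_csv",
    "stream_windows",
]

_CSV_COLUMNS = ("time_s", "eog_h", "eog_v")


@dataclass
class SignalRecord:
    """Timestamped two-channel (horizontal, vertical) EOG recording.

    Channels are stored as float arrays in ``units`` (e.g. ``"uV"`` before
    the analogue front end, ``"adc_counts"`` after digitization).
    """

    horizontal: np.ndarray
    vertical: np.ndarray
    sampling_hz: float
    units: str = "uV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.horizontal = np.asarray(self.horizontal, dtype=float)
        self.vertical = np.asarray(self.vertical, dtype=float)
        if self.horizontal.ndim != 1 or self.vertical.ndim != 1:
            raise ValueError("channels must be 1-D sample sequences")
        if len(self.horizontal) != len(self.vertical):
            raise ValueError(
                f"channel lengths differ: horizontal has {len(self.horizontal)}"
                f" samples, vertical has {len(self.vertical)}"
            )
        if len(self.horizontal) < 1:
            raise ValueError("record must contain at least one sample")
        if not self.sampling_hz > 0:
            raise ValueError(f"sampling_hz must be positive, got {self.sampling_hz}")

    @property
    def n_samples(self) -> int:
        return len(self.horizontal)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_hz

    def channel(self, name: str) -> np.ndarray:
        if name in ("h", "horizontal"):
            return self.horizontal
        if name in ("v", "vertical"):
            return self.vertical
        raise KeyError(f"unknown channel {name!r}; expected 'h' or 'v'")


@dataclass
class Event:
    """A typed pipeline event (saccade / blink / click / command)."""

    kind: str
    index: int
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "index": int(self.index), "payload": self.payload})

    @classmethod
    def from_json(cls, line: str) -> "Event":
        d = json.loads(line)
        return cls(kind=d["kind"], index=int(d["index"]), payload=d.get("payload", {}))


@dataclass
class EventLog:
    """Ordered event list tied to a record of ``n_samples`` samples."""

    events: list[Event] = field(default_factory=list)
    n_samples: int | None = None

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        indices = [e.index for e in self.events]
        if any(b < a for a, b in zip(indices, indices[1:])):
            raise ValueError("event indices must be non-decreasing")
        if self.n_samples is not None and any(i >= self.n_samples for i in indices):
            raise ValueError("event index beyond record length")

    def append(self, event: Event) -> None:
        if self.events and event.index < self.events[-1].index:
            raise ValueError("events must be appended in non-decreasing index order")
        if self.n_samples is not None and event.index >= self.n_samples:
            raise ValueError("event index beyond record length")
        self.events.append(event)

    def write_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for e in self.events:
                fh.write(e.to_json() + "\n")
        return path

    @classmethod
    def read_jsonl(cls, path: str | Path, n_samples: int | None = None) -> "EventLog":
        events = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    events.append(Event.from_json(line))
        return cls(events=events, n_samples=n_samples)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_csv(record: SignalRecord, path: str | Path) -> Path:
    """Write a record as CSV plus a ``.meta.json`` sidecar.

    The sidecar keeps the sampling rate, units and free-form metadata so a
    round trip through :func:`read_csv` preserves them.
    """
    path = Path(path)
    if record.n_samples < 1:  # SignalRecord already forbids this; guard anyway
        raise ValueError("refusing to write an empty record")
    frame = pd.DataFrame(
        {
            "time_s": record.time_s,
            "eog_h": record.horizontal,
            "eog_v": record.vertical,
        }
    )
    frame.to_csv(path, index=False, float_format="%.9g")
    meta = {"sampling_hz": record.sampling_hz, "units": record.units, "meta": record.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


def read_csv(path: str | Path) -> SignalRecord:
    """Read a two-channel EOG CSV written by :func:`write_csv` (or compatible).

    Requires columns ``eog_h`` and ``eog_v``; ``time_s`` is used to infer the
    sampling rate when no sidecar is present and must then be strictly
    increasing and uniform.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path} is empty") from exc
    for col in ("eog_h", "eog_v"):
        if col not in frame.columns:
            raise ValueError(f"{path} is missing required column {col!r}")
    if len(frame) == 0:
        raise ValueError(f"{path} contains a header but no samples")
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValueError(f"column {col!r} contains non-numeric values")

    sampling_hz = None
    units = "uV"
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        d = json.loads(sidecar.read_text(encoding="utf-8"))
        sampling_hz = d.get("sampling_hz")
        units = d.get("units", units)
        meta = d.get("meta", {})
    if sampling_hz is None:
        if "time_s" not in frame.columns:
            raise ValueError(f"{path}: no time_s column and no sidecar sampling rate")
        t = frame["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0:
            raise ValueError(f"{path}: cannot infer sampling rate from one sample")
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time_s must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: time_s is not uniformly sampled")
        sampling_hz = 1.0 / dt[0]
    return SignalRecord(
        horizontal=frame["eog_h"].to_numpy(dtype=float),
        vertical=frame["eog_v"].to_numpy(dtype=float),
        sampling_hz=float(sampling_hz),
        units=units,
        meta=meta,
    )


def stream_windows(
    record: SignalRecord, window_len: int, lookahead: int
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(t, window)`` fixed-length analysis windows around each centre.

    The window for centre ``t`` is ``record[t-pre : t-pre+window_len]`` with
    ``pre = window_len - lookahead`` (e.g. 50-sample windows spanning
    ``[t-25, t+24]`` for the default 25-sample lookahead).  A centre is valid
    only when the full window fits *and* the sample at ``t + lookahead``
    exists — the real-time pipeline may not emit an output for ``t`` before
    that sample has been acquired.  Partial windows are never yielded; a
    window longer than the record gives an empty sequence.  Yielded windows
    are copies (shape ``(window_len, 2)``, columns horizontal/vertical);
    mutating them does not touch the record.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if not 0 <= lookahead < window_len:
        raise ValueError("lookahead must satisfy 0 <= lookahead < window_len")
    pre = window_len - lookahead
    n = record.n_samples
    stacked = np.column_stack([record.horizontal, record.vertical])
    for t in range(pre, n - lookahead):
        start = t - pre
        yield t, stacked[start : start + window_len].copy()


def seconds_to_samples(t_s: float, sampling_hz: float) -> int:
    return int(round(t_s * sampling_hz))


def require_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what} contains non-finite values")
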