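"""Blink-template matching and click (multi-blink) detection.

A per-user blink template is averaged from labelled vertical-channel
blink segments (onset-aligned, resampled to a fixed length, amplitude
standardized).  Blinks are then detected by sliding Pearson-normalized
cross-correlation of the template along the vertical EOG: local maxima of
the correlation above a similarity threshold, kept non-overlapping,
become blink events.  Pearson similarity makes detection invariant to
channel gain and offset, and sign-sensitive (an inverted waveform never
matches).

Deliberate double or triple blinks inside a configurable time interval
form a "click", the validation action that confirms a selected command
(the guard against the Midas-touch problem of always-active eyes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .signal_io import require_finite

__all__ = ["BlinkTemplate", "BlinkEvent", "ClickEvent", "build_template", "match", "detect_click"]

DEFAULT_TEMPLATE_LEN = 30  # 300 ms at 100 Hz — blinks are over well within this


@dataclass
class BlinkTemplate:
    """Standardized average blink waveform plus similarity threshold.

    ``min_amplitude`` optionally gates matches on raw peak-to-peak window
    amplitude (channel units): Pearson similarity is blind to scale, so a
    smooth low-amplitude drift segment can correlate highly with the
    pulse shape; requiring blink-like amplitude as well removes those.
    When None (default) matching is purely correlation-based.
    """

    waveform: np.ndarray
    similarity_threshold: float = 0.8
    sampling_hz: float = 100.0
    min_amplitude: float | None = None

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 1 or len(self.waveform) < 2:
            raise ValueError("template waveform must be a 1-D vector of >= 2 samples")
        if float(np.std(self.waveform)) == 0.0:
            raise ValueError("template waveform is constant")
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.waveform)

    def to_json(self, path: str | Path) -> Path:
        d = {
            "waveform": self.waveform.tolist(),
            "similarity_threshold": self.similarity_threshold,
            "sampling_hz": self.sampling_hz,
            "min_amplitude": self.min_amplitude,
        }
        path = Path(path)
        path.write_text(json.dumps(d), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BlinkTemplate":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class BlinkEvent:
    """One detected blink: onset sample index and similarity score."""

    index: int
    similarity: float


@dataclass
class ClickEvent:
    """A validation click: ``count`` consecutive blinks within a window."""

    index: int  # onset of the first blink in the group
    count: int
    span: int  # samples between first and last blink onsets


def build_template(
    segments: list[np.ndarray],
    length: int = DEFAULT_TEMPLATE_LEN,
    similarity_threshold: float = 0.8,
    sampling_hz: float = 100.0,
    amplitude_fraction: float | None = None,
) -> BlinkTemplate:
    """Average onset-aligned blink segments into a standardized template.

    Segments of any length are linearly resampled to ``length`` samples
    before the pointwise mean; the mean is then z-scored so template
    matching is independent of recording gain.  When
    ``amplitude_fraction`` is given, the template additionally requires
    matched windows to reach that fraction of the median segment
    peak-to-peak amplitude (see :class:`BlinkTemplate`).
    """
    if not segments:
        raise ValueError("need at least one blink segment")
    grid = np.linspace(0.0, 1.0, length)
    resampled = []
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.ndim != 1 or len(seg) < 2:
            raise ValueError("each blink segment must be a 1-D vector of >= 2 samples")
        require_finite(seg, "blink segment")
        resampled.append(np.interp(grid, np.linspace(0.0, 1.0, len(seg)), seg))
    mean = np.mean(resampled, axis=0)
    sd = float(np.std(mean))
    if sd == 0.0:
        raise ValueError("blink segments average to a constant waveform")
    min_amplitude = None
    if amplitude_fraction is not None:
        min_amplitude = amplitude_fraction * float(np.median([np.ptp(s) for s in segments]))
    return BlinkTemplate(
        waveform=(mean - mean.mean()) / sd,
        similarity_threshold=similarity_threshold,
        sampling_hz=sampling_hz,
        min_amplitude=min_amplitude,
    )


def sliding_similarity(template: BlinkTemplate, channel: np.ndarray) -> np.ndarray:
    """Pearson correlation of the template with every channel window.

    Entry ``i`` is the correlation against ``channel[i : i+len(template)]``
    (0 where the window is constant).  Length ``n - len(template) + 1``.
    """
    x = np.asarray(channel, dtype=float)
    require_finite(x, "channel")
    L = len(template)
    if len(x) <= L:
        raise ValueError(f"channel must be longer than the {L}-sample template")
    w = template.waveform - template.waveform.mean()
    w_norm = float(np.sqrt(w @ w))
    windows = np.lib.stride_tricks.sliding_window_view(x, L)
    means = windows.mean(axis=1)
    num = windows @ w  # template already zero-mean, so means drop out
    sq = np.einsum("ij,ij->i", windows, windows) - L * means**2
    den = np.sqrt(np.maximum(sq, 0.0)) * w_norm
    out = np.zeros(len(windows))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def match(template: BlinkTemplate, channel: np.ndarray) -> list[BlinkEvent]:
    """Detect blinks on the vertical channel by template similarity.

    Local maxima of the sliding Pearson correlation above the template's
    similarity threshold become events; maxima closer than one template
    length are suppressed greedily in time order (non-overlapping
    matches).  Event indices are match onsets (start of the window).
    """
    x = np.asarray(channel, dtype=float)
    r = sliding_similarity(template, x)
    L = len(template)
    peaks, _ = find_peaks(r, height=template.similarity_threshold)
    events: list[BlinkEvent] = []
    last = -np.inf
    for p in peaks:
        if p - last < L:
            continue
        if template.min_amplitude is not None and np.ptp(x[p : p + L]) < template.min_amplitude:
            continue
        last = p
        events.append(BlinkEvent(index=int(p), similarity=float(r[p])))
    return events


def detect_click(
    blinks: list[BlinkEvent],
    required_count: int = 2,
    max_interval_s: float = 2.0,
    sampling_hz: float = 100.0,
) -> list[ClickEvent]:
    """Group consecutive blinks into validation clicks.

    Greedy left-to-right: the earliest run of ``required_count``
    consecutive blinks whose onset span fits within ``max_interval_s``
    forms a click, its blinks are consumed, and scanning continues after
    them, so clicks never share blinks and are disjoint in time.
    """
    if required_count not in (2, 3):
        raise ValueError("required_count must be 2 or 3")
    if not max_interval_s > 0:
        raise ValueError("max_interval_s must be > 0")
    idx = [b.index for b in blinks]
    if any(b < a for a, b in zip(idx, idx[1:])):
        raise ValueError("blink events must be sorted by index")
    max_span = int(round(max_interval_s * sampling_hz))
    clicks: list[ClickEvent] = []
    i = 0
    while i + required_count <= len(blinks):
        span = blinks[i + required_count - 1].index - blinks[i].index
        if span <= max_span:
            clicks.append(ClickEvent(index=blinks[i].index, count=required_count, span=span))
            i += required_count
        else:
            i += 1
    return clicks
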