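"""Linear saccadic model: calibration, candidate detection, quantification.

The EOG is treated as linear in gaze angle, ``eye_movement = k * EOG_variation``,
with a per-channel gain ``k`` (degrees per signal unit) fitted during a
calibration session in which the user fixates a series of known screen
positions.  A saccade candidate is declared wherever the magnitude of the
single-scale CWT of the channel (a magnified derivative) exceeds a minimum
threshold; the EOG variation across the transition is then read off as the
difference between post- and pre-transition medians over 100 ms flanking
windows, and the movement angle is ``k`` times that variation, signed
(positive = rightward / upward).

The threshold itself is calibrated: by default half of the smallest
calibration saccade's peak CWT magnitude, which keeps the exact value
uncritical (the CWT magnifies transitions well clear of the noise floor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .cwt_filter import CWTConfig, cwt_single_scale
from .signal_io import require_finite

__all__ = [
    "CalibrationModel",
    "CalibrationSegment",
    "SaccadeCandidate",
    "calibrate",
    "detect_candidates",
    "measure_variation",
    "quantify",
]

_CHANNELS = ("h", "v")


@dataclass
class CalibrationModel:
    """Per-channel linear gain and detection threshold.

    ``k_h``/``k_v`` are in degrees per signal unit; ``threshold_h``/
    ``threshold_v`` are CWT-coefficient magnitudes; ``refractory`` is the
    minimum accepted separation between candidates, in samples.
    """

    k_h: float
    k_v: float
    threshold_h: float
    threshold_v: float
    refractory: int = 20
    sampling_hz: float = 100.0

    def __post_init__(self) -> None:
        for name in ("k_h", "k_v", "threshold_h", "threshold_v"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.refractory < 1:
            raise ValueError("refractory must be >= 1 sample")

    def k(self, channel: str) -> float:
        return self.k_h if channel == "h" else self.k_v

    def threshold(self, channel: str) -> float:
        return self.threshold_h if channel == "h" else self.threshold_v

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class CalibrationSegment:
    """One labelled calibration recording: a single saccade of known angle."""

    samples: np.ndarray
    angle_deg: float
    channel: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be 'h' or 'v', got {self.channel!r}")


@dataclass
class SaccadeCandidate:
    """A threshold-crossing transition on one channel.

    ``index`` is the transition position in signal time (0-based sample),
    ``variation`` the signed amplitude change across it in signal units,
    ``angle_deg = k * variation`` the signed movement estimate.
    """

    index: int
    channel: str
    variation: float
    angle_deg: float


def quantify(variation: float, k: float) -> float:
    """Movement angle in degrees: ``k * variation``, sign preserved.

    Negative variations map to leftward (H) or downward (V) movements.
    """
    if not (np.isfinite(variation) and np.isfinite(k)):
        raise ValueError("variation and k must be finite")
    return k * variation


def measure_variation(
    x: np.ndarray,
    index: int,
    sampling_hz: float,
    gap_s: float = 0.05,
    window_s: float = 0.1,
) -> float | None:
    """Signed amplitude change across a transition at ``index``.

    Difference between the medians of 100 ms windows after and before the
    transition, offset by ``gap_s`` to skip the transition itself.
    Returns None when either flanking window does not fit in the record.
    """
    gap = max(1, int(round(gap_s * sampling_hz)))
    win = max(1, int(round(window_s * sampling_hz)))
    lo = index - gap - win
    hi = index + gap + win
    if lo < 0 or hi >= len(x):
        return None
    pre = np.median(x[lo : index - gap])
    post = np.median(x[index + gap + 1 : hi + 1])
    return float(post - pre)


def calibrate(
    segments: list[CalibrationSegment],
    cfg: CWTConfig | None = None,
    sampling_hz: float = 100.0,
    threshold_fraction: float = 0.5,
    refractory_s: float = 0.2,
) -> CalibrationModel:
    """Fit per-channel gain ``k`` and detection threshold from labelled segments.

    Each segment must contain exactly one saccade of known signed angle.
    For every segment the CWT peak locates the transition and the flanking-
    median rule measures the EOG variation; ``k`` is then the least-squares
    slope of angle on variation *through the origin* (the model has no
    intercept), and the threshold is ``threshold_fraction`` times the
    smallest calibration peak magnitude.  At least two distinct |angle|
    values are required per channel.
    """
    cfg = cfg or CWTConfig()
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    per_channel: dict[str, dict[str, list[float]]] = {
        ch: {"angles": [], "variations": [], "peaks": []} for ch in _CHANNELS
    }
    for seg in segments:
        require_finite(seg.samples, "calibration segment")
        coeffs = cwt_single_scale(seg.samples, cfg, align="center")
        peak = int(np.argmax(np.abs(coeffs)))
        variation = measure_variation(seg.samples, peak, sampling_hz)
        if variation is None:
            raise ValueError(
                f"calibration segment too short to measure the variation around"
                f" its transition (peak at sample {peak} of {len(seg.samples)})"
            )
        acc = per_channel[seg.channel]
        acc["angles"].append(seg.angle_deg)
        acc["variations"].append(variation)
        acc["peaks"].append(float(np.abs(coeffs[peak])))

    fitted = {}
    for ch, acc in per_channel.items():
        if len(set(np.round(np.abs(acc["angles"]), 6))) < 2:
            raise ValueError(
                f"channel {ch!r} needs segments at >= 2 distinct known angles,"
                f" got {sorted(set(acc['angles']))}"
            )
        v = np.asarray(acc["variations"])
        a = np.asarray(acc["angles"])
        denom = float(v @ v)
        if denom == 0.0:
            raise ValueError(f"channel {ch!r} calibration measurements have zero variance")
        fitted[ch] = {
            "k": float(a @ v) / denom,
            "threshold": threshold_fraction * min(acc["peaks"]),
        }
        if not fitted[ch]["k"] > 0:
            raise ValueError(
                f"channel {ch!r} calibration produced non-positive gain"
                f" k={fitted[ch]['k']:.4g}; check segment polarity/labels"
            )
    return CalibrationModel(
        k_h=fitted["h"]["k"],
        k_v=fitted["v"]["k"],
        threshold_h=fitted["h"]["threshold"],
        threshold_v=fitted["v"]["threshold"],
        refractory=max(1, int(round(refractory_s * sampling_hz))),
        sampling_hz=sampling_hz,
    )


def detect_candidates(
    coeffs: np.ndarray,
    channel_samples: np.ndarray,
    model: CalibrationModel,
    channel: str,
    onset_delay: int = 0,
) -> list[SaccadeCandidate]:
    """Threshold the CWT magnitude and quantify each detected transition.

    A candidate is placed at every local extremum of ``|coeffs|`` above the
    channel threshold; extrema are accepted greedily in time order with a
    minimum separation of ``model.refractory`` samples (a causal rule: an
    accepted detection is never retracted by a later, larger peak).
    ``onset_delay`` converts detection indices back to signal-time onsets
    when ``coeffs`` came from the causal CWT alignment.  Candidates whose
    flanking measurement windows do not fit in the record are dropped.
    """
    if channel not in _CHANNELS:
        raise ValueError(f"channel must be 'h' or 'v', got {channel!r}")
    mag = np.abs(np.asarray(coeffs, dtype=float))
    x = np.asarray(channel_samples, dtype=float)
    thr = model.threshold(channel)
    k = model.k(channel)
    peaks, _ = find_peaks(mag, height=thr)
    out: list[SaccadeCandidate] = []
    last = -np.inf
    for p in peaks:
        if p - last < model.refractory:
            continue
        last = p
        onset = int(p) - onset_delay
        variation = measure_variation(x, onset, model.sampling_hz)
        if variation is None:
            continue
        out.append(
            SaccadeCandidate(
                index=onset,
                channel=channel,
                variation=variation,
                angle_deg=quantify(variation, k),
            )
        )
    return out
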