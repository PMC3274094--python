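"""Ground-truthed synthetic two-channel EOG generator.

Emulates both the physiology the detection pipeline assumes and the
analogue acquisition chain it sits behind:

* **Saccades** — the corneo-retinal dipole makes the electrode-pair
  voltage roughly proportional to gaze angle, so a saccade appears as a
  smoothed step on the horizontal and/or vertical channel.  Steps are
  modelled as logistic sigmoids with a ~40 ms transition; amplitude is
  ``uv_per_degree`` x degrees (default 15 uV/deg keeps 10-40 degree
  saccades within the 50-3500 uV physiological EOG range).  Rightward and
  upward gaze deflect the H and V channels positively.
* **Blinks** — eyelid artefacts on the vertical channel only: a
  positive pulse with a fast rise (30 ms, faster than any saccadic
  transition) and a slower return to baseline, 250 ms in total — far
  shorter than the held fixation that follows a saccadic step, which is
  the property the blink/saccade discrimination relies on.
* **Nuisance terms** — baseline drift (white noise low-passed below
  0.1 Hz, scaled to a target RMS), mains interference (50 Hz sinusoid
  with random phase) and white measurement noise.
* **Front end** — two-stage amplification (differential first stage,
  gain 20; adjustable inverting second stage, 0-250 in 256 digital-pot
  steps; total per-channel gain 0-5000) with first-order band-pass
  corners at 0.05 Hz and 35 Hz, followed by a 12-bit ADC at 100 Hz.
  Filters are applied causally, as the analogue hardware would.

Every generated recording carries a :class:`GroundTruth` aligned to the
scheduled event onsets (the causal first-order filters delay onsets by
well under one sample at 100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import json
import numpy as np
import yaml
from scipy.signal import butter, lfilter
from scipy.special import expit

from .signal_io import SignalRecord

__all__ = [
    "FrontEndConfig",
    "ScenarioSpec",
    "SaccadeSpec",
    "BlinkSpec",
    "GroundTruth",
    "TrueSaccade",
    "TrueBlink",
    "generate_recording",
    "render_uv",
    "calibration_scenario",
    "saccade_series_scenario",
    "staircase_scenario",
]

SECOND_STAGE_MAX = 250.0
SECOND_STAGE_STEPS = 256
_VALID_SAMPLING = tuple(range(100, 301, 10))


@dataclass
class FrontEndConfig:
    """Parameters of the emulated analogue front end and ADC.

    The differential first stage has fixed mid-band gain
    ``first_stage_gain`` (20) and sets the band-pass corners; the second
    stage is an inverting amplifier whose gain a digital potentiometer
    steps over [0, 250] in 256 positions, for a total per-channel gain of
    0-5000.  The ADC digitizes ``adc_range_v`` volts bipolar at
    ``adc_bits`` resolution, ``sampling_hz`` adjustable over 100-300 Hz in
    10 Hz steps.
    """

    first_stage_gain: float = 20.0
    second_stage_gain: float = 100.0
    low_cutoff_hz: float = 0.05
    high_cutoff_hz: float = 35.0
    adc_bits: int = 12
    sampling_hz: float = 100.0
    adc_range_v: float = 3.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.second_stage_gain <= SECOND_STAGE_MAX:
            raise ValueError(
                f"second_stage_gain must lie in [0, {SECOND_STAGE_MAX}],"
                f" got {self.second_stage_gain}"
            )
        # snap to the digital potentiometer's 256 positions
        step = SECOND_STAGE_MAX / (SECOND_STAGE_STEPS - 1)
        self.second_stage_gain = round(self.second_stage_gain / step) * step
        if self.first_stage_gain < 0:
            raise ValueError("first_stage_gain must be >= 0")
        if not 0.0 <= self.total_gain <= 5000.0:
            raise ValueError(f"total gain {self.total_gain} outside [0, 5000]")
        if int(self.sampling_hz) != self.sampling_hz or int(self.sampling_hz) not in _VALID_SAMPLING:
            raise ValueError(
                f"sampling_hz must be one of {{100, 110, ..., 300}}, got {self.sampling_hz}"
            )
        if not 0 < self.low_cutoff_hz < self.high_cutoff_hz < self.sampling_hz / 2:
            raise ValueError(
                "cut-offs must satisfy 0 < low < high < sampling_hz/2, got"
                f" {self.low_cutoff_hz}, {self.high_cutoff_hz} at fs={self.sampling_hz}"
            )
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")
        if not self.adc_range_v > 0:
            raise ValueError("adc_range_v must be > 0")

    @property
    def total_gain(self) -> float:
        return self.first_stage_gain * self.second_stage_gain

    @property
    def max_total_gain(self) -> float:
        """Largest configurable end-to-end gain (first stage x pot at 250)."""
        return self.first_stage_gain * SECOND_STAGE_MAX

    @property
    def lsb_v(self) -> float:
        return self.adc_range_v / 2**self.adc_bits

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FrontEndConfig":
        return cls(**d)


@dataclass
class SaccadeSpec:
    """One scheduled saccade: gaze shifts by (h_deg, v_deg) at onset_s."""

    onset_s: float
    h_deg: float
    v_deg: float


@dataclass
class BlinkSpec:
    """One scheduled blink burst: ``count`` pulses ``gap_s`` apart."""

    onset_s: float
    count: int = 1
    gap_s: float = 0.5


@dataclass
class ScenarioSpec:
    """A scripted recording session: events plus noise/sensitivity settings.

    Amplitude fields are in microvolts at the electrodes (pre-amplifier);
    ``drift_amplitude_uv`` is the RMS of the drift term.  Event footprints
    must be separated by at least ``refractory_gap_s``.
    """

    duration_s: float
    saccades: list[SaccadeSpec] = field(default_factory=list)
    blinks: list[BlinkSpec] = field(default_factory=list)
    drift_amplitude_uv: float = 20.0
    mains_amplitude_uv: float = 5.0
    mains_hz: float = 50.0
    noise_sd_uv: float = 5.0
    uv_per_degree: float = 15.0
    blink_amplitude_uv: float = 300.0
    saccade_transition_s: float = 0.04
    blink_duration_s: float = 0.25
    blink_rise_s: float = 0.03
    refractory_gap_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.saccades = [s if isinstance(s, SaccadeSpec) else SaccadeSpec(*s) for s in self.saccades]
        self.blinks = [b if isinstance(b, BlinkSpec) else BlinkSpec(*b) for b in self.blinks]
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        for name in (
            "drift_amplitude_uv",
            "mains_amplitude_uv",
            "noise_sd_uv",
            "uv_per_degree",
            "blink_amplitude_uv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.blink_rise_s < self.blink_duration_s:
            raise ValueError("blink_rise_s must lie in (0, blink_duration_s)")
        for b in self.blinks:
            if b.count not in (1, 2, 3):
                raise ValueError(f"blink count must be 1, 2 or 3, got {b.count}")
            if b.count > 1 and not b.gap_s > 0:
                raise ValueError("inter-blink gap must be > 0")
        self._check_footprints()

    def _footprints(self) -> list[tuple[float, float, str]]:
        spans = []
        for s in self.saccades:
            half = self.saccade_transition_s
            spans.append((s.onset_s - half, s.onset_s + half, "saccade"))
        for b in self.blinks:
            end = b.onset_s + (b.count - 1) * b.gap_s + self.blink_duration_s
            spans.append((b.onset_s, end, "blink"))
        return sorted(spans)

    def _check_footprints(self) -> None:
        spans = self._footprints()
        for (s0, e0, k0), (s1, e1, k1) in zip(spans, spans[1:]):
            if s1 - e0 < self.refractory_gap_s:
                raise ValueError(
                    f"{k1} at {s1:.3f}s starts within the {self.refractory_gap_s}s"
                    f" refractory gap after the {k0} ending at {e0:.3f}s"
                )
        for s0, e0, kind in spans:
            if s0 < 0 or e0 > self.duration_s:
                raise ValueError(f"{kind} footprint [{s0:.3f}, {e0:.3f}]s outside the recording")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        d["saccades"] = [SaccadeSpec(**s) if isinstance(s, dict) else SaccadeSpec(*s) for s in d.get("saccades", [])]
        d["blinks"] = [BlinkSpec(**b) if isinstance(b, dict) else BlinkSpec(*b) for b in d.get("blinks", [])]
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioSpec":
        return cls.from_dict(_load_config_file(path))

    def to_file(self, path: str | Path) -> Path:
        return _dump_config_file(self.to_dict(), path)


@dataclass
class TrueSaccade:
    index: int
    h_deg: float
    v_deg: float
    direction: str | None = None


@dataclass
class TrueBlink:
    index: int
    count: int
    pulse_indices: list[int] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Scheduled-event bookkeeping aligned to sample indices."""

    saccades: list[TrueSaccade]
    blinks: list[TrueBlink]
    n_samples: int

    def __post_init__(self) -> None:
        for s in self.saccades:
            if not 0 <= s.index < self.n_samples:
                raise ValueError("saccade index outside record")
        for b in self.blinks:
            if not 0 <= b.index < self.n_samples:
                raise ValueError("blink index outside record")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            saccades=[TrueSaccade(**s) for s in d["saccades"]],
            blinks=[TrueBlink(**b) for b in d["blinks"]],
            n_samples=d["n_samples"],
        )


def _load_config_file(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_config_file(d: dict, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(d, indent=1), encoding="utf-8")
    return path


def _blink_pulse(t: np.ndarray, onset: float, amp: float, rise: float, dur: float) -> np.ndarray:
    """Fast half-cosine rise, slower half-cosine return to baseline."""
    u = t - onset
    out = np.zeros_like(t)
    up = (u >= 0) & (u < rise)
    down = (u >= rise) & (u < dur)
    out[up] = 0.5 * amp * (1 - np.cos(np.pi * u[up] / rise))
    out[down] = 0.5 * amp * (1 + np.cos(np.pi * (u[down] - rise) / (dur - rise)))
    return out


def render_uv(spec: ScenarioSpec, sampling_hz: float = 100.0) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render the clean (noise-free, pre-amplifier) microvolt traces.

    Returns ``(h_uv, v_uv, truth)``.  Useful for inspecting the event
    model in isolation; :func:`generate_recording` adds nuisance terms and
    the front-end chain on top of these traces plus scheduled noise.
    """
    from .event_fusion import classify_direction  # local import avoids a cycle

    n = int(round(spec.duration_s * sampling_hz))
    t = np.arange(n) / sampling_hz
    h = np.zeros(n)
    v = np.zeros(n)
    tau = spec.saccade_transition_s / 6.0  # ~5-95% swing within one transition
    true_saccades = []
    for s in spec.saccades:
        step = expit((t - s.onset_s) / tau)
        h += spec.uv_per_degree * s.h_deg * step
        v += spec.uv_per_degree * s.v_deg * step
        true_saccades.append(
            TrueSaccade(
                index=int(round(s.onset_s * sampling_hz)),
                h_deg=s.h_deg,
                v_deg=s.v_deg,
                direction=classify_direction(s.h_deg, s.v_deg, min_angle=0.0),
            )
        )
    true_blinks = []
    for b in spec.blinks:
        pulses = []
        for j in range(b.count):
            onset = b.onset_s + j * b.gap_s
            v += _blink_pulse(t, onset, spec.blink_amplitude_uv, spec.blink_rise_s, spec.blink_duration_s)
            pulses.append(int(round(onset * sampling_hz)))
        true_blinks.append(TrueBlink(index=pulses[0], count=b.count, pulse_indices=pulses))
    truth = GroundTruth(saccades=true_saccades, blinks=true_blinks, n_samples=n)
    return h, v, truth


def _drift(rng: np.random.Generator, n: int, fs: float, rms_uv: float) -> np.ndarray:
    if rms_uv == 0 or n < 10:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = butter(1, 0.1, btype="low", fs=fs)
    d = lfilter(b, a, white)
    scale = np.sqrt(np.mean(d**2))
    return d * (rms_uv / scale) if scale > 0 else np.zeros(n)


def _front_end(x_uv: np.ndarray, fe: FrontEndConfig) -> np.ndarray:
    """Amplify, band-pass and digitize one channel; returns ADC counts."""
    volts = x_uv * 1e-6 * fe.first_stage_gain
    bh, ah = butter(1, fe.low_cutoff_hz, btype="high", fs=fe.sampling_hz)
    bl, al = butter(1, fe.high_cutoff_hz, btype="low", fs=fe.sampling_hz)
    volts = lfilter(bl, al, lfilter(bh, ah, volts))
    volts = volts * fe.second_stage_gain
    half = 2 ** (fe.adc_bits - 1)
    counts = np.clip(np.rint(volts / fe.lsb_v), -half, half - 1)
    return counts


def generate_recording(
    spec: ScenarioSpec, fe: FrontEndConfig | None = None
) -> tuple[SignalRecord, GroundTruth]:
    """Generate a seeded two-channel EOG recording with ground truth.

    The clean event traces from :func:`render_uv` are summed with drift,
    mains interference and white noise (all drawn from
    ``default_rng(spec.seed)``), passed through the emulated analogue
    front end and quantized by the ADC.  Identical ``(spec, fe)`` produce
    bit-identical records.
    """
    fe = fe or FrontEndConfig()
    fs = fe.sampling_hz
    rng = np.random.default_rng(spec.seed)
    h, v, truth = render_uv(spec, sampling_hz=fs)
    n = len(h)
    t = np.arange(n) / fs
    for x in (h, v):
        x += _drift(rng, n, fs, spec.drift_amplitude_uv)
        x += spec.mains_amplitude_uv * np.sin(2 * np.pi * spec.mains_hz * t + rng.uniform(0, 2 * np.pi))
        x += rng.normal(0.0, spec.noise_sd_uv, n)
    record = SignalRecord(
        horizontal=_front_end(h, fe),
        vertical=_front_end(v, fe),
        sampling_hz=fs,
        units="adc_counts",
        meta={
            "lsb_v": fe.lsb_v,
            "total_gain": fe.total_gain,
            "uv_per_degree": spec.uv_per_degree,
            "seed": spec.seed,
        },
    )
    return record, truth


# ---------------------------------------------------------------------------
# scenario builders used by the calibration and evaluation protocols


def calibration_scenario(
    angles: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0),
    channels: tuple[str, ...] = ("h", "v"),
    n_blink_events: int = 3,
    spacing_s: float = 1.2,
    seed: int = 0,
    **kwargs,
) -> ScenarioSpec:
    """Scripted calibration session: known-angle saccades plus blinks.

    For each channel the gaze steps out to each angle and back to centre
    (so every angle contributes a positive and a negative transition),
    then ``n_blink_events`` double blinks are recorded for the blink
    template.  Extra keyword arguments override :class:`ScenarioSpec`
    noise/sensitivity defaults.
    """
    saccades: list[SaccadeSpec] = []
    t = 1.0
    for ch in channels:
        for a in angles:
            out = (a, 0.0) if ch == "h" else (0.0, a)
            saccades.append(SaccadeSpec(t, *out))
            t += spacing_s
            saccades.append(SaccadeSpec(t, -out[0], -out[1]))
            t += spacing_s
    blinks = []
    for _ in range(n_blink_events):
        blinks.append(BlinkSpec(t, count=2, gap_s=0.5))
        t += 2.0
    return ScenarioSpec(
        duration_s=t + 1.0, saccades=saccades, blinks=blinks, seed=seed, **kwargs
    )


def saccade_series_scenario(
    n_saccades: int = 200,
    angle_range: tuple[float, float] = (10.0, 40.0),
    spacing_s: float = 1.3,
    seed: int = 0,
    **kwargs,
) -> ScenarioSpec:
    """Random out-and-back saccade series for accuracy measurements.

    Saccades alternate between an outward step of magnitude drawn
    uniformly from ``angle_range`` (random channel and sign) and the
    matching return to centre; each transition is a ground-truth saccade,
    so ``n_saccades`` transitions are scheduled in total.
    """
    if n_saccades % 2:
        raise ValueError("n_saccades must be even (out-and-back pairs)")
    rng = np.random.default_rng(seed)
    saccades = []
    t = 1.0
    for _ in range(n_saccades // 2):
        mag = rng.uniform(*angle_range)
        sign = rng.choice([-1.0, 1.0])
        ch = rng.choice(["h", "v"])
        delta = (sign * mag, 0.0) if ch == "h" else (0.0, sign * mag)
        saccades.append(SaccadeSpec(t, *delta))
        t += spacing_s
        saccades.append(SaccadeSpec(t, -delta[0], -delta[1]))
        t += spacing_s
    return ScenarioSpec(duration_s=t + 1.0, saccades=saccades, seed=seed + 1, **kwargs)


def staircase_scenario(
    angles: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0),
    channel: str = "h",
    spacing_s: float = 1.5,
    seed: int = 0,
    **kwargs,
) -> ScenarioSpec:
    """Progressive gaze shifts (10, 20, 30, 40 degrees) on one channel.

    The gaze returns to centre between steps, so the EOG shows a staircase
    of increasingly tall steps — the canonical demonstration signal for
    the detection pipeline.
    """
    saccades = []
    t = 1.0
    for a in angles:
        delta = (a, 0.0) if channel == "h" else (0.0, a)
        saccades.append(SaccadeSpec(t, *delta))
        t += spacing_s
        saccades.append(SaccadeSpec(t, -delta[0], -delta[1]))
        t += spacing_s
    return ScenarioSpec(duration_s=t + 1.0, saccades=saccades, seed=seed, **kwargs)
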