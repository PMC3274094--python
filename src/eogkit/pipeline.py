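"""Two-phase processing pipeline: fit user models, then detect and decode.

Phase one (optional, re-run when a user's signals change): from a
ground-truthed calibration recording, fit the linear saccadic calibration,
build the blink template and train the RBF validator.  Phase two: run a
recording through CWT filtering, candidate detection, network validation,
blink matching and event fusion, producing validated saccades, clicks and
decoded commands.

Real-time contract: phase two uses the *causal* CWT alignment, so every
emitted saccade depends only on samples up to its detection index plus the
configured lookahead (25 samples = 250 ms at 100 Hz, the wait for the
second half of the network's analysis window).  Event indices reported to
callers are signal-time onsets; ``DetectionResult.emitted_at`` gives the
corresponding causal emission samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .blink_detector import (
    BlinkEvent,
    BlinkTemplate,
    ClickEvent,
    build_template,
    detect_click,
    match,
)
from .cwt_filter import CWTConfig, causal_delay, cwt_single_scale
from .elm_rbf import ELMModel, build_training_set, train_elm
from .event_fusion import (
    CommandEvent,
    FusionPolicy,
    ValidatedSaccade,
    decode_commands,
    events_to_log,
    fuse,
)
from .saccade_model import CalibrationModel, CalibrationSegment, SaccadeCandidate, calibrate, detect_candidates
from .signal_io import EventLog, SignalRecord
from .synthetic_eog import GroundTruth, _dump_config_file, _load_config_file

__all__ = ["PipelineConfig", "UserModels", "DetectionResult", "fit_user_models", "detect_session"]


@dataclass
class PipelineConfig:
    """All tunables of the detection pipeline in one serializable place."""

    cwt: CWTConfig = field(default_factory=CWTConfig)
    window_len: int = 50
    lookahead: int = 25
    threshold_fraction: float = 0.5
    refractory_s: float = 0.2
    n_hidden: int = 20
    elm_mode: str = "weighted"
    n_training_segments: int = 100
    blink_similarity_threshold: float = 0.8
    blink_amplitude_fraction: float = 0.4
    # template segments span pre-onset baseline + pulse + return-to-baseline
    # tail: a blink is over within the window while a saccadic step is not,
    # which is what lets the matcher reject vertical saccades.
    blink_pre_s: float = 0.1
    blink_post_s: float = 0.35
    template_len: int = 45
    click_count: int = 2
    click_interval_s: float = 2.0
    validation_window_s: float = 2.0
    coincidence_s: float = 0.25
    merge_s: float = 0.05
    min_angle_deg: float = 5.0

    def __post_init__(self) -> None:
        if isinstance(self.cwt, dict):
            self.cwt = CWTConfig.from_dict(self.cwt)
        if not 0 <= self.lookahead < self.window_len:
            raise ValueError("lookahead must satisfy 0 <= lookahead < window_len")
        if self.click_count not in (2, 3):
            raise ValueError("click_count must be 2 or 3")

    def policy(self, sampling_hz: float) -> FusionPolicy:
        return FusionPolicy(
            coincidence_s=self.coincidence_s,
            merge_s=self.merge_s,
            min_angle_deg=self.min_angle_deg,
            sampling_hz=sampling_hz,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cwt"] = self.cwt.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(_load_config_file(path))

    def to_file(self, path: str | Path) -> Path:
        return _dump_config_file(self.to_dict(), path)


@dataclass
class UserModels:
    """The three per-user artifacts of the calibration/training phase."""

    calibration: CalibrationModel
    template: BlinkTemplate
    elm: ELMModel

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.calibration.to_json(directory / "calibration.json")
        self.template.to_json(directory / "blink_template.json")
        self.elm.to_json(directory / "elm.json")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "UserModels":
        directory = Path(directory)
        return cls(
            calibration=CalibrationModel.from_json(directory / "calibration.json"),
            template=BlinkTemplate.from_json(directory / "blink_template.json"),
            elm=ELMModel.from_json(directory / "elm.json"),
        )


@dataclass
class DetectionResult:
    """Everything phase two produced for one recording."""

    candidates: list[SaccadeCandidate]
    validated: list[ValidatedSaccade]
    blinks: list[BlinkEvent]
    clicks: list[ClickEvent]
    commands: list[CommandEvent]
    emitted_at: dict[int, int] = field(default_factory=dict)  # saccade index -> emission sample

    def to_event_log(self, n_samples: int | None = None) -> EventLog:
        return events_to_log(self.validated, self.clicks, self.commands, n_samples)

    def summary(self) -> dict:
        return {
            "candidates": len(self.candidates),
            "validated_saccades": len(self.validated),
            "blinks": len(self.blinks),
            "clicks": len(self.clicks),
            "commands": [c.command for c in self.commands],
        }


def decision_latency(cfg: PipelineConfig, template_len: int, sampling_hz: float = 100.0) -> int:
    """Samples between a saccade's onset and its validated emission.

    The network validation itself waits ``causal_delay + lookahead``
    samples (the CWT group delay plus the 25-sample / 250 ms second half
    of the analysis window).  Blink arbitration can extend this: a blink
    whose pulse starts up to ``coincidence_s`` after the onset still
    discards the candidate, and that blink is only recognized once its
    template window completes.  The emission sample is the onset plus the
    larger of the two, and no output depends on any later sample.
    """
    coincidence = int(round(cfg.coincidence_s * sampling_hz))
    return max(causal_delay(cfg.cwt) + cfg.lookahead, coincidence + template_len)


def calibration_segments_from_truth(
    record: SignalRecord, truth: GroundTruth, half_width_s: float = 0.5
) -> list[CalibrationSegment]:
    """Cut one labelled segment per ground-truth saccade (per moving axis)."""
    half = int(round(half_width_s * record.sampling_hz))
    segments = []
    for s in truth.saccades:
        lo, hi = s.index - half, s.index + half
        if lo < 0 or hi > record.n_samples:
            continue
        for ch, deg in (("h", s.h_deg), ("v", s.v_deg)):
            if deg != 0.0:
                segments.append(
                    CalibrationSegment(
                        samples=record.channel(ch)[lo:hi], angle_deg=deg, channel=ch
                    )
                )
    return segments


def blink_segments_from_truth(
    record: SignalRecord,
    truth: GroundTruth,
    pre_s: float = 0.1,
    post_s: float = 0.35,
) -> list[np.ndarray]:
    """Cut aligned vertical-channel segments around each true blink pulse.

    Each segment runs from ``pre_s`` before the pulse onset to ``post_s``
    after it, so the template records baseline - pulse - baseline.
    """
    fs = record.sampling_hz
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    segs = []
    for b in truth.blinks:
        for p in b.pulse_indices:
            if p - pre >= 0 and p + post <= record.n_samples:
                segs.append(record.vertical[p - pre : p + post])
    return segs


def fit_user_models(
    record: SignalRecord,
    truth: GroundTruth,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> UserModels:
    """Phase one: calibration, blink template and trained RBF validator."""
    cfg = cfg or PipelineConfig()
    fs = record.sampling_hz
    calibration = calibrate(
        calibration_segments_from_truth(record, truth),
        cfg.cwt,
        sampling_hz=fs,
        threshold_fraction=cfg.threshold_fraction,
        refractory_s=cfg.refractory_s,
    )
    blink_segs = blink_segments_from_truth(record, truth, cfg.blink_pre_s, cfg.blink_post_s)
    if not blink_segs:
        raise ValueError("calibration recording contains no blink segments")
    template = build_template(
        blink_segs,
        length=cfg.template_len,
        similarity_threshold=cfg.blink_similarity_threshold,
        sampling_hz=fs,
        amplitude_fraction=cfg.blink_amplitude_fraction,
    )
    coeffs = {ch: cwt_single_scale(record.channel(ch), cfg.cwt, align="center") for ch in ("h", "v")}
    training = build_training_set(
        coeffs,
        truth,
        window_len=cfg.window_len,
        lookahead=cfg.lookahead,
        n_segments=cfg.n_training_segments,
        seed=seed,
    )
    elm = train_elm(training, n_hidden=cfg.n_hidden, seed=seed, mode=cfg.elm_mode)
    return UserModels(calibration=calibration, template=template, elm=elm)


def detect_session(
    record: SignalRecord, models: UserModels, cfg: PipelineConfig | None = None
) -> DetectionResult:
    """Phase two: CWT -> candidates -> RBF validation -> blinks -> fusion.

    Raises ValueError when the record's sampling rate disagrees with the
    calibration model's.
    """
    cfg = cfg or PipelineConfig()
    fs = record.sampling_hz
    if abs(fs - models.calibration.sampling_hz) > 1e-9:
        raise ValueError(
            f"recording sampled at {fs} Hz but models were calibrated at"
            f" {models.calibration.sampling_hz} Hz"
        )
    delay = causal_delay(cfg.cwt)
    pre = cfg.window_len - cfg.lookahead
    n = record.n_samples

    candidates: list[SaccadeCandidate] = []
    coeffs: dict[str, np.ndarray] = {}
    for ch in ("h", "v"):
        x = record.channel(ch)
        c = cwt_single_scale(x, cfg.cwt, align="causal")
        coeffs[ch] = c
        candidates.extend(
            detect_candidates(c, x, models.calibration, ch, onset_delay=delay)
        )
    candidates.sort(key=lambda c: c.index)

    classes: list[int] = []
    for cand in candidates:
        t = cand.index + delay  # detection index on the causal coefficient timeline
        start = t - pre
        if start < 0 or t + cfg.lookahead > n - 1:
            classes.append(0)  # window (or its emission sample) unavailable
            continue
        window = coeffs[cand.channel][start : start + cfg.window_len]
        classes.append(models.elm.classify(window))

    # match indices point at the template window start, blink_pre_s before
    # the pulse onset; re-index to pulse onsets for fusion and click timing
    pre_blink = int(round(cfg.blink_pre_s * fs))
    raw_blinks = match(models.template, record.vertical) if n > cfg.template_len else []
    blinks = [BlinkEvent(index=b.index + pre_blink, similarity=b.similarity) for b in raw_blinks]
    clicks = detect_click(
        blinks, required_count=cfg.click_count, max_interval_s=cfg.click_interval_s, sampling_hz=fs
    )
    validated = fuse(candidates, classes, blinks, cfg.policy(fs))
    commands = decode_commands(
        validated,
        clicks,
        validation_window_s=cfg.validation_window_s,
        sampling_hz=fs,
    )
    latency = decision_latency(cfg, len(models.template), fs)
    emitted = {s.index: s.index + latency for s in validated}
    return DetectionResult(
        candidates=candidates,
        validated=validated,
        blinks=blinks,
        clicks=clicks,
        commands=commands,
        emitted_at=emitted,
    )
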