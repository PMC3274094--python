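"""Fusion of linear-model candidates, RBF validation and blink events.

The eye-movement detector keeps a saccade candidate only when the RBF
network classifies its window as a genuine saccade *and* no blink event
coincides with it (a blink-coincident candidate is an eyelid artefact and
is discarded; it is not re-detected afterwards).  Surviving horizontal
and vertical candidates occurring within a short merge window are fused
into a single oblique movement, quantified by the linear model's angles
and mapped to one of eight direction classes (U, D, L, R and diagonals)
by 45-degree sectors.

Validated saccades select interface commands; a validation click (double
or triple blink) within the validation window — which starts when the
eye movement commences — confirms the selection and emits the command.
A later selection supersedes an unconfirmed earlier one, and unconfirmed
selections lapse silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .blink_detector import BlinkEvent, ClickEvent
from .saccade_model import SaccadeCandidate
from .signal_io import Event, EventLog

__all__ = [
    "DIRECTIONS",
    "DEFAULT_LAYOUT",
    "FusionPolicy",
    "ValidatedSaccade",
    "CommandEvent",
    "classify_direction",
    "fuse",
    "decode_commands",
    "events_to_log",
]

DIRECTIONS = ("R", "UR", "U", "UL", "L", "DL", "D", "DR")
DEFAULT_LAYOUT = {d: i + 1 for i, d in enumerate(DIRECTIONS)}


@dataclass
class FusionPolicy:
    """Timing rules of the detector block, in seconds.

    coincidence_s : half-width of the blink-coincidence window around a
        candidate ("the same instant"); candidates this close to a blink
        onset are discarded.
    merge_s : horizontal and vertical candidates closer than this are one
        oblique movement.
    min_angle_deg : movements below this on both axes carry no direction
        class and are dropped.
    """

    coincidence_s: float = 0.25
    merge_s: float = 0.05
    min_angle_deg: float = 5.0
    sampling_hz: float = 100.0

    @property
    def coincidence(self) -> int:
        return int(round(self.coincidence_s * self.sampling_hz))

    @property
    def merge(self) -> int:
        return int(round(self.merge_s * self.sampling_hz))


@dataclass
class ValidatedSaccade:
    """A saccade that survived RBF validation and blink rejection."""

    index: int
    h_deg: float
    v_deg: float
    direction: str


@dataclass
class CommandEvent:
    """A decoded interface command: selection saccade plus validating click."""

    command: int
    saccade: ValidatedSaccade
    click: ClickEvent


def classify_direction(h_deg: float, v_deg: float, min_angle: float = 5.0) -> str | None:
    """Eight-sector direction class from signed H/V angles.

    Sectors are 45 degrees wide, centred on the eight directions
    (R at 0, U at 90, ...).  Returns None when both components are below
    ``min_angle``.
    """
    if not (math.isfinite(h_deg) and math.isfinite(v_deg)):
        raise ValueError("angles must be finite")
    if abs(h_deg) < min_angle and abs(v_deg) < min_angle:
        return None
    theta = math.degrees(math.atan2(v_deg, h_deg))
    return DIRECTIONS[int(round(theta / 45.0)) % 8]


def fuse(
    candidates: list[SaccadeCandidate],
    elm_classes: list[int],
    blinks: list[BlinkEvent],
    policy: FusionPolicy | None = None,
) -> list[ValidatedSaccade]:
    """Combine candidates, network decisions and blink events.

    A candidate is kept iff its network class is 1 and no blink onset lies
    within the coincidence window around its index.  Kept H and V
    candidates within the merge window collapse into one oblique saccade;
    movements with no direction class (both axes under ``min_angle_deg``)
    are dropped.  ``elm_classes`` is aligned with ``candidates``.
    """
    policy = policy or FusionPolicy()
    if len(candidates) != len(elm_classes):
        raise ValueError("elm_classes must align one-to-one with candidates")
    blink_idx = [b.index for b in blinks]
    kept = [
        c
        for c, cls in sorted(
            zip(candidates, elm_classes), key=lambda pair: pair[0].index
        )
        if cls == 1
        and not any(abs(c.index - b) <= policy.coincidence for b in blink_idx)
    ]
    fused: list[ValidatedSaccade] = []
    i = 0
    while i < len(kept):
        c = kept[i]
        h, v = (c.angle_deg, 0.0) if c.channel == "h" else (0.0, c.angle_deg)
        index = c.index
        if (
            i + 1 < len(kept)
            and kept[i + 1].channel != c.channel
            and kept[i + 1].index - c.index <= policy.merge
        ):
            other = kept[i + 1]
            if other.channel == "h":
                h = other.angle_deg
            else:
                v = other.angle_deg
            index = min(c.index, other.index)
            i += 1
        i += 1
        direction = classify_direction(h, v, policy.min_angle_deg)
        if direction is not None:
            fused.append(ValidatedSaccade(index=index, h_deg=h, v_deg=v, direction=direction))
    return fused


def decode_commands(
    saccades: list[ValidatedSaccade],
    clicks: list[ClickEvent],
    layout: dict[str, int] | None = None,
    validation_window_s: float = 2.0,
    sampling_hz: float = 100.0,
) -> list[CommandEvent]:
    """Turn validated saccades plus clicks into interface commands.

    Events are scanned in time order.  Each validated saccade opens (or
    replaces) the pending selection; the first click whose onset falls
    after the selection and within ``validation_window_s`` of it emits
    the mapped command and closes the selection.  Clicks with no pending
    selection in range are ignored; selections never confirmed lapse.
    """
    layout = DEFAULT_LAYOUT if layout is None else layout
    window = int(round(validation_window_s * sampling_hz))
    timeline: list[tuple[int, int, object]] = [(s.index, 0, s) for s in saccades]
    timeline += [(c.index, 1, c) for c in clicks]
    timeline.sort(key=lambda e: (e[0], e[1]))
    pending: ValidatedSaccade | None = None
    out: list[CommandEvent] = []
    for index, kind, obj in timeline:
        if kind == 0:
            pending = obj  # a new selection supersedes an unconfirmed one
        else:
            if (
                pending is not None
                and 0 < obj.index - pending.index <= window
                and pending.direction in layout
            ):
                out.append(CommandEvent(command=layout[pending.direction], saccade=pending, click=obj))
                pending = None
    return out


def events_to_log(
    saccades: list[ValidatedSaccade],
    clicks: list[ClickEvent],
    commands: list[CommandEvent],
    n_samples: int | None = None,
) -> EventLog:
    """Serialize fusion outputs as a JSON-lines-ready event log."""
    events = [
        Event("saccade", s.index, {"h_deg": s.h_deg, "v_deg": s.v_deg, "direction": s.direction})
        for s in saccades
    ]
    events += [Event("click", c.index, {"count": c.count, "span": c.span}) for c in clicks]
    events += [
        Event("command", c.click.index, {"command": c.command, "direction": c.saccade.direction})
        for c in commands
    ]
    events.sort(key=lambda e: e.index)
    return EventLog(events=events, n_samples=n_samples)
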