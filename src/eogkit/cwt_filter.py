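"""Single-scale continuous wavelet transform of an EOG channel.

The detector front end correlates the signal with one dilated copy of the
Haar / db1 mother wavelet,

    psi_{b,a}(t) = |a|^{-1/2} psi((t - b) / a),

at a single scale (default a = 60 samples).  The Haar wavelet is +1 on
[0, 1/2) and -1 on [1/2, 1), so the coefficient sequence behaves like a
magnified, noise-averaged derivative of the EOG: a saccadic step produces a
triangular coefficient peak of magnitude sqrt(a)/2 times the step height,
while constants (and, after kernel de-meaning, slow offsets) produce zero.
A *rising* step yields a *negative* extremum with this sign convention.

Two output alignments are offered:

``center``
    Coefficient ``i`` correlates the wavelet support centred on sample
    ``i`` (samples ``[i - a/2, i + a/2)``), so a step at sample ``s`` puts
    its extremum at index ``s``.  This is the natural alignment for
    offline analysis and calibration.
``causal``
    Coefficient ``j`` uses only samples ``<= j`` (support ``[j-a, j)``);
    the extremum of a step at ``s`` appears ``a - 1 - a//2`` samples later.
    The real-time detection pipeline uses this alignment so its outputs
    depend on no future samples beyond the declared lookahead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_io import require_finite

__all__ = ["CWTConfig", "cwt_single_scale", "wavelet_kernel", "causal_delay"]

_SUPPORTED_WAVELETS = ("db1", "haar")
_PAD_MODES = ("symmetric", "reflect", "edge", "constant")


@dataclass
class CWTConfig:
    """Configuration of the single-scale CWT stage.

    wavelet : ``"db1"`` (identically the Haar wavelet).
    scale : dilation ``a`` in samples, > 0 (default 60, the scale with the
        strongest correlation against saccadic EOG transitions).
    boundary : padding mode used at the record edges (centre alignment
        pads both sides; causal alignment pads only the start).
    """

    wavelet: str = "db1"
    scale: float = 60.0
    boundary: str = "symmetric"

    def __post_init__(self) -> None:
        if self.wavelet not in _SUPPORTED_WAVELETS:
            raise ValueError(
                f"unsupported wavelet {self.wavelet!r}; supported: {_SUPPORTED_WAVELETS}"
            )
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.boundary not in _PAD_MODES:
            raise ValueError(f"boundary must be one of {_PAD_MODES}")

    @property
    def kernel_len(self) -> int:
        return int(math.ceil(self.scale))

    def to_dict(self) -> dict:
        return {"wavelet": self.wavelet, "scale": self.scale, "boundary": self.boundary}

    @classmethod
    def from_dict(cls, d: dict) -> "CWTConfig":
        return cls(**d)


def wavelet_kernel(cfg: CWTConfig) -> np.ndarray:
    """Sampled, L2-normalized, zero-mean wavelet at scale ``a``.

    The dilated mother wavelet is sampled at the integer grid points of its
    support, ``psi(j / a) / sqrt(a)`` for ``j = 0 .. ceil(a) - 1``.  The
    sampled kernel is then de-meaned so the discrete transform annihilates
    constants exactly even when the two half-supports hold unequal numbers
    of grid points (odd or non-integer scales); for even integer scales the
    correction is identically zero.
    """
    a = cfg.scale
    j = np.arange(cfg.kernel_len, dtype=float)
    u = j / a
    psi = np.where(u < 0.5, 1.0, np.where(u < 1.0, -1.0, 0.0))
    k = psi / math.sqrt(a)
    return k - k.mean()


def causal_delay(cfg: CWTConfig) -> int:
    """Index shift between causal and centre alignment (29 at scale 60)."""
    L = cfg.kernel_len
    return L - 1 - L // 2


def cwt_single_scale(
    channel: np.ndarray, cfg: CWTConfig | None = None, align: str = "center"
) -> np.ndarray:
    """Correlate a channel with the single dilated wavelet; same length out.

    Each coefficient is the inner product of the signal with the
    L2-normalized scale-``a`` wavelet translated to that position (see
    module docstring for the two alignment conventions).  Input must be
    finite and at least ``ceil(a)`` samples long.
    """
    cfg = cfg or CWTConfig()
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("channel must be a 1-D sample sequence")
    require_finite(x, "channel")
    L = cfg.kernel_len
    if len(x) < L:
        raise ValueError(f"channel has {len(x)} samples; scale {cfg.scale} needs >= {L}")
    k = wavelet_kernel(cfg)
    n = len(x)
    if align == "center":
        xp = np.pad(x, L, mode=cfg.boundary)
        v = np.correlate(xp, k, mode="valid")  # length n + L + 1
        start = L - L // 2
        return v[start : start + n]
    if align == "causal":
        # coefficient j integrates the wavelet over raw samples [j - L, j - 1]
        xp = np.concatenate([np.pad(x[:L], (L, 0), mode=cfg.boundary)[:L], x])
        v = np.correlate(xp, k, mode="valid")  # length n + 1
        return v[1 : n + 1]
    raise ValueError(f"align must be 'center' or 'causal', got {align!r}")
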