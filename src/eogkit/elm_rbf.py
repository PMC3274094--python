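"""RBF network trained by the extreme learning machine (ELM) algorithm.

Validates 50-sample CWT-processed candidate windows as genuine saccades
(target 1) versus rest, fixation artefacts or blinks (target 0).  The
network output is a linear combination of Gaussian basis functions,

    f(x) = sum_i  beta_i * exp(-||w_i o x - mu_i||^2 / sigma_i^2),

with ``N_H`` hidden units (default 20).  Per the ELM scheme the hidden
parameters — per-neuron input weights ``w_i`` (applied elementwise to the
window before centre subtraction), centres ``mu_i`` and widths
``sigma_i`` — are drawn at random from a seeded scheme, and only the
output weights ``beta`` are fitted, as the minimum-norm least-squares
solution ``beta = H^+ T`` through the Moore-Penrose pseudoinverse of the
hidden-layer output matrix ``H``.  Training is therefore a single linear
solve, fast enough to retrain whenever the user's signals change.

A conventional RBF argument ``||x - mu_i||`` is available behind
``mode="conventional"`` for comparison.

Random scheme (the algorithm only prescribes "randomly chosen"): features
are scaled by the global standard deviation of the training windows;
``w_i ~ U(-1, 1)`` per element, ``mu_i`` uniform over the per-feature span
of the scaled training data, and ``sigma_i ~ U(0.5, 2) * sqrt(d)`` in
scaled feature space (the sqrt(d) factor keeps d-dimensional squared
distances commensurate with sigma^2, so activations neither saturate nor
vanish).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal_io import require_finite

__all__ = ["ELMModel", "TrainingSet", "train_elm", "hidden_matrix", "build_training_set"]

DEFAULT_WINDOW_LEN = 50
DEFAULT_HIDDEN = 20


@dataclass
class TrainingSet:
    """Rows of fixed-length CWT windows with binary saccade labels."""

    X: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.T = np.asarray(self.T, dtype=float).ravel()
        if self.X.shape[0] != self.T.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but T has {self.T.shape[0]} labels"
            )
        if not np.all(np.isin(self.T, (0.0, 1.0))):
            raise ValueError("labels must be binary (0/1)")
        require_finite(self.X, "training windows")


@dataclass
class ELMModel:
    """Trained RBF validator: hidden parameters, output weights and seed."""

    weights: np.ndarray  # (N_H, d) per-neuron elementwise input weights
    centres: np.ndarray  # (N_H, d)
    widths: np.ndarray  # (N_H,)
    beta: np.ndarray  # (N_H,)
    input_scale: float
    seed: int
    mode: str = "weighted"
    decision_threshold: float = 0.5
    # per-window L2 normalization: the network judges the *shape* of the
    # coefficient window (step-like vs blink/fixation artefact), leaving
    # amplitude to the threshold stage; this is what lets a validator
    # trained on a handful of calibration angles generalize to any
    # saccade size.  "none" feeds globally scaled raw windows instead.
    window_norm: str = "l2"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.centres = np.asarray(self.centres, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.weights.shape != self.centres.shape:
            raise ValueError("weights and centres must share shape (N_H, d)")
        if self.widths.shape != (self.weights.shape[0],) or self.beta.shape != self.widths.shape:
            raise ValueError("widths and beta must have one entry per hidden neuron")
        if self.weights.shape[0] < 1:
            raise ValueError("at least one hidden neuron required")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be > 0")
        if self.mode not in ("weighted", "conventional"):
            raise ValueError("mode must be 'weighted' or 'conventional'")
        if self.window_norm not in ("l2", "none"):
            raise ValueError("window_norm must be 'l2' or 'none'")

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[0]

    @property
    def window_len(self) -> int:
        return self.weights.shape[1]

    def score(self, window: np.ndarray) -> float:
        """Network output f(x) for one window."""
        w = np.asarray(window, dtype=float)
        if w.shape != (self.window_len,):
            raise ValueError(
                f"window must have length {self.window_len}, got shape {w.shape}"
            )
        require_finite(w, "window")
        return float((hidden_matrix(self, w[None, :]) @ self.beta)[0])

    def classify(self, window: np.ndarray) -> int:
        """1 when a saccadic movement is validated, 0 otherwise."""
        return int(self.score(window) >= self.decision_threshold)

    def to_json(self, path: str | Path) -> Path:
        d = {
            "weights": self.weights.tolist(),
            "centres": self.centres.tolist(),
            "widths": self.widths.tolist(),
            "beta": self.beta.tolist(),
            "input_scale": self.input_scale,
            "seed": self.seed,
            "mode": self.mode,
            "decision_threshold": self.decision_threshold,
            "window_norm": self.window_norm,
        }
        path = Path(path)
        path.write_text(json.dumps(d), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ELMModel":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _prepare(X: np.ndarray, scale: float, window_norm: str) -> np.ndarray:
    Xs = np.atleast_2d(np.asarray(X, dtype=float)) / scale
    if window_norm == "l2":
        d = Xs.shape[1]
        norms = np.linalg.norm(Xs, axis=1, keepdims=True)
        floor = 1e-3 * np.sqrt(d)  # near-silent windows stay near the origin
        Xs = Xs * (np.sqrt(d) / np.maximum(norms, floor))
    return Xs


def hidden_matrix(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix H with H[j, i] = g_i(x_j)."""
    Xs = _prepare(X, model.input_scale, model.window_norm)
    if model.mode == "weighted":
        diff = Xs[:, None, :] * model.weights[None, :, :] - model.centres[None, :, :]
    else:
        diff = Xs[:, None, :] - model.centres[None, :, :]
    sq = np.einsum("jik,jik->ji", diff, diff)
    return np.exp(-sq / model.widths[None, :] ** 2)


def train_elm(
    data: TrainingSet,
    n_hidden: int = DEFAULT_HIDDEN,
    seed: int = 0,
    mode: str = "weighted",
    decision_threshold: float = 0.5,
    window_norm: str = "l2",
) -> ELMModel:
    """Draw random hidden parameters and solve for beta analytically.

    ``beta`` is the minimum-norm least-squares solution of ``H beta = T``
    (Moore-Penrose pseudoinverse applied to the hidden-layer output
    matrix).  Identical data and seed yield identical models.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    X, T = data.X, data.T
    d = X.shape[1]
    rng = np.random.default_rng(seed)
    scale = float(X.std())
    if scale == 0.0:
        scale = 1.0  # constant training windows: degenerate but solvable
    Xs = _prepare(X, scale, window_norm)
    weights = rng.uniform(-1.0, 1.0, size=(n_hidden, d))
    if mode == "weighted":
        ref = Xs[:, None, :] * weights[None, :, :]
        lo = ref.min(axis=(0, 1))
        hi = ref.max(axis=(0, 1))
    else:
        lo = Xs.min(axis=0)
        hi = Xs.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    centres = lo + rng.uniform(0.0, 1.0, size=(n_hidden, d)) * span
    widths = rng.uniform(0.5, 2.0, size=n_hidden) * np.sqrt(d)
    model = ELMModel(
        weights=weights,
        centres=centres,
        widths=widths,
        beta=np.zeros(n_hidden),
        input_scale=scale,
        seed=seed,
        mode=mode,
        decision_threshold=decision_threshold,
        window_norm=window_norm,
    )
    H = hidden_matrix(model, X)
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)  # minimum-norm LS solution
    model.beta = beta
    return model


def build_training_set(
    coeffs_by_channel: dict[str, np.ndarray],
    truth,
    window_len: int = DEFAULT_WINDOW_LEN,
    lookahead: int = 25,
    n_segments: int = 100,
    jitter: int = 2,
    seed: int = 0,
) -> TrainingSet:
    """Assemble labelled CWT windows from a ground-truthed recording.

    Positive windows are centred (with +/- ``jitter`` sample augmentation)
    on true saccade onsets of the moving channel; negatives are blink
    pulses on the vertical channel and event-free stretches of both
    channels (rest/fixation), sampled to bring the total to
    ``n_segments`` at roughly balanced classes.  Windows span
    ``[t - pre, t - pre + window_len)`` with ``pre = window_len -
    lookahead``, matching the slice the detector feeds the network.
    """
    rng = np.random.default_rng(seed)
    pre = window_len - lookahead
    n = truth.n_samples

    def window_at(ch: str, t: int) -> np.ndarray | None:
        start = t - pre
        if start < 0 or start + window_len > len(coeffs_by_channel[ch]):
            return None
        return coeffs_by_channel[ch][start : start + window_len]

    positives, negatives = [], []
    saccade_indices = []
    for s in truth.saccades:
        saccade_indices.append(s.index)
        for ch, deg in (("h", s.h_deg), ("v", s.v_deg)):
            if deg == 0.0:
                continue
            for off in range(-jitter, jitter + 1):
                w = window_at(ch, s.index + off)
                if w is not None:
                    positives.append(w)
    for b in truth.blinks:
        for p in b.pulse_indices:
            for off in (0, window_len // 4):
                w = window_at("v", p + off)
                if w is not None:
                    negatives.append(w)

    n_pos = min(len(positives), n_segments // 2)
    if n_pos == 0:
        raise ValueError("recording contains no usable saccade windows")
    pos_idx = rng.choice(len(positives), size=n_pos, replace=False)
    positives = [positives[i] for i in pos_idx]

    # rest / fixation negatives: windows well clear of any saccade onset
    forbidden = np.asarray(saccade_indices) if saccade_indices else np.empty(0)
    guard = window_len
    tries = 0
    while len(negatives) < n_segments - n_pos and tries < 50 * n_segments:
        tries += 1
        t = int(rng.integers(pre, n - lookahead))
        if forbidden.size and np.min(np.abs(forbidden - t)) < guard:
            continue
        ch = rng.choice(["h", "v"])
        w = window_at(ch, t)
        if w is not None:
            negatives.append(w)

    X = np.vstack([positives, negatives])
    T = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    return TrainingSet(X=X, T=T)
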