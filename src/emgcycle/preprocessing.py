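"""Raw sEMG to standardized linear envelopes.

The chain is the classical linear-envelope recipe: zero-phase high-pass at
10 Hz (drift/motion-artifact removal), full-wave rectification, zero-phase
low-pass at 10 Hz (amplitude envelope), then standardization of the whole
session by the single median rectified amplitude pooled over all muscles and
trials.  Standardization preserves inter-muscle amplitude ratios and makes
envelopes comparable across participants without MVC normalization.

Filters are 4th-order Butterworth applied forward-backward (``sosfiltfilt``),
so burst timing is not skewed by filter delay.  Negative post-filter
overshoot is clipped to zero because the envelopes feed a non-negative
factorization downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .synthetic import EmgSession

__all__ = [
    "EnvelopeMatrix",
    "highpass",
    "rectify",
    "lowpass_envelope",
    "standardize_session",
    "preprocess",
    "DEFAULT_HIGHPASS_HZ",
    "DEFAULT_LOWPASS_HZ",
]

DEFAULT_HIGHPASS_HZ = 10.0
DEFAULT_LOWPASS_HZ = 10.0
FILTER_ORDER = 4

#: shortest series sosfiltfilt can handle at FILTER_ORDER (padlen constraint)
_MIN_LEN = 6 * (FILTER_ORDER + 1) + 1


class DegenerateSessionError(ValueError):
    """Raised when a session's pooled rectified median is zero."""


@dataclass
class EnvelopeMatrix:
    """Nonnegative muscle x time envelope (the data matrix M of the model).

    ``rectified`` keeps the post-rectification, pre-smoothing signal so that
    session-wide standardization can pool medians across trials; it is
    dropped once the matrix is standardized.
    """

    values: np.ndarray
    fs_hz: float
    muscle_labels: tuple[str, ...]
    condition_label: int = 0
    trial_id: int = 0
    participant_id: str = "sim"
    rectified: np.ndarray | None = field(default=None, repr=False)
    standardized: bool = False

    def validate(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.muscle_labels):
            raise ValueError("values must be muscle x time with one row per label")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values must be finite")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


def _check_series(signal: np.ndarray, fs_hz: float, cutoff_hz: float) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if fs_hz <= 2 * cutoff_hz:
        raise ValueError(f"fs_hz must exceed 2 x cutoff ({cutoff_hz} Hz)")
    if x.size < _MIN_LEN:
        raise ValueError(
            f"series of length {x.size} is shorter than the filter warm-up "
            f"length ({_MIN_LEN})"
        )
    return x


def highpass(
    signal: np.ndarray, fs_hz: float, cutoff_hz: float = DEFAULT_HIGHPASS_HZ
) -> np.ndarray:
    """Zero-phase Butterworth high-pass; removes DC and drift."""
    x = _check_series(signal, fs_hz, cutoff_hz)
    sos = sps.butter(FILTER_ORDER, cutoff_hz, btype="highpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("rectify requires finite input")
    return np.abs(x)


def lowpass_envelope(
    signal: np.ndarray, fs_hz: float, cutoff_hz: float = DEFAULT_LOWPASS_HZ
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; negative overshoot clipped to 0."""
    x = _check_series(signal, fs_hz, cutoff_hz)
    sos = sps.butter(FILTER_ORDER, cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
    return np.clip(sps.sosfiltfilt(sos, x), 0.0, None)


def standardize_session(envelopes: Sequence[EnvelopeMatrix]) -> list[EnvelopeMatrix]:
    """Divide every envelope by the session-wide median rectified amplitude.

    The median is pooled over all muscles and all trials of the session, so
    relative inter-muscle (and inter-trial) amplitude ratios are unchanged.
    """
    if len(envelopes) == 0:
        raise ValueError("empty session")
    pools = []
    for env in envelopes:
        if env.rectified is None:
            raise ValueError(
                "standardize_session needs the pre-smoothing rectified signal; "
                "build envelopes with preprocess(..., standardize=False)"
            )
        pools.append(np.abs(env.rectified).ravel())
    median = float(np.median(np.concatenate(pools)))
    if median <= 0:
        raise DegenerateSessionError("session-wide rectified median is zero")
    out = []
    for env in envelopes:
        out.append(
            EnvelopeMatrix(
                values=env.values / median,
                fs_hz=env.fs_hz,
                muscle_labels=env.muscle_labels,
                condition_label=env.condition_label,
                trial_id=env.trial_id,
                participant_id=env.participant_id,
                rectified=None,
                standardized=True,
            )
        )
    return out


def preprocess(
    session: EmgSession,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    lowpass_hz: float = DEFAULT_LOWPASS_HZ,
    standardize: bool = True,
) -> EnvelopeMatrix:
    """High-pass, rectify and low-pass each muscle of one trial.

    With ``standardize=True`` the trial is standardized by its own pooled
    rectified median; pass ``standardize=False`` and use
    :func:`standardize_session` to pool the median over all trials of a
    session (the multi-trial workflow).
    """
    session.validate()
    n_muscles, _ = session.samples.shape
    rect = np.empty_like(session.samples, dtype=float)
    env = np.empty_like(session.samples, dtype=float)
    for m in range(n_muscles):
        hp = highpass(session.samples[m], session.fs_hz, highpass_hz)
        rect[m] = rectify(hp)
        env[m] = lowpass_envelope(rect[m], session.fs_hz, lowpass_hz)
    out = EnvelopeMatrix(
        values=env,
        fs_hz=session.fs_hz,
        muscle_labels=tuple(session.muscle_labels),
        condition_label=session.condition_label,
        trial_id=session.trial_id,
        participant_id=session.participant_id,
        rectified=rect,
    )
    if standardize:
        out = standardize_session([out])[0]
    return out
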