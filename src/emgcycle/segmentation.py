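"""Motion-cycle segmentation from envelope local minima.

Cyclic tasks imprint a strong periodicity on the summed muscle envelope; its
local minima mark the low-activity instants between consecutive cycles, so a
trial can be segmented without any kinematic signal.  The composite envelope
(sum over muscles) is searched for prominent local minima separated by at
least half the nominal cycle period; the period itself is inferred from the
dominant autocorrelation lag when not supplied.

Conventions: 0-based, half-open cycles ``[start, next_start)``; partial
leading/trailing cycles outside the first/last detected minimum are
discarded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocessing import EnvelopeMatrix

__all__ = [
    "CycleBoundaries",
    "CycleSet",
    "UnsegmentableError",
    "composite_envelope",
    "infer_cadence",
    "detect_boundaries",
    "segment",
    "write_boundaries_csv",
    "DEFAULT_PROMINENCE_FRAC",
]

DEFAULT_PROMINENCE_FRAC = 0.1

#: cadence search window (s) for the autocorrelation period estimate
_MIN_CADENCE_S = 0.2
_MAX_CADENCE_S = 5.0


class UnsegmentableError(ValueError):
    """Raised when fewer than two usable envelope minima are found."""


@dataclass
class CycleBoundaries:
    start_indices: np.ndarray
    fs_hz: float

    def validate(self, signal_length: int | None = None) -> None:
        b = self.start_indices
        if b.size < 2:
            raise ValueError("at least 2 boundaries are needed for one cycle")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if signal_length is not None and (b[0] < 0 or b[-1] > signal_length):
            raise ValueError("boundary outside signal")

    @property
    def n_cycles(self) -> int:
        return self.start_indices.size - 1


@dataclass
class CycleSet:
    cycles: list[np.ndarray]  # each muscle x native-length
    fs_hz: float
    muscle_labels: tuple[str, ...]
    condition_label: int = 0
    trial_id: int = 0


def composite_envelope(env: EnvelopeMatrix) -> np.ndarray:
    """Per-sample sum of all muscle envelopes: one periodic activity trace."""
    env.validate()
    return env.values.sum(axis=0)


def infer_cadence(series: np.ndarray, fs_hz: float) -> float:
    """Nominal cycle period (s) from the dominant autocorrelation lag."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = x.size
    lo = max(2, int(_MIN_CADENCE_S * fs_hz))
    hi = min(n - 2, int(_MAX_CADENCE_S * fs_hz))
    if hi <= lo:
        raise UnsegmentableError("series too short to infer a cadence")
    # FFT autocorrelation, biased normalization is fine for peak location
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[: n]
    window = acf[lo : hi + 1]
    peaks, _ = sps.find_peaks(window, prominence=0.0)
    if peaks.size == 0:
        raise UnsegmentableError("no periodic structure found in composite envelope")
    heights = window[peaks]
    # score each strong peak by the mean ACF over its harmonics: the true
    # period scores high at every multiple, while sub-period peaks (burst
    # spacing within a cycle) and octave errors do not
    strong = peaks[heights >= 0.5 * heights.max()] + lo
    # candidates must have >= 2 multiples in range so the harmonic score
    # averages noise instead of trusting one long-lag ACF value
    lag_cap = max(lo + 1, (min(hi, n - 1)) // 2)
    capped = strong[strong <= lag_cap]
    if capped.size:
        strong = capped
    # unbias by lag so long-lag multiples are not penalized
    unbiased = acf[: n] * (n / np.maximum(n - np.arange(n), 1))
    acf0 = unbiased[0] if unbiased[0] > 0 else 1.0
    scores = []
    for lag in strong:
        mults = np.arange(lag, min(hi, n - 1) + 1, lag)
        scores.append(float(np.mean(unbiased[mults])) / acf0)
    best = max(scores)
    # earliest lag scoring close to the best: a true period and its octaves
    # score alike, and the fundamental is the smallest such lag
    threshold = best - 0.15 * abs(best)
    lag = int(strong[next(i for i, s in enumerate(scores) if s >= threshold)])
    return lag / fs_hz


def _pick_in_window(
    candidates: np.ndarray, depths: np.ndarray, lo: float, hi: float
) -> int | None:
    """Deepest candidate minimum inside [lo, hi]; earlier index on ties."""
    mask = (candidates >= lo) & (candidates <= hi)
    if not mask.any():
        return None
    idx = candidates[mask]
    dep = depths[mask]
    order = np.lexsort((idx, dep))
    return int(idx[order[0]])


def detect_boundaries(
    series: np.ndarray,
    fs_hz: float,
    min_period_s: float | None = None,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    cadence_s: float | None = None,
) -> CycleBoundaries:
    """Prominent local minima of the composite envelope, as cycle boundaries.

    Candidate boundaries are local minima whose prominence (on the inverted
    series) is at least ``prominence_frac`` of the series range.  Selection
    exploits the signal's periodicity: starting from the deepest candidate,
    the walk steps one cadence at a time in both directions and accepts the
    deepest candidate within a quarter-cadence of the expected position
    (earlier index on depth ties).  Accepted boundaries are therefore
    separated by at least ``min_period_s`` (default: half the
    autocorrelation cadence), and a cycle with a filled-in or missing trough
    cannot pull the walk onto the shallow intra-cycle dips between
    successive muscle bursts.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if np.any(x < 0):
        raise ValueError("expected a nonnegative envelope series")
    rng_ = x.max() - x.min()
    if rng_ <= 0:
        raise UnsegmentableError("constant series has no local minima")
    if cadence_s is None:
        cadence_s = infer_cadence(x, fs_hz)
    if min_period_s is None:
        min_period_s = 0.5 * cadence_s
    if min_period_s <= 0:
        raise ValueError("min_period_s must be positive")
    cad = cadence_s * fs_hz
    half_window = min(0.25 * cad, max(cad - min_period_s * fs_hz, 1.0))

    candidates, _ = sps.find_peaks(-x, prominence=prominence_frac * rng_)
    if candidates.size < 2:
        raise UnsegmentableError(
            f"found {candidates.size} usable minima; trial is unsegmentable"
        )
    depths = x[candidates]
    anchor = int(candidates[np.lexsort((candidates, depths))[0]])

    accepted = [anchor]
    for direction in (+1, -1):
        last = float(anchor)
        while True:
            expected = last + direction * cad
            pick = _pick_in_window(
                candidates, depths, expected - half_window, expected + half_window
            )
            if pick is None:
                # tolerate a single misplaced trough: widen once
                pick = _pick_in_window(
                    candidates,
                    depths,
                    expected - 2 * half_window,
                    expected + 2 * half_window,
                )
            if pick is None or pick in accepted:
                break
            accepted.append(pick)
            last = float(pick)
    accepted.sort()
    if len(accepted) < 2:
        raise UnsegmentableError("fewer than 2 minima after periodic selection")
    return CycleBoundaries(start_indices=np.asarray(accepted, dtype=int), fs_hz=fs_hz)


def segment(
    env: EnvelopeMatrix, b: CycleBoundaries, min_cycle_samples: int = 4
) -> CycleSet:
    """Cut the envelope into half-open cycles ``[b_k, b_{k+1})``.

    Concatenating the cycles reproduces ``env.values[:, b_0:b_last]``
    exactly; no samples are lost or duplicated.
    """
    env.validate()
    b.validate(signal_length=env.values.shape[1])
    cycles = []
    starts = b.start_indices
    for k in range(starts.size - 1):
        block = env.values[:, starts[k] : starts[k + 1]]
        if block.shape[1] < min_cycle_samples:
            raise ValueError(
                f"cycle {k} has {block.shape[1]} samples (< {min_cycle_samples})"
            )
        cycles.append(block.copy())
    return CycleSet(
        cycles=cycles,
        fs_hz=env.fs_hz,
        muscle_labels=env.muscle_labels,
        condition_label=env.condition_label,
        trial_id=env.trial_id,
    )


def write_boundaries_csv(b: CycleBoundaries, path) -> None:
    pd.DataFrame(
        {"cycle_index": np.arange(b.start_indices.size), "start_sample": b.start_indices}
    ).to_csv(path, index=False)
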