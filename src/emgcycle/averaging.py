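"""Time normalization and anchor-aligned cycle averaging.

Consecutive motion cycles differ both in duration and in when, within the
cycle, each muscle turns on and off.  Plain resampling followed by pointwise
averaging smears bursts whose timing jitters from cycle to cycle.  Here each
cycle is first linearly resampled to a common normalized length, activation
anchors (onset, peak, offset of each muscle burst) are detected, and every
cycle is piecewise-linearly warped so its anchors land on the median anchor
positions across cycles before the pointwise mean is taken.  The warp is
monotone by construction, so temporal order within a cycle is never
reversed; muscles with no detectable burst are averaged without warping.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CycleSet

__all__ = [
    "NormalizedCycleSet",
    "AverageCycle",
    "time_normalize",
    "detect_anchors",
    "normalize_cycles",
    "merge_normalized",
    "average_cycles",
    "DEFAULT_T_NORM",
    "DEFAULT_ONSET_FRAC",
]

DEFAULT_T_NORM = 200
DEFAULT_ONSET_FRAC = 0.2


class DegenerateCycleError(ValueError):
    """Raised for cycles too short to resample (or with no usable data)."""


@dataclass
class NormalizedCycleSet:
    """Cycle x muscle x normalized-time tensor plus per-cycle anchor table.

    ``anchor_table`` columns: cycle, muscle, onset, peak, offset (positions
    in normalized-time samples; NaN where a muscle never exceeds threshold).
    """

    tensor: np.ndarray
    anchor_table: pd.DataFrame
    fs_hz: float
    muscle_labels: tuple[str, ...]
    condition_label: int = 0
    trial_id: int = 0

    @property
    def n_cycles(self) -> int:
        return self.tensor.shape[0]

    @property
    def t_norm(self) -> int:
        return self.tensor.shape[2]


@dataclass
class AverageCycle:
    matrix: np.ndarray  # muscle x T_norm
    n_cycles_used: int
    muscle_labels: tuple[str, ...] = ()


def time_normalize(cycle: np.ndarray, t_norm: int = DEFAULT_T_NORM) -> np.ndarray:
    """Linear-interpolation resampling of a muscle x time block to ``t_norm``.

    Endpoints are preserved exactly; linear input stays linear.
    """
    block = np.atleast_2d(np.asarray(cycle, dtype=float))
    n = block.shape[1]
    if n < 4:
        raise DegenerateCycleError(f"cycle of {n} samples is too short to resample")
    xp = np.arange(n, dtype=float)
    x = np.linspace(0.0, n - 1.0, t_norm)
    return np.vstack([np.interp(x, xp, row) for row in block])


def detect_anchors(
    cycle: np.ndarray, onset_frac: float = DEFAULT_ONSET_FRAC
) -> np.ndarray:
    """Onset / peak / offset per muscle, in samples of the cycle's grid.

    Onset is the first sample above ``onset_frac`` of the muscle's per-cycle
    maximum, offset the last such sample, peak the argmax.  A muscle whose
    trace never exceeds the threshold (an all-zero trace) yields a NaN row.
    """
    block = np.atleast_2d(np.asarray(cycle, dtype=float))
    if np.any(block < 0):
        raise ValueError("anchors expect a nonnegative envelope cycle")
    out = np.full((block.shape[0], 3), np.nan)
    for m, row in enumerate(block):
        peak_val = row.max()
        if peak_val <= 0:
            continue
        above = np.nonzero(row > onset_frac * peak_val)[0]
        out[m] = (above[0], int(np.argmax(row)), above[-1])
    return out


def normalize_cycles(
    cs: CycleSet,
    t_norm: int = DEFAULT_T_NORM,
    onset_frac: float = DEFAULT_ONSET_FRAC,
) -> NormalizedCycleSet:
    """Resample every cycle of a set to ``t_norm`` and tabulate its anchors."""
    if len(cs.cycles) == 0:
        raise DegenerateCycleError("empty cycle set")
    tensor = np.stack([time_normalize(c, t_norm) for c in cs.cycles])
    rows = []
    for k in range(tensor.shape[0]):
        anchors = detect_anchors(tensor[k], onset_frac)
        for m, label in enumerate(cs.muscle_labels):
            rows.append(
                {
                    "cycle": k,
                    "muscle": label,
                    "onset": anchors[m, 0],
                    "peak": anchors[m, 1],
                    "offset": anchors[m, 2],
                }
            )
    return NormalizedCycleSet(
        tensor=tensor,
        anchor_table=pd.DataFrame(rows),
        fs_hz=cs.fs_hz,
        muscle_labels=cs.muscle_labels,
        condition_label=cs.condition_label,
        trial_id=cs.trial_id,
    )


def merge_normalized(sets: list[NormalizedCycleSet]) -> NormalizedCycleSet:
    """Concatenate normalized cycle sets (e.g. trials of one condition)."""
    if not sets:
        raise DegenerateCycleError("nothing to merge")
    first = sets[0]
    if any(
        s.t_norm != first.t_norm or s.muscle_labels != first.muscle_labels
        for s in sets
    ):
        raise ValueError("cycle sets must share t_norm and muscle labels")
    tensor = np.concatenate([s.tensor for s in sets], axis=0)
    tables = []
    offset = 0
    for s in sets:
        table = s.anchor_table.copy()
        table["cycle"] = table["cycle"] + offset
        tables.append(table)
        offset += s.n_cycles
    return NormalizedCycleSet(
        tensor=tensor,
        anchor_table=pd.concat(tables, ignore_index=True),
        fs_hz=first.fs_hz,
        muscle_labels=first.muscle_labels,
        condition_label=first.condition_label,
    )


def _monotone_anchor_pairs(
    src_interior: np.ndarray, tgt_interior: np.ndarray, last: float
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor pairs {0, interior..., last}; interior pairs that would break
    strict monotonicity in either axis are dropped."""
    keep_src, keep_tgt = [0.0], [0.0]
    for s, t in zip(src_interior, tgt_interior):
        if keep_src[-1] < s < last and keep_tgt[-1] < t < last:
            keep_src.append(float(s))
            keep_tgt.append(float(t))
    keep_src.append(last)
    keep_tgt.append(last)
    return np.asarray(keep_src), np.asarray(keep_tgt)


def _warp_trace(
    trace: np.ndarray, src_anchors: np.ndarray, tgt_anchors: np.ndarray
) -> np.ndarray:
    """Piecewise-linear warp mapping target anchor positions onto source ones."""
    t = np.arange(trace.size, dtype=float)
    src_pos = np.interp(t, tgt_anchors, src_anchors)
    return np.interp(src_pos, t, trace)


def average_cycles(ncs: NormalizedCycleSet) -> AverageCycle:
    """Anchor-aligned mean cycle.

    For every muscle, the median onset/peak/offset across cycles defines the
    target anchor set; each cycle's trace is warped so its own anchors align
    to the targets (with the cycle endpoints fixed) and the warped traces are
    averaged pointwise.  Muscles without anchors in a cycle contribute
    unwarped.  With identical input cycles the warp is the identity and the
    average equals the input.
    """
    if ncs.n_cycles < 2:
        raise DegenerateCycleError("need at least 2 cycles to average")
    n_cycles, n_muscles, t_norm = ncs.tensor.shape
    anchors = ncs.anchor_table.pivot_table(
        index="cycle", columns="muscle", values=["onset", "peak", "offset"], sort=False
    )
    out = np.zeros((n_muscles, t_norm))
    last = float(t_norm - 1)
    for m, label in enumerate(ncs.muscle_labels):
        per_cycle = np.stack(
            [
                anchors["onset"][label].to_numpy(),
                anchors["peak"][label].to_numpy(),
                anchors["offset"][label].to_numpy(),
            ],
            axis=1,
        )  # cycle x 3
        with np.errstate(all="ignore"):
            med = np.nanmedian(per_cycle, axis=0)
        acc = np.zeros(t_norm)
        for k in range(n_cycles):
            trace = ncs.tensor[k, m]
            if np.any(np.isnan(per_cycle[k])) or np.any(np.isnan(med)):
                acc += trace
                continue
            src_a, tgt_a = _monotone_anchor_pairs(per_cycle[k], med, last)
            acc += _warp_trace(trace, src_a, tgt_a)
        out[m] = acc / n_cycles
    return AverageCycle(
        matrix=np.clip(out, 0.0, None),
        n_cycles_used=n_cycles,
        muscle_labels=ncs.muscle_labels,
    )
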