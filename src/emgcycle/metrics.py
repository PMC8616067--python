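"""Phase-level statistics: relative contribution and inter-cycle stability.

Two bespoke quantities summarize a fitted phase decomposition:

* the **relative phase contribution** ``C_i`` — the fraction of the total
  reconstructed signal amplitude generated by phase ``i``, computed from the
  summed muscle weights and the time integral of the temporal pattern:
  ``C_i = (sum_m W_mi)(sum_t H_i(t)) / sum_j (sum_m W_mj)(sum_t H_j(t))``;

* the **temporal and spatial stability indices** — the mean zero-lag linear
  correlation coefficient over all unordered pairs of motion cycles, taken
  between per-cycle temporal patterns (H rows, time-normalized) or per-cycle
  muscle weightings (W columns).  Both lie in [-1, 1]; 1 means every cycle
  reproduces the same pattern exactly.

Per-cycle patterns are obtained by refitting the factorization to each cycle
independently at the reference order and permuting its phases to the
reference model (``mode="nmf"``); a fixed-W nonnegative projection of each
cycle is available as a cheaper alternative (``mode="projection"``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .averaging import NormalizedCycleSet
from .decomposition import SynergyModel, match_phases, nmf, vaf

__all__ = [
    "PhaseContribution",
    "StabilityIndices",
    "relative_contribution",
    "temporal_stability",
    "spatial_stability",
    "per_cycle_models",
    "stability_from_models",
    "cycle_reference",
]


class DegenerateMetricError(ValueError):
    """All cycle pairs were skipped (zero-variance traces) or too few cycles."""


@dataclass
class PhaseContribution:
    C: np.ndarray  # n fractions summing to 1

    def validate(self) -> None:
        if np.any(self.C < 0) or np.any(self.C > 1):
            raise ValueError("contributions must lie in [0, 1]")
        if abs(float(self.C.sum()) - 1.0) > 1e-9:
            raise ValueError("contributions must sum to 1")


@dataclass
class StabilityIndices:
    temporal: np.ndarray  # per phase
    spatial: np.ndarray  # per phase
    n_cycles: int


def relative_contribution(W: np.ndarray, H: np.ndarray) -> PhaseContribution:
    """Fraction of total reconstructed amplitude attributable to each phase.

    Invariant under a joint positive rescaling of (W, H) and under the
    W/H scale transfer of model normalization.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(W < 0) or np.any(H < 0):
        raise ValueError("W and H must be nonnegative")
    if W.shape[1] != H.shape[0]:
        raise ValueError("W columns must match H rows")
    raw = W.sum(axis=0) * H.sum(axis=1)
    total = float(raw.sum())
    if total <= 0:
        raise ValueError("all-zero model has no defined contribution")
    out = PhaseContribution(C=raw / total)
    out.validate()
    return out


def _pairwise_mean_corr(vectors: np.ndarray) -> float:
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need >= 2 equal-length vectors")
    vals = []
    skipped = 0
    for a, b in combinations(range(vectors.shape[0]), 2):
        va, vb = vectors[a], vectors[b]
        if va.std() <= 0 or vb.std() <= 0:
            skipped += 1
            continue
        vals.append(float(np.corrcoef(va, vb)[0, 1]))
    if not vals:
        raise DegenerateMetricError(
            f"all {skipped} cycle pairs had a zero-variance trace"
        )
    if skipped:
        warnings.warn(f"skipped {skipped} zero-variance cycle pairs", stacklevel=3)
    return float(np.mean(vals))


def temporal_stability(H_set: np.ndarray) -> float:
    """Mean pairwise correlation of one phase's temporal pattern across cycles.

    ``H_set``: cycle x normalized-time array of the phase's H row per cycle.
    """
    H_set = np.asarray(H_set, dtype=float)
    return _pairwise_mean_corr(H_set)


def spatial_stability(W_set: np.ndarray) -> float:
    """Mean pairwise correlation of one phase's muscle weights across cycles.

    ``W_set``: cycle x muscle array of the phase's W column per cycle;
    needs at least 3 muscles for the correlation to be meaningful.
    """
    W_set = np.asarray(W_set, dtype=float)
    if W_set.ndim != 2 or W_set.shape[1] < 3:
        raise ValueError("spatial stability needs weight vectors over >= 3 muscles")
    return _pairwise_mean_corr(W_set)


def cycle_reference(reference: SynergyModel, t_norm: int) -> SynergyModel:
    """Collapse a reference fitted on concatenated cycles to one average cycle.

    The reference H (phase x n_cycles*t_norm) is reshaped and averaged over
    cycles so per-cycle models (phase x t_norm) can be matched against it.
    """
    n, t_total = reference.H.shape
    if t_total == t_norm:
        return reference
    if t_total % t_norm:
        raise ValueError(f"reference H width {t_total} not a multiple of {t_norm}")
    H_avg = reference.H.reshape(n, t_total // t_norm, t_norm).mean(axis=1)
    return SynergyModel(
        W=reference.W.copy(),
        H=H_avg,
        n_phases=n,
        vaf=reference.vaf,
        converged=reference.converged,
        n_iter=reference.n_iter,
        seed=reference.seed,
    )


def _project_H(M: np.ndarray, W: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Nonnegative least-squares activation of fixed W via multiplicative updates."""
    rng_free = np.full((W.shape[1], M.shape[1]), M.mean() / max(W.shape[1], 1) + 1e-9)
    H = rng_free
    WtM = W.T @ M
    WtW = W.T @ W
    for _ in range(n_iter):
        H *= WtM / (WtW @ H + 1e-12)
    return H


def per_cycle_models(
    cycles: NormalizedCycleSet,
    reference: SynergyModel,
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-5,
    mode: str = "nmf",
) -> list[SynergyModel]:
    """Fit one matched model per motion cycle.

    ``mode="nmf"`` refits W and H to each cycle independently and permutes
    the phases to the reference; ``mode="projection"`` keeps the reference W
    fixed and estimates only H (already in reference order).  Cycles whose
    fit fails (e.g. an all-zero cycle) are dropped with a warning; at least
    two surviving cycles are required.
    """
    if mode not in ("nmf", "projection"):
        raise ValueError("mode must be 'nmf' or 'projection'")
    ref = cycle_reference(reference, cycles.t_norm)
    models: list[SynergyModel] = []
    for k in range(cycles.n_cycles):
        M = cycles.tensor[k]
        try:
            if mode == "nmf":
                model = nmf(
                    M,
                    ref.n_phases,
                    seed=int(seed) + k,
                    restarts=restarts,
                    max_iter=max_iter,
                    tol=tol,
                )
                model = match_phases(model, ref)
            else:
                H = _project_H(M, ref.W)
                model = SynergyModel(
                    W=ref.W.copy(),
                    H=H,
                    n_phases=ref.n_phases,
                    vaf=vaf(M, ref.W, H),
                    converged=True,
                    n_iter=0,
                    seed=int(seed) + k,
                )
        except ValueError as exc:
            warnings.warn(f"cycle {k} dropped: {exc}", stacklevel=2)
            continue
        models.append(model)
    if len(models) < 2:
        raise DegenerateMetricError("fewer than 2 cycles survived per-cycle fitting")
    return models


def stability_from_models(models: list[SynergyModel]) -> StabilityIndices:
    """Per-phase temporal and spatial stability from matched per-cycle models."""
    if len(models) < 2:
        raise DegenerateMetricError("need >= 2 matched per-cycle models")
    n = models[0].n_phases
    H_stack = np.stack([m.H for m in models])  # cycle x phase x T
    W_stack = np.stack([m.W for m in models])  # cycle x muscle x phase
    temporal = np.array([temporal_stability(H_stack[:, i, :]) for i in range(n)])
    spatial = np.array([spatial_stability(W_stack[:, :, i]) for i in range(n)])
    return StabilityIndices(temporal=temporal, spatial=spatial, n_cycles=len(models))
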