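"""Non-negative matrix factorization of envelope data into motion phases.

The envelope matrix ``M`` (muscle x time) is modelled as ``M ~ W @ H`` with
``W`` (muscle x phase) the spatial muscle weightings and ``H`` (phase x
time) the temporal activation of each phase, both elementwise nonnegative.
Factors are fitted by Lee–Seung multiplicative updates for the Frobenius
loss, which keep the factors nonnegative and never increase the loss.  NMF
is non-convex, so each fit is the best of several seeded random restarts.

Decomposition quality is measured by the global variance accounted for,
``VAF = 1 - ||M - WH||_F^2 / ||M||_F^2`` (uncentered), and the model order
is the smallest number of phases whose VAF reaches a threshold (0.95 by
default, with three phases the expected answer for pedaling: traction,
power initiation, power end).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynergyModel",
    "OrderSelectionError",
    "nmf",
    "vaf",
    "select_order",
    "normalize_model",
    "match_phases",
    "phase_assignment",
]

_EPS = 1e-12


class OrderSelectionError(ValueError):
    """No order reached the VAF threshold; carries the best model found."""

    def __init__(self, message: str, best_order: int, best_vaf: float):
        super().__init__(message)
        self.best_order = best_order
        self.best_vaf = best_vaf


@dataclass
class SynergyModel:
    """One fitted factorization: spatial weights W, temporal patterns H."""

    W: np.ndarray  # muscle x phase
    H: np.ndarray  # phase x time
    n_phases: int
    vaf: float
    converged: bool
    n_iter: int
    seed: int = 0
    loss_curves: list[np.ndarray] = field(default_factory=list, repr=False)

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def vaf(M: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Global uncentered variance accounted for by the reconstruction WH."""
    M = np.asarray(M, dtype=float)
    total = float(np.sum(M * M))
    if total <= 0:
        raise ValueError("VAF undefined for an all-zero matrix")
    resid = M - np.asarray(W) @ np.asarray(H)
    return 1.0 - float(np.sum(resid * resid)) / total


def _check_matrix(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D (muscle x time)")
    if not np.all(np.isfinite(M)):
        raise ValueError("M must be finite")
    if np.any(M < 0):
        raise ValueError("M must be nonnegative")
    if not M.any():
        raise ValueError("M is all zero")
    return M


def nmf(
    M: np.ndarray,
    n: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> SynergyModel:
    """Best-of-restarts multiplicative-update NMF at fixed order ``n``.

    Each restart initializes W, H uniformly in (0, 1] scaled to the data
    mean, then alternates the Lee–Seung Frobenius updates until the relative
    loss change drops below ``tol`` or ``max_iter`` is reached.  The loss
    sequence of every restart is retained (``loss_curves``); the returned
    factors are those of the restart with the lowest final loss.
    Deterministic given ``seed``.
    """
    M = _check_matrix(M)
    m, t = M.shape
    if not 1 <= n <= min(m, t):
        raise ValueError(f"order n={n} outside 1..min(m, t)={min(m, t)}")
    scale = np.sqrt(M.mean() / n)

    best = None
    curves: list[np.ndarray] = []
    for r in range(restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed) % (2**63), spawn_key=(r,))
        )
        # uniform in (0, 1]: 1 - U[0, 1)
        W = (1.0 - rng.random((m, n))) * scale
        H = (1.0 - rng.random((n, t))) * scale
        losses = []
        prev = np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            H *= (W.T @ M) / (W.T @ W @ H + _EPS)
            W *= (M @ H.T) / (W @ (H @ H.T) + _EPS)
            resid = M - W @ H
            loss = float(np.sum(resid * resid))
            losses.append(loss)
            if np.isfinite(prev) and prev - loss <= tol * max(prev, _EPS):
                converged = True
                break
            prev = loss
        curves.append(np.asarray(losses))
        if best is None or losses[-1] < best[0]:
            best = (losses[-1], W, H, converged, it)

    assert best is not None
    loss, W, H, converged, n_iter = best
    return SynergyModel(
        W=W,
        H=H,
        n_phases=n,
        vaf=vaf(M, W, H),
        converged=converged,
        n_iter=n_iter,
        seed=seed,
        loss_curves=curves,
    )


def select_order(
    M: np.ndarray,
    vaf_threshold: float = 0.95,
    n_max: int | None = None,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> int:
    """Smallest order in ``1..n_max`` whose best-of-restarts VAF reaches the
    threshold.  Raises :class:`OrderSelectionError` (carrying the best order
    and VAF found) if none does."""
    M = _check_matrix(M)
    if n_max is None:
        n_max = min(M.shape)
    n_max = min(n_max, min(M.shape))
    best_order, best_vaf = 0, -np.inf
    for n in range(1, n_max + 1):
        model = nmf(M, n, seed=seed, restarts=restarts, max_iter=max_iter, tol=tol)
        if model.vaf > best_vaf:
            best_order, best_vaf = n, model.vaf
        if model.vaf >= vaf_threshold:
            return n
    raise OrderSelectionError(
        f"no order up to {n_max} reached VAF {vaf_threshold:.3f} "
        f"(best: n={best_order}, VAF={best_vaf:.4f})",
        best_order=best_order,
        best_vaf=best_vaf,
    )


def normalize_model(model: SynergyModel) -> SynergyModel:
    """Scale each H row to unit maximum, transferring the scale to W.

    The reconstruction ``W @ H`` is unchanged; this is the display
    convention in which temporal patterns peak at 1 and the muscle weights
    carry the amplitude.
    """
    maxima = model.H.max(axis=1)
    if np.any(maxima <= 0):
        raise ValueError("cannot normalize a model with an all-zero H row")
    return dataclasses.replace(
        model, W=model.W * maxima[None, :], H=model.H / maxima[:, None]
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa <= 0 or sb <= 0:
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


def phase_assignment(model: SynergyModel, reference: SynergyModel) -> np.ndarray:
    """Greedy one-to-one phase assignment, reference order -> model index.

    Pairs are ranked by correlation between temporal patterns (H rows); ties
    are broken by the spatial (W column) correlation, then by the lower
    index pair.  ``perm[i]`` is the model phase matched to reference phase
    ``i``.
    """
    if model.W.shape[0] != reference.W.shape[0] or model.n_phases != reference.n_phases:
        raise ValueError("model and reference must share m and n")
    if model.H.shape[1] != reference.H.shape[1]:
        raise ValueError("model and reference H must cover the same time base")
    n = model.n_phases
    pairs = []
    for i in range(n):  # reference phase
        for j in range(n):  # model phase
            pairs.append(
                (
                    -_safe_corr(reference.H[i], model.H[j]),
                    -_safe_corr(reference.W[:, i], model.W[:, j]),
                    i,
                    j,
                )
            )
    pairs.sort()
    perm = np.full(n, -1)
    used = set()
    for _, _, i, j in pairs:
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    return perm


def match_phases(model: SynergyModel, reference: SynergyModel) -> SynergyModel:
    """Permute the model's phases into the reference order (see
    :func:`phase_assignment`).  Matching a model to itself returns it
    unchanged."""
    perm = phase_assignment(model, reference)
    return dataclasses.replace(model, W=model.W[:, perm], H=model.H[perm, :])
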