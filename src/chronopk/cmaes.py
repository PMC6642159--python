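"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES) minimiser.

A compact implementation of the standard (mu/mu_w, lambda)-CMA-ES with
rank-one and rank-mu covariance updates and cumulative step-size
adaptation, plus simple box-constraint handling: candidates are repaired
by clipping to the box and a quadratic penalty on the repair distance is
added to the objective, so the search remains unconstrained internally
while reported solutions are always feasible.

The default population size is ``4 + floor(3 ln d)`` and the initial
step size 0.3 of the box width, both seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CMAResult", "cma_minimize"]


@dataclass
class CMAResult:
    x: np.ndarray
    fun: float
    n_evals: int
    n_iter: int
    converged: bool
    message: str


def cma_minimize(
    f,
    x0,
    sigma0: float,
    *,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    popsize: int | None = None,
    max_evals: int = 10_000,
    tol_fun: float = 1e-11,
    tol_x: float = 1e-12,
    seed: int | None = None,
    penalty_weight: float = 1e6,
) -> CMAResult:
    """Minimise ``f`` starting from ``x0`` with step size ``sigma0``.

    Parameters
    ----------
    f : callable
        Objective taking a 1-d array, returning a finite float (or a large
        value for failed evaluations).
    bounds : (lower, upper) arrays, optional
        Box constraints; candidates are repaired by clipping and the
        objective is penalised by the squared normalised repair distance.
    tol_fun : float
        Stop when the spread of recent generation-best values falls below
        this (relative to their magnitude).
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    rng = np.random.default_rng(seed)

    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be < upper bounds")
        width = hi - lo
    else:
        lo = hi = width = None

    lam = popsize if popsize is not None else 4 + int(3 * np.log(d))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / d) / (d + 4 + 2 * mueff / d)
    cs = (mueff + 2) / (d + mueff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((d + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (d + 1)) - 1) + cs
    chiN = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d**2))

    m = x0.copy()
    sigma = float(sigma0)
    C = np.eye(d)
    pc = np.zeros(d)
    ps = np.zeros(d)
    B, D = np.eye(d), np.ones(d)
    eigen_stale = 0

    def evaluate(x: np.ndarray) -> tuple[float, np.ndarray]:
        if lo is None:
            return float(f(x)), x
        x_rep = np.clip(x, lo, hi)
        pen = float(np.sum(((x - x_rep) / width) ** 2))
        val = float(f(x_rep))
        return val + penalty_weight * pen, x_rep

    best_x, best_f = None, np.inf
    recent_best: list[float] = []
    n_evals = 0
    n_iter = 0
    message = "max_evals reached"
    converged = False

    while n_evals < max_evals:
        n_iter += 1
        if eigen_stale > max(1, int(1 / (10 * d * (c1 + cmu)))):
            C = (C + C.T) / 2
            Dsq, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(Dsq, 1e-30))
            eigen_stale = 0
        eigen_stale += 1

        Z = rng.standard_normal((lam, d))
        Y = Z * D @ B.T          # y_k = B D z_k
        X = m + sigma * Y
        vals = np.empty(lam)
        reps = np.empty_like(X)
        for k in range(lam):
            vals[k], reps[k] = evaluate(X[k])
        n_evals += lam

        order = np.argsort(vals)
        if vals[order[0]] < best_f:
            best_f = float(vals[order[0]])
            best_x = reps[order[0]].copy()

        y_w = w @ Y[order[:mu]]
        m = m + sigma * y_w

        C_inv_sqrt_y = B @ ((B.T @ y_w) / D)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * C_inv_sqrt_y
        hsig = (
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * n_iter)) / chiN
            < 1.4 + 2 / (d + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        artmp = Y[order[:mu]]
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
            + cmu * (artmp.T * w) @ artmp
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chiN - 1))

        recent_best.append(float(vals[order[0]]))
        horizon = 10 + int(30 * d / lam)
        if len(recent_best) > horizon:
            recent_best.pop(0)
            spread = max(recent_best) - min(recent_best)
            scale = max(abs(recent_best[-1]), 1e-12)
            if spread <= tol_fun * scale or spread <= 1e-300:
                converged, message = True, "tol_fun"
                break
        if sigma * np.max(D) < tol_x * (1.0 if width is None else float(np.max(width))):
            converged, message = True, "tol_x"
            break
        if not np.all(np.isfinite(C)):
            message = "covariance degenerated"
            break

    return CMAResult(
        x=best_x if best_x is not None else m,
        fun=float(best_f),
        n_evals=n_evals,
        n_iter=n_iter,
        converged=converged,
        message=message,
    )
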