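"""Shared maximum-likelihood machinery: multistart quasi-Newton, numeric Hessians."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import optimize

Bounds = Sequence[tuple[float | None, float | None]]


def maximize(
    loglik: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Bounds,
    n_starts: int = 5,
    seed: int = 0,
    jitter: float = 0.5,
) -> tuple[np.ndarray, float, bool]:
    """Maximize a log-likelihood with L-BFGS-B from several jittered starts.

    Returns (argmax, max value, converged).  ``converged`` is True if at
    least one start terminated successfully at the reported optimum.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.size == 0:
        return x0, float(loglik(x0)), True
    rng = np.random.default_rng(seed)

    def neg(theta: np.ndarray) -> float:
        val = loglik(theta)
        return np.inf if not np.isfinite(val) else -val

    best_x, best_val, best_ok = x0, -np.inf, False
    for k in range(n_starts):
        start = x0 if k == 0 else x0 + rng.normal(scale=jitter, size=x0.size)
        start = _clip_to_bounds(start, bounds)
        res = optimize.minimize(
            neg, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        val = -res.fun
        if val > best_val + 1e-12 or (not best_ok and val >= best_val - 1e-9 and res.success):
            best_x, best_val, best_ok = res.x, max(val, best_val), bool(res.success)
    return best_x, float(best_val), best_ok


def _clip_to_bounds(x: np.ndarray, bounds: Bounds) -> np.ndarray:
    out = x.copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None:
            out[i] = max(out[i], lo + 1e-10 if out[i] <= lo else out[i])
        if hi is not None:
            out[i] = min(out[i], hi)
    return out


def hessian(f: Callable[[np.ndarray], float], x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def covariance_from_loglik(
    loglik: Callable[[np.ndarray], float], theta: np.ndarray
) -> tuple[np.ndarray | None, bool]:
    """Observed-information covariance matrix; (None, False) if not invertible PD."""
    if theta.size == 0:
        return np.zeros((0, 0)), True
    H = hessian(loglik, theta)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None, False
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return None, False
    return cov, True
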