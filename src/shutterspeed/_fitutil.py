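"""Shared helpers for least-squares fitting: covariance, CIs, bound flags."""

from __future__ import annotations

import numpy as np
from scipy import stats


def covariance_from_jacobian(jac: np.ndarray, rss: float, n_obs: int) -> np.ndarray:
    """Linearized parameter covariance ``s^2 (J^T J)^+`` from a residual Jacobian.

    Uses the pseudo-inverse so rank-deficient (unidentifiable) problems
    yield large-but-finite variances along the identifiable directions and
    the fit can still report diagnostics.
    """
    n_par = jac.shape[1]
    dof = max(n_obs - n_par, 1)
    s2 = rss / dof
    jtj = jac.T @ jac
    # regularize the pseudo-inverse cut-off relative to the largest singular value
    cov = s2 * np.linalg.pinv(jtj, rcond=1e-12)
    return cov


def t_confidence_intervals(estimates: np.ndarray, std_errors: np.ndarray,
                           dof: int, level: float = 0.95):
    """Symmetric t-based confidence intervals per parameter."""
    tcrit = stats.t.ppf(0.5 + level / 2.0, max(dof, 1))
    lo = estimates - tcrit * std_errors
    hi = estimates + tcrit * std_errors
    return lo, hi


def flag_active_bounds(names, values, lower, upper,
                       rtol: float = 1e-6) -> dict[str, str]:
    """Map parameter name -> 'lower'/'upper' for estimates sitting on a bound."""
    flags: dict[str, str] = {}
    for name, val, lo, hi in zip(names, values, lower, upper):
        span = (hi - lo) if np.isfinite(hi - lo) else max(abs(val), 1.0)
        tol = rtol * max(span, abs(val), 1.0)
        if np.isfinite(lo) and abs(val - lo) <= tol:
            flags[name] = "lower"
        elif np.isfinite(hi) and abs(val - hi) <= tol:
            flags[name] = "upper"
    return flags


def numeric_jacobian(fun, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of a vector function."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(fun(x))
    jac = np.empty((f0.size, x.size))
    for j in range(x.size):
        h = rel_step * max(abs(x[j]), 1e-8)
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        jac[:, j] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2.0 * h)
    return jac
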