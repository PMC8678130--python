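"""Shared data containers for relaxation acquisitions and fit results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

VALID_SEQUENCES = ("IR", "NP", "PP")


@dataclass
class RelaxAcquisition:
    """One (tau, signal) relaxation curve with acquisition metadata.

    Parameters
    ----------
    tau_s : array-like
        Delay values in seconds; strictly increasing, all >= 0, length >= 8.
    signal : array-like
        Signal magnitudes (arbitrary units), same length as ``tau_s``.
    field_mhz : float
        Relaxation field in MHz proton Larmor frequency.
    sequence_type : {"IR", "NP", "PP"}
        Inversion-recovery, non-polarized build-up, or pre-polarized decay.
    temperature_c : float
        Sample temperature in Celsius (metadata only).
    meta : dict
        Free-form labels (sample id, dose, arm, timepoint, ground truth
        when synthetic, ...).
    """

    tau_s: np.ndarray
    signal: np.ndarray
    field_mhz: float
    sequence_type: str
    temperature_c: float = 25.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau_s = np.asarray(self.tau_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.tau_s.ndim != 1 or self.tau_s.size < 8:
            raise ValueError("tau_s must be a 1-D sequence with >= 8 delays")
        if self.signal.shape != self.tau_s.shape:
            raise ValueError("signal must have the same length as tau_s")
        if np.any(self.tau_s < 0) or not np.all(np.isfinite(self.tau_s)):
            raise ValueError("tau_s values must be finite and non-negative")
        if np.any(np.diff(self.tau_s) <= 0):
            raise ValueError("tau_s must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.sequence_type not in VALID_SEQUENCES:
            raise ValueError(
                f"sequence_type must be one of {VALID_SEQUENCES}; "
                f"got {self.sequence_type!r}")
        self.field_mhz = float(self.field_mhz)
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")

    @property
    def n_obs(self) -> int:
        return int(self.tau_s.size)


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics for one least-squares fit.

    ``estimates`` maps parameter names to point estimates; ``std_errors``
    and ``ci95`` carry the matching linearized (or bootstrap) standard
    errors and 95% confidence intervals.  ``active_bounds`` maps a
    parameter name to ``"lower"``/``"upper"`` when its estimate sits on a
    box constraint within tolerance.  A fit that failed to converge from
    every start has ``converged = False`` and its estimates are not
    reportable.
    """

    estimates: dict[str, float]
    std_errors: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    converged: bool
    active_bounds: dict[str, str]
    n_obs: int
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def reportable(self) -> bool:
        """Whether the estimates may be used in downstream summaries."""
        return bool(self.converged)

    def to_record(self) -> dict[str, Any]:
        """Flatten to a JSON-serializable record."""
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "ci95": {k: [float(lo), float(hi)]
                     for k, (lo, hi) in self.ci95.items()},
            "rss": float(self.rss),
            "converged": bool(self.converged),
            "active_bounds": dict(self.active_bounds),
            "n_obs": int(self.n_obs),
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


def welch_test(a, b) -> tuple[float, float]:
    """Welch two-sample t test returning ``(statistic, p_value)``.

    Degenerate inputs (both groups constant) return (0.0, 1.0) when the
    means agree, (inf, 0.0) otherwise, so downstream summaries never see
    NaN from zero-variance groups.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test requires >= 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
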