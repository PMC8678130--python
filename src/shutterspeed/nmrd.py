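"""Global two-site-exchange fit of multi-field FFC magnetization decays.

In vivo, no contrast agent is needed: at relaxation fields below ~1 MHz
the intrinsic intra/extracellular rate difference is itself large enough
to make the observed magnetization decay sensitive to water exchange.
One subject's dataset is a set of decays at several relaxation fields; a
single constrained least-squares objective is fitted across all of them,
sharing the extracellular volume fraction ``v_ex`` and the extracellular
water lifetime ``tau_ex`` while holding the extracellular rate ``r1_ex``
fixed per field to values measured on a Matrigel phantom.  The
intracellular rate ``r1_in`` is free at each field (no dispersion shape
is imposed) and per-curve amplitudes are nuisance parameters solved in
closed form (variable projection), so the nonlinear search runs over just
``(v_ex, tau_ex, r1_in per field)``.

The efflux rate is reported as the derived quantity
``k_io = (1/tau_ex) * v_ex / (1 - v_ex)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import twosite
from ._fitutil import (covariance_from_jacobian, flag_active_bounds,
                       numeric_jacobian, t_confidence_intervals)
from .containers import FitResult, RelaxAcquisition, welch_test

__all__ = [
    "V_EX_BOUNDS",
    "NMRDDataset",
    "GlobalFitSpec",
    "matrigel_r1ex_lookup",
    "fit_nmrd_global",
    "predict_dataset",
    "longitudinal_summary",
]

# Literature ranges for the extracellular volume fraction of mouse hind
# limbs, used as fit constraints by tissue class.
V_EX_BOUNDS: dict[str, tuple[float, float]] = {
    "healthy": (0.09, 0.19),
    "tumor": (0.15, 0.5),
}

DEFAULT_FIELD_WINDOW_MHZ = (0.01, 1.0)


def matrigel_r1ex_lookup(table, field_mhz: float) -> float:
    """Interpolate the Matrigel extracellular rate at a relaxation field.

    ``table`` is an (N, 2) array-like of (field_mhz, r1_ex) pairs, N >= 2.
    Interpolation is linear in log(field) — dispersion profiles live on a
    log-frequency axis — and exact at table nodes.  Queries outside the
    tabulated range raise (no extrapolation).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("Matrigel table must be (N, 2) with N >= 2")
    if np.any(arr[:, 0] <= 0) or np.any(arr[:, 1] <= 0):
        raise ValueError("Matrigel fields and rates must be positive")
    order = np.argsort(arr[:, 0])
    fields, rates = arr[order, 0], arr[order, 1]
    field_mhz = float(field_mhz)
    if not fields[0] <= field_mhz <= fields[-1]:
        raise ValueError(
            f"field {field_mhz} MHz outside Matrigel table range "
            f"[{fields[0]}, {fields[-1]}] MHz")
    return float(np.interp(np.log(field_mhz), np.log(fields), rates))


@dataclass
class NMRDDataset:
    """Per-subject multi-field acquisition set plus the Matrigel table.

    Requires >= 3 distinct relaxation fields, every field inside the
    Matrigel table's interpolation range, and (by default) inside the
    0.01-1 MHz analysis window.
    """

    acquisitions: list[RelaxAcquisition]
    matrigel_r1ex: np.ndarray
    tissue_class: str = "tumor"
    meta: dict = dc_field(default_factory=dict)
    field_window_mhz: tuple[float, float] = DEFAULT_FIELD_WINDOW_MHZ

    def __post_init__(self) -> None:
        self.matrigel_r1ex = np.asarray(self.matrigel_r1ex, dtype=float)
        if self.tissue_class not in V_EX_BOUNDS:
            raise ValueError(
                f"tissue_class must be one of {sorted(V_EX_BOUNDS)}")
        fields = [a.field_mhz for a in self.acquisitions]
        if len(set(fields)) < 3:
            raise ValueError("NMRDDataset requires >= 3 distinct fields")
        lo, hi = self.field_window_mhz
        for f in fields:
            if not lo <= f <= hi:
                raise ValueError(
                    f"field {f} MHz outside analysis window [{lo}, {hi}] MHz")
            matrigel_r1ex_lookup(self.matrigel_r1ex, f)  # range check

    @property
    def fields_mhz(self) -> np.ndarray:
        """Sorted unique relaxation fields present in the dataset."""
        return np.unique([a.field_mhz for a in self.acquisitions])


@dataclass
class GlobalFitSpec:
    """Configuration of the shared-parameter global fit.

    ``v_ex_bounds=None`` selects the tissue-class default.  The
    deterministic multi-start grid is the product of ``v_ex_starts``
    (default: 20/50/80% of the allowed range) and ``tau_ex_starts``
    (seconds).  ``extra_starts`` may supply explicit ``(v_ex, tau_ex)``
    pairs, e.g. warm starts from a previous fit.  ``n_boot > 0`` switches
    the uncertainties of the shared parameters from linearized standard
    errors to a per-curve residual bootstrap (seed required).
    """

    v_ex_bounds: tuple[float, float] | None = None
    tau_ex_bounds: tuple[float, float] = (1e-3, 50.0)
    r1_in_bounds: tuple[float, float] = (1e-3, 200.0)
    v_ex_starts: tuple[float, ...] | None = None
    tau_ex_starts: tuple[float, ...] = (0.1, 0.5, 2.5)
    extra_starts: tuple[tuple[float, float], ...] = ()
    ftol: float = 1e-8
    xtol: float = 1e-8
    n_boot: int = 0
    seed: int | None = None
    uncertainties: bool = True

    def resolve_v_ex_bounds(self, tissue_class: str) -> tuple[float, float]:
        return self.v_ex_bounds or V_EX_BOUNDS[tissue_class]


def _init_rate(tau: np.ndarray, y: np.ndarray) -> float:
    """Crude apparent-rate estimate (half-life of the decaying deviation)."""
    tail = float(np.mean(y[-2:]))
    dev = np.abs(y - tail)
    d0 = dev[0]
    if d0 <= 0:
        return 1.0
    below = np.nonzero(dev <= 0.5 * d0)[0]
    if below.size == 0 or tau[below[0]] <= 0:
        return 1.0 / max(tau[-1], 1e-6)
    return float(np.log(2.0) / tau[below[0]])


def _relative_weights(signal: np.ndarray,
                      floor_frac: float = 1e-3) -> np.ndarray:
    """Per-point weights ``1 / max(|s|, floor)``.

    A field-cycling relaxometer's dominant error is relative (a stated
    fractional uncertainty on the rate), so residuals are weighted by the
    inverse local signal magnitude; the floor (a fraction of the curve
    maximum) keeps near-zero tail points from dominating and doubles as
    the overall per-curve normalization across very different absolute
    amplitudes.
    """
    scale = max(float(np.max(np.abs(signal))), 1e-300)
    return 1.0 / np.maximum(np.abs(signal), floor_frac * scale)


class _GlobalContext:
    """Precomputed per-curve arrays for the variable-projection objective."""

    def __init__(self, data: NMRDDataset):
        self.curves = data.acquisitions
        self.fields = sorted({a.field_mhz for a in self.curves})
        self.field_index = {f: i for i, f in enumerate(self.fields)}
        self.r1_ex = np.array([
            matrigel_r1ex_lookup(data.matrigel_r1ex, f) for f in self.fields])
        self.weights = [_relative_weights(a.signal) for a in self.curves]
        self.n_obs = sum(a.n_obs for a in self.curves)
        self.init_rates = np.full(len(self.fields), np.nan)
        for acq in self.curves:
            i = self.field_index[acq.field_mhz]
            if np.isnan(self.init_rates[i]):
                self.init_rates[i] = _init_rate(acq.tau_s, acq.signal)

    def curve_models(self, theta: np.ndarray):
        """Model curves at theta = [v_ex, tau_ex, r1_in per field].

        Amplitudes (m_inf, m_start) are profiled out per curve: every
        sequence obeys ``s = m_inf + (m_start - m_inf) E(tau)`` which is
        linear in (m_inf, m_start) given the decay factor E; NP curves
        constrain m_start = 0.
        """
        v_ex, tau_ex = theta[0], theta[1]
        r1_ins = theta[2:]
        p_i, p_o = 1.0 - v_ex, v_ex
        k_oi = 1.0 / tau_ex
        k_io = k_oi * p_o / p_i
        r1_fast, r1_slow, a_fast = twosite._biexp_arrays(
            r1_ins, self.r1_ex, k_io, k_oi, p_i, p_o)
        preds, amplitudes = [], []
        for acq, w in zip(self.curves, self.weights):
            i = self.field_index[acq.field_mhz]
            tau = acq.tau_s
            e_dec = (a_fast[i] * np.exp(-r1_fast[i] * tau)
                     + (1.0 - a_fast[i]) * np.exp(-r1_slow[i] * tau))
            y = acq.signal
            w2 = w * w
            if acq.sequence_type == "NP":
                x = 1.0 - e_dec
                denom = float((w2 * x) @ x)
                m_inf = float((w2 * x) @ y) / denom if denom > 0 else 0.0
                m_start = 0.0
            else:  # PP or IR: both endpoints free
                x0 = 1.0 - e_dec
                g00 = float((w2 * x0) @ x0)
                g01 = float((w2 * x0) @ e_dec)
                g11 = float((w2 * e_dec) @ e_dec)
                b0 = float((w2 * x0) @ y)
                b1 = float((w2 * e_dec) @ y)
                det = g00 * g11 - g01 * g01
                if det > 1e-14 * max(g00 * g11, 1e-300):
                    m_inf = (g11 * b0 - g01 * b1) / det
                    m_start = (g00 * b1 - g01 * b0) / det
                else:  # decay factor (numerically) constant: amplitude only
                    tot = g00 + 2 * g01 + g11
                    m_inf = m_start = (b0 + b1) / tot if tot > 0 else 0.0
            preds.append(m_inf * (1.0 - e_dec) + m_start * e_dec)
            amplitudes.append((m_inf, m_start))
        return preds, amplitudes

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        preds, _ = self.curve_models(theta)
        return np.concatenate([
            w * (pred - acq.signal)
            for w, pred, acq in zip(self.weights, preds, self.curves)])


def predict_dataset(data: NMRDDataset, v_ex: float, tau_ex: float,
                    r1_in_per_field: Mapping[float, float]):
    """Noise-free model curves for a dataset at given shared parameters.

    Amplitudes are profiled against the dataset's signals exactly as in
    the fit objective.  Returns ``(curves, amplitudes)`` in acquisition
    order; useful for plotting and for consistency checks against the
    single-curve forward model.
    """
    ctx = _GlobalContext(data)
    theta = np.concatenate([[v_ex, tau_ex],
                            [r1_in_per_field[f] for f in ctx.fields]])
    return ctx.curve_models(theta)


def fit_nmrd_global(data: NMRDDataset,
                    spec: GlobalFitSpec | None = None) -> FitResult:
    """Global constrained fit of one subject's multi-field dataset.

    Minimizes a single weighted least-squares objective (per-curve weights
    ``1/max|signal|`` balance the very different absolute amplitudes
    across fields) over ``v_ex`` (bounded by tissue class), ``tau_ex`` and
    one ``r1_in`` per field; per-curve amplitudes are solved in closed
    form.  Deterministic multi-start over ``(v_ex, tau_ex)``; ties broken
    by the smaller implied ``k_io``.

    The returned estimates include the derived efflux rate ``k_io`` (delta
    method standard error) and per-field ``r1_in@<field>MHz`` entries;
    ``diagnostics`` carries the per-curve amplitudes, the effective
    single-exponential rate per field (the quantity a dispersion profile
    plots), the start log, and the bounds in force.
    """
    spec = spec or GlobalFitSpec()
    ctx = _GlobalContext(data)
    n_fields = len(ctx.fields)
    vex_lo, vex_hi = spec.resolve_v_ex_bounds(data.tissue_class)
    lower = np.concatenate([[vex_lo, spec.tau_ex_bounds[0]],
                            np.full(n_fields, spec.r1_in_bounds[0])])
    upper = np.concatenate([[vex_hi, spec.tau_ex_bounds[1]],
                            np.full(n_fields, spec.r1_in_bounds[1])])

    r1_in0 = np.clip(ctx.init_rates, spec.r1_in_bounds[0] * 1.001,
                     spec.r1_in_bounds[1] * 0.999)
    vex_starts = spec.v_ex_starts or tuple(
        vex_lo + frac * (vex_hi - vex_lo) for frac in (0.2, 0.5, 0.8))
    start_pairs = [(v, t) for v in vex_starts for t in spec.tau_ex_starts]
    start_pairs += list(spec.extra_starts)

    def kio_of(theta):
        return (1.0 / theta[1]) * theta[0] / (1.0 - theta[0])

    best = None
    starts_log = []
    for v0, t0 in start_pairs:
        x0 = np.concatenate([[v0, t0], r1_in0])
        x0 = np.clip(x0, lower + 1e-9 * (upper - lower),
                     upper - 1e-9 * (upper - lower))
        try:
            res = least_squares(ctx.residuals, x0, bounds=(lower, upper),
                                method="trf", x_scale="jac",
                                ftol=spec.ftol, xtol=spec.xtol)
        except Exception as exc:
            starts_log.append({"start": [v0, t0], "error": str(exc)})
            continue
        starts_log.append({"start": [v0, t0], "cost": float(res.cost),
                           "success": bool(res.success)})
        if not res.success:
            continue
        if best is None or res.cost < best.cost * (1 - 1e-10) or (
                abs(res.cost - best.cost) <= 1e-10 * max(best.cost, 1e-300)
                and kio_of(res.x) < kio_of(best.x)):
            best = res

    names = (["v_ex", "tau_ex"]
             + [f"r1_in@{f:g}MHz" for f in ctx.fields])
    if best is None:
        nan = float("nan")
        return FitResult(
            estimates={n: nan for n in names + ["k_io"]},
            std_errors={n: nan for n in names + ["k_io"]},
            ci95={n: (nan, nan) for n in names + ["k_io"]},
            rss=nan, converged=False, active_bounds={}, n_obs=ctx.n_obs,
            seed=spec.seed, warnings=["no start converged"],
            diagnostics={"starts": starts_log})

    theta = best.x
    rss = float(2.0 * best.cost)
    preds, amplitudes = ctx.curve_models(theta)
    n_theta = theta.size
    amp_flat, amp_slices = [], []
    for acq, (m_inf, m_start) in zip(ctx.curves, amplitudes):
        if acq.sequence_type == "NP":
            amp_slices.append((len(amp_flat), 1))
            amp_flat.append(m_inf)
        else:
            amp_slices.append((len(amp_flat), 2))
            amp_flat.extend([m_inf, m_start])
    dof = ctx.n_obs - (n_theta + len(amp_flat))

    v_ex, tau_ex = float(theta[0]), float(theta[1])
    k_io = twosite.kio_from_tau_ex(tau_ex, v_ex)
    estimates = dict(zip(names, theta.tolist()))
    estimates["k_io"] = k_io

    if spec.uncertainties:
        # Covariance from the full parameterization (shared + per-curve
        # amplitudes fixed at their profiled optimum), so shared-parameter
        # standard errors account for the nuisance amplitudes.
        def full_residual(full: np.ndarray) -> np.ndarray:
            th = full[:n_theta]
            vx, tx = th[0], th[1]
            p_i, p_o = 1.0 - vx, vx
            k_oi = 1.0 / tx
            r1_fast, r1_slow, a_fast = twosite._biexp_arrays(
                th[2:], ctx.r1_ex, k_oi * p_o / p_i, k_oi, p_i, p_o)
            out = []
            for acq, w, (off, width) in zip(ctx.curves, ctx.weights,
                                            amp_slices):
                i = ctx.field_index[acq.field_mhz]
                e_dec = (a_fast[i] * np.exp(-r1_fast[i] * acq.tau_s)
                         + (1.0 - a_fast[i]) * np.exp(-r1_slow[i] * acq.tau_s))
                m_inf = full[n_theta + off]
                m_start = full[n_theta + off + 1] if width == 2 else 0.0
                out.append(w * (m_inf * (1.0 - e_dec) + m_start * e_dec
                                - acq.signal))
            return np.concatenate(out)

        full_x = np.concatenate([theta, amp_flat])
        jac = numeric_jacobian(full_residual, full_x)
        cov = covariance_from_jacobian(jac, rss, ctx.n_obs)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))[:n_theta]
        # delta method for k_io = v_ex / ((1 - v_ex) tau_ex)
        grad = np.array([1.0 / ((1.0 - v_ex) ** 2 * tau_ex),
                         -v_ex / ((1.0 - v_ex) * tau_ex ** 2)])
        k_io_se = float(np.sqrt(max(float(grad @ cov[:2, :2] @ grad), 0.0)))
    else:
        se = np.full(n_theta, np.nan)
        k_io_se = float("nan")

    std_errors = dict(zip(names, se.tolist()))
    std_errors["k_io"] = k_io_se

    warnings: list[str] = []
    # Shutter-speed premise: exchange is only visible where the
    # intra/extracellular rate difference is comparable to or larger than
    # the exchange rates.  If most fields lack that contrast at the fitted
    # optimum, the lifetime estimate is not identifiable and its
    # linearized CI is unreliable.
    k_oi_hat = 1.0 / tau_ex
    exch = k_io + k_oi_hat
    contrast_ok = np.abs(theta[2:] - ctx.r1_ex) >= exch / 3.0
    if np.count_nonzero(contrast_ok) < 0.5 * len(ctx.fields):
        warnings.append(
            "identifiability: intra/extracellular rate contrast below the "
            "exchange rate at most fields; tau_ex (hence k_io) is not "
            "reliably determined")

    if spec.n_boot > 0:
        if spec.seed is None:
            raise ValueError("bootstrap uncertainties require spec.seed")
        boot = _bootstrap_shared(ctx, data, spec, theta, preds)
        for key in ("v_ex", "tau_ex", "k_io"):
            std_errors[key] = boot[key]["se"]

    est_vec = np.array([estimates[n] for n in names + ["k_io"]])
    se_vec = np.array([std_errors[n] for n in names + ["k_io"]])
    lo_ci, hi_ci = t_confidence_intervals(est_vec, se_vec, dof)
    ci95 = {n: (float(lo), float(hi))
            for n, lo, hi in zip(names + ["k_io"], lo_ci, hi_ci)}

    r1_obs = {}
    if spec.uncertainties:  # full-report mode: include the plottable profile
        for acq in ctx.curves:
            i = ctx.field_index[acq.field_mhz]
            p_i, p_o = 1.0 - v_ex, v_ex
            k_oi = 1.0 / tau_ex
            rf, rs, af = twosite._biexp_arrays(
                theta[2 + i], ctx.r1_ex[i], k_oi * p_o / p_i, k_oi, p_i, p_o)
            sol = twosite.BiexpSolution(float(rf), float(rs), float(af),
                                        1.0 - float(af))
            r1_obs[acq.field_mhz] = twosite.effective_monoexp_r1(
                sol, acq.tau_s)

    return FitResult(
        estimates=estimates,
        std_errors=std_errors,
        ci95=ci95,
        rss=rss,
        converged=True,
        active_bounds=flag_active_bounds(
            names, theta, lower, upper, rtol=1e-6),
        n_obs=ctx.n_obs,
        seed=spec.seed,
        warnings=warnings,
        diagnostics={
            "starts": starts_log,
            "amplitudes": {f"{acq.field_mhz:g}MHz_{acq.sequence_type}": amp
                           for acq, amp in zip(ctx.curves, amplitudes)},
            "r1_obs_profile": r1_obs,
            "bounds": {"v_ex": (vex_lo, vex_hi),
                       "tau_ex": spec.tau_ex_bounds,
                       "r1_in": spec.r1_in_bounds},
        })


def _bootstrap_shared(ctx: _GlobalContext, data: NMRDDataset,
                      spec: GlobalFitSpec, theta_hat: np.ndarray,
                      preds: list[np.ndarray]) -> dict:
    """Per-curve residual bootstrap of the shared parameters.

    Residuals are resampled with replacement within each curve (respecting
    the heteroscedastic multi-curve structure) and the fit restarted from
    the point estimate only.
    """
    rng = np.random.default_rng(spec.seed)
    draws = {"v_ex": [], "tau_ex": [], "k_io": []}
    lower = np.concatenate([[spec.resolve_v_ex_bounds(data.tissue_class)[0],
                             spec.tau_ex_bounds[0]],
                            np.full(theta_hat.size - 2, spec.r1_in_bounds[0])])
    upper = np.concatenate([[spec.resolve_v_ex_bounds(data.tissue_class)[1],
                             spec.tau_ex_bounds[1]],
                            np.full(theta_hat.size - 2, spec.r1_in_bounds[1])])
    resid = [acq.signal - pred for acq, pred in zip(ctx.curves, preds)]
    originals = [acq.signal.copy() for acq in ctx.curves]
    try:
        for _ in range(spec.n_boot):
            for acq, pred, r in zip(ctx.curves, preds, resid):
                idx = rng.integers(0, r.size, r.size)
                acq.signal = pred + r[idx]
            ctx.weights = [_relative_weights(a.signal) for a in ctx.curves]
            res = least_squares(ctx.residuals, theta_hat,
                                bounds=(lower, upper), method="trf",
                                x_scale="jac", ftol=spec.ftol, xtol=spec.xtol)
            if not res.success:
                continue
            v, t = float(res.x[0]), float(res.x[1])
            draws["v_ex"].append(v)
            draws["tau_ex"].append(t)
            draws["k_io"].append(twosite.kio_from_tau_ex(t, v))
    finally:
        for acq, orig in zip(ctx.curves, originals):
            acq.signal = orig
        ctx.weights = [_relative_weights(a.signal) for a in ctx.curves]
    return {key: {"se": float(np.std(vals, ddof=1)) if len(vals) > 1
                  else float("nan"), "draws": vals}
            for key, vals in draws.items()}


def longitudinal_summary(records: Sequence[tuple[str, float, FitResult]]
                         ) -> pd.DataFrame:
    """Cohort summary of fitted ``k_io`` and ``v_ex`` by arm and timepoint.

    ``records`` is a sequence of ``(arm, timepoint, fit)`` tuples; arms
    are expected to include ``"control"`` and ``"treated"``.  Returns one
    row per (timepoint, arm) with means, SDs, counts, exclusion counts for
    non-converged fits, and Welch tests of treated vs control per
    timepoint.  Cells with fewer than 2 converged fits keep their row but
    the contrast is omitted with a recorded reason.
    """
    cells: dict[tuple[float, str], list[FitResult]] = {}
    for arm, timepoint, fit in records:
        cells.setdefault((float(timepoint), str(arm)), []).append(fit)

    values: dict[tuple[float, str], dict[str, np.ndarray]] = {}
    rows = []
    for (tp, arm), fits in sorted(cells.items()):
        good = [f for f in fits if f.reportable]
        values[(tp, arm)] = {
            "k_io": np.array([f.estimates["k_io"] for f in good]),
            "v_ex": np.array([f.estimates["v_ex"] for f in good]),
        }
        rows.append({
            "timepoint": tp, "arm": arm,
            "mean_k_io": float(np.mean(values[(tp, arm)]["k_io"]))
            if good else np.nan,
            "sd_k_io": float(np.std(values[(tp, arm)]["k_io"], ddof=1))
            if len(good) > 1 else np.nan,
            "mean_v_ex": float(np.mean(values[(tp, arm)]["v_ex"]))
            if good else np.nan,
            "sd_v_ex": float(np.std(values[(tp, arm)]["v_ex"], ddof=1))
            if len(good) > 1 else np.nan,
            "n": len(good),
            "n_excluded": len(fits) - len(good),
            "p_k_io_vs_control": np.nan,
            "p_v_ex_vs_control": np.nan,
            "note": "",
        })

    frame = pd.DataFrame(rows)
    for idx, row in frame.iterrows():
        if row["arm"] == "control":
            continue
        key_t = (row["timepoint"], row["arm"])
        key_c = (row["timepoint"], "control")
        if key_c not in values:
            frame.loc[idx, "note"] = "no control cell at this timepoint"
            continue
        treated, control = values[key_t], values[key_c]
        if treated["k_io"].size < 2 or control["k_io"].size < 2:
            frame.loc[idx, "note"] = ("contrast omitted: fewer than 2 "
                                      "converged fits")
            continue
        _, p_k = welch_test(treated["k_io"], control["k_io"])
        _, p_v = welch_test(treated["v_ex"], control["v_ex"])
        frame.loc[idx, "p_k_io_vs_control"] = p_k
        frame.loc[idx, "p_v_ex_vs_control"] = p_v
    return frame
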