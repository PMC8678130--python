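"""Synthetic relaxometry data with known ground truth.

Emulates the statistical structure of a desk-scale water-exchange study:
in-vitro inversion-recovery curves of cell pellets with an extracellular
Gd agent, in-vivo multi-field FFC decay sets of tumor-bearing limbs, and
treated-vs-control mouse cohorts followed over a treatment course.  All
noiseless signals come from :mod:`shutterspeed.twosite` (the generator
shares no private forward math with the fitters' model — both call the
same public closed form), every random draw flows from an explicit seed,
and every generated object embeds its ground truth in metadata.

The in-vivo intracellular dispersion template and the Matrigel table
shipped here are synthetic stand-ins with realistic shapes and
magnitudes, not measured values; the truth manifest labels them as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import twosite
from .containers import RelaxAcquisition
from .invitro import GdAgentSpec, r1ex_with_agent
from .nmrd import NMRDDataset, matrigel_r1ex_lookup

__all__ = [
    "DEFAULT_FIELDS_MHZ",
    "DispersionTruth",
    "CohortTruth",
    "default_dispersion_truth",
    "default_matrigel_table",
    "default_invitro_truth",
    "default_agent",
    "gen_ir_dataset",
    "gen_nmrd_dataset",
    "gen_cohort",
]

# The seven relaxation fields of the in-vivo analysis window (MHz proton
# Larmor frequency).
DEFAULT_FIELDS_MHZ = (0.01, 0.02, 0.037, 0.07, 0.15, 0.39, 1.0)

POLARIZATION_FIELD_MHZ = 13.0


@dataclass(frozen=True)
class DispersionTruth:
    """Ground-truth field dependence of the intracellular rate.

    ``r1_in(nu) = amplitude / (1 + (nu / corner_mhz)^2) + offset`` — a
    Lorentzian-plus-offset template: smooth, positive and decreasing over
    the 0.01-1 MHz window, the qualitative shape of tissue dispersion
    profiles.  ``r1_ex_table`` is the accompanying synthetic Matrigel-like
    extracellular rate table ((field MHz, r1_ex s^-1) pairs).
    """

    amplitude: float = 8.0
    corner_mhz: float = 0.1
    offset: float = 1.5
    r1_ex_table: np.ndarray = dc_field(
        default_factory=lambda: default_matrigel_table())

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.offset <= 0 or self.corner_mhz <= 0:
            raise ValueError("dispersion template parameters must be positive")

    def r1_in_at(self, field_mhz) -> np.ndarray:
        """Intracellular rate (s^-1) at one or more fields (MHz)."""
        nu = np.asarray(field_mhz, dtype=float)
        return self.amplitude / (1.0 + (nu / self.corner_mhz) ** 2) + self.offset


def default_matrigel_table() -> np.ndarray:
    """Synthetic Matrigel-like extracellular R1ex dispersion table.

    A stand-in for phantom measurements: Lorentzian-plus-offset values at
    the seven analysis fields, lower than the intracellular template at
    every field so the fit has shutter-speed contrast.  Synthetic — not
    measured values.
    """
    fields = np.asarray(DEFAULT_FIELDS_MHZ)
    rates = 2.5 / (1.0 + (fields / 0.15) ** 2) + 0.8
    return np.column_stack([fields, rates])


def default_invitro_truth() -> twosite.TwoSiteParams:
    """Default pellet ground truth (untreated cells, agent present).

    The efflux rate 20 s^-1 is ~25x the default in-vivo rate, matching
    the magnitude gap between pellet and tissue measurements; ``r1_ex``
    matches :func:`default_agent`.
    """
    return twosite.TwoSiteParams(r1_in=0.6, r1_ex=35.5, k_io=20.0, v_ex=0.2)


def default_agent() -> GdAgentSpec:
    """10 mM extracellular Gd-HPDO3A with a plausible 0.5 T relaxivity."""
    return GdAgentSpec(relaxivity_r1=3.5, concentration=10.0,
                       baseline_r1_ex=0.5)


def _log_tau_grid(n_tau: int, lo: float, hi: float) -> np.ndarray:
    return np.geomspace(lo, hi, n_tau)


def gen_ir_dataset(truth: twosite.TwoSiteParams,
                   agent: GdAgentSpec | None = None,
                   n_tau: int = 64,
                   tau_range: tuple[float, float] = (1e-3, 5.0),
                   noise_sd: float = 0.01,
                   noise_model: str = "gaussian",
                   inv_eff: float = 1.0,
                   seed: int | None = None,
                   meta: dict | None = None) -> RelaxAcquisition:
    """Simulate one pellet inversion-recovery acquisition at 0.5 T.

    ``n_tau`` delays (default 64) log-spaced over ``tau_range``; if an
    ``agent`` is given its linear relaxivity overrides ``truth.r1_ex``.
    ``noise_sd`` is the additive Gaussian noise SD as a fraction of
    ``m_inf``; ``noise_model="rician"`` instead folds the signal to a
    noisy magnitude (two-channel quadrature noise).  Deterministic for a
    fixed seed; the ground truth travels in the returned metadata.
    """
    if n_tau < 8:
        raise ValueError("n_tau must be >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError("noise_model must be 'gaussian' or 'rician'")
    if agent is not None:
        truth = twosite.TwoSiteParams(
            r1_in=truth.r1_in, r1_ex=r1ex_with_agent(agent), k_io=truth.k_io,
            v_ex=truth.v_ex, m_inf=truth.m_inf)
    tau = _log_tau_grid(n_tau, *tau_range)
    sol = twosite.exchange_eigensystem(truth)
    clean = twosite.ir_signal(tau, sol, m_inf=truth.m_inf, inv_eff=inv_eff)
    rng = np.random.default_rng(seed)
    sd = noise_sd * truth.m_inf
    if noise_sd == 0:
        signal = clean
    elif noise_model == "gaussian":
        signal = clean + rng.normal(0.0, sd, clean.shape)
    else:
        signal = np.hypot(clean + rng.normal(0.0, sd, clean.shape),
                          rng.normal(0.0, sd, clean.shape))
    info = {
        "truth": {"r1_in": truth.r1_in, "r1_ex": truth.r1_ex,
                  "k_io": truth.k_io, "v_ex": truth.v_ex,
                  "m_inf": truth.m_inf, "inv_eff": inv_eff},
        "noise_sd": noise_sd, "noise_model": noise_model, "seed": seed,
    }
    if meta:
        info.update(meta)
    # 0.5 T at the proton gyromagnetic ratio ~= 21.3 MHz
    return RelaxAcquisition(tau_s=tau, signal=signal, field_mhz=21.29,
                            sequence_type="IR", temperature_c=25.0, meta=info)


def gen_nmrd_dataset(dispersion: DispersionTruth, v_ex: float, tau_ex: float,
                     fields=DEFAULT_FIELDS_MHZ,
                     n_tau: int = 32,
                     tau_window: tuple[float, float] = (2.8, 4.0),
                     noise: float = 0.02,
                     seed: int | None = None,
                     tissue_class: str = "tumor",
                     meta: dict | None = None) -> NMRDDataset:
    """Simulate one subject's multi-field pre-polarized FFC dataset.

    One PP decay per relaxation field: ``n_tau`` delays (default 32)
    log-spaced from 5 ms up to a per-field maximum drawn uniformly from
    ``tau_window`` (seconds) — a long-time range that samples both the
    rapidly and slowly relaxing components.  The starting magnetization is
    normalized to 1 (prepared at the polarization field) and the
    equilibrium value scales with the relaxation field,
    ``m_inf = field / 13 MHz``.  Noise is multiplicative Gaussian at the
    given fraction of the local signal.  Ground truth and per-field
    intrinsic rates are embedded in metadata; the accompanying Matrigel
    table comes from the dispersion truth.
    """
    fields = tuple(float(f) for f in fields)
    if len(set(fields)) != len(fields):
        raise ValueError("fields must be distinct")
    if n_tau < 8:
        raise ValueError("n_tau must be >= 8")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    k_io = twosite.kio_from_tau_ex(tau_ex, v_ex)
    rng = np.random.default_rng(seed)
    acquisitions = []
    per_field_truth = {}
    for f in fields:
        r1_in = float(dispersion.r1_in_at(f))
        r1_ex = matrigel_r1ex_lookup(dispersion.r1_ex_table, f)
        params = twosite.TwoSiteParams(r1_in=r1_in, r1_ex=r1_ex, k_io=k_io,
                                       v_ex=v_ex)
        sol = twosite.exchange_eigensystem(params)
        t_max = float(rng.uniform(*tau_window))
        tau = _log_tau_grid(n_tau, 5e-3, t_max)
        m_inf = f / POLARIZATION_FIELD_MHZ
        clean = twosite.ffc_decay_signal(tau, sol, m_start=1.0, m_inf=m_inf)
        signal = clean * (1.0 + noise * rng.standard_normal(clean.shape)) \
            if noise > 0 else clean
        per_field_truth[f] = {"r1_in": r1_in, "r1_ex": r1_ex,
                              "m_inf": m_inf, "m_start": 1.0}
        acquisitions.append(RelaxAcquisition(
            tau_s=tau, signal=signal, field_mhz=f, sequence_type="PP",
            temperature_c=25.0,
            meta={"truth_r1_in": r1_in, "truth_r1_ex": r1_ex}))
    info = {
        "truth": {"v_ex": v_ex, "tau_ex": tau_ex, "k_io": k_io,
                  "per_field": per_field_truth,
                  "dispersion": "synthetic Lorentzian template"},
        "noise": noise, "seed": seed,
    }
    if meta:
        info.update(meta)
    return NMRDDataset(acquisitions=acquisitions,
                       matrigel_r1ex=np.asarray(dispersion.r1_ex_table),
                       tissue_class=tissue_class, meta=info)


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a treated-vs-control longitudinal mouse cohort.

    ``timepoints`` are acquisition days relative to the first treatment
    (default: baseline plus three days after each of three treatments,
    given at three-day intervals).  Per-timepoint multipliers scale the
    treated arm's mean ``k_io`` and ``v_ex``; the control arm stays at the
    baseline means.  Between-animal variability is lognormal on ``k_io``
    (coefficient of variation ``kio_cv``) and additive normal on ``v_ex``
    (``vex_sd``), redrawn per animal and timepoint.  Baseline magnitudes:
    in-vivo efflux 0.8 s^-1 (about 25x below the pellet default) and
    tumor ``v_ex`` 0.30.
    """

    n_per_arm: int = 7
    timepoints: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0)
    kio_base: float = 0.8
    vex_base: float = 0.30
    treated_kio_multipliers: tuple[float, ...] = (1.0, 0.6, 1.0, 1.0)
    treated_vex_multipliers: tuple[float, ...] = (1.0, 0.85, 1.15, 1.30)
    kio_cv: float = 0.25
    vex_sd: float = 0.04
    noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        n_tp = len(self.timepoints)
        if (len(self.treated_kio_multipliers) != n_tp
                or len(self.treated_vex_multipliers) != n_tp):
            raise ValueError("multiplier tuples must match timepoints")
        if (min(self.treated_kio_multipliers) <= 0
                or min(self.treated_vex_multipliers) <= 0):
            raise ValueError("multipliers must be positive")
        for mult in self.treated_vex_multipliers:
            if not 0.0 < self.vex_base * mult < 1.0:
                raise ValueError("perturbed v_ex must stay inside (0, 1)")

    def arm_means(self, arm: str, tp_index: int) -> tuple[float, float]:
        """Configured (mean k_io, mean v_ex) for an arm at a timepoint."""
        if arm == "treated":
            return (self.kio_base * self.treated_kio_multipliers[tp_index],
                    self.vex_base * self.treated_vex_multipliers[tp_index])
        return self.kio_base, self.vex_base


def gen_cohort(truth: CohortTruth,
               dispersion: DispersionTruth | None = None,
               fields=DEFAULT_FIELDS_MHZ,
               n_tau: int = 32,
               tau_window: tuple[float, float] = (2.8, 4.0),
               vex_clip: tuple[float, float] = (0.16, 0.49)):
    """Simulate a full treated-vs-control cohort with a truth manifest.

    Hierarchical sampling: for each animal at each timepoint, the true
    ``k_io`` is drawn lognormally around the arm/timepoint mean
    (mean-preserving parameterization) and the true ``v_ex`` normally,
    clipped to ``vex_clip`` (just inside the tumor fit bounds); a full
    multi-field dataset is then generated via :func:`gen_nmrd_dataset`
    with its own child seed.  Everything is reproducible from
    ``truth.seed``.

    Returns ``(records, manifest)`` where each record is a dict with keys
    ``arm``, ``animal``, ``timepoint``, ``dataset`` and the manifest holds
    the configured arm means, per-animal truths, and child seeds.
    """
    dispersion = dispersion or default_dispersion_truth()
    rng = np.random.default_rng(truth.seed)
    sigma = float(np.sqrt(np.log1p(truth.kio_cv ** 2)))
    records = []
    manifest: dict = {
        "seed": truth.seed,
        "synthetic": True,
        "dispersion": "synthetic Lorentzian template (not measured data)",
        "configured_means": {},
        "animals": [],
    }
    for arm in ("control", "treated"):
        for j, tp in enumerate(truth.timepoints):
            kio_mean, vex_mean = truth.arm_means(arm, j)
            manifest["configured_means"][f"{arm}@t{tp:g}"] = {
                "k_io": kio_mean, "v_ex": vex_mean}
    for arm in ("control", "treated"):
        for animal in range(truth.n_per_arm):
            for j, tp in enumerate(truth.timepoints):
                kio_mean, vex_mean = truth.arm_means(arm, j)
                k_io = float(kio_mean
                             * np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
                v_ex = float(np.clip(
                    rng.normal(vex_mean, truth.vex_sd), *vex_clip))
                tau_ex = 1.0 / twosite.influx_from_efflux(k_io, v_ex)
                child_seed = int(rng.integers(0, 2 ** 31 - 1))
                dataset = gen_nmrd_dataset(
                    dispersion, v_ex=v_ex, tau_ex=tau_ex, fields=fields,
                    n_tau=n_tau, tau_window=tau_window, noise=truth.noise,
                    seed=child_seed,
                    meta={"arm": arm, "animal": animal, "timepoint": tp})
                records.append({"arm": arm, "animal": animal,
                                "timepoint": tp, "dataset": dataset})
                manifest["animals"].append({
                    "arm": arm, "animal": animal, "timepoint": tp,
                    "true_k_io": k_io, "true_v_ex": v_ex,
                    "true_tau_ex": tau_ex, "seed": child_seed})
    return records, manifest


def default_dispersion_truth() -> DispersionTruth:
    """The default synthetic in-vivo dispersion truth."""
    return DispersionTruth()
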