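# Methods

## Model

The package implements the standard two-site-exchange (2SX,
"shutter-speed") treatment of longitudinal relaxation with
transcytolemmal water exchange. Two well-mixed water pools —
intracellular (population p_i, intrinsic rate R1_in) and extracellular
(p_o, R1_ex) — exchange with first-order rate constants k_io (efflux) and
k_oi (influx). The per-compartment deviation from thermal equilibrium
follows the linear system `d' = A d` with

    A = [[-(R1_in + k_io),   k_oi          ],
         [  k_io,           -(R1_ex + k_oi)]]

whose eigen-solution gives the apparent biexponential rates R1_fast ≥
R1_slow (trace/discriminant closed form) and, for any initial deviation
proportional to the equilibrium populations, amplitude fractions
a_fast = (p_i R1_in + p_o R1_ex − R1_slow)/(R1_fast − R1_slow),
a_slow = 1 − a_fast. All three acquisition types map onto one signal
form `s(τ) = M∞ + (M_start − M∞)·(a_fast e^{−R1_fast τ} + a_slow e^{−R1_slow τ})`
with M_start = −inv_eff·M∞ (inversion recovery), 0 (non-polarized
build-up) or > M∞ (pre-polarized decay).

Assumptions built into the model:

* **Populations equal volume fractions.** Uniform water density and NMR
  visibility across compartments; this is the simplest closure that lets
  V_ex appear directly in the fit.
* **Detailed balance is structural.** k_oi is always derived as
  k_io·(1 − V_ex)/V_ex, never a free parameter, removing a
  non-identifiable degree of freedom. Equivalently τ_ex = 1/k_oi and
  k_io = (1/τ_ex)·V_ex/(1 − V_ex).
* **Two compartments, longitudinal only.** No transverse (T2) exchange
  effects, no third pool (e.g. vascular), no radiofrequency pulse physics.
* **No theory of R1_in(field).** The intracellular dispersion is handled
  empirically (free per field in vivo; a Lorentzian template in the
  generator).

### Numerical notes

* R1_fast uses the additive closed form; **R1_slow is computed as
  det(A-rates)/R1_fast** (product form) because the subtractive
  (trace − disc)/2 form loses up to 5 significant digits when the two
  rates differ by many orders of magnitude — property testing found the
  determinant identity violated at, e.g., R1_in ≈ 10³, R1_ex ≈ 0.03.
* The degenerate equal-eigenvalue case returns the monoexponential limit
  (a_fast = 0, common rate in R1_slow) instead of raising, keeping fit
  objectives continuous.
* An independent matrix-exponential propagator (`propagate_numeric`,
  scipy `expm`, cross-checked against an RK4 integrator in the tests)
  serves as the validation oracle for the closed form; agreement is
  better than 1e-8 relative over wide random parameter ranges.
* The per-field "effective monoexponential rate" (what a dispersion
  profile plots) is defined as the rate of the best least-squares
  single-exponential approximation to the noiseless biexponential on the
  acquisition's own τ grid; the amplitude is profiled out analytically
  and the 1-D problem solved by bounded minimization on
  [R1_slow, R1_fast], validated against a dense grid scan.

## In-vitro fit (`fit_ir_2sx`)

Unweighted least squares on the signed IR signal (the zero-crossing is
retained; the generator's optional Rician mode exists for magnitude
data, but fitting folded data is out of scope). R1_ex is fixed — from
the agent specification `baseline + relaxivity × concentration` (linear
inner-sphere model) or a supernatant measurement — and
(k_io, R1_in, V_ex, M∞, inv_eff) are free within box constraints:

| parameter | default bounds | rationale |
|---|---|---|
| k_io | [0, 200] s⁻¹ | physically plausible efflux range |
| R1_in | [10⁻³, 20] s⁻¹ | tissue-water rates at 0.5 T |
| V_ex | [0.01, 0.6] | plausible pellet packing |
| M∞ | (0, ∞) | absorbs units/gain |
| inv_eff | [0.5, 1] | realistic inversion pulses |

A deterministic 12-point multi-start grid (inv_eff ∈ {0.8, 1}, k_io ∈
{0.5, 5, 50} s⁻¹, V_ex ∈ {0.1, 0.3}; R1_in start 1 s⁻¹, M∞ start from
the data maximum) guards against local minima; ties are broken by the
smaller k_io. Standard errors are linearized (Jacobian), CIs use the t
distribution. Failure from every start returns a flagged, non-reportable
result. A warning is recorded when the fixed R1_ex lies within 3× of the
fitted R1_in (weak shutter-speed contrast).

**Identifiability limitation (important).** With V_ex free, the
(k_io, V_ex, R1_in) directions are nearly collinear in this design: the
Cramér–Rao floor for k_io at 1% signal noise on 64 log-spaced delays is
≈ 50% relative SE at k_io = 1–5 s⁻¹ (R1_ex = 35.5 s⁻¹, V_ex = 0.2), and
worse at k_io = 20 s⁻¹ where k_io + k_oi = 100 s⁻¹ exceeds the ΔR1 ≈ 35
s⁻¹ contrast (beyond the shutter-speed condition). Per-fit k_io values
under these conditions carry tens of percent uncertainty — the
linearized CIs report this honestly (coverage ≈ 95%). Precise per-sample
k_io requires external knowledge of the pellet V_ex (pass degenerate-ish
bounds to fix it; this cuts the error to ~5%) or stronger extracellular
enhancement. Dose-response conclusions rest on group means across
samples, which average this noise down.

## In-vivo global fit (`fit_nmrd_global`)

One weighted least-squares objective over all fields of a subject.
Shared free parameters: V_ex (bounds by tissue class: 0.09–0.19 healthy,
0.15–0.5 tumor) and τ_ex ∈ [10⁻³, 50] s; per-field free R1_in ∈ [10⁻³,
200] s⁻¹ (no dispersion shape imposed; an independent value per field);
R1_ex fixed per field by **log-field linear interpolation** of the
Matrigel table (dispersion profiles live on log-frequency axes; exact at
nodes; no extrapolation). k_io is reported as the derived quantity
(1/τ_ex)·V_ex/(1 − V_ex) with a delta-method standard error.

* **Variable projection.** Per-curve amplitudes (M∞, M_start; M_start
  fixed at 0 for NP) enter the model linearly and are solved in closed
  form inside the objective, reducing the nonlinear search to
  2 + (number of fields) parameters. The reported optimum is identical
  to the full parameterization; the covariance is computed from the full
  (shared + amplitude) Jacobian so shared-parameter SEs account for the
  nuisance amplitudes.
* **Weighting.** Per-point weights 1/max(|s|, 10⁻³·max|s|). The
  relaxometer's stated uncertainty is relative (a percentage of 1/T1),
  so small-signal tail points are the best-measured ones; uniform
  weights discard them and degrade k_io recovery by an order of
  magnitude under the generator's multiplicative noise. The floor keeps
  near-zero points from dominating.
* **Multi-start.** Deterministic grid: V_ex at 20/50/80% of its allowed
  range × τ_ex ∈ {0.1, 0.5, 2.5} s; per-field R1_in initialized from a
  half-life estimate of each curve. Warm starts can be injected
  (`extra_starts`), which also makes bound-widening monotone in the
  objective by construction.
* **Uncertainties.** Linearized by default. A per-curve residual
  bootstrap (`n_boot > 0`, seed required) is available for
  near-bound situations where the linearized SE is unreliable; it is off
  by default because simulation studies with thousands of fits cannot
  afford it. `uncertainties=False` skips SE/CI computation entirely for
  point-estimate-only replicate studies.
* **Identifiability flagging.** Exchange is only visible where
  |R1_in − R1_ex| is comparable to or larger than k_io + k_oi. When the
  fitted solution violates this at most fields the τ_ex/k_io estimate
  sits on an almost-flat ridge whose linearized CI can be deceptively
  narrow, so the fit records an explicit identifiability warning in
  addition to active-bound flags.

## Synthetic data

The generator emulates the statistical structure of a two-arm
longitudinal relaxometry study; all noiseless signals come from the same
public forward model the fitters use (no private math), and every draw
flows from explicit seeds with ground truth embedded in metadata.

Defaults (the study conditions):

* **In vitro:** 64 delays log-spaced over 1 ms–5 s; truth k_io = 20 s⁻¹
  (≈ 25× the in-vivo default, the magnitude gap between pellet and
  tissue measurements), R1_in = 0.6 s⁻¹, V_ex = 0.2; 10 mM extracellular
  agent with relaxivity 3.5 s⁻¹mM⁻¹ over a 0.5 s⁻¹ baseline → R1_ex =
  35.5 s⁻¹; additive Gaussian noise, SD 1% of M∞ (Rician folding
  optional) — the paperless choice here is the noise model only; the
  level is the stated one.
* **In vivo:** seven relaxation fields 0.01, 0.02, 0.037, 0.07, 0.15,
  0.39, 1 MHz; 32 delays log-spaced from 5 ms to a per-field maximum
  drawn uniformly from 2.8–4 s; pre-polarized sequence with start
  magnetization normalized to 1 and equilibrium ∝ field/13 MHz
  (polarization-field ratio); multiplicative Gaussian noise, 2%;
  truth V_ex = 0.30, k_io = 0.8 s⁻¹.
* **Dispersion/Matrigel templates are synthetic stand-ins** with
  realistic shapes and magnitudes, not measured values: R1_in(ν) =
  8/(1 + (ν/0.1)²) + 1.5 s⁻¹ and R1_ex(ν) = 2.5/(1 + (ν/0.15)²) + 0.8
  s⁻¹ at the seven fields. They guarantee rate contrast at most fields;
  the truth manifest labels them synthetic, and real tables can be
  supplied as 2-column CSV.
* **Cohort:** arms of n = 7; timepoints 0 (baseline), 3, 6, 9 days
  relative to the first of three treatments given at 3-day intervals
  (profiles acquired 3 days after each). Treated-arm multipliers:
  k_io (1, 0.6, 1, 1) — a 40% drop after the first treatment, returning
  to baseline; V_ex (1, 0.85, 1.15, 1.30) — an initial dip followed by
  growth as membranes become freely permeable. Between-animal
  variability: mean-preserving lognormal with 25% CV on k_io, additive
  normal SD 0.04 on V_ex (clipped just inside the tumor fit bounds),
  redrawn per animal × timepoint. These variability levels produce group
  SDs of realistic magnitude without asserting unpublished numbers.

What the generator does **not** emulate: field-switching transients and
coil sensitivity, drift, motion, partial-volume mixtures of healthy and
tumor tissue, correlated (within-animal) trajectories over time, or
actual tumor-specific dispersion shapes. Passing tests therefore show
that the estimation machinery is correct and well-calibrated under the
stated noise structure — not that real tissue obeys the two-site model.

## Pipeline and I/O

Curve files are two-column CSV with a commented metadata header (lossless
to 17 significant digits); a reader for a stanza-per-field Stelar-like
text export is provided behind the same acquisition contract and
documented as a non-authoritative dialect. The JSON run config is
schema-checked (unknown keys rejected). The simulate → fit → summarize
pipeline is deterministic given the config seed (summaries byte-identical
across reruns), records a config hash and all optimizer starts in its
log, and isolates per-subject failures into a failure table instead of
aborting.

## Problem sizes used in validation

The acceptance experiments use: 1000 random parameter sets for the
oracle comparison; 100 replicates × 3 truths for in-vitro recovery
(64 delays); 50 replicates for in-vivo recovery (7 fields × 32 delays);
200 (power), 500 (null calibration) and 100 (trajectory recovery)
simulated cohorts at n = 7/arm with 16 delays per field and a single
deterministic optimizer start per fit — a reduced per-fit sampling that
leaves the per-animal estimator faithful (16 delays give the same group
power as 32 within Monte-Carlo error, whereas 8 measurably degrade it).
`scripts/acceptance.py` runs the same experiments at smaller replicate
counts, printed alongside each value.

## Known limitations

* Per-sample in-vitro k_io with V_ex free is a high-variance estimate by
  design (see above); treat single-curve values with their CIs, not as
  point facts.
* The in-vivo fit assumes the Matrigel table transfers to tissue
  extracellular space; any bias there propagates into R1_in and, near
  the shutter-speed limit, into k_io.
* Welch tests are per-timepoint and unadjusted for multiplicity across
  timepoints; longitudinal correlation within animals is neither
  simulated nor modeled.
* The linearized CIs undercover in the fast-exchange regime
  (k_io + k_oi ≫ ΔR1); the bootstrap option or informative V_ex bounds
  are the remedies.
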