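# Methods

## Forward model of the recording

The simulator represents a cultured neuron in whole-cell configuration as a
single compartment of capacitance `Cm` accessed through a series (access)
resistance `Rs`, carrying an ohmic leak `g_leak (Vm − E_leak)` and a
voltage-gated Na⁺ conductance `g_Na m³h (Vm − E_Na)`:

    Cm dVm/dt = (Vcmd − Vm)/Rs − g_Na m³h (Vm − E_Na) − g_leak (Vm − E_leak)
    dx/dt     = (x∞(Vm) − x)/τx(Vm),     x ∈ {m, h}

Gate steady states are Boltzmann functions of voltage — `m∞` rising with
midpoint `act_V_half` and slope 6 mV, `h∞` falling with midpoint
`inact_V_half = −62 mV` and slope 6 mV.  The recorded signal is the pipette
current `(Vcmd − Vm)/Rs`, which automatically contains the two artifacts the
analysis pipeline must remove: the capacitive charging transient (time
constant `Rs·Cm`) and the ohmic leak.  The Na⁺ reversal potential comes from
the Nernst equation for the experimental solutions (100 mM bath / 5 mM
pipette Na⁺ at 295 K → +76.2 mV).  K⁺ and Ca²⁺ currents are omitted; in the
emulated recording situation they are pharmacologically blocked (Cs⁺/TEA/4-AP
internal and external solutions, Cd²⁺).

Units package-wide: mV, ms, pA, pF, MΩ, nS (so nS × mV = pA); the single
conversion mV/MΩ → pA lives in one utility.  All stored command potentials
are liquid-junction corrected (−7 mV); the amplifier value is derivable and
never stored, so no double correction is possible.

### Gating kinetics

The source procedure specifies protocols and the −12 mV I–V maximum but no
kinetics, so the time-constant profiles are package choices: Gaussian bells
of voltage,

    τm(V) = 0.05 + 0.25·exp(−((V+40)/15)²) ms      (peak 0.3 ms near −40 mV)
    τh(V) = 1.0  + 1.5 ·exp(−((V+65)/20)²) ms      (peak 2.5 ms near −65 mV)

— room-temperature values in the range reported for neuronal Nav currents.
Two constraints anchor them: (i) 200 ms prepulses must reach steady-state
availability (τh ≪ 200 ms everywhere), and (ii) with the calibrated
activation midpoint the noise-free I–V maximum must fall exactly on the
−12 mV sweep of the 5 mV grid.  `calibrate_default_kinetics` enforces (ii)
by scanning activation midpoints (slope fixed) and simulating the full
P/4-corrected I–V; the scan is monotone and returns −41 mV at the default
integration step.  `default_cell_parameters()` caches this calibration.

### Numerics

Integration uses Strang splitting at a fixed 10 µs step: half-step
exponential update of the gates, full exponential (implicit-style) update of
`Vm` with frozen conductances, half-step of the gates again.  Each sub-flow
is exact for frozen coefficients, the scheme is second order, and it is
unconditionally stable for the stiff charging time constant `Rs·Cm`
(~0.25 ms).  Halving the step moves the peak current by ~0.02 %.  The
initial state is the self-consistent steady state at holding.  Degenerate
cells (`Cm ≤ 0`, `Rs ≤ 0`) are rejected; a non-finite state aborts with an
error rather than returning garbage.

Samples record the pipette current at the sample instant *before* the state
advances (synchronous DAC/ADC).  The acquisition chain then applies a
causal 4-pole Bessel low-pass at 10 kHz (magnitude-normalized: −3 dB at the
cutoff, DC gain 1, so charge is conserved), decimates from the 100 kHz
simulation rate to 20 kHz, adds white Gaussian recording noise (default SD
3 pA, commensurate with the 100 pA leak QC bound) and optionally quantizes.

### P/N subpulses

The P/4 convention is the classic one: each main sweep's command deviation
from holding is replayed scaled by −1/4 from a hyperpolarized subpulse
holding level (−97 mV) where the Na⁺ conductance stays shut.  The convention
is recorded in bundle metadata so the analysis never guesses polarity.

## Analysis pipeline

* **P/4 subtraction** — every trace is first aligned to its own pre-step
  baseline (removing holding-current offsets that scaling would multiply);
  the linear component is the mean subpulse response divided by the scale
  and is subtracted from the main sweep.  On noise-free linear cells the
  residual is < 1e−6 pA at any amplitude.
* **Capacitance** — `Cm = |∫(I − I_ss) dt| / |ΔV|` over the charging
  transient of a dedicated −10 mV test pulse, window = 8 fitted time
  constants.  Because a sharp exponential sampled at 20 kHz is integrated
  poorly by quadrature alone, the trapezoidal integral is corrected by the
  analytic-minus-sampled difference of the fitted mono-exponential; the
  estimator is then exact on ideal RC responses across Cm ∈ [5, 50] pF,
  Rs ∈ [5, 20] MΩ and within ~3 % on filtered, noisy simulated cells (the
  residual bias is the `Rm/(Rm+Rs)` divider plus filter-window effects).
  Transients faster than about two sample intervals (Rs·Cm ≲ 0.1 ms) are
  below the resolution of the 20 kHz record and outside the estimator's
  stated domain.
* **Series resistance** — `Rs = |ΔV| / I₀` with the instantaneous transient
  current inferred as `I₀ = Q/τ` (charge-equivalent exponential amplitude).
  Unlike the raw sampled maximum, both `Q` and `τ` survive the hardware
  filter; bias stays within ~4 % across the physiological grid, versus up to
  −45 % for naive peak-picking.
* **Peak I–V and density** — peak = most negative sample 0.2–10 ms after
  step onset (the first 0.2 ms are excluded so residual capacitive
  transients can never pose as Na⁺ peaks); density = |peak at −12 mV| / Cm,
  reported as a positive magnitude.
* **Inactivation** — peaks in the test-pulse window normalized to the
  most-negative-prepulse current I₀ (fixed, not a free amplitude, matching
  its operational definition), fitted by derivative-based least squares with
  the analytic logistic Jacobian; bounds V_half ∈ [−120, 0] mV,
  S ∈ (0.5, 30] mV, init at the interpolated 0.5 crossing with S = 7 mV,
  parameter tolerance 1e−8.  Non-convergence or a bound hit clears the
  `converged` flag, never silently.
* **QC** — leak ≤ 100 pA, Rs ≤ 20 MΩ, activation voltage range ≥ 20 mV, all
  boundaries inclusive.  The activation range is operationalized as the span
  from the most negative potential whose peak magnitude exceeds 10 % of the
  maximum to the potential of the maximum; the threshold fraction is
  configurable and recorded with the QC configuration.  The leak metric is
  the magnitude of the mean holding current, not a fitted conductance.

## Cohort generation and statistics

A `CohortFixture` holds one experimental condition's target mean density,
between-cell SD and n.  Fixtures derived from reported group statistics
invert the printed standard errors exactly (SD = SE·√n).  For the
microglia-coculture experiment no per-group n is printed; the package
default is 40 cells per condition (configurable).  Treated-group SEs in the
dose experiments are likewise not printed; fixtures preserve the control
group's coefficient of variation.  The IL-18 experiment pooled its control
cultures; the pooled bipolar control is anchored to the no-microglia-surplus
bipolar control group (43.6 ± 2.7 pA/pF).

Calibration maps target densities onto maximal conductances by inverting the
*measured* noise-free pipeline density (single test-potential sweep with its
P/4 family plus the capacitance pulse) with a few multiplicative secant
iterations, so whatever bias the measurement chain has is absorbed into the
calibration rather than propagated.  Passive parameters (Cm, Rs, g_leak) are
jittered ±20 % around the default cell.  Per-cell target densities are drawn
from a log-normal **truncated at a 150 pA/pF recordability ceiling**, with
the location parameter solved so the truncated mean equals the fixture
target: reported group statistics describe cells that passed inclusion QC,
and an untruncated tail generates cells with multi-nA peak currents whose
series-resistance voltage error collapses clamp control — the pipeline
correctly rejects them, which would otherwise bias every high-variance
cohort mean downward.  Sampling is stratified inverse-CDF (one draw per
probability stratum, shuffled): the cohort's sample mean then tracks the
fixture mean at any n while the spread stays log-normal, which is the point
of a generator calibrated to reproduce printed group statistics.  One master
seed per cohort; per-cell noise seeds derive from it by counter.

Group comparison: one-way fixed-effects ANOVA from explicit sums of squares,
then Tukey–Kramer HSD computed directly from the studentized-range
distribution with the harmonic pairwise standard error (valid for unequal
n); significance stars at p < 0.05 / 0.01 / 0.005.  No Welch correction is
applied (homoscedasticity is part of the emulated design).  Zero
within-group variance is reported as F = ∞ with p → 0.  The Tukey p-values
agree with a 10⁵-draw permutation reference within Monte-Carlo error and
with the `statsmodels` implementation to 1e−4.

## What the simulator does and does not emulate

Emulated: step-protocol structure and timing, junction-corrected potentials,
P/4 families, series-resistance voltage errors, capacitive transients, ohmic
leak, hardware filtering, sampling, recording noise, between-cell
variability of conductance density and passive properties calibrated per
experimental condition.  Not emulated: space-clamp (dendritic) artifacts,
Markov-state channel gating, K⁺/Ca²⁺ currents, seal drift over the
recording, culture-to-culture (preparation-level) variance components.
Passing recovery tests therefore shows the *analysis chain* is correct and
unbiased under the stated recording model — not that every biological source
of variance in real cultures is captured.

## Known limitations

* Uncompensated Rs shifts the measured inactivation midpoint depolarized
  (~1.3 mV at Rs = 10 MΩ, ≤ 0.5 mV in the well-clamped limit) and couples
  the leak conductance weakly to the measured density (~3 % per doubling of
  g_leak at Rs = 10 MΩ).  These are properties of the recording situation —
  precisely the errors the activation-range QC bounds — not of the
  estimators, which are verified unbiased in the well-clamped limit.
* The capacitance integral cannot resolve charging transients faster than
  about two sample intervals (see above).
* At the fixture-implied between-cell variances, n = 40 per group yields
  Tukey p-values around 0.01–0.05 for the control-vs-TGF-β contrast, i.e.
  below the power needed for p < 0.005; detecting that contrast at the
  strictest significance tier requires n ≳ 65 at these effect sizes.

## Problem sizes

Default acceptance-scale runs use the fixture ns (36–51 cells per cohort),
23 + 13 main sweeps plus 144 subpulse sweeps and one test pulse per cell at
a 10 µs integration step — a few minutes per full replication on one CPU.
Unit and property suites run on single sweeps, reduced grids (3–13 sweeps)
or closed-form fixtures.
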