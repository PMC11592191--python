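# Methods

`nmephys` re-creates, as tested code, the desk side of a developmental
ion-channel study in the avian cochlear nucleus (nucleus magnocellularis,
NM): whole-cell patch-clamp sweep analysis, Boltzmann modeling of
steady-state potassium conductances, and the group-statistics battery that
compares experimental conditions.  Because no raw recordings are released
for studies of this kind, the package ships a synthetic conductance-model
generator whose defaults emulate the study's experimental conditions; every
quantitative claim in the test suite is made against that generator's known
ground truth.

Units everywhere: mV, ms, pA, nS, pF, MΩ (so 1 nS·mV = 1 pA and
ms/MΩ = nF).

## The conductance model

A channel population's voltage dependence is the two-state Boltzmann sigmoid

    P_O(V) = B + (1 − B) / (1 + e^((V50 − V)/K)),

with `V50` the half-activation voltage (mV), `K > 0` the slope factor (mV)
and `B ∈ [0, 1)` a baseline open fraction.  Analysis proceeds along two
routes:

1. **Open-probability route.**  The steady-state I-V curve is differenced
   between consecutive 5-mV command levels (forward difference, reported at
   the midpoint — hence the read-out grid −42.5, −2.5, +17.5 mV), divided by
   its largest value within a voltage bin, and fitted with the sigmoid.
2. **Raw-I-V route.**  Treating dI/dV = G_max·P_O(V) as a separable ODE
   gives the closed form

       I(V) = B·G_max·V + G_max·(1 − B)·K·ln(e^{V/K} + e^{V50/K}) + C,

   fitted directly to the in-bin (V, I) points.  This yields `G_max` (nS),
   the maximal differential conductance, the proxy for channel number that
   the condition statistics compare.

Two voltage bins on the junction-corrected axis separate channel classes:
LVA (low-voltage-activated, Kv1-like) over [−60, −25] mV with `B` fixed at
0, and HVA (high-voltage-activated, Kv3-like) over [−20, +30] mV with `B`
free — residual saturated LVA current forms a genuine baseline slope under
the HVA bin, and the free `B` absorbs it (verified by a dedicated test).

Numerical choices:

- The sigmoid is evaluated through `scipy.special.expit` and the closed form
  through `log-sum-exp`, so no parameter combination overflows.
- Fits use `lmfit` (Levenberg–Marquardt) with bounds `K ∈ [0.3, 60]` mV,
  `V50 ∈ [−150, 80]` mV, `G_max > 0`, `B ∈ [0, 0.999]`; starting values come
  from the empirical slope curve (max slope → G_max, half-crossing → V50,
  bin width/6 → K).
- The integration constant `C` is an additive offset with no physical
  anchor inside the LVA bin (V = 0 lies outside it); it is initialized so
  the model passes through the lowest-voltage in-bin point and co-fitted.
- A fit whose covariance cannot be estimated is flagged unconverged rather
  than silently accepted; negative noisy slopes are clipped to zero for the
  open-probability curve only, never for the raw-I-V fit.
- The two routes agree on noiseless data to well under the between-neuron
  spread, but not exactly: the open-probability route normalizes by the
  largest *finite-difference* slope, which at 5-mV spacing sits below the
  true G_max, shifting its V50 by about a millivolt.  The raw-I-V route is
  the default source of reported parameters.

## Sweep analysis

**Voltage clamp.**  Commands run from a −70 mV holding potential for 150 ms
per level.  The steady-state current is the mean over the half-open window
`[duration − 3 ms, duration − 2 ms)` — 1 ms of samples beginning 3 ms before
command offset, away from the offset capacitive transient.  A liquid
junction potential of −10 mV is added to nominal commands exactly once
(guarded by a protocol flag); no leak subtraction is applied, so fitted LVA
G_max carries the leak slope (about +1 nS with the default generator, ~5–10%
of the control value — visible in the identity-condition recovery test's
tolerance).

**Current clamp.**  Active properties come from square injections 25% above
the current threshold I_T, defined as the lowest amplitude that evokes an
action potential on at least 5 of 10 repetitions (generalized to ≥50% when
fewer repetitions exist).  The spike detector — the recordings themselves
don't define one — takes local peaks above −20 mV preceded within 2 ms by an
upward dV/dt crossing of 10 mV/ms (both configurable); the AP window runs
from that crossing to 5 ms past the peak, clipped at the next event.
Latency is stimulus onset to AP peak; rise and repolarization rates are the
extreme central-difference dV/dt values in the window; features are averaged
over the repetitions that contain a spike, with the contributing count
reported.

Passive properties come from a −10 pA, 100 ms step: RMP is the 20 ms
pre-onset mean; R_in is the late voltage change (last 5 ms of the step)
divided by the injected current; τ is a single-exponential fit over the
first 10 ms after onset (5 ms for E20–21 cells) with a 0.1 ms post-onset
blank against the stimulus artifact.  The fit's asymptote is pinned to the
measured steady state: a free asymptote over a window of roughly one time
constant is badly conditioned (median τ error ~11% at 0.2 mV noise), while
the pinned fit reaches ~2%.  C = τ/R by construction, re-asserted on the
data container.

## QC and statistics

Neurons enter the dataset only with RMP strictly below −50 mV (E13) or
−55 mV (E20–21) and series resistance ≤ 10 MΩ.  Within each analysis group
and metric, points more than two sample SDs from the group mean are excluded
in a single pass (the rule is deliberately not iterated).

Two-condition contrasts use Welch's unpaired t-test; three or more use
one-way ANOVA with Bonferroni-adjusted all-pairs (or control-referenced)
comparisons, plus a heteroscedasticity-robust pair — Welch's ANOVA and the
Brown–Forsythe F\* for means — for the Boltzmann read-out comparisons.
Welch and Brown–Forsythe statistics are computed from group summary
statistics in vectorized form; this is what makes the 10,000-replicate null
calibration cheap, and the implementation is cross-checked in tests against
`pingouin.welch_anova` and against exact-rational hand computations of a
worked example.  Shapiro–Wilk is available and reported but does not gate
test selection.  Reports carry both SD and SEM per group, and the usual
star coding (0.05/0.01/0.001/0.0001).

## The synthetic generator

One compartment with capacitance C_m, a leak, two Boltzmann K⁺ conductances
and a minimal m³h Na mechanism.  Two conventions are available for the
steady-state K⁺ I-V (`iv_form`):

- `"ohmic"` — the chord form G_max·P_O(V)·(V − E_K);
- `"boltzmann_slope"` — the current whose *differential* conductance is
  exactly G_max·P_O(V), referenced to zero at E_K.

Condition presets default to `boltzmann_slope`: the study's reported G_max
is a differential-conductance maximum, so the generator's G_max must mean
the same thing for parameter recovery to be well-posed (under the chord
form, dI/dV = G[P + P′·(V − E_K)] is not even monotone over the LVA bin).
Current-clamp dynamics always use chord conductances with first-order
gates — dynamics need a conductance, not an I-V template — so `iv_form`
only selects the voltage-clamp steady state.

Voltage-clamp sweeps relax first-order to the steady state with activation
time constants of 3 ms (LVA) and 1.5 ms (HVA), ≤ 5 ms so the 147–148 ms
averaging window sits ≥ 28 time constants from onset; the membrane
experiences the junction-corrected voltage, nominal levels being what the
protocol reports.  Current clamp integrates C_m·dV/dt = −I_ion + I_inj by
forward Euler at a fixed 0.01 ms step (recording grids may subsample);
subthreshold responses match the analytic RC solution to well under 0.5%.

Default parameters for the early (E13) high-frequency preset: LVA G_max
20.19 nS, V50 −50 mV, K 5 mV (open probability ≈ 0.82 at −42.5 mV); HVA
G_max 72.76 nS, V50 −3 mV, K 7 mV (≈ 0.52 at −2.5 mV); E_K −90 mV; leak
1.2 nS; C_m 50 pF; resting potential pinned per neuron to N(−65, 1.2) mV by
solving for the leak reversal.  At these values the control cohort lands
near the study's operating point: steady-state current ≈ 3.1 nA at +20 mV,
R_in ≈ 175 MΩ, τ ≈ 8–9 ms, rheobase ≈ 120–160 pA.  The treated ("BDNF")
condition scales LVA G_max by 11.92/20.19 and HVA by 50.40/72.76 — the
ratios of the fitted group means under treatment to control — with group
sizes 16 (control) and 20 (treated); the antagonist-rescue preset
(BDNF_ANA12, n = 11) uses 18.39/20.19 and 80.16/72.76.  Commands extend to
+30 mV nominal so the corrected axis reaches +20 mV.

Per-neuron biological variability is log-normal on conductances (CV 0.18
LVA, 0.30 HVA — matching the reported group CVs — plus 0.20 on leak and
0.10 on C_m): conductances are positive and right-skewed, which a normal
jitter would violate.  Recording noise is additive and i.i.d. Gaussian —
10 pA on current, 0.3 mV on voltage.  One root seed; per-neuron child
streams derive from (seed, neuron index), so cohorts are pure functions of
(spec, base parameters, seed).  Neurons are grouped ≤ 6 per synthetic
embryo; embryo identity is recorded but not modeled as a random effect.

The Na mechanism (g_na 1000 nS, activation −45/4 mV, inactivation −52/5 mV,
τ_m 0.05 ms, τ_h 1 ms) is a fixture chosen once so the preset fires single
onset spikes with latency ≈ 5–9 ms, rise ≈ 500 mV/ms and repolarization
≈ −55 mV/ms near 1.25·I_T; it makes no biophysical claim about NM sodium
channels.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: space-clamp and dendritic filtering, series
resistance and capacitance-compensation artifacts (series resistance exists
only as QC metadata, log-normal around 6.5 MΩ), channel kinetics beyond
first-order activation (no inactivation of K⁺ currents), temperature
effects, drifting seals, and 1/f or line noise.  Parameter-recovery results
measure the estimator under the stated noise model, not robustness to
unmodeled physiology.

## Validation studies (`nmephys.validation`)

The quantitative claims asserted by the test suite and recomputed by
`scripts/acceptance.py`:

- **Closed form ≡ quadrature**: the closed-form I-V matches a 0.01 mV
  trapezoid integral of G_max·P_O to ≤ 1e−6 relative (observed ~2e−8) over
  V ∈ [−100, +30] for 20 randomized parameter sets; its central-difference
  derivative matches G_max·P_O at the read-out voltages to ≤ 1e−6 relative
  (the difference quotient is evaluated in 50-digit arithmetic so the check
  measures the formulas, not float cancellation).
- **Recovery**: exact-model fits recover parameters to ~1e−14; 100
  simulated 16-neuron cohorts with trace noise at 2% of the largest in-bin
  current give median cohort-mean errors ≈ 0.1 mV (V50), 1.6% (K), 0.7%
  (G_max).
- **Passive**: the τ = 8 ms / R = 200 MΩ / C = 40 pF cell with 0.2 mV noise
  is recovered with median errors under 3% over 100 seeds.
- **Calibration**: Welch t (n = 16 vs 20) and Welch ANOVA (16/20/11, SD
  ratio 3) hold their 5% size within [0.04, 0.06] over 10,000 null
  replicates, where the classic ANOVA under the same heteroscedastic null
  runs liberal (~0.07).
- **Condition effect**: one full cohort pair reproduces the treated
  signature — lower steady-state currents at −40/+20 mV, lower fitted G_max
  in both bins, higher τ and R_in, slower repolarization — and the LVA
  G_max Welch contrast at n = 16 vs 20 is significant at α = 0.05 in ≈ 100%
  of 200 replicate cohorts (the simulated effect, two-plus SDs, is far above
  the detection floor).

Problem sizes (200 replicates for power, 100 cohorts/seeds for recovery,
10,000 null replicates, one full current-clamp pair) were chosen so the
whole battery completes in a few minutes on one CPU while keeping
Monte-Carlo error well inside the asserted margins.

## Known limitations

- Fitted LVA G_max includes the leak slope because, like the method it
  implements, the pipeline performs no leak subtraction.
- The +17.5 mV HVA read-out extrapolates beyond the data when commands stop
  at +20 mV nominal (+10 corrected); presets therefore extend commands to
  +30 mV nominal.
- Open-probability normalization is per bin; whether normalizing across the
  full voltage range would be preferable is left open deliberately — per-bin
  matches treating the two channel classes as independent sigmoids.
- The ±2 SD outlier rule is single-pass by design; iterating it would
  change results for heavy-tailed metrics.
- Embryo nesting is recorded but not modeled (no mixed models), matching
  the statistical battery being reproduced.
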