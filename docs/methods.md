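# Methods

This note documents the models, parameter choices and numerical
conventions behind `trpgate`, in the order data flow through the package.

## 1. Tetrameric PIP2/DAG gating model (`trpgate.gating`)

**States.** C0…C4 index the number of PIP2-bound subunits of the
homotetramer; O is the single open state. Binding along the chain is
independent-subunit mass action: C_i → C_{i+1} at (4−i)·k_on·[PIP2],
C_{i+1} → C_i at (i+1)·k_off. The per-subunit dissociation constant is
Kd = k_off/k_on.

**Opening topology.** The experimental state diagram specifies four
closed states and one open state but not the connection point. We attach
O to the fully liganded C4 in the *supportive* mode. Rationale: it
produces the steep PIP2 dependence seen experimentally, and — when the
resting PIP2 level saturates the chain — a channel current that decays
*more slowly* than the lipid during depletion and recovers *faster* than
the lipid during replenishment, which is exactly the observed pattern
(current 243 ms / 2.7 s against lipid 135 ms / 5.66 s in the shipped
calibration). The *inhibitory* mode (polarity-switch mutants K771Q in
TRPC6, K716Q in TRPC7) attaches O to the empty C0 instead: the minimal
change that reverses the sign of the PIP2-depletion effect. Whether the
real mutant acts through effector coupling or phosphoinositide
selectivity is not modeled; only the phenomenological sign flip is.

**DAG dependence.** DAG (or its analog OAG) enters only through the
opening rate, β(d) = β_max·d^h/(EC50^h + d^h) with EC50 = 46 µM and
h = 0.8 (the wild-type OAG dose–response values). The closing rate α is
lipid-independent. This placement follows the observation that
binding-site mutants shift current amplitude but not the OAG EC50, i.e.
PIP2 acts allosterically downstream of DAG binding.

**Steady state.** The stationary distribution is the null space of the
generator; along the binding chain it obeys detailed balance, giving the
closed form Po = w_g·θ / (Σ_i C(4,i)x^i + w_g·θ) with x = [PIP2]/Kd,
θ = β/α, and w_g the weight of the gateway state (x⁴ supportive, 1
inhibitory). Unit tests hold the numerical null space to this closed form
at 1e−8 on a 5×5 (x, θ) grid. If the chain is disconnected (no ligand and
no opening/closing flux) the stationary distribution is not unique; the
result is flagged `degenerate` rather than raised.

**Current.** Gating carries no voltage dependence (none is observed for
these channels); voltage only scales the ohmic driving force, with
reversal at 0 mV. Current is
I(t) = [f + (1−f)·Po(t)/Po_ref]·g_total·(V−E_rev), with f an optional
PIP2-independent conductance fraction (default 0; exposed because up to
half of the OAG-evoked current may be PIP2-independent — the shipped
calibration instead reaches the ≈0.5 wild-type inhibition ratio through a
finite depletion floor, and f is the documented alternative). Po_ref is
the open probability at rest on the OAG plateau, and g_total = 20 nS
makes the resting inward current −1 nA at −50 mV.

**Integration.** The time-inhomogeneous master equation is integrated
with LSODA (rtol 1e−8, atol 1e−10), split at every protocol voltage edge,
with the exact Jacobian. Occupancies are projected back onto the
probability simplex after integration; drift beyond 1e−6 raises. A
continuous-time Markov (Gillespie) simulator of n independent channels,
with lipids piecewise-constant on their sampling grid, serves as a
stochastic oracle: the ODE solution must lie within 3 standard errors of
the 10⁴-channel mean at every checkpoint.

## 2. Lipid dynamics (`trpgate.signaling`)

**VSP episode.** While the command potential is at or above +50 mV the
phosphatase pulls PIP2 toward `depletion_floor`·PIP2_rest at rate k_vsp;
replenishment toward rest proceeds at k_rec throughout:
dP/dt = −k_vsp·a(V)·(P − floor·P_rest) + k_rec·(P_rest − P), a(V) ∈ {0,1}.
The equation is linear per segment, so the solution is assembled exactly
from piecewise exponentials (no solver error). Graded voltage dependence
of the enzyme is out of scope; the threshold step stands in for it. The
floor lumps PIP2 pools the enzyme cannot reach.

**Receptor cascade.** Agonist (applied 10–40 s) activates PLC
(k_plc_act/k_plc_deact); active PLC hydrolyzes PIP2 at k_hyd·plc·[PIP2],
producing one DAG and one IP3 per PIP2; DAG is degraded at k_dag_deg and
PIP2 resynthesized toward rest at k_pip2_synth. IP3 is tracked purely for
stoichiometric bookkeeping (cumulative hydrolysis flux must equal DAG
present + DAG degraded, verified to 1e−6 relative). The agonist washout
time is required to make the DAG surge transient: with sustained agonist
the hydrolysis flux — and hence DAG — plateaus instead of declining.
Exogenous OAG applications are modeled as an independent, additive DAG
input (a logistic bath wash-in), not as hydrolysis-derived DAG.

**Kd scan.** Peak receptor-evoked inward current at −50 mV as a function
of the channel's Kd, varied through k_on at fixed k_off so the
unbinding-limited decay kinetics stay comparable across the scan. Peaks
are strictly decreasing in Kd, and with the shipped calibration a
five-fold Kd increase (2 → 10 µM) halves the peak — the model behavior
reported for the low-affinity pre-S1 mutants. Construct presets instead
vary k_off at fixed k_on, because faster unbinding is the natural carrier
of the mutants' faster current decay.

## 3. Shipped calibration (`trpgate.defaults`)

The defaults are a packaged *calibration*, not measurements. Fixed by
literature: Kd(WT) = 2 µM; OAG EC50 46 µM, h 0.8. Fixed by construction:
k_rec = 1/5.66 s⁻¹ (the replenishment phase is exactly single-exponential,
so the fitted τ is exactly 5.66 s). Calibrated once, in this order:

1. k_vsp = 4.535911 s⁻¹ — root-found so the logistic fit of the simulated
   FRET depletion returns t½ = 135.000 ms (the fitted value is
   insensitive to the floor, so this decouples).
2. β_max = 40 s⁻¹, PIP2_rest = 18 µM, floor = 0.2006 — chosen on the
   (β_max, PIP2_rest) manifold with floor secant-adjusted so the
   wild-type last-plateau-pulse inhibition ratio is 0.500. Along this
   manifold decay and recovery trade off; the shipped point gives decay
   ≈ 243 ms and recovery ≈ 2.7 s (affinity index ≈ 11, close to the
   per-cell experimental value ≈ 10), and satisfies the qualitative
   pattern current-decay > lipid-depletion, current-recovery <
   lipid-replenishment. Remaining rates: k_on = 5 /µM/s, k_off = 10 /s,
   α = 20 /s — fast enough that gating tracks the lipid quasi-steadily.
3. K771Q preset: inhibitory polarity, Kd = 25 µM (k_off = 125 /s),
   β_max = 886.857 s⁻¹ — secant-calibrated so the same pipeline reports
   I_post/I_pre = 1.240.
4. Cascade pool 28.5414 µM (with k_hyd 0.5, k_dag_deg 0.12, k_pip2_synth
   2.0 /s) — secant-calibrated so the Kd-scan peak ratio at 10 vs 2 µM
   is 0.500.

## 4. Synthetic data (`trpgate.synthetic`)

Each simulated cell: OAG washes in as a logistic with per-cell half-time
drawn from U(30, 120) s (the observed range of times-to-peak; slope 6 s),
the VSP pulse train runs through the gating model, and the trace is
sampled at 1 ms inside pulse windows (±0.2/0.1 s padding) and 50 ms
elsewhere. Per-cell variability is lognormal (mean-1, CV default 0.15) on
k_off and α only. Noise is additive Gaussian (σ in trace units) plus
linear drift. Truth and noise use separate seed streams keyed by
(seed, cell index) and (noise seed, cell index): changing the noise seed
changes residuals, never the generating truth, and every artifact embeds
its truth block in the sidecar metadata. Dose–response replicates use
per-replicate σ = 0.03 (3 % of the maximal Δratio) as the realistic
precision of ROI-averaged ratiometric photometry.

What the generator does **not** emulate: capacitive transients, series
resistance, endogenous background currents, Ca²⁺-dependent inactivation,
Fura-2 photophysics, and rundown. Passing tests therefore demonstrate
correctness of the pipeline under the model's assumptions, not robustness
to every artifact of real recordings.

## 5. Fitting pipeline (`trpgate.fitting`)

Decay: logistic I_min + I_d/(1+exp[(t−t½)/f_s]), t from step onset,
fitted from 5 ms after onset (skipping the capacitive edge) to step end.
Recovery: I_0 + A·exp(−t/τ), t from repolarization, fitted from 20 ms
after repolarization to the next pulse. I_pre is the mean current over
the 100 ms before the step; I_post is the recovery fit extrapolated to
the repolarization instant (I_0 + A) — a window-free definition immune to
contamination by the recovery itself. Initial guesses: t½ from the 50 %
crossing of a smoothed segment, f_s = 10 % of the span, τ from log-linear
regression, all overridable. Optimizer: lmfit least squares, xtol 1e−8,
capped iterations; non-convergence (flat segment, non-saturating doses,
too few samples) is a reported state with a reason string, never an
exception and never fabricated parameters. Baselines below 0.01 nA are
flagged unreliable for the ratio.

FRET episodes keep 0.3 s of pre-step baseline in the depletion fit:
optical traces have no capacitive edge to skip, and the logistic needs
the flat shoulder to locate its corner — fitted to the bare falling
exponential alone the optimum degenerates to t½ → 0.

Cell summaries average the 2–4 analyzable pulses with the largest
baseline current (the plateau pulses). The affinity index is reported in
two forms: τ/t½ of the pulse means (default) and the mean of per-pulse
ratios; the experimental per-cell value lies between the two conventions
and the package asserts rankings, not absolute indices.

## 6. Screening statistics (`trpgate.screening`)

Per construct: n, mean, SD, SEM per metric (SEM undefined for single
cells). Comparisons to wild type: one-way ANOVA per metric, then a
Dunnett-type many-to-one test computed by parametric resampling of the
max-|t| statistic (pooled variance, 50 000 seeded draws; unbalanced
groups handled directly; identical groups give p = 1). The resampled
procedure matches a pooled t-test in the two-group limit and the
multivariate-t Dunnett implementation with three comparators (both
verified in tests), and its familywise type-I rate under a global null
calibrates to 0.036 at nominal 0.05 over 500 replicate screens. Kinetic
metrics (t½, τ, affinity index) are compared on the log scale — they are
strictly positive and lognormally generated; the inhibition ratio on the
natural scale. Flags (`faster_decay`, `slower_recovery`,
`reduced_inhibition`, `potentiated`, …) are a pure function of the means
and p-values at the 0.05 tier; `potentiated` additionally requires a mean
ratio above 1, and `no_current` is only ever set by an explicit marker,
mirroring constructs that produce no agonist-evoked current at all.

## 7. Problem sizes

Default test/acceptance workloads: 102-s three-pulse reference cells
(~5 000 samples), two-pulse 78-s panel cells, 10⁴-channel Gillespie runs
over 1 s, 100-seed Hill recovery, and 500-screen type-I calibration with
a cached 50 000-draw null. The full suite runs in about two minutes on
one CPU.

## 8. Known limitations

* The opening topology (C4-only / C0-only) is a modeling decision, not an
  experimental fact; intermediate-occupancy opening is not explored.
* Decay ≈ 229 ms and recovery ≈ 2.01 s cannot be hit simultaneously by
  this topology under the ratio and lipid-kinetics constraints; the
  calibration favors the constraint set and the observed orderings.
* The receptor cascade is a minimal reconstruction (no IP3 receptor,
  Ca²⁺ feedback, PIP ↔ PIP2 interconversion, or receptor desensitization
  kinetics beyond washout).
* Absolute affinity indices depend on gating rates, not only on Kd; they
  are meaningful as within-panel rankings only — the same caveat the
  experimental index carries.
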