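# trpgate

Quantitative analysis of PIP2-dependent TRPC6/TRPC7 channel gating:
a tetrameric PIP2/DAG gating model coupled to membrane-lipid dynamics,
a synthetic patch-clamp/FRET data generator, the kinetic trace-fitting
pipeline, and construct-screening statistics.

## The problem

TRPC6 is a diacylglycerol (DAG)-activated cation channel whose activity
also requires the membrane phosphoinositide PIP2. A voltage-sensitive
phosphatase (VSP) co-expressed with the channel converts a depolarizing
command step into a transient, controllable PIP2 depletion, so whole-cell
recordings under a pulse protocol (+100 mV / 700 ms from a −50 mV holding
potential) read out the channel's PIP2 binding and unbinding kinetics:

* the **decay** of the outward current during the step, fitted with
  *I* = *I*min + *I*d / (1 + exp[(*t* − *t*½)/*f*s]);
* the **recovery** of the inward current after repolarization, fitted with
  *I* = *I*0 + *A*·exp(−*t*/τ);
* the **inhibition ratio** *I*post/*I*pre of the currents just after vs.
  just before the step (< 1: inhibition by PIP2 depletion; > 1:
  potentiation, the signature of polarity-switch mutants);
* the **affinity index** τ/*t*½ (both in ms), a relative proxy for the
  channel–PIP2 dissociation constant used to rank mutant constructs;
* OAG (a DAG analog) dose–response curves fitted with the Hill equation
  *R* = *R*max·*C*ⁿ/(EC50ⁿ + *C*ⁿ).

`trpgate` implements this whole analysis chain as a tested library plus a
CLI. Because the underlying recordings are not publicly deposited, the
package ships a synthetic-data generator whose defaults are calibrated so
the simulated experiments reproduce the study-level observables (PIP2
depletion *t*½ = 135 ms and replenishment τ = 5.66 s; wild-type
*I*post/*I*pre ≈ 0.5; polarity-switched ratio ≈ 1.24; half current at
five-fold Kd). See `docs/methods.md` for the model and calibration.

## The model in brief

The channel is a homotetramer; each subunit binds PIP2 independently
(association k_on·[PIP2], dissociation k_off, Kd = k_off/k_on = 2 µM for
wild type), giving closed states C0…C4. A single open state O attaches to
C4 in the *supportive* (wild-type) mode or to C0 in the *inhibitory*
(polarity-switch) mode, with opening rate β(DAG) — a Hill function of DAG —
and closing rate α. The master equation is integrated over lipid time
courses produced either by the VSP episode (piecewise-exponential PIP2
depletion/replenishment) or by a receptor → PLC → PIP2/DAG/IP3 cascade,
and open probability is converted to ohmic whole-cell current.

## Worked example

```python
import trpgate as tg
from trpgate import defaults
from trpgate.synthetic import simulate_reference_cell

proto = defaults.standard_protocol()          # 3 pulses, +100 mV / 700 ms
trace = simulate_reference_cell("WT", proto)  # noiseless calibrated cell
s = tg.summarize_cell(trace, proto)
print(f"decay t_half = {s.t_half_ms:.1f} ms")
print(f"recovery tau = {s.tau_s:.2f} s")
print(f"I_post/I_pre = {s.inhibition_ratio:.3f}")
print(f"affinity index = {s.affinity_index:.2f}")
```

prints

```
decay t_half = 243.1 ms
recovery tau = 2.72 s
I_post/I_pre = 0.499
affinity index = 11.19
```

i.e. the simulated wild-type channel current decays more slowly than the
lipid itself depletes (243 ms vs. 135 ms — resting PIP2 saturates the
binding chain, delaying closure) and recovers faster than the lipid
replenishes (2.7 s vs. 5.66 s), losing about half its current per VSP
episode. Swapping `"WT"` for `"K771Q"` selects the inhibitory-polarity
preset and the same pipeline reports a ratio of ≈ 1.24 (potentiation).

The CLI chains the same stages:

```sh
trpgate simulate-panel --constructs WT,R437Q --n-cells 6 --seed 1 --out-dir run/
trpgate fit --in-dir run/
trpgate screen --cells run/cells.csv --wt-label WT --out-dir run/
trpgate kd-scan --kd 2,4,10,20 --out run/kd_scan.csv
```

`screen` compares each construct to the wild type (one-way ANOVA followed
by a resampling-based Dunnett-type many-to-one test) and emits phenotype
flags such as `faster_decay` / `slower_recovery` (low-affinity mutants) or
`potentiated` (polarity switch).

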