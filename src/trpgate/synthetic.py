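"""Synthetic data generator: study-shaped whole-cell current traces, FRET
PIP2 traces, mutant panels and dose-response tables.

Every artifact is deterministic given its seeds and embeds its generating
truth in ``meta`` so parameter-recovery tests need no external
bookkeeping.  Two independent seed streams are used: the panel seed fixes
the generating truth (per-cell rate draws, OAG onset), the noise seed only
the measurement residuals — changing the noise seed never changes truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import defaults
from .fitting import _expdecay, _hill, _logistic
from .gating import simulate_gating, steady_state
from .protocol import VoltageProtocol
from .signaling import VspParams, simulate_vsp_episode
from .traces import CurrentTrace, FretTrace

__all__ = [
    "ConstructSpec", "NoiseModel",
    "generate_cell_trace", "generate_panel", "generate_fret_trace",
    "generate_dose_response", "simulate_reference_cell", "draw_cell_truth",
    "make_logistic_decay", "make_exponential_recovery",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ConstructSpec:
    """One construct in a panel: label, gating overrides, cell count and
    per-cell lognormal variability (applied to k_off and alpha only, so the
    cell-to-cell spread does not silently redefine a construct's Kd
    *systematically* — the draws are mean-1)."""

    label: str
    overrides: dict = field(default_factory=dict)
    cell_variability_cv: float = 0.15
    n_cells: int = 6

    def __post_init__(self):
        if not self.label:
            raise ValueError("label must be nonempty")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_variability_cv < 0:
            raise ValueError("cell_variability_cv must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: Gaussian white noise (trace units — nA for
    current, ratio units for FRET) plus a linear baseline drift."""

    sigma: float = 0.0
    baseline_drift_per_s: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, time_s: np.ndarray, value: np.ndarray,
              stream: tuple = ()) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence(self.rng_seed, spawn_key=tuple(stream)))
        out = value + self.baseline_drift_per_s * time_s
        if self.sigma > 0:
            out = out + rng.normal(0.0, self.sigma, size=value.shape)
        return out


def _truth_rng(seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(cell_index,)))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    s2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2)))


def _oag_timecourse(t: np.ndarray, oag_uM: float, half_time_s: float,
                    slope_s: float) -> np.ndarray:
    """Bath OAG seen by the membrane: logistic wash-in to the plateau."""
    return oag_uM / (1.0 + np.exp(-(t - half_time_s) / slope_s))


def draw_cell_truth(spec: ConstructSpec, cell_index: int, seed: int = 0,
                    onset_half_time_s: float | None = None):
    """Per-cell generating truth: gating params with lognormal (mean-1,
    CV = spec.cell_variability_cv) factors on k_off and alpha, and the OAG
    wash-in half-time drawn from U(30, 120) s.  Deterministic in
    (seed, cell_index) and independent of the noise stream."""
    rng = _truth_rng(seed, cell_index)
    onset = (rng.uniform(30.0, 120.0) if onset_half_time_s is None
             else float(onset_half_time_s))
    params = defaults.construct_params(spec.label, spec.overrides)
    cv = spec.cell_variability_cv
    params = replace(params, k_off=params.k_off * _lognormal_factor(rng, cv),
                     alpha=params.alpha * _lognormal_factor(rng, cv))
    return params, onset


def generate_cell_trace(spec: ConstructSpec, cell_index: int,
                        protocol: VoltageProtocol, noise: NoiseModel,
                        *, seed: int = 0, vsp: VspParams | None = None,
                        oag_uM: float = defaults.OAG_UM,
                        onset_half_time_s: float | None = None,
                        onset_slope_s: float = 6.0,
                        dt_pulse_s: float = 1e-3,
                        dt_base_s: float = 0.05) -> CurrentTrace:
    """Simulate one cell: OAG wash-in to a plateau, VSP pulse train, gating
    model, two-rate sampling, then noise.

    Deterministic given (seed, cell_index) for the truth and
    ``noise.rng_seed`` for the residuals.  The OAG wash-in half-time is
    drawn per cell from U(30, 120) s unless given explicitly.
    """
    vsp = defaults.WT_VSP if vsp is None else vsp
    params, onset = draw_cell_truth(spec, cell_index, seed,
                                    onset_half_time_s=onset_half_time_s)

    t = protocol.sample_times(dt_pulse_s=dt_pulse_s, dt_base_s=dt_base_s)
    lipids = simulate_vsp_episode(vsp, protocol, sample_times=t)
    lipids = lipids.with_dag(_oag_timecourse(t, oag_uM, onset, onset_slope_s))

    po_ref = steady_state(params, vsp.pip2_rest_uM, oag_uM).po
    res = simulate_gating(params, lipids, protocol, po_ref=po_ref)
    trace = res.trace
    trace.value = noise.apply(trace.time_s, trace.value, stream=(cell_index, 0))
    trace.meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "current",
        "construct": spec.label,
        "seed": int(seed),
        "cell_index": int(cell_index),
        "truth": {
            "k_on": params.k_on, "k_off": params.k_off,
            "kd_pip2_uM": params.kd_pip2,
            "beta_max": params.beta_max, "alpha": params.alpha,
            "polarity": params.polarity,
            "po_ref": float(po_ref),
            "oag_uM": oag_uM, "onset_half_time_s": onset,
            "onset_slope_s": onset_slope_s,
            "k_vsp": vsp.k_vsp, "k_rec": vsp.k_rec,
            "pip2_rest_uM": vsp.pip2_rest_uM,
            "depletion_floor": vsp.depletion_floor,
        },
        "noise": {"sigma": noise.sigma,
                  "baseline_drift_per_s": noise.baseline_drift_per_s,
                  "rng_seed": noise.rng_seed},
        "sampling": {"dt_pulse_s": dt_pulse_s, "dt_base_s": dt_base_s},
        "protocol": {
            "holding_mV": protocol.holding_mV, "step_mV": protocol.step_mV,
            "step_duration_s": protocol.step_duration_s,
            "pulse_onsets_s": list(protocol.pulse_onsets_s),
            "total_duration_s": protocol.total_duration_s,
        },
    }
    return trace


def generate_panel(specs, protocol: VoltageProtocol, noise: NoiseModel,
                   *, seed: int = 0, **kw):
    """One trace per cell per construct plus a truth table.

    Returns (traces, truth) where truth is a DataFrame with one row per
    cell listing the generating parameters.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one ConstructSpec")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate construct labels in panel")
    traces, rows = [], []
    cell_counter = 0
    for spec in specs:
        for j in range(spec.n_cells):
            tr = generate_cell_trace(spec, cell_counter, protocol, noise,
                                     seed=seed, **kw)
            traces.append(tr)
            row = {"construct": spec.label, "cell_index": cell_counter}
            row.update(tr.meta["truth"])
            rows.append(row)
            cell_counter += 1
    return traces, pd.DataFrame(rows)


def generate_fret_trace(vsp: VspParams, protocol: VoltageProtocol,
                        noise: NoiseModel, *, scale: float = 1.0,
                        dt_pulse_s: float = 1e-3,
                        dt_base_s: float = 0.05) -> FretTrace:
    """FRET-reported PIP2: the ratio is a linear rescaling of pip2(t), so
    fitted kinetics are invariant to ``scale``."""
    t = protocol.sample_times(dt_pulse_s=dt_pulse_s, dt_base_s=dt_base_s)
    lipids = simulate_vsp_episode(vsp, protocol, sample_times=t)
    ratio = scale * lipids.pip2_uM / vsp.pip2_rest_uM
    ratio = noise.apply(t, ratio, stream=(0, 1))
    return FretTrace(t, ratio, voltage_mV=np.asarray(protocol.voltage(t)), meta={
        "schema_version": SCHEMA_VERSION, "kind": "fret", "construct": "PIP2-FRET",
        "truth": {"k_vsp": vsp.k_vsp, "k_rec": vsp.k_rec,
                  "pip2_rest_uM": vsp.pip2_rest_uM,
                  "depletion_floor": vsp.depletion_floor, "scale": scale},
        "noise": {"sigma": noise.sigma,
                  "baseline_drift_per_s": noise.baseline_drift_per_s,
                  "rng_seed": noise.rng_seed},
        "protocol": {
            "holding_mV": protocol.holding_mV, "step_mV": protocol.step_mV,
            "step_duration_s": protocol.step_duration_s,
            "pulse_onsets_s": list(protocol.pulse_onsets_s),
            "total_duration_s": protocol.total_duration_s,
        },
    })


def generate_dose_response(ec50_uM: float, hill_n: float, r_max: float,
                           concentrations_uM, *, sd: float = 0.0,
                           n_per_point=1, seed: int = 0) -> pd.DataFrame:
    """Hill-equation dose-response table with per-dose replicates.

    Returns a long-form DataFrame (conc_uM, replicate, response) whose
    ``attrs['truth']`` records the generating parameters.
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    n_rep = (np.full(conc.size, int(n_per_point)) if np.isscalar(n_per_point)
             else np.asarray(n_per_point, dtype=int))
    if n_rep.size != conc.size:
        raise ValueError("n_per_point length mismatch")
    rng = np.random.default_rng(seed)
    rows = []
    for c, n in zip(conc, n_rep):
        mu = _hill(c, r_max, ec50_uM, hill_n)
        vals = mu + (rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n))
        rows += [{"conc_uM": c, "replicate": i, "response": v}
                 for i, v in enumerate(vals)]
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {"ec50_uM": ec50_uM, "hill_n": hill_n, "r_max": r_max,
                         "sd": sd, "seed": seed}
    return df


def simulate_reference_cell(construct: str = "WT",
                            protocol: VoltageProtocol | None = None,
                            *, vsp_active: bool = True,
                            seed: int = 0) -> CurrentTrace:
    """Noiseless single-cell simulation with the shipped calibration: no
    cell-to-cell variability, OAG wash-in half-time fixed at 45 s.  This is
    the deterministic reference condition used for the calibrated-target
    checks (wild-type ratio ~0.5, polarity-switch ratio ~1.24, enzyme-dead
    VSP control ~1)."""
    protocol = defaults.standard_protocol() if protocol is None else protocol
    spec = ConstructSpec(label=construct, cell_variability_cv=0.0, n_cells=1)
    vsp = defaults.WT_VSP if vsp_active else defaults.INACTIVE_VSP
    return generate_cell_trace(spec, 0, protocol, NoiseModel(), seed=seed,
                               vsp=vsp, onset_half_time_s=45.0)


# ----------------------------------------------------------------------
# closed-form synthetic segments for fitter validation

def make_logistic_decay(t_half_ms: float, f_s_ms: float, *, i_min: float = 0.0,
                        i_d: float = 1.0, duration_ms: float = 700.0,
                        dt_ms: float = 1.0):
    """Noiseless logistic decay segment (times in seconds from onset)."""
    t = np.arange(0.0, duration_ms + 0.5 * dt_ms, dt_ms) * 1e-3
    return t, _logistic(t, i_min, i_d, t_half_ms * 1e-3, f_s_ms * 1e-3)


def make_exponential_recovery(tau_s: float, *, i_0: float = -1.0, a: float = 0.5,
                              duration_s: float = 10.0, dt_s: float = 0.01):
    """Noiseless exponential recovery segment (times from repolarization)."""
    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    return t, _expdecay(t, i_0, a, tau_s)
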