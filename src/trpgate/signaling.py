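"""Membrane lipid dynamics driving the gating model.

Two lipid sources are modeled:

* the voltage-sensitive phosphatase (VSP) episode — a depolarizing command
  step switches on 5-phosphatase activity, PIP2 relaxes exponentially
  toward a depletion floor, and recovers toward its resting level after
  repolarization; and
* a receptor -> PLC cascade in which active PLC hydrolyzes PIP2 into DAG
  (and IP3) while PIP2 is resynthesized toward rest, producing the
  transient PIP2 dip / DAG surge of agonist stimulation.

Both emit :class:`LipidTimecourse` objects consumed by
:func:`trpgate.gating.simulate_gating`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .gating import GatingParams, simulate_gating
from .protocol import VoltageProtocol

__all__ = [
    "LipidTimecourse",
    "VspParams",
    "ReceptorCascadeParams",
    "simulate_vsp_episode",
    "simulate_receptor_activation",
    "kd_scan",
]


@dataclass
class LipidTimecourse:
    """Sampled pip2(t) and dag(t) in uM on a strictly increasing grid."""

    time_s: np.ndarray
    pip2_uM: np.ndarray
    dag_uM: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pip2_uM = np.asarray(self.pip2_uM, dtype=float)
        self.dag_uM = np.asarray(self.dag_uM, dtype=float)
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.pip2_uM.shape != self.time_s.shape or self.dag_uM.shape != self.time_s.shape:
            raise ValueError("pip2/dag arrays must match the time grid")
        if np.any(self.pip2_uM < 0) or np.any(self.dag_uM < 0):
            raise ValueError("lipid concentrations must be >= 0")

    @classmethod
    def constant(cls, pip2_uM: float, dag_uM: float, t_end_s: float,
                 n: int = 2) -> "LipidTimecourse":
        t = np.linspace(0.0, t_end_s, max(n, 2))
        return cls(t, np.full_like(t, pip2_uM), np.full_like(t, dag_uM))

    def pip2_at(self, t):
        return np.interp(t, self.time_s, self.pip2_uM)

    def dag_at(self, t):
        return np.interp(t, self.time_s, self.dag_uM)

    def with_dag(self, dag_uM: np.ndarray) -> "LipidTimecourse":
        return LipidTimecourse(self.time_s, self.pip2_uM, np.asarray(dag_uM, float))


@dataclass(frozen=True)
class VspParams:
    """VSP-driven PIP2 depletion/replenishment kinetics.

    While the command potential is at or above ``activation_threshold_mV``
    the phosphatase pulls PIP2 toward ``depletion_floor * pip2_rest_uM`` at
    rate ``k_vsp``; replenishment toward rest proceeds at ``k_rec`` at all
    times.  The floor is a lump for the PIP2 the enzyme cannot reach
    (compartmentalized pools, fast local resynthesis).
    """

    k_vsp: float = 5.0
    k_rec: float = 1.0 / 5.66
    pip2_rest_uM: float = 25.0
    activation_threshold_mV: float = 50.0
    depletion_floor: float = 0.15

    def __post_init__(self):
        if self.k_vsp < 0 or self.k_rec < 0:
            raise ValueError("k_vsp and k_rec must be >= 0")
        if not 0.0 <= self.depletion_floor < 1.0:
            raise ValueError("depletion_floor must lie in [0, 1)")
        if self.pip2_rest_uM <= 0:
            raise ValueError("pip2_rest_uM must be > 0")


def simulate_vsp_episode(vsp: VspParams, protocol: VoltageProtocol,
                         sample_times: np.ndarray | None = None) -> LipidTimecourse:
    """PIP2 time course under the pulse protocol (dag is left at zero).

    The governing ODE is linear within each constant-voltage segment, so
    the solution is assembled exactly from piecewise exponentials:
    dP/dt = -k_vsp*a(V)*(P - floor*P_rest) + k_rec*(P_rest - P), with
    a(V) a 0/1 step at the activation threshold.
    """
    if sample_times is None:
        sample_times = protocol.sample_times()
    sample_times = np.asarray(sample_times, dtype=float)
    segs = list(protocol.segments())
    for a, b, _ in segs:
        if b - a <= 0:
            raise ValueError("protocol contains an empty segment")
    if min(b - a for a, b, _ in segs) < np.min(np.diff(sample_times)):
        raise ValueError("protocol step shorter than one sampling interval")

    pr, fl = vsp.pip2_rest_uM, vsp.depletion_floor
    pip2 = np.empty_like(sample_times)
    p = pr  # start at rest
    for a, b, v in segs:
        act = 1.0 if v >= vsp.activation_threshold_mV else 0.0
        k = vsp.k_vsp * act + vsp.k_rec
        p_ss = p if k == 0 else (vsp.k_vsp * act * fl + vsp.k_rec) * pr / k
        m = (sample_times >= a) & (sample_times < b)
        if b == segs[-1][1]:
            m |= sample_times == b
        dt = sample_times[m] - a
        pip2[m] = p_ss + (p - p_ss) * np.exp(-k * dt)
        p = p_ss + (p - p_ss) * np.exp(-k * (b - a))
    return LipidTimecourse(sample_times, pip2, np.zeros_like(sample_times))


@dataclass(frozen=True)
class ReceptorCascadeParams:
    """Receptor -> PLC -> PIP2 hydrolysis cascade (mass action).

    Agonist is applied from ``agonist_on_time_s`` to ``agonist_off_time_s``
    (washout makes the DAG surge transient); the active-PLC fraction
    relaxes with k_plc_act / k_plc_deact; PIP2 is hydrolyzed at
    k_hyd * plc * pip2 producing one DAG and one IP3 per PIP2, degraded /
    resynthesized with k_dag_deg and k_pip2_synth.  IP3 is tracked only
    for mass-balance bookkeeping (no IP3 receptor downstream).
    """

    agonist_on_time_s: float = 10.0
    agonist_off_time_s: float = 40.0
    k_plc_act: float = 0.5
    k_plc_deact: float = 0.05
    k_hyd: float = 0.5
    k_dag_deg: float = 0.15
    k_pip2_synth: float = 1.0
    pip2_rest_uM: float = 25.0

    def __post_init__(self):
        for name in ("k_plc_act", "k_plc_deact", "k_hyd", "k_dag_deg", "k_pip2_synth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pip2_rest_uM <= 0:
            raise ValueError("pip2_rest_uM must be > 0")
        if self.agonist_off_time_s <= self.agonist_on_time_s:
            raise ValueError("agonist_off_time_s must exceed agonist_on_time_s")


def simulate_receptor_activation(cascade: ReceptorCascadeParams, duration_s: float,
                                 dt_s: float = 0.05, rtol: float = 1e-8,
                                 atol: float = 1e-10) -> pd.DataFrame:
    """Integrate the cascade; returns a DataFrame with columns
    time_s, pip2_uM, dag_uM, ip3_uM, plc, hyd_flux_cum_uM, dag_deg_cum_uM.

    ``hyd_flux_cum_uM`` accumulates the hydrolysis flux so tests can verify
    the stoichiometric balance  hyd_cum == dag + dag_deg_cum  exactly.
    """
    if duration_s <= cascade.agonist_on_time_s:
        raise ValueError("duration must exceed agonist_on_time_s")

    c = cascade

    def rhs(t, y, agonist):
        plc, pip2, dag, ip3, hyd_cum, deg_cum = y
        flux = c.k_hyd * plc * pip2
        return [
            c.k_plc_act * agonist * (1.0 - plc) - c.k_plc_deact * plc,
            -flux + c.k_pip2_synth * (c.pip2_rest_uM - pip2),
            flux - c.k_dag_deg * dag,
            flux,
            flux,
            c.k_dag_deg * dag,
        ]

    t_grid = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    y0 = np.array([0.0, c.pip2_rest_uM, 0.0, 0.0, 0.0, 0.0])
    pre = t_grid[t_grid <= c.agonist_on_time_s]
    rows = []
    if pre.size:
        rows.append(np.tile(y0, (pre.size, 1)))  # rest is a fixed point pre-agonist
    edges = [(c.agonist_on_time_s, min(c.agonist_off_time_s, duration_s), 1.0)]
    if duration_s > c.agonist_off_time_s:
        edges.append((c.agonist_off_time_s, duration_s, 0.0))
    y = y0
    for a, b, drive in edges:
        m = (t_grid > a) & (t_grid <= b)
        t_eval = np.unique(np.append(t_grid[m], b))
        sol = solve_ivp(rhs, (a, b), y, args=(drive,), method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            last = sol.t[-1] if sol.t.size else a
            raise RuntimeError(f"cascade integration failed at t={last:.3f}s: "
                               f"{sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise RuntimeError("cascade produced non-finite state")
        if m.any():
            rows.append(sol.y.T[: m.sum()] if t_eval.size > m.sum() else sol.y.T)
        y = sol.y[:, -1]
    y = np.vstack(rows)
    return pd.DataFrame({
        "time_s": t_grid, "plc": y[:, 0], "pip2_uM": y[:, 1], "dag_uM": y[:, 2],
        "ip3_uM": y[:, 3], "hyd_flux_cum_uM": y[:, 4], "dag_deg_cum_uM": y[:, 5],
    })


def kd_scan(cascade: ReceptorCascadeParams, gating: GatingParams,
            kd_values_uM, duration_s: float = 60.0,
            holding_mV: float = -50.0) -> pd.DataFrame:
    """Peak receptor-evoked inward current as a function of the channel's
    PIP2 dissociation constant.

    Kd is varied through k_on at fixed k_off so the unbinding-limited decay
    kinetics stay comparable across the scan.  Current uses absolute-Po
    scaling (po_ref = 1); ``peak_inward_nA`` is reported as a magnitude.
    """
    kd_values = [float(k) for k in np.atleast_1d(np.asarray(kd_values_uM, dtype=float))]
    if len(kd_values) == 0:
        raise ValueError("kd_values_uM must be non-empty")
    if any(k <= 0 for k in kd_values):
        raise ValueError("kd values must be > 0")
    if gating.polarity != "supportive":
        raise ValueError("kd_scan requires supportive polarity")

    df = simulate_receptor_activation(cascade, duration_s)
    lipids = LipidTimecourse(df["time_s"].to_numpy(), df["pip2_uM"].to_numpy(),
                             df["dag_uM"].to_numpy())
    protocol = VoltageProtocol(holding_mV=holding_mV, pulse_onsets_s=(),
                               total_duration_s=duration_s)
    base = replace(gating, pip2_independent_fraction=0.0)
    rows = []
    for kd in kd_values:
        params = base.with_kd_via_kon(kd)
        res = simulate_gating(params, lipids, protocol, po_ref=1.0)
        peak = -np.min(res.trace.current_nA)
        rows.append({"kd_uM": kd, "peak_inward_nA": float(peak)})
    return pd.DataFrame(rows)
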