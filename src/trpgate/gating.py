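"""Tetrameric PIP2/DAG gating model of TRPC channels.

The channel is a homotetramer whose four subunits bind PIP2 independently,
giving a linear chain of closed states C0..C4 indexed by the number of
PIP2-bound subunits.  A single open state O connects to one end of the
chain:

* ``supportive`` polarity (wild-type-like): opening proceeds from the fully
  liganded C4, so losing PIP2 pulls occupancy away from the open-connected
  state and the current falls when PIP2 is depleted.
* ``inhibitory`` polarity (polarity-switch mutants such as K771Q): opening
  proceeds from the empty C0, so PIP2 depletion *increases* open
  probability and the current is potentiated.

DAG (or its analog OAG) enters only through the opening rate, as a Hill
factor beta(dag) = beta_max * dag^h / (ec50^h + dag^h); the closing rate
alpha is lipid-independent.  Gating rates carry no voltage dependence:
voltage only scales the ohmic current.

State order everywhere: [C0, C1, C2, C3, C4, O].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .protocol import VoltageProtocol
from .traces import CurrentTrace

__all__ = [
    "GatingParams",
    "ChannelStateVector",
    "GatingSimResult",
    "beta_of_dag",
    "build_rate_matrix",
    "steady_state",
    "simulate_gating",
    "gillespie_oracle",
]

N_STATES = 6
OPEN = 5
POLARITIES = ("supportive", "inhibitory")


@dataclass(frozen=True)
class GatingParams:
    """Rate constants and mode of the tetrameric gating scheme.

    Units: k_on in /uM/s, k_off, beta_max and alpha in /s, dag_ec50 in uM,
    g_total_nS in nS, e_rev_mV in mV.  kd_pip2 = k_off/k_on (uM).
    """

    k_on: float = 5.0
    k_off: float = 10.0
    beta_max: float = 75.0
    alpha: float = 20.0
    dag_ec50: float = 46.0
    dag_hill: float = 0.8
    polarity: str = "supportive"
    pip2_independent_fraction: float = 0.0
    g_total_nS: float = 20.0
    e_rev_mV: float = 0.0
    n_subunits: int = 4

    def __post_init__(self):
        for name in ("k_on", "k_off", "beta_max", "alpha", "dag_ec50"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_on == 0:
            raise ValueError("k_on must be positive (kd_pip2 undefined otherwise)")
        if self.dag_hill <= 0:
            raise ValueError("dag_hill must be > 0")
        if not 0.0 <= self.pip2_independent_fraction <= 1.0:
            raise ValueError("pip2_independent_fraction must lie in [0, 1]")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if self.n_subunits != 4:
            raise ValueError("the model is tetrameric: n_subunits is fixed at 4")

    @property
    def kd_pip2(self) -> float:
        """Per-subunit PIP2 dissociation constant, uM."""
        return self.k_off / self.k_on

    def with_kd_via_kon(self, kd_uM: float) -> "GatingParams":
        """Set kd_pip2 by rescaling k_on at fixed k_off (used in Kd scans so
        the unbinding-limited kinetics stay comparable)."""
        if kd_uM <= 0:
            raise ValueError("kd_uM must be > 0")
        return replace(self, k_on=self.k_off / kd_uM)

    def with_kd_via_koff(self, kd_uM: float) -> "GatingParams":
        """Set kd_pip2 by rescaling k_off at fixed k_on (used for mutant
        constructs, whose faster current decay reflects faster unbinding)."""
        if kd_uM <= 0:
            raise ValueError("kd_uM must be > 0")
        return replace(self, k_off=self.k_on * kd_uM)


@dataclass
class ChannelStateVector:
    """Occupancy of [C0..C4, O] at one instant; probabilities sum to 1."""

    occupancy: np.ndarray
    time_s: float = 0.0
    degenerate: bool = False

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (N_STATES,):
            raise ValueError(f"occupancy must have shape ({N_STATES},)")
        if np.any(self.occupancy < -1e-9) or np.any(self.occupancy > 1 + 1e-9):
            raise ValueError("occupancy entries must lie in [0, 1]")
        if abs(self.occupancy.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy must sum to 1")

    @property
    def po(self) -> float:
        """Open probability."""
        return float(self.occupancy[OPEN])


def beta_of_dag(params: GatingParams, dag_uM: float):
    """Opening rate as a Hill function of the DAG/OAG concentration."""
    d = np.asarray(dag_uM, dtype=float)
    if np.any(d < 0):
        raise ValueError("dag_uM must be >= 0")
    h = params.dag_hill
    with np.errstate(divide="ignore"):
        num = np.where(d > 0, d ** h, 0.0)
    out = params.beta_max * num / (params.dag_ec50 ** h + num)
    return out if out.shape else float(out)


def build_rate_matrix(params: GatingParams, pip2_uM: float, dag_uM: float) -> np.ndarray:
    """Generator matrix Q (6x6) with Q[i, j] the i->j rate; rows sum to zero.

    Binding chain: C_i -> C_{i+1} at (4-i)*k_on*pip2, C_{i+1} -> C_i at
    (i+1)*k_off.  The open state connects to C4 (supportive) or C0
    (inhibitory) with rates beta(dag) / alpha.
    """
    if pip2_uM < 0:
        raise ValueError("pip2_uM must be >= 0")
    if dag_uM < 0:
        raise ValueError("dag_uM must be >= 0")
    Q = np.zeros((N_STATES, N_STATES))
    for i in range(4):
        Q[i, i + 1] = (4 - i) * params.k_on * pip2_uM
        Q[i + 1, i] = (i + 1) * params.k_off
    beta = beta_of_dag(params, dag_uM)
    gate = 4 if params.polarity == "supportive" else 0
    Q[gate, OPEN] = beta
    Q[OPEN, gate] = params.alpha
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def steady_state(params: GatingParams, pip2_uM: float, dag_uM: float) -> ChannelStateVector:
    """Stationary distribution of the gating scheme at fixed lipid levels.

    Computed as the normalized null space of the generator.  If the chain is
    disconnected (e.g. pip2 = 0 with beta = alpha = 0) the stationary
    distribution is not unique; the result is then flagged ``degenerate``
    and the returned vector is the null-space member with the largest C0
    weight, not an error.
    """
    Q = build_rate_matrix(params, pip2_uM, dag_uM)
    ns = null_space(Q.T, rcond=1e-12)
    degenerate = ns.shape[1] != 1
    if ns.shape[1] == 0:  # numerical fallback, should not happen
        w, v = np.linalg.eig(Q.T)
        ns = np.real(v[:, [np.argmin(np.abs(w))]])
    if degenerate and ns.shape[1] > 1:
        vec = ns[:, np.argmax(np.abs(ns[0, :]))]
    else:
        vec = ns[:, 0]
    vec = np.abs(vec)
    vec = vec / vec.sum()
    return ChannelStateVector(vec, degenerate=degenerate)


@dataclass
class GatingSimResult:
    """Time-resolved occupancy plus the derived current trace."""

    time_s: np.ndarray
    occupancy: np.ndarray  # (n_samples, 6)
    po_ref: float
    trace: CurrentTrace | None = None

    @property
    def po(self) -> np.ndarray:
        return self.occupancy[:, OPEN]

    def state_at(self, i: int) -> ChannelStateVector:
        return ChannelStateVector(self.occupancy[i], time_s=float(self.time_s[i]))


def _occupancy_current(params: GatingParams, po: np.ndarray, po_ref: float,
                       voltage_mV: np.ndarray) -> np.ndarray:
    """Ohmic current in nA given open probability and command voltage.

    The conductance is scaled so that a cell sitting at the reference open
    probability ``po_ref`` (rest, OAG plateau) passes g_total*(V - e_rev);
    an optional PIP2-independent fraction bypasses the gating model.
    """
    f = params.pip2_independent_fraction
    scale = f + (1.0 - f) * po / po_ref
    return scale * params.g_total_nS * (voltage_mV - params.e_rev_mV) * 1e-3


def simulate_gating(params: GatingParams, lipids, protocol: VoltageProtocol | None = None,
                    *, p0: np.ndarray | None = None, po_ref: float | None = None,
                    sample_times: np.ndarray | None = None,
                    rtol: float = 1e-8, atol: float = 1e-10) -> GatingSimResult:
    """Integrate the time-inhomogeneous master equation over a lipid time
    course and convert open probability to whole-cell current.

    Parameters
    ----------
    lipids : LipidTimecourse
        Sampled pip2(t)/dag(t); its grid is the default sampling grid.
    protocol : VoltageProtocol, optional
        Needed to emit a current trace; integration is split at every
        voltage edge.  Without a protocol only occupancies are returned.
    p0 : array, optional
        Initial occupancy (default: steady state at the initial lipids;
        if that is degenerate, all probability starts in C0).
    po_ref : float, optional
        Reference open probability for the current calibration (default 1,
        i.e. absolute Po scaling).
    """
    t_grid = np.asarray(lipids.time_s, dtype=float)
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("lipid time grid must be strictly increasing with >= 2 points")
    if sample_times is None:
        sample_times = t_grid
    else:
        sample_times = np.asarray(sample_times, dtype=float)
        if np.any(np.diff(sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")

    if p0 is None:
        ss = steady_state(params, float(lipids.pip2_at(t_grid[0])),
                          float(lipids.dag_at(t_grid[0])))
        p0 = np.eye(N_STATES)[0] if ss.degenerate else ss.occupancy
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-6:
        raise ValueError("initial occupancy must sum to 1")
    po_ref = 1.0 if po_ref is None else float(po_ref)
    if po_ref <= 0:
        raise ValueError("po_ref must be > 0")

    def rhs(t, y):
        Q = build_rate_matrix(params, float(lipids.pip2_at(t)), float(lipids.dag_at(t)))
        return Q.T @ y

    def jac(t, y):
        Q = build_rate_matrix(params, float(lipids.pip2_at(t)), float(lipids.dag_at(t)))
        return Q.T

    t0, t1 = sample_times[0], sample_times[-1]
    breaks = [t0, t1]
    if protocol is not None:
        breaks += [e for e in protocol.edges if t0 < e < t1]
    breaks = np.unique(np.asarray(breaks, dtype=float))

    occ = np.empty((sample_times.size, N_STATES))
    y = p0.copy()
    for a, b in zip(breaks[:-1], breaks[1:]):
        last = b == breaks[-1]
        mask = (sample_times >= a) & ((sample_times <= b) if last
                                      else (sample_times < b))
        t_eval = np.unique(np.append(sample_times[mask], b))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", jac=jac,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"master-equation integration failed on "
                               f"[{a:.6g}, {b:.6g}]: {sol.message}")
        if mask.any():
            occ[mask] = sol.y.T[: mask.sum()] if t_eval.size > mask.sum() else sol.y.T
        y = sol.y[:, -1]

    # Conservation drift stays at solver tolerance; project back onto the
    # probability simplex and fail loudly if drift is actually large.
    sums = occ.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise RuntimeError("occupancy conservation violated beyond tolerance")
    occ = np.clip(occ, 0.0, None)
    occ /= occ.sum(axis=1, keepdims=True)

    trace = None
    if protocol is not None:
        v = np.asarray(protocol.voltage(sample_times), dtype=float)
        current = _occupancy_current(params, occ[:, OPEN], po_ref, v)
        trace = CurrentTrace(sample_times.copy(), current, voltage_mV=v)
    return GatingSimResult(sample_times.copy(), occ, po_ref, trace)


def gillespie_oracle(params: GatingParams, lipids, n_channels: int, seed: int,
                     *, p0: np.ndarray | None = None):
    """Stochastic (CTMC) simulation of ``n_channels`` independent channels.

    Lipids are treated as piecewise constant on their sampling grid (left
    value on each interval).  Returns (times, occupancy_fraction) with
    occupancy recorded at every lipid grid point; Po is column 5.  Fully
    reproducible for a fixed seed.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    t_grid = np.asarray(lipids.time_s, dtype=float)
    rng = np.random.default_rng(seed)
    if p0 is None:
        ss = steady_state(params, float(lipids.pip2_at(t_grid[0])),
                          float(lipids.dag_at(t_grid[0])))
        p0 = np.eye(N_STATES)[0] if ss.degenerate else ss.occupancy
    counts = rng.multinomial(n_channels, np.asarray(p0, float))
    occ = np.empty((t_grid.size, N_STATES))
    occ[0] = counts / n_channels

    for k in range(t_grid.size - 1):
        t, t_end = t_grid[k], t_grid[k + 1]
        Q = build_rate_matrix(params, float(lipids.pip2_at(t)), float(lipids.dag_at(t)))
        src, dst = np.nonzero(np.triu(Q, 1) + np.tril(Q, -1))
        rates = Q[src, dst]
        keep = rates > 0
        src, dst, rates = src[keep], dst[keep], rates[keep]
        while True:
            a = counts[src] * rates
            a_tot = a.sum()
            if a_tot <= 0:
                break
            t += rng.exponential(1.0 / a_tot)
            if t >= t_end:
                break
            j = rng.choice(a.size, p=a / a_tot)
            counts[src[j]] -= 1
            counts[dst[j]] += 1
        occ[k + 1] = counts / n_channels
    return t_grid.copy(), occ
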