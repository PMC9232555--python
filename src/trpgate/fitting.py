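"""Kinetic trace fitting: the analysis applied to every pulse of a
whole-cell recording (and to FRET-reported PIP2 traces).

During the depolarizing step the outward current falls as PIP2 is
depleted; that decay is fitted with the logistic

    I(t) = I_min + I_d / (1 + exp[(t - t_half) / f_s])

with t measured from step onset (t_half in ms is the "decay" statistic).
After repolarization the inward current recovers as PIP2 is replenished,
fitted with the single exponential

    I(t) = I_0 + A * exp(-t / tau)

with t from the repolarization instant (tau in s is the "recovery"
statistic).  The inhibition ratio I_post/I_pre compares the current just
after the step (the recovery fit extrapolated to t = 0, i.e. I_0 + A)
with the mean current over the 100 ms preceding the step; ratios above 1
signal potentiation.  The affinity index tau/t_half (both in ms) serves
as a relative, construct-to-construct proxy for the PIP2 dissociation
constant.  Dose-response tables are fitted with the Hill equation
R = R_max * C^n / (EC50^n + C^n).

Fitters never raise on poor data: they return a result whose
``converged`` flag and ``reason`` are honest, and fabricate nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .protocol import VoltageProtocol
from .traces import Trace

__all__ = [
    "DecayFit", "RecoveryFit", "HillFitResult", "PulseKinetics", "CellSummary",
    "fit_decay", "fit_recovery", "hill_fit",
    "inhibition_ratio", "analyze_pulse", "summarize_cell",
]

MAX_ITER = 500
XTOL = 1e-8


# ----------------------------------------------------------------------
# result containers

@dataclass
class DecayFit:
    t_half_ms: float = np.nan
    f_s_ms: float = np.nan
    i_min: float = np.nan
    i_d: float = np.nan
    residual_norm: float = np.nan
    converged: bool = False
    reason: str = ""


@dataclass
class RecoveryFit:
    tau_s: float = np.nan
    a: float = np.nan
    i_0: float = np.nan
    residual_norm: float = np.nan
    converged: bool = False
    reason: str = ""


@dataclass
class HillFitResult:
    ec50_uM: float = np.nan
    hill_n: float = np.nan
    r_max: float = np.nan
    residual_norm: float = np.nan
    converged: bool = False
    reason: str = ""


@dataclass
class PulseKinetics:
    """Per-pulse fit results for one depolarization of one cell."""

    pulse_index: int
    decay: DecayFit
    recovery: RecoveryFit
    i_pre_nA: float = np.nan
    i_post_nA: float = np.nan
    inhibition_ratio: float = np.nan
    pre_reliable: bool = True

    @property
    def converged(self) -> bool:
        return self.decay.converged and self.recovery.converged


@dataclass
class CellSummary:
    """Pulse-averaged kinetics of one cell (2-4 pulses near the plateau)."""

    construct: str = ""
    t_half_ms: float = np.nan
    tau_s: float = np.nan
    inhibition_ratio: float = np.nan
    affinity_index: float = np.nan          # (mean tau in ms) / (mean t_half in ms)
    affinity_index_per_pulse: float = np.nan  # mean over pulses of tau_i/t_half_i
    n_pulses: int = 0
    complete: bool = False
    reason: str = ""
    pulses: list = field(default_factory=list)


# ----------------------------------------------------------------------
# core fitters

def _logistic(t, i_min, i_d, t_half, f_s):
    return i_min + i_d / (1.0 + np.exp((t - t_half) / f_s))


def _expdecay(t, i_0, a, tau):
    return a * np.exp(-t / tau) + i_0


def _smooth(y: np.ndarray) -> np.ndarray:
    w = max(3, y.size // 20) | 1
    return np.convolve(y, np.ones(w) / w, mode="same") if y.size >= w else y


def fit_decay(time_s: np.ndarray, value: np.ndarray, t0: float | None = None,
              f_s_guess_s: float | None = None) -> DecayFit:
    """Logistic fit of a decaying segment; times are shifted to ``t0``
    (default: first sample) so t_half is measured from step onset."""
    time_s = np.asarray(time_s, dtype=float)
    value = np.asarray(value, dtype=float)
    if time_s.size < 20:
        return DecayFit(reason="fewer than 20 samples")
    t = time_s - (time_s[0] if t0 is None else t0)
    span = t[-1] - t[0]

    sm = _smooth(value)
    i_min0, i_d0 = sm[-1], sm[0] - sm[-1]
    scale = max(np.max(np.abs(sm)), 1e-12)
    if i_d0 <= 1e-6 * scale:
        return DecayFit(reason="no decay detected")
    # initial t_half: first 50%-crossing of the smoothed segment
    below = np.nonzero(sm <= i_min0 + 0.5 * i_d0)[0]
    t_half0 = t[below[0]] if below.size else 0.5 * (t[0] + t[-1])
    f_s0 = f_s_guess_s if f_s_guess_s is not None else 0.1 * span

    model = Model(_logistic)
    params = model.make_params(i_min=i_min0, i_d=i_d0, t_half=max(t_half0, 1e-4),
                               f_s=f_s0)
    params["f_s"].set(min=1e-6)
    params["t_half"].set(min=0.0, max=5.0 * span)
    try:
        res = model.fit(value, params, t=t, max_nfev=MAX_ITER * 5, fit_kws={"xtol": XTOL})
    except Exception as exc:  # pragma: no cover - lmfit internal failure
        return DecayFit(reason=f"fit failed: {exc}")
    p = res.params
    ok = res.success and p["t_half"].value > 0 and p["f_s"].value > 0
    return DecayFit(
        t_half_ms=p["t_half"].value * 1e3, f_s_ms=p["f_s"].value * 1e3,
        i_min=p["i_min"].value, i_d=p["i_d"].value,
        residual_norm=float(np.sqrt(np.sum(res.residual ** 2))),
        converged=bool(ok), reason="" if ok else "optimizer did not converge",
    )


def fit_recovery(time_s: np.ndarray, value: np.ndarray,
                 t0: float | None = None) -> RecoveryFit:
    """Exponential fit of a recovering segment; times shifted to ``t0``
    (default: first sample, normally the repolarization instant) so the
    extrapolated I(0) = I_0 + A is the current just after the step."""
    time_s = np.asarray(time_s, dtype=float)
    value = np.asarray(value, dtype=float)
    if time_s.size < 10:
        return RecoveryFit(reason="fewer than 10 samples")
    t = time_s - (time_s[0] if t0 is None else t0)

    n_tail = max(3, value.size // 10)
    i0_0 = float(np.mean(value[-n_tail:]))
    a0 = float(value[0] - i0_0)
    scale = max(np.max(np.abs(value)), 1e-12)
    if abs(a0) <= 1e-6 * scale:
        return RecoveryFit(reason="no relaxation detected")
    # tau initial guess from log-linear regression on the deviation
    dev = np.sign(a0) * (value - i0_0)
    m = dev > 0.05 * abs(a0)
    if m.sum() >= 3:
        slope = np.polyfit(t[m], np.log(dev[m]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0

    model = Model(_expdecay)
    params = model.make_params(i_0=i0_0, a=a0, tau=max(tau0, 1e-6))
    params["tau"].set(min=1e-9)
    try:
        res = model.fit(value, params, t=t, max_nfev=MAX_ITER * 5, fit_kws={"xtol": XTOL})
    except Exception as exc:  # pragma: no cover
        return RecoveryFit(reason=f"fit failed: {exc}")
    p = res.params
    ok = res.success and p["tau"].value > 0
    return RecoveryFit(
        tau_s=p["tau"].value, a=p["a"].value, i_0=p["i_0"].value,
        residual_norm=float(np.sqrt(np.sum(res.residual ** 2))),
        converged=bool(ok), reason="" if ok else "optimizer did not converge",
    )


def _hill(c, r_max, ec50, n):
    cn = np.power(c, n)
    return r_max * cn / (np.power(ec50, n) + cn)


def hill_fit(concentration_uM: np.ndarray, response: np.ndarray) -> HillFitResult:
    """Hill equation fit of a dose-response table (>= 4 distinct doses)."""
    c = np.asarray(concentration_uM, dtype=float)
    r = np.asarray(response, dtype=float)
    if np.unique(c).size < 4:
        return HillFitResult(reason="fewer than 4 distinct concentrations")
    if np.any(c <= 0):
        return HillFitResult(reason="non-positive concentration")

    r_max0 = float(np.max(r))
    if r_max0 <= 0:
        return HillFitResult(reason="no positive response")
    half = 0.5 * r_max0
    order = np.argsort(c)
    cs, rs = c[order], r[order]
    above = np.nonzero(rs >= half)[0]
    ec50_0 = float(cs[above[0]]) if above.size else float(np.median(cs))

    model = Model(_hill)
    params = model.make_params(r_max=r_max0, ec50=ec50_0, n=1.0)
    params["ec50"].set(min=1e-9)
    params["n"].set(min=1e-3, max=10.0)
    params["r_max"].set(min=0.0)
    try:
        res = model.fit(r, params, c=c, max_nfev=MAX_ITER * 5, fit_kws={"xtol": XTOL})
    except Exception as exc:  # pragma: no cover
        return HillFitResult(reason=f"fit failed: {exc}")
    p = res.params
    # saturation check: top dose must reach a meaningful fraction of r_max
    top = _hill(np.max(c), p["r_max"].value, p["ec50"].value, p["n"].value)
    saturating = p["r_max"].value > 0 and top >= 0.6 * p["r_max"].value
    ok = bool(res.success and saturating)
    return HillFitResult(
        ec50_uM=p["ec50"].value, hill_n=p["n"].value, r_max=p["r_max"].value,
        residual_norm=float(np.sqrt(np.sum(res.residual ** 2))),
        converged=ok,
        reason="" if ok else ("dose range does not saturate" if res.success
                              else "optimizer did not converge"),
    )


# ----------------------------------------------------------------------
# pulse-level analysis

DECAY_SKIP_S = 0.005     # skip the capacitive edge after step onset
RECOVERY_SKIP_S = 0.020  # skip the edge after repolarization
PRE_WINDOW_S = 0.100     # baseline window before the step


def _pulse_windows(trace: Trace, protocol: VoltageProtocol, k: int):
    onset, end = protocol.pulse_bounds(k)
    nxt = (protocol.pulse_onsets_s[k + 1] if k + 1 < protocol.n_pulses
           else trace.time_s[-1] + 1e-9)
    return onset, end, nxt


def analyze_pulse(trace: Trace, protocol: VoltageProtocol, k: int,
                  noise_floor_nA: float = 0.01) -> PulseKinetics:
    """Fit decay, recovery and the inhibition ratio for pulse ``k``."""
    onset, end, nxt = _pulse_windows(trace, protocol, k)

    dec_seg = trace.segment(onset + DECAY_SKIP_S, end)
    decay = fit_decay(dec_seg.time_s, dec_seg.value, t0=onset)

    rec_seg = trace.segment(end + RECOVERY_SKIP_S, nxt)
    recovery = fit_recovery(rec_seg.time_s, rec_seg.value, t0=end)

    pre_seg = trace.segment(onset - PRE_WINDOW_S, onset)
    i_pre = float(np.mean(pre_seg.value)) if len(pre_seg) else np.nan
    reliable = np.isfinite(i_pre) and abs(i_pre) >= noise_floor_nA

    i_post = recovery.i_0 + recovery.a if recovery.converged else np.nan
    ratio = i_post / i_pre if reliable and np.isfinite(i_post) else np.nan
    return PulseKinetics(pulse_index=k, decay=decay, recovery=recovery,
                         i_pre_nA=i_pre, i_post_nA=i_post,
                         inhibition_ratio=ratio, pre_reliable=bool(reliable))


def inhibition_ratio(trace: Trace, protocol: VoltageProtocol,
                     k: int | None = None, **kw):
    """I_post/I_pre for pulse ``k``, or for every pulse when k is None."""
    if k is not None:
        return analyze_pulse(trace, protocol, k, **kw).inhibition_ratio
    return np.array([analyze_pulse(trace, protocol, i, **kw).inhibition_ratio
                     for i in range(protocol.n_pulses)])


def analyze_fret_episode(trace: Trace, protocol: VoltageProtocol, k: int = 0,
                         baseline_s: float = 0.3) -> tuple:
    """Depletion / replenishment kinetics of a FRET-reported PIP2 trace.

    Optical signals carry no capacitive edge, so the depletion fit keeps a
    stretch of pre-step baseline: the logistic needs the flat shoulder to
    locate its corner (fitting it to the bare falling phase is degenerate,
    t_half -> 0).  Times are still measured from step onset.  Returns
    (DecayFit, RecoveryFit).
    """
    onset, end, nxt = _pulse_windows(trace, protocol, k)
    dep = trace.segment(onset - baseline_s, end)
    decay = fit_decay(dep.time_s, dep.value, t0=onset)
    rep = trace.segment(end + RECOVERY_SKIP_S, nxt)
    recovery = fit_recovery(rep.time_s, rep.value, t0=end)
    return decay, recovery


def summarize_cell(trace: Trace, protocol: VoltageProtocol,
                   max_pulses: int = 4, min_pulses: int = 2,
                   construct: str | None = None, **kw) -> CellSummary:
    """Average per-pulse kinetics over the 2-4 pulses nearest the plateau
    peak (largest baseline current magnitude) and derive the affinity
    index, both as the ratio of the averages (tau/t_half in ms) and as the
    pulse-averaged per-pulse ratio."""
    label = construct if construct is not None else str(trace.meta.get("construct", ""))
    pulses = [analyze_pulse(trace, protocol, k, **kw)
              for k in range(protocol.n_pulses)]
    good = [p for p in pulses if p.converged and p.pre_reliable]
    if len(good) < min_pulses:
        return CellSummary(construct=label, n_pulses=len(good), pulses=pulses,
                           reason=f"only {len(good)} analyzable pulses "
                                  f"(need >= {min_pulses})")
    good.sort(key=lambda p: -abs(p.i_pre_nA))
    sel = sorted(good[:max_pulses], key=lambda p: p.pulse_index)

    t_half = float(np.mean([p.decay.t_half_ms for p in sel]))
    tau = float(np.mean([p.recovery.tau_s for p in sel]))
    ratio = float(np.mean([p.inhibition_ratio for p in sel]))
    per_pulse = float(np.mean([p.recovery.tau_s * 1e3 / p.decay.t_half_ms
                               for p in sel]))
    return CellSummary(
        construct=label, t_half_ms=t_half, tau_s=tau, inhibition_ratio=ratio,
        affinity_index=tau * 1e3 / t_half, affinity_index_per_pulse=per_pulse,
        n_pulses=len(sel), complete=True, pulses=pulses,
    )
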