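"""Voltage command protocols for whole-cell recordings.

The standard protocol holds the membrane at -50 mV and applies strong
depolarizing steps (+100 mV, 700 ms) at regular intervals; each step
activates the co-expressed voltage-sensitive phosphatase and transiently
depletes PIP2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoltageProtocol"]


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant voltage command: holding level plus square steps.

    Parameters
    ----------
    holding_mV : float
        Holding potential between steps (default -50 mV).
    step_mV : float
        Potential during the depolarizing step (default +100 mV).
    step_duration_s : float
        Duration of each step (default 0.7 s).
    pulse_onsets_s : tuple of float
        Onset time of each step, strictly increasing and non-overlapping.
    total_duration_s : float
        End of the recording; must cover every step.
    """

    holding_mV: float = -50.0
    step_mV: float = 100.0
    step_duration_s: float = 0.7
    pulse_onsets_s: tuple = field(default_factory=tuple)
    total_duration_s: float = 10.0

    def __post_init__(self):
        if self.step_duration_s <= 0:
            raise ValueError("step_duration_s must be positive")
        on = np.asarray(self.pulse_onsets_s, dtype=float)
        if on.size and np.any(np.diff(on) <= self.step_duration_s):
            raise ValueError("pulses overlap or are not strictly increasing")
        if on.size and on[-1] + self.step_duration_s > self.total_duration_s:
            raise ValueError("pulse extends past total_duration_s")
        if on.size and on[0] < 0:
            raise ValueError("pulse onset before t=0")
        object.__setattr__(self, "pulse_onsets_s", tuple(float(t) for t in on))

    @classmethod
    def standard(cls, n_pulses: int = 3, first_onset_s: float = 60.0,
                 period_s: float = 15.0, tail_s: float = 12.0) -> "VoltageProtocol":
        """The pulse-train protocol used throughout: +100 mV / 700 ms steps
        every ``period_s`` from a -50 mV holding potential."""
        onsets = tuple(first_onset_s + i * period_s for i in range(n_pulses))
        total = onsets[-1] + 0.7 + tail_s if onsets else tail_s
        return cls(pulse_onsets_s=onsets, total_duration_s=total)

    @classmethod
    def single_pulse(cls, onset_s: float = 1.0, tail_s: float = 14.0) -> "VoltageProtocol":
        return cls(pulse_onsets_s=(onset_s,),
                   total_duration_s=onset_s + 0.7 + tail_s)

    # ------------------------------------------------------------------
    def pulse_bounds(self, k: int) -> tuple:
        """(onset, end) of pulse ``k`` in seconds."""
        t0 = self.pulse_onsets_s[k]
        return t0, t0 + self.step_duration_s

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets_s)

    @property
    def edges(self) -> np.ndarray:
        """All voltage transition times, sorted, including 0 and the end."""
        e = [0.0, self.total_duration_s]
        for t0 in self.pulse_onsets_s:
            e += [t0, t0 + self.step_duration_s]
        return np.unique(np.asarray(e, dtype=float))

    def segments(self):
        """Yield (t_start, t_end, voltage_mV) for each constant-voltage piece."""
        e = self.edges
        for a, b in zip(e[:-1], e[1:]):
            mid = 0.5 * (a + b)
            yield a, b, self.voltage(mid)

    def voltage(self, t):
        """Command voltage at time(s) ``t`` (step interval is [onset, end))."""
        t = np.asarray(t, dtype=float)
        v = np.full(t.shape, self.holding_mV)
        for t0 in self.pulse_onsets_s:
            v = np.where((t >= t0) & (t < t0 + self.step_duration_s),
                         self.step_mV, v)
        return v if v.shape else float(v)

    def sample_times(self, dt_pulse_s: float = 1e-3, dt_base_s: float = 0.05,
                     pre_pad_s: float = 0.2, post_pad_s: float = 0.1) -> np.ndarray:
        """Two-rate sampling grid: fine around each pulse (pre-pad covers the
        baseline window, post-pad the early recovery), coarse elsewhere."""
        base = np.arange(0.0, self.total_duration_s + 0.5 * dt_base_s, dt_base_s)
        fine = []
        for t0 in self.pulse_onsets_s:
            a = max(0.0, t0 - pre_pad_s)
            b = min(self.total_duration_s, t0 + self.step_duration_s + post_pad_s)
            fine.append(np.arange(a, b + 0.5 * dt_pulse_s, dt_pulse_s))
        t = np.concatenate([base] + fine) if fine else base
        return np.unique(np.round(t, 9))
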