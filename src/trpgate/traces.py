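"""In-memory time-series containers shared by the simulator, generator and
fitting pipeline: whole-cell current traces and FRET-ratio traces."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Trace", "CurrentTrace", "FretTrace"]


@dataclass
class Trace:
    """A sampled observable on a strictly increasing time grid.

    ``value`` carries the observable (current in nA, or a FRET ratio);
    ``voltage_mV`` the command voltage if known; ``meta`` free-form metadata
    including, for synthetic traces, the generating truth block.
    """

    time_s: np.ndarray
    value: np.ndarray
    voltage_mV: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    kind = "trace"

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.value.shape:
            raise ValueError("time_s and value must be 1-D arrays of equal length")
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.voltage_mV is not None:
            self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
            if self.voltage_mV.shape != self.time_s.shape:
                raise ValueError("voltage_mV length mismatch")

    def __len__(self):
        return self.time_s.size

    def segment(self, t0: float, t1: float) -> "Trace":
        """Copy of the samples with t0 <= t < t1."""
        m = (self.time_s >= t0) & (self.time_s < t1)
        return replace(
            self,
            time_s=self.time_s[m].copy(),
            value=self.value[m].copy(),
            voltage_mV=None if self.voltage_mV is None else self.voltage_mV[m].copy(),
            meta=dict(self.meta),
        )


@dataclass
class CurrentTrace(Trace):
    """Whole-cell membrane current in nA (inward negative)."""

    kind = "current"

    @property
    def current_nA(self) -> np.ndarray:
        return self.value


@dataclass
class FretTrace(Trace):
    """FRET ratio reporting membrane PIP2 (arbitrary ratio units)."""

    kind = "fret"

    @property
    def ratio(self) -> np.ndarray:
        return self.value
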