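"""File formats and configuration plumbing.

Traces travel as a CSV (columns ``time_s``, ``value``, optional
``voltage_mV``) plus a JSON sidecar of the same stem carrying schema
version, trace kind, construct, protocol, seeds and — for synthetic data —
the generating truth block.  Run configurations are YAML and round-trip
deterministically (sorted keys), so a config hash identifies a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .traces import CurrentTrace, FretTrace, Trace

__all__ = [
    "TraceIOError", "MissingColumnError", "NonMonotoneTimeError", "SchemaError",
    "write_trace", "read_trace", "RunConfig", "write_manifest",
]

SCHEMA_VERSION = 1


class TraceIOError(ValueError):
    """Base class for trace-format failures; ``code`` is machine-readable."""

    code = "trace-io-error"


class MissingColumnError(TraceIOError):
    code = "missing-column"


class NonMonotoneTimeError(TraceIOError):
    code = "non-monotone-time"


class SchemaError(TraceIOError):
    code = "schema-mismatch"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: Trace, path) -> Path:
    """Write CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s, "value": trace.value})
    if trace.voltage_mV is not None:
        df["voltage_mV"] = trace.voltage_mV
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    meta = dict(trace.meta)
    meta.setdefault("schema_version", SCHEMA_VERSION)
    meta.setdefault("kind", trace.kind)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True,
                                         default=float))
    return path


def read_trace(path) -> Trace:
    """Read a trace CSV (+ sidecar if present), validating the schema.

    Accepts ``time_ms`` as an alternative time column (converted to
    seconds).  Distinct error codes: missing-column, non-monotone-time,
    schema-mismatch.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_ms" in df.columns and "time_s" not in df.columns:
        df["time_s"] = df.pop("time_ms") * 1e-3
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise MissingColumnError(f"column {col!r} missing in {path.name}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise NonMonotoneTimeError(f"time not strictly increasing in {path.name}")

    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        if "schema_version" not in meta:
            raise SchemaError(f"sidecar {side.name} lacks schema_version")
        if int(meta["schema_version"]) > SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {meta['schema_version']}")
    kind = meta.get("kind", "current")
    if kind not in ("current", "fret"):
        raise SchemaError(f"unknown trace kind {kind!r}")
    cls = CurrentTrace if kind == "current" else FretTrace
    v = df["voltage_mV"].to_numpy(dtype=float) if "voltage_mV" in df.columns else None
    return cls(t, df["value"].to_numpy(dtype=float), voltage_mV=v, meta=meta)


@dataclass
class RunConfig:
    """YAML-backed run configuration; sections are plain dicts so the file
    round-trips bit-identically (sorted-key canonical dump)."""

    protocol: dict = field(default_factory=dict)
    gating: dict = field(default_factory=dict)
    vsp: dict = field(default_factory=dict)
    cascade: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    panel: list = field(default_factory=list)
    analysis: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"protocol": self.protocol, "gating": self.gating, "vsp": self.vsp,
                "cascade": self.cascade, "noise": self.noise, "panel": self.panel,
                "analysis": self.analysis, "stats": self.stats}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True,
                              default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f: data.get(f) for f in
                 ("protocol", "gating", "vsp", "cascade", "noise",
                  "panel", "analysis", "stats") if data.get(f) is not None}
        return cls(**known)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def write_manifest(out_dir, *, command: str, seed: int | None = None,
                   config: RunConfig | None = None, extra: dict | None = None) -> Path:
    """Record what produced the artifacts in a directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config_digest": config.digest if config is not None else None,
        "trpgate_version": __version__,
        "schema_version": SCHEMA_VERSION,
    }
    manifest.update(extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=float))
    return path
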