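"""Waveform and manifest serialization.

Waveforms travel as two-column CSV with the exact header
``time_ms,pressure_mmhg``; run metadata travels as a JSON manifest that can
reproduce the run when its config snapshot is fed back in.  All writers are
atomic: content goes to ``<path>.partial`` and is renamed on success, so an
interrupted run never leaves a file without the ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulatorConfig
from .errors import InputError, WaveformFormatError
from .waveform import WaveformRecord

__all__ = ["write_waveform", "read_waveform", "RunManifest",
           "write_manifest", "read_manifest"]

_HEADER = "time_ms,pressure_mmhg"


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".partial")
    tmp.write_text(text)
    tmp.replace(path)


def write_waveform(w: WaveformRecord, path: str | Path) -> None:
    """Write a waveform as CSV with header ``time_ms,pressure_mmhg``."""
    path = Path(path)
    lines = [_HEADER]
    lines += [f"{t:.10g},{p:.10g}" for t, p in zip(w.t, w.p)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_waveform(path: str | Path, site: str | None = None,
                  period: float = 0.0) -> WaveformRecord:
    """Read a waveform CSV, enforcing the header and a uniform time axis."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if header != _HEADER:
        raise WaveformFormatError(
            f"{path}: expected header '{_HEADER}', found '{header}'")
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float)
    p = df["pressure_mmhg"].to_numpy(dtype=float)
    # WaveformRecord validation raises InputError on non-monotone time
    return WaveformRecord(site or path.stem, t, p, period)


# ----------------------------------------------------------------------
@dataclass
class RunManifest:
    """Machine-readable record of one simulation run."""

    config: dict
    version: str = __version__
    converged: bool = False
    n_cycles_run: int = 0
    outputs: dict[str, str] = field(default_factory=dict)  # site -> filename
    summary: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.config_hash:
            blob = json.dumps(self.config, sort_keys=True).encode()
            self.config_hash = hashlib.sha256(blob).hexdigest()[:16]

    def to_config(self) -> SimulatorConfig:
        """Round-trip: rebuild the exact configuration of the run."""
        return SimulatorConfig.from_dict(self.config)


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    path = Path(path)
    _atomic_write(path, json.dumps(dataclasses.asdict(manifest), indent=2,
                                   sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    try:
        return RunManifest(**data)
    except TypeError as exc:
        raise InputError(f"{path}: not a run manifest ({exc})") from exc
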