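"""Waveform file I/O and run configuration.

Waveforms travel as two-column CSV with the exact header ``time_s,value``:
float seconds and float sample value.  The time column must be uniformly
spaced; the sampling rate is inferred from the median step and any step
deviating more than 1% is rejected.  CSV is the single canonical
interchange format -- plain text round-trips losslessly at the precision
written and needs no device-specific tooling.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .core import ConfigError, InputError, WaveformSignal
from .estimators import KashifParams, PIParams, SRParams
from .synth import SynthConfig
from .ursino import UrsinoParams

__all__ = ["read_waveform", "write_waveform", "RunConfig", "load_config"]

_HEADER = "time_s,value"


def read_waveform(path: str | Path, units: str = "") -> WaveformSignal:
    """Read a waveform CSV (``time_s,value`` header, uniform time grid).

    Raises
    ------
    InputError
        On a missing/empty file, wrong header, or a time step deviating
        more than 1% from the median (the message cites the first
        offending row).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with path.open() as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != _HEADER:
            raise InputError(
                f"{path}: expected header '{_HEADER}', got '{header}'")
        body = fh.read()
    if not body.strip():
        raise InputError(f"{path}: empty file")
    data = np.loadtxt(body.splitlines(), delimiter=",", ndmin=2)
    if data.size == 0 or data.shape[0] < 2:
        raise InputError(f"{path}: needs at least 2 samples")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise InputError(f"{path}: non-increasing time column")
    bad = np.nonzero(np.abs(dt - med) > 0.01 * med)[0]
    if bad.size:
        row = bad[0] + 2  # 1-based, after header
        raise InputError(
            f"{path}: non-uniform time step at data row {row} "
            f"(dt={dt[bad[0]]:.6g}, median {med:.6g})")
    return WaveformSignal(v, fs=1.0 / med, t0=float(t[0]), units=units)


def write_waveform(signal: WaveformSignal, path: str | Path) -> None:
    """Write a waveform as ``time_s,value`` CSV with 10 significant digits."""
    path = Path(path)
    if len(signal) == 0:
        raise InputError("refusing to write an empty signal")
    arr = np.column_stack([signal.t, signal.values])
    try:
        np.savetxt(path, arr, delimiter=",", header=_HEADER, comments="",
                   fmt="%.10g")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Run configuration

_SECTIONS = {
    "synth": SynthConfig,
    "sr": SRParams,
    "pi": PIParams,
    "kashif": KashifParams,
    "ursino": UrsinoParams,
}


@dataclasses.dataclass
class RunConfig:
    """Aggregated configuration: one optional section per parameter set.

    Defaults of every section reproduce the published constants; unknown
    sections or keys are rejected with the offending name.
    """

    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    sr: SRParams = dataclasses.field(default_factory=SRParams)
    pi: PIParams = dataclasses.field(default_factory=PIParams)
    kashif: KashifParams = dataclasses.field(default_factory=KashifParams)
    ursino: UrsinoParams = dataclasses.field(default_factory=UrsinoParams)
    seed: int = 0
    verbose: bool = False


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides.

    The file is a mapping with optional sections ``synth``, ``sr``, ``pi``,
    ``kashif``, ``ursino`` and scalar keys ``seed`` / ``verbose``.
    """
    raw: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw.update(loaded)
    raw.update(overrides)

    kwargs: dict = {}
    for key, val in raw.items():
        if key in ("seed", "verbose"):
            kwargs[key] = val
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(val, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(val) - names
            if unknown:
                raise ConfigError(
                    f"unknown key '{sorted(unknown)[0]}' in section '{key}'")
            if "vm_window" in val and val["vm_window"] is not None:
                val = {**val, "vm_window": tuple(val["vm_window"])}
            kwargs[key] = cls(**val)
        else:
            raise ConfigError(f"unknown configuration key '{key}'")
    return RunConfig(**kwargs)
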