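"""Core data carriers and exceptions shared across the package.

Every waveform in the pipeline -- arterial blood pressure (ABP, mmHg),
cerebral blood flow velocity (CBFv, cm/s), cerebral blood flow (CBF, ml/s)
and intracranial pressure (ICP, mmHg) -- travels as a
:class:`WaveformSignal`: a uniformly sampled series with an explicit
sampling rate, start time and unit label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class IcpestError(Exception):
    """Base class for package errors."""


class ConfigError(IcpestError):
    """Invalid configuration; the message names the offending field/key."""


class InputError(IcpestError):
    """Malformed or inconsistent input data (non-uniform grid, bad file...)."""


class NumericalError(IcpestError):
    """A solver or numerical routine failed; message carries diagnostics."""


class DetectionError(IcpestError):
    """Beat detection found no usable cardiac cycles."""


class AlignmentError(IcpestError):
    """ABP/CBFv beat matching failed for too many beats."""


class EstimationError(IcpestError):
    """An estimator could not produce any output (e.g. all beats skipped)."""


@dataclass
class WaveformSignal:
    """Uniformly sampled physiological signal.

    Parameters
    ----------
    values : ndarray
        Physical samples (mmHg, cm/s or ml/s depending on ``units``).
    fs : float
        Sampling rate in samples/second.
    t0 : float
        Time of the first sample, seconds.
    units : str
        Unit label, e.g. ``"mmHg"`` or ``"cm/s"``.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise InputError(f"fs must be > 0, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InputError("values must be a 1-D array with length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise InputError("values must be finite")

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        """Span from first to one past the last sample, seconds."""
        return self.values.size / self.fs

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "WaveformSignal":
        """New signal on the same time grid with different samples."""
        return WaveformSignal(np.asarray(values, dtype=float), self.fs, self.t0,
                              self.units if units is None else units)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ICPSeries:
    """An intracranial-pressure estimate over time.

    ``granularity`` records whether the series is per-sample (the SR
    estimator, which outputs on the input grid) or per-beat (PI and the
    two-element estimator, one value per detected cardiac cycle stamped at
    the beat onset).
    """

    t: np.ndarray
    icp: np.ndarray
    granularity: str = "per-sample"  # or "per-beat"
    method: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.icp = np.asarray(self.icp, dtype=float)
        if self.t.shape != self.icp.shape:
            raise InputError("t and icp must have the same length")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.icp))):
            raise InputError("ICPSeries must be finite")

    def resample_hold(self, t_new: np.ndarray) -> np.ndarray:
        """Previous-value-hold resampling onto ``t_new``.

        Per-beat series are step functions by construction; samples of
        ``t_new`` earlier than the first timestamp take the first value.
        """
        t_new = np.asarray(t_new, dtype=float)
        idx = np.searchsorted(self.t, t_new, side="right") - 1
        idx = np.clip(idx, 0, self.t.size - 1)
        return self.icp[idx]

    def __len__(self) -> int:
        return self.t.size
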