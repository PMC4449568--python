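"""Waveform conditioning shared by all estimators.

Four primitives: zero-phase low-pass extraction of the DC trend, beat-onset
detection, per-beat feature extraction (systolic / end-diastolic / mean),
and estimation of the transit-time shift between a peripheral ABP recording
and the CBFv measured at the middle cerebral artery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import AlignmentError, DetectionError, InputError, WaveformSignal

__all__ = [
    "BeatTable", "lowpass_dc", "detect_beats", "beat_features",
    "estimate_time_shift", "apply_shift",
]


@dataclass
class BeatTable:
    """Per-beat annotations on a pulsatile signal.

    ``onsets`` are the sample indices of beat starts (pre-upstroke minima);
    ``systolic_idx`` the in-beat maxima.  Feature arrays (filled by
    :func:`beat_features`) cover *complete* beats only, i.e. beat ``i``
    spans ``[onsets[i], onsets[i+1])`` and there are ``len(onsets) - 1`` of
    them; the trailing incomplete beat is dropped.
    """

    onsets: np.ndarray
    systolic_idx: np.ndarray
    systolic: np.ndarray = field(default_factory=lambda: np.empty(0))
    diastolic: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_complete(self) -> int:
        return max(0, len(self.onsets) - 1)


def lowpass_dc(x: WaveformSignal, cutoff: float = 0.2) -> WaveformSignal:
    """Zero-phase low-pass filter extracting the DC trend.

    4th-order Butterworth applied forward-backward (``filtfilt``): exactly
    unit gain at DC and no phase distortion, so slow trends keep their
    timing.  Default 0.2 Hz cutoff isolates the sub-cardiac, sub-respiratory
    component the resistance-only pressure model is valid for.
    """
    if cutoff <= 0:
        raise InputError(f"cutoff must be > 0, got {cutoff}")
    if cutoff >= x.fs / 2:
        raise InputError(f"cutoff {cutoff} Hz must be below Nyquist {x.fs / 2} Hz")
    sos = sps.butter(4, cutoff, btype="low", fs=x.fs, output="sos")
    # pad with the signal mean over the filter's settling time: edges then
    # relax toward the DC level instead of toward reflected pulse copies,
    # which would bias the trend estimate near the record boundaries
    npad = int(round(3.0 * x.fs / cutoff))
    m = float(x.values.mean())
    ext = np.concatenate([np.full(npad, m), x.values, np.full(npad, m)])
    y = sps.sosfiltfilt(sos, ext, padtype=None)[npad:npad + len(x)]
    return x.copy_with(y)


def _pulse_band(x: WaveformSignal) -> np.ndarray:
    """Band-pass 0.5-10 Hz (clipped below Nyquist) isolating the pulse."""
    hi = min(10.0, 0.45 * x.fs)
    if hi <= 0.5:
        raise InputError(f"fs {x.fs} Hz too low for beat detection")
    sos = sps.butter(2, [0.5, hi], btype="band", fs=x.fs, output="sos")
    return sps.sosfiltfilt(sos, x.values)


def detect_beats(x: WaveformSignal) -> BeatTable:
    """Detect cardiac beat onsets and systolic peaks.

    Peak-finding on the derivative of the band-passed (0.5-10 Hz) signal
    with a 0.3-s refractory period marks the systolic upstrokes; each onset
    is placed at the pre-upstroke minimum of the raw signal.  Robust to
    additive noise up to a few percent of the pulse amplitude because the
    band-pass removes both baseline drift and sample-to-sample noise.

    Raises
    ------
    DetectionError
        If the signal carries no detectable pulsatility.
    """
    bp = _pulse_band(x)
    d = np.gradient(bp) * x.fs
    dmax = d.max(initial=0.0)
    scale = np.median(np.abs(x.values)) + 1.0
    if dmax <= 1e-9 * scale * x.fs:
        raise DetectionError("no pulsatile component found")
    refractory = max(1, int(round(0.3 * x.fs)))
    # two-pass threshold: the median height of refractory-spaced candidate
    # peaks is robust to isolated noise spikes that would inflate the max
    cand, _ = sps.find_peaks(d, height=0.0, distance=refractory)
    if len(cand) == 0:
        raise DetectionError("no pulsatile component found")
    peaks, _ = sps.find_peaks(d, height=0.4 * float(np.median(d[cand])),
                              distance=refractory)
    if len(peaks) < 2:
        raise DetectionError(f"found {len(peaks)} upstrokes; need >= 2 beats")

    back = max(1, int(round(0.25 * x.fs)))
    onsets = np.empty(len(peaks), dtype=int)
    for k, p in enumerate(peaks):
        lo = max(0, p - back)
        onsets[k] = lo + int(np.argmin(x.values[lo:p + 1]))
    onsets = np.unique(onsets)
    if len(onsets) < 2:
        raise DetectionError("degenerate onset sequence")

    sys_idx = np.empty(len(onsets), dtype=int)
    for k in range(len(onsets)):
        hi = onsets[k + 1] if k + 1 < len(onsets) else len(x.values)
        sys_idx[k] = onsets[k] + int(np.argmax(x.values[onsets[k]:hi]))
    return BeatTable(onsets=onsets, systolic_idx=sys_idx)


def beat_features(x: WaveformSignal, beats: BeatTable) -> BeatTable:
    """Fill per-beat systolic / end-diastolic / mean features.

    For complete beat i spanning ``[onsets[i], onsets[i+1])``:
    systolic is the in-beat maximum, diastolic the value at the *next*
    onset (end-diastolic convention) and mean the sample average over the
    beat.  The trailing incomplete beat carries no features.
    """
    n = beats.n_complete
    if n < 1:
        raise DetectionError("need at least one complete beat")
    syst = np.empty(n)
    dias = np.empty(n)
    mean = np.empty(n)
    for i in range(n):
        a, b = beats.onsets[i], beats.onsets[i + 1]
        seg = x.values[a:b]
        syst[i] = seg.max()
        dias[i] = x.values[b]
        mean[i] = seg.mean()
    return BeatTable(onsets=beats.onsets, systolic_idx=beats.systolic_idx,
                     systolic=syst, diastolic=dias, mean=mean)


def estimate_time_shift(abp: WaveformSignal, cbfv: WaveformSignal) -> float:
    """Transit-time shift tau between peripheral ABP and MCA CBFv, seconds.

    The pressure pulse reaches a peripheral (radial/finger) site later than
    the middle cerebral artery, so the ABP recording lags CBFv.  tau is the
    median over matched beats of (ABP systolic-peak time - CBFv
    systolic-peak time); tau > 0 means ABP lags, and the cerebral pressure
    surrogate is ``P_MCA(t) = P_r(t + tau)`` (see :func:`apply_shift`).

    Raises
    ------
    AlignmentError
        If more than half of the beats cannot be matched one-to-one.
    """
    ba = detect_beats(abp)
    bc = detect_beats(cbfv)
    ta = abp.t0 + ba.systolic_idx / abp.fs
    tc = cbfv.t0 + bc.systolic_idx / cbfv.fs
    tol = 0.5 * float(np.median(np.diff(tc))) if len(tc) > 1 else 0.4
    diffs = []
    for tpk in ta:
        j = int(np.argmin(np.abs(tc - tpk)))
        if abs(tc[j] - tpk) <= tol:
            diffs.append(tpk - tc[j])
    if len(diffs) < 0.5 * min(len(ta), len(tc)):
        raise AlignmentError(
            f"only {len(diffs)} of {min(len(ta), len(tc))} beats matched")
    return float(np.median(diffs))


def apply_shift(abp: WaveformSignal, tau: float) -> WaveformSignal:
    """Advance ABP by tau seconds: returns P_MCA with P_MCA(t) = P_r(t+tau).

    Linear interpolation on the same output grid; edges are extended with
    the boundary samples.
    """
    t = abp.t
    shifted = np.interp(t + tau, t, abp.values)
    return abp.copy_with(shifted)
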