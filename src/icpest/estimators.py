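"""Three non-invasive ICP estimators operating on ABP and CBFv.

* **SR (simple-resistance) method** -- the package's core.  Below ~0.2 Hz
  the vascular and CSF compliances of the intracranial circuit carry no
  current, leaving two resistive sub-circuits: an arterial resistance R_a
  between ABP and the capillary pressure, and a CSF
  formation/outflow divider (R_f, R_o) between the capillary pressure and
  the venous sinus.  With the flow obtained from CBFv via Q = alpha*CBFv,

      P_c  = P_a - R_a * Q_CBF
      P_ic = P_vs + (P_c - P_vs) * R_o / (R_f + R_o)

  applied sample-wise to the low-pass-filtered signals gives a per-sample
  ICP estimate that needs no compliance fitting and reacts immediately to
  trend changes.

* **PI regression** -- Gosling's pulsatility index per beat,
  PI = (systolic - end-diastolic)/mean CBFv, mapped linearly to ICP.

* **Two-element (Kashif-style) model** -- a single arterial resistance R_a
  and compliance C_a between cerebral arterial pressure and ICP, with ICP
  held constant over an estimation window; R_a and C_a are identified from
  within-beat morphology and ICP recovered as P_MCA - R_a * Q_CBF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import EstimationError, ICPSeries, InputError, WaveformSignal
from .sigproc import (BeatTable, apply_shift, beat_features, detect_beats,
                      estimate_time_shift, lowpass_dc)

__all__ = [
    "SRParams", "PIParams", "KashifParams",
    "sr_capillary_pressure", "sr_icp", "cbfv_to_cbf", "sr_estimate",
    "pi_index", "pi_to_icp", "pi_estimate", "kashif_estimate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SRParams:
    """Constants of the simple-resistance estimator.

    R_a lumps the proximal+distal intracranial arterial resistance; P_vs is
    the venous sinus pressure; R_f and R_o are the CSF formation and
    outflow resistances; alpha converts CBFv (cm/s) to CBF (ml/s); cutoff
    is the DC-trend low-pass corner in Hz.
    """

    R_a: float = 6.0        # mmHg·s/ml
    P_vs: float = 6.0       # mmHg
    R_f: float = 2380.0     # mmHg·s/ml
    R_o: float = 523.0      # mmHg·s/ml
    alpha: float = 0.15     # (ml/s) per (cm/s)
    cutoff: float = 0.2     # Hz

    def __post_init__(self) -> None:
        for name in ("R_a", "P_vs", "R_f", "R_o", "alpha", "cutoff"):
            if getattr(self, name) <= 0:
                raise InputError(f"SRParams.{name} must be > 0")


@dataclass(frozen=True)
class PIParams:
    """Linear regression ICP = a*PI + b (mmHg)."""

    a: float = 5.305
    b: float = 4.0


@dataclass(frozen=True)
class KashifParams:
    """Two-element model settings.

    ``window_s`` is the span over which mean ICP is assumed constant;
    the classic choice is 60 s, configurable down to a single beat.
    ``alpha`` converts CBFv to CBF as in the SR method.
    """

    window_s: float = 60.0
    alpha: float = 0.15

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise InputError("KashifParams.window_s must be > 0")


# ---------------------------------------------------------------------------
# SR method


def sr_capillary_pressure(pa_dc, q_cbf, params: SRParams | None = None):
    """Capillary pressure from the arterial resistive drop: Pa - R_a*Q."""
    params = params or SRParams()
    pa_dc = np.asarray(pa_dc, dtype=float)
    q_cbf = np.asarray(q_cbf, dtype=float)
    if not (np.all(np.isfinite(pa_dc)) and np.all(np.isfinite(q_cbf))):
        raise InputError("non-finite input to sr_capillary_pressure")
    return pa_dc - params.R_a * q_cbf


def sr_icp(p_c, params: SRParams | None = None):
    """ICP from the CSF formation/outflow divider.

    P_ic = P_vs + (P_c - P_vs) * R_o / (R_f + R_o): a linear interpolation
    between capillary and venous-sinus pressure weighted by the outflow
    resistance share.
    """
    params = params or SRParams()
    p_c = np.asarray(p_c, dtype=float)
    if not np.all(np.isfinite(p_c)):
        raise InputError("non-finite input to sr_icp")
    return params.P_vs + (p_c - params.P_vs) * params.R_o / (params.R_f + params.R_o)


def cbfv_to_cbf(cbfv, params: SRParams | None = None):
    """Flow from velocity: Q_CBF = alpha * CBFv (ml/s from cm/s)."""
    params = params or SRParams()
    cbfv = np.asarray(cbfv, dtype=float)
    if np.any(cbfv < 0):
        warnings.warn("negative CBFv values passed through cbfv_to_cbf",
                      stacklevel=2)
    return params.alpha * cbfv


def _common_grid(abp: WaveformSignal, cbfv: WaveformSignal) -> tuple[WaveformSignal, WaveformSignal]:
    """Resample cbfv onto abp's grid if the grids differ (linear interp)."""
    if np.isclose(abp.fs, cbfv.fs) and np.isclose(abp.t0, cbfv.t0) and len(abp) == len(cbfv):
        return abp, cbfv
    lo = max(abp.t0, cbfv.t0)
    hi = min(abp.t[-1], cbfv.t[-1])
    if hi - lo < 2.0:
        raise InputError("ABP and CBFv overlap by less than 2 s")
    n = int(np.floor((hi - lo) * abp.fs)) + 1
    t = lo + np.arange(n) / abp.fs
    a = np.interp(t, abp.t, abp.values)
    c = np.interp(t, cbfv.t, cbfv.values)
    return (WaveformSignal(a, abp.fs, lo, abp.units),
            WaveformSignal(c, abp.fs, lo, cbfv.units))


def sr_estimate(abp: WaveformSignal, cbfv: WaveformSignal,
                params: SRParams | None = None) -> ICPSeries:
    """Per-sample ICP estimate by the simple-resistance method.

    Pipeline: low-pass both inputs at ``params.cutoff`` (DC trend), convert
    CBFv to CBF, apply the arterial drop then the CSF divider.
    """
    params = params or SRParams()
    abp, cbfv = _common_grid(abp, cbfv)
    pa_dc = lowpass_dc(abp, params.cutoff)
    v_dc = lowpass_dc(cbfv, params.cutoff)
    q = cbfv_to_cbf(v_dc.values, params)
    p_c = sr_capillary_pressure(pa_dc.values, q, params)
    icp = sr_icp(p_c, params)
    return ICPSeries(t=abp.t, icp=icp, granularity="per-sample", method="sr")


# ---------------------------------------------------------------------------
# PI method


def pi_index(systolic, diastolic, mean):
    """Gosling pulsatility index: (systolic - diastolic)/mean."""
    systolic = np.asarray(systolic, dtype=float)
    diastolic = np.asarray(diastolic, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise InputError("pi_index requires mean > 0")
    return (systolic - diastolic) / mean


def pi_to_icp(pi, params: PIParams | None = None):
    """Linear regression ICP = a*PI + b."""
    params = params or PIParams()
    return params.a * np.asarray(pi, dtype=float) + params.b


def pi_estimate(cbfv: WaveformSignal, params: PIParams | None = None) -> ICPSeries:
    """Per-beat ICP estimate from the pulsatility index of CBFv.

    One value per complete beat, stamped at the beat onset.  Beats with a
    non-positive mean velocity are excluded (and logged): PI is undefined
    there.
    """
    params = params or PIParams()
    beats = beat_features(cbfv, detect_beats(cbfv))
    ok = beats.mean > 0
    if not np.all(ok):
        log.warning("pi_estimate: dropping %d beats with non-positive mean CBFv",
                    int(np.sum(~ok)))
    if not np.any(ok):
        raise EstimationError("no beats with positive mean CBFv")
    pi = pi_index(beats.systolic[ok], beats.diastolic[ok], beats.mean[ok])
    t = cbfv.t0 + beats.onsets[:-1][ok] / cbfv.fs
    return ICPSeries(t=t, icp=pi_to_icp(pi, params), granularity="per-beat",
                     method="pi")


# ---------------------------------------------------------------------------
# Two-element (Kashif-style) method


def _fit_beat_two_element(p: np.ndarray, q: np.ndarray, d: np.ndarray
                          ) -> tuple[float, float, float] | None:
    """Identify (C_a, R_a, P_ic) of the two-element model within one beat.

    Steps: (i) C_a by no-intercept regression of Q on dP/dt over the
    systolic upstroke (top quartile of dP/dt), where the compliance branch
    dominates; (ii) R_a from two instants of equal dP/dt -- there the
    compliance currents cancel, so R_a = dP/dQ between them; for every
    sample instant t1, each crossing of its derivative value elsewhere in
    the beat is located by linear interpolation (an exact-match tightening
    of a coarse discrete-tolerance rule) and the pair with maximal flow
    separation |Q(t1) - Q(t2)| is kept; (iii) beat ICP =
    mean(P) - R_a*mean(Q_hat) with Q_hat = Q - C_a*dP/dt; (iv) one
    refinement of C_a with the resistive flow (P - P_ic)/R_a removed,
    correcting the upstroke bias of step (i).

    Returns None when no valid instant pair exists (degenerate beat).
    """
    n = p.size
    if n < 8:
        return None
    thr = np.quantile(d, 0.75)
    up = d >= thr
    denom = float(np.sum(d[up] ** 2))
    if denom <= 0:
        return None
    ca = float(np.sum(q[up] * d[up]) / denom)

    # equal-dP/dt instant pair with maximal flow separation:
    # cross[i, j] true where d crosses d[i] inside segment [j, j+1]
    rng_d = float(d.max() - d.min())
    if rng_d <= 0:
        return None
    dl, dr = d[:-1], d[1:]
    lo = np.minimum(dl, dr)[None, :]
    hi = np.maximum(dl, dr)[None, :]
    di = d[:, None]
    cross = (di >= lo) & (di <= hi) & (np.abs(dr - dl)[None, :] > 1e-12)
    # exclude segments touching the sample itself
    idx = np.arange(n)
    seg = np.arange(n - 1)
    cross &= ~((seg[None, :] == idx[:, None]) | (seg[None, :] == idx[:, None] - 1))
    if not np.any(cross):
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (di - dl[None, :]) / (dr - dl)[None, :]
    q_star = q[:-1][None, :] + w * np.diff(q)[None, :]
    p_star = p[:-1][None, :] + w * np.diff(p)[None, :]
    dq = np.where(cross, q[:, None] - q_star, 0.0)
    i, j = np.unravel_index(int(np.argmax(np.abs(dq))), dq.shape)
    if abs(dq[i, j]) < 1e-9:
        return None
    ra = float((p[i] - p_star[i, j]) / dq[i, j])
    if not np.isfinite(ra) or ra <= 0:
        return None

    q_hat = q - ca * d
    pic = float(np.mean(p) - ra * np.mean(q_hat))
    # refinement: remove resistive flow before re-estimating the compliance
    q_cap = q - (p - pic) / ra
    ca = float(np.sum(q_cap[up] * d[up]) / denom)
    q_hat = q - ca * d
    pic = float(np.mean(p) - ra * np.mean(q_hat))
    return ca, ra, pic



def kashif_estimate(abp: WaveformSignal, cbfv: WaveformSignal,
                    params: KashifParams | None = None,
                    return_params: bool = False,
                    tau: float | None = None):
    """Windowed ICP estimate with the two-element arterial model.

    The peripheral ABP is advanced by the transit-time shift to stand in
    for cerebral arterial pressure; per beat, (C_a, R_a) are identified
    from the waveform morphology and a beat-level ICP computed; beats are
    then averaged over consecutive windows of ``window_s`` during which
    mean ICP is assumed constant.  The returned series has one value per
    usable beat (stamped at its onset) holding its window's mean.

    With ``return_params=True`` also returns per-beat arrays
    ``(C_a, R_a, ICP_beat)`` for parameter-recovery studies.  When the
    pressure input is already cerebral (e.g. model-generated P_MCA rather
    than a peripheral recording) pass ``tau=0.0`` to skip the transit-delay
    estimate; by default tau is estimated from matched systolic peaks.
    """
    params = params or KashifParams()
    abp, cbfv = _common_grid(abp, cbfv)
    if tau is None:
        tau = estimate_time_shift(abp, cbfv)
    pmca = apply_shift(abp, tau)
    # direct conversion: transient negative velocities are legitimate here
    # (compliance backflow in early diastole), no warning needed
    q = params.alpha * cbfv.values

    beats = detect_beats(pmca)
    fs = pmca.fs
    dpdt = np.gradient(pmca.values) * fs   # full-signal central differences
    t_beat, ca_l, ra_l, pic_l = [], [], [], []
    for i in range(beats.n_complete):
        a, b = beats.onsets[i], beats.onsets[i + 1]
        if np.mean(cbfv.values[a:b]) <= 0:
            log.info("kashif: beat %d skipped (non-positive mean CBFv)", i)
            continue
        fit = _fit_beat_two_element(pmca.values[a:b], q[a:b], dpdt[a:b])
        if fit is None:
            log.info("kashif: beat %d skipped (degenerate morphology)", i)
            continue
        ca, ra, pic = fit
        t_beat.append(pmca.t0 + a / fs)
        ca_l.append(ca)
        ra_l.append(ra)
        pic_l.append(pic)
    if not pic_l:
        raise EstimationError("all beats skipped; cannot estimate ICP")

    t_beat = np.asarray(t_beat)
    pic_beat = np.asarray(pic_l)
    win = np.floor((t_beat - t_beat[0]) / params.window_s).astype(int)
    icp = np.empty_like(pic_beat)
    for wdx in np.unique(win):
        m = win == wdx
        icp[m] = pic_beat[m].mean()
    series = ICPSeries(t=t_beat, icp=icp, granularity="per-beat", method="kashif")
    if return_params:
        return series, np.asarray(ca_l), np.asarray(ra_l), pic_beat
    return series
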