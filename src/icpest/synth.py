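"""Synthetic ABP / CBFv waveform generation, including Valsalva trials.

The generator produces pulsatile arterial pressure with a controllable mean,
pulse pressure, heart rate and beat-to-beat jitter, plus an optional
Valsalva-maneuver (VM) episode.  A VM raises intrathoracic pressure, which
propagates to the cerebral venous outflow; here that is modelled as a ramped
offset on the central-venous source of the circuit simulator (and optionally
on systemic ABP itself).  True reference ICP and CBF for a trial come from
driving the full intracranial circuit with the generated ABP, so the
estimators can be scored against a mechanistically consistent ground truth
without any recorded data.

Each beat is a fast quasi-Gaussian systolic upstroke followed by an
exponential diastolic runoff -- a single systolic peak and monotone decay,
which is all the downstream DC-trend methods are sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .core import ConfigError, WaveformSignal
from .ursino import SimResult, UrsinoParams, simulate

__all__ = ["SynthConfig", "synth_abp", "synth_vm_trial"]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic waveform generator.

    Attributes
    ----------
    duration : float
        Record length, seconds.
    fs : float
        Sampling rate, Hz.  100 Hz default: the estimators operate on the
        sub-0.2 Hz trend, so acquisition-grade rates buy nothing here.
    heart_rate : float
        Beats per minute.
    mean_abp : float
        Target time-averaged ABP, mmHg.
    pulse_pressure : float
        Systolic minus diastolic pressure, mmHg.
    hr_jitter : float
        Fractional standard deviation of the beat-to-beat interval.
    noise_std : float
        Additive Gaussian measurement noise on ABP, mmHg.
    cbfv_noise_std : float
        Additive Gaussian noise on derived CBFv, cm/s.
    slow_abp_std : float
        Standard deviation (mmHg) of slow physiological ABP variability
        (Mayer waves, vasomotion): an Ornstein-Uhlenbeck process with
        ``slow_tau`` correlation time, demeaned over the record so the
        target mean is preserved.
    slow_cbfv_std : float
        Standard deviation (cm/s) of slow CBFv variability independent of
        ABP (cerebral vasomotion, probe-angle drift), same process.
    slow_tau : float
        Correlation time of the slow-variability processes, seconds.
    resp_rate : float
        Respiratory rate, Hz.
    resp_abp_amp : float
        Amplitude (mmHg) of the respiratory oscillation of the ABP
        baseline, random phase per record.
    vm_window : tuple or None
        (start, end) seconds of the VM episode, or None for none.
    vm_abp_delta : float
        Systemic pressure offset during VM, mmHg (1-s linear ramps).
    vm_pvs_delta : float
        Venous/intrathoracic pressure rise during VM, mmHg.
    seed : int
        Seed of the generator's private RNG; identical config implies
        bit-identical output.
    """

    duration: float = 45.0
    fs: float = 100.0
    heart_rate: float = 70.0
    mean_abp: float = 90.0
    pulse_pressure: float = 40.0
    hr_jitter: float = 0.03
    noise_std: float = 1.0
    cbfv_noise_std: float = 1.0
    slow_abp_std: float = 2.0
    slow_cbfv_std: float = 1.0
    slow_tau: float = 10.0
    resp_rate: float = 0.25
    resp_abp_amp: float = 3.0
    vm_window: tuple[float, float] | None = None
    vm_abp_delta: float = 0.0
    vm_pvs_delta: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "fs", "heart_rate", "slow_tau", "resp_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"SynthConfig.{name} must be > 0")
        for name in ("pulse_pressure", "hr_jitter", "noise_std",
                     "cbfv_noise_std", "slow_abp_std", "slow_cbfv_std",
                     "resp_abp_amp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"SynthConfig.{name} must be >= 0")
        if self.vm_window is not None:
            s, e = self.vm_window
            if not (0 <= s < e <= self.duration):
                raise ConfigError(
                    f"SynthConfig.vm_window {self.vm_window} must lie within "
                    f"[0, {self.duration}]")


def _beat_shape(t: np.ndarray, T: float) -> np.ndarray:
    """Normalised pulse over one beat of length T: 0 at both ends, peak 1.

    Gaussian upstroke (sigma 45 ms, realistic finger-ABP rise time) into an
    exponential diastolic decay; the residual end value is removed with a
    linear baseline so consecutive beats join continuously.
    """
    t_peak = 0.09 + 0.04 * T       # systolic peak a little after onset
    sigma = 0.045
    tau = 0.35 * T                 # diastolic runoff constant
    g = np.where(
        t < t_peak,
        np.exp(-0.5 * ((t - t_peak) / sigma) ** 2),
        np.exp(-(t - t_peak) / tau),
    )
    # force exact zeros at the beat edges
    g0 = np.exp(-0.5 * (t_peak / sigma) ** 2)
    gT = np.exp(-(T - t_peak) / tau)
    base = g0 + (gT - g0) * (t / T)
    g = g - base
    m = g.max()
    return g / m if m > 0 else g


def _ou_process(rng: np.random.Generator, n: int, fs: float, std: float,
                tau: float) -> np.ndarray:
    """Demeaned Ornstein-Uhlenbeck path: slow physiological variability.

    Stationary initialisation, correlation time ``tau``; the record mean is
    subtracted so the process perturbs window-to-window levels without
    moving the whole-record mean.
    """
    if std == 0:
        return np.zeros(n)
    a = np.exp(-1.0 / (fs * tau))
    innov = std * np.sqrt(1.0 - a * a) * rng.standard_normal(n)
    innov[0] = std * rng.standard_normal()
    x = lfilter([1.0], [1.0, -a], innov)
    return x - x.mean()


def _ramped_box(t: np.ndarray, start: float, end: float, ramp: float = 1.0) -> np.ndarray:
    """Unit box over [start, end] with linear ramps of ``ramp`` seconds."""
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((end - t) / ramp, 0.0, 1.0)
    return np.minimum(up, down)


def synth_abp(config: SynthConfig) -> WaveformSignal:
    """Generate a pulsatile ABP waveform per ``config``.

    The pre-noise time average is held within 2 mmHg of ``mean_abp`` by
    construction (each beat's offset is chosen from the shape's own mean),
    and the beat count over the record equals duration*heart_rate/60 up to
    edge effects when ``hr_jitter`` is zero.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    T0 = 60.0 / config.heart_rate

    if config.pulse_pressure == 0:
        x = np.full(n, float(config.mean_abp))
    else:
        x = np.empty(n)
        x.fill(np.nan)
        # random initial phase so records do not all start at a beat onset
        onset = -rng.uniform(0.0, T0)
        while onset < config.duration:
            T = T0 * max(0.3, 1.0 + config.hr_jitter * rng.standard_normal())
            i0 = max(0, int(np.ceil(onset * config.fs)))
            i1 = min(n, int(np.ceil((onset + T) * config.fs)))
            if i1 > i0:
                tb = t[i0:i1] - onset
                g = _beat_shape(tb, T)
                # per-beat DC offset keeps the beat mean at mean_abp
                gm = _beat_shape(np.arange(int(round(T * config.fs))) / config.fs, T).mean()
                x[i0:i1] = config.mean_abp + config.pulse_pressure * (g - gm)
            onset += T

    if config.vm_window is not None and config.vm_abp_delta != 0.0:
        s, e = config.vm_window
        x = x + config.vm_abp_delta * _ramped_box(t, s, e)

    if config.resp_abp_amp > 0:
        phase = rng.uniform(0.0, 2 * np.pi)
        x = x + config.resp_abp_amp * np.sin(2 * np.pi * config.resp_rate * t + phase)

    x = x + _ou_process(rng, n, config.fs, config.slow_abp_std, config.slow_tau)

    if config.noise_std > 0:
        x = x + config.noise_std * rng.standard_normal(n)

    return WaveformSignal(x, config.fs, 0.0, "mmHg")


def vm_pvs_offset(config: SynthConfig) -> np.ndarray:
    """Central-venous pressure offset trace implied by the VM episode."""
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    if config.vm_window is None or config.vm_pvs_delta == 0.0:
        return np.zeros(n)
    s, e = config.vm_window
    return config.vm_pvs_delta * _ramped_box(t, s, e)


def synth_vm_trial(
    config: SynthConfig,
    params: UrsinoParams | None = None,
    alpha: float = 0.15,
) -> tuple[WaveformSignal, WaveformSignal, WaveformSignal]:
    """Generate one Valsalva trial: (ABP, CBFv, true ICP).

    ABP comes from :func:`synth_abp`; the intracranial circuit is then
    driven with that ABP while the VM adds ``vm_pvs_delta`` to the venous
    source over ``vm_window``.  CBFv is the simulated CBF divided by the
    flow/velocity proportionality ``alpha`` plus measurement noise; the
    returned ICP is the simulator's intracranial node pressure.

    For any ``vm_pvs_delta > 0`` the passive network guarantees the true
    ICP averages higher inside the VM window than at rest.

    Returns
    -------
    (abp, cbfv, icp_true) : WaveformSignal triple
        mmHg, cm/s, mmHg on the common grid.
    """
    if config.vm_window is None:
        config = replace(config, vm_window=(15.0, 30.0))
    abp = synth_abp(config)
    sim: SimResult = simulate(abp, params, vm_pvs_offset(config))
    cbfv_vals = sim.Q_CBF / alpha
    # independent stream so ABP samples are unchanged by these options
    rng = np.random.default_rng((config.seed, 0x5EED))
    cbfv_vals = cbfv_vals + _ou_process(rng, cbfv_vals.size, config.fs,
                                        config.slow_cbfv_std, config.slow_tau)
    if config.cbfv_noise_std > 0:
        cbfv_vals = cbfv_vals + config.cbfv_noise_std * rng.standard_normal(cbfv_vals.size)
    cbfv = WaveformSignal(cbfv_vals, config.fs, 0.0, "cm/s")
    icp = WaveformSignal(sim.Pic, config.fs, 0.0, "mmHg")
    return abp, cbfv, icp
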