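"""Valsalva-trial evaluation harness.

The experimental protocol is a 45-s trial: 15 s rest, 15 s Valsalva
maneuver (VM), 15 s rest.  The first 5 s of the VM phase and the first
10 s of the recovery rest are discarded as transition periods, leaving a
10-s VM analysis window and a 5-s late-rest window.  Per trial the mean
estimated ICP in the rest and VM windows is computed; per subject (a set
of trials) a one-tailed paired t-test asks whether the VM mean exceeds the
rest mean, i.e. whether the estimator detects the transient intracranial
hypertension the maneuver induces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .core import ICPSeries, InputError, WaveformSignal

__all__ = [
    "TrialSegmentation", "PhaseStats", "segment_trial", "rmse",
    "phase_means", "paired_t_one_tailed", "run_vm_experiment", "VMReport",
]

log = logging.getLogger(__name__)

TRIAL_DURATION = 45.0
_PHASES = {  # seconds, half-open
    "rest1": (0.0, 15.0),
    "vm_full": (15.0, 30.0),
    "vm_analysis": (20.0, 30.0),
    "rest2_full": (30.0, 45.0),
    "rest2_analysis": (40.0, 45.0),
}


@dataclass(frozen=True)
class TrialSegmentation:
    """Sample-index windows (half-open) of the 45-s VM protocol."""

    fs: float
    rest1: tuple[int, int]
    vm_full: tuple[int, int]
    vm_analysis: tuple[int, int]
    rest2_full: tuple[int, int]
    rest2_analysis: tuple[int, int]


def segment_trial(duration: float, fs: float) -> TrialSegmentation:
    """Windows of the 45-s protocol at sampling rate ``fs``.

    The protocol is fixed: trials of any other duration are rejected
    rather than rescaled, because the phase timings are part of the
    experimental design.
    """
    if fs <= 0:
        raise InputError(f"fs must be > 0, got {fs}")
    if abs(duration - TRIAL_DURATION) > 1e-9:
        raise InputError(
            f"protocol requires 45-s trials, got {duration} s")
    idx = {k: (int(round(a * fs)), int(round(b * fs)))
           for k, (a, b) in _PHASES.items()}
    return TrialSegmentation(fs=fs, **idx)


def rmse(est: ICPSeries, ref: ICPSeries) -> float:
    """Root-mean-square error between two ICP series.

    Both series are resampled by previous-value hold onto the denser grid
    over their overlapping time support.
    """
    lo = max(est.t[0], ref.t[0])
    hi = min(est.t[-1], ref.t[-1])
    if hi <= lo:
        raise InputError("ICP series do not overlap in time")
    # denser of the two grids restricted to the overlap
    src = est if len(est) >= len(ref) else ref
    m = (src.t >= lo) & (src.t <= hi)
    t = src.t[m]
    if t.size == 0:
        raise InputError("empty overlap after resampling")
    e = est.resample_hold(t)
    r = ref.resample_hold(t)
    return float(np.sqrt(np.mean((e - r) ** 2)))


def _window_mean(icp: ICPSeries, seg: TrialSegmentation,
                 window: tuple[int, int]) -> float:
    lo, hi = window[0] / seg.fs, window[1] / seg.fs
    if icp.granularity == "per-beat":
        # a beat belongs to the window containing its onset
        m = (icp.t >= lo) & (icp.t < hi)
    else:
        m = (icp.t >= lo) & (icp.t < hi)
    if not np.any(m):
        raise InputError(f"window [{lo}, {hi}) s contains no samples")
    return float(np.mean(icp.icp[m]))


def phase_means(icp: ICPSeries, seg: TrialSegmentation) -> tuple[float, float]:
    """(rest_mean, vm_mean) of an ICP series over the protocol windows.

    Rest is the initial 15-s phase (uncontaminated by VM recovery); VM is
    the analysis window that excludes the first 5 s of the maneuver.
    """
    return (_window_mean(icp, seg, seg.rest1),
            _window_mean(icp, seg, seg.vm_analysis))


def paired_t_one_tailed(rest: Sequence[float], vm: Sequence[float]
                        ) -> tuple[float, float, bool]:
    """One-tailed paired t-test of vm > rest.

    Returns (t, p, significant) with t = mean(d)/(sd(d)/sqrt(n)) on
    d = vm - rest, df = n - 1, upper-tail p, significance at 0.05.

    Raises
    ------
    InputError
        On mismatched lengths, n < 2, or zero-variance nonzero differences
        (the statistic would be infinite).
    """
    rest = np.asarray(rest, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if rest.shape != vm.shape or rest.ndim != 1:
        raise InputError("rest and vm must be equal-length 1-D vectors")
    n = rest.size
    if n < 2:
        raise InputError(f"paired t-test needs n >= 2, got n={n}")
    d = vm - rest
    sd = float(np.std(d, ddof=1))
    md = float(np.mean(d))
    if sd == 0.0:
        if md == 0.0:
            return 0.0, 0.5, False
        raise InputError("zero-variance nonzero differences: t is infinite")
    t = md / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p, p < 0.05


@dataclass
class PhaseStats:
    """Per-method outcome of a VM experiment."""

    rest_means: np.ndarray
    vm_means: np.ndarray
    rest2_means: np.ndarray
    t: float | None
    p: float | None
    significant: bool | None
    note: str = ""

    def summary(self) -> str:
        r, v = self.rest_means, self.vm_means
        line = (f"rest {np.mean(r):.1f} ± {np.std(r, ddof=1):.1f}  "
                f"VM {np.mean(v):.1f} ± {np.std(v, ddof=1):.1f}")
        if self.significant:
            line += "*"
        return line


@dataclass
class VMReport:
    """Outcome of :func:`run_vm_experiment` across methods."""

    methods: dict[str, PhaseStats]
    dropped: list[tuple[int, str, str]] = field(default_factory=list)

    def to_markdown(self) -> str:
        """Comparison table: mean +/- sd per phase per method.

        An asterisk marks one-tailed paired significance (p < 0.05) of
        VM over rest, mirroring the conventional presentation.
        """
        lines = ["| Method | Resting state | VM state | t | p |",
                 "|---|---|---|---|---|"]
        for name, res in self.methods.items():
            r, v = res.rest_means, res.vm_means
            star = "*" if res.significant else ""
            tcell = "--" if res.t is None else f"{res.t:.2f}"
            pcell = res.note or (f"{res.p:.4f}{star}" if res.p is not None else "--")
            lines.append(
                f"| {name} | {np.mean(r):.1f} ± {np.std(r, ddof=1):.1f} "
                f"| {np.mean(v):.1f} ± {np.std(v, ddof=1):.1f} "
                f"| {tcell} | {pcell} |")
        for idx, name, reason in self.dropped:
            lines.append(f"\n_dropped: trial {idx} ({name}): {reason}_")
        return "\n".join(lines)


def run_vm_experiment(
    trials: Sequence[tuple[WaveformSignal, WaveformSignal]],
    methods: dict[str, Callable[[WaveformSignal, WaveformSignal], ICPSeries]],
) -> VMReport:
    """Score ICP estimators on a set of 45-s VM trials (one subject).

    Parameters
    ----------
    trials : sequence of (abp, cbfv)
        Each a 45-s recording following the rest/VM/rest protocol.
    methods : dict name -> callable(abp, cbfv) -> ICPSeries
        The estimators to compare.

    Returns
    -------
    VMReport
        Per method: per-trial phase means, the paired one-tailed t-test
        of VM > rest, and a markdown comparison table.  Trials where an
        estimator fails are dropped for that method with a logged reason.
    """
    out: dict[str, PhaseStats] = {}
    dropped: list[tuple[int, str, str]] = []
    for name, fn in methods.items():
        rest, vm, rest2 = [], [], []
        for k, (abp, cbfv) in enumerate(trials):
            try:
                seg = segment_trial(round(abp.duration, 6), abp.fs)
                icp = fn(abp, cbfv)
                r, v = phase_means(icp, seg)
                r2 = _window_mean(icp, seg, seg.rest2_analysis)
            except Exception as exc:  # noqa: BLE001 - trial-level isolation
                log.warning("trial %d dropped for %s: %s", k, name, exc)
                dropped.append((k, name, str(exc)))
                continue
            rest.append(r)
            vm.append(v)
            rest2.append(r2)
        rest_a, vm_a, rest2_a = map(np.asarray, (rest, vm, rest2))
        if len(rest) < 2:
            out[name] = PhaseStats(rest_a, vm_a, rest2_a, None, None, None,
                                     note=f"t-test skipped: n={len(rest)} < 2")
        else:
            try:
                t, p, sig = paired_t_one_tailed(rest_a, vm_a)
                out[name] = PhaseStats(rest_a, vm_a, rest2_a, t, p, sig)
            except InputError as exc:
                out[name] = PhaseStats(rest_a, vm_a, rest2_a, None, None,
                                         None, note=str(exc))
    return VMReport(methods=out, dropped=dropped)
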