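"""Lumped-parameter intracranial circuit simulator (Ursino model).

The intracranial hemo- and hydro-dynamics are modelled as a linear electrical
analog: pressures are voltages (mmHg), flows are currents (ml/s), vascular
segments are resistors (mmHg·s/ml) and vessel/CSF storage are capacitors
(ml/mmHg).  The arterial terminal is driven by the ABP waveform P_a(t) and
the downstream terminal by central venous pressure P_cv (optionally offset,
e.g. to emulate the intrathoracic pressure rise of a Valsalva maneuver).

Topology (series vascular path with shunt compliances)::

    P_a --R1-- P1 --R2-- P2(=P_c) --Rpv-- Pv --Rdv-- Pvs --Rve-- P_cv
                |         |    |           |          |
               C1        C2    Rf         Cvi        Cve (to ambient)
                \\        /     |           |
                 \\      /     P_ic --Ro-- Pvs
                  \\    /       |
                   P_ic ------ Cic (to ambient)

C1, C2 and Cvi reference the intracranial pressure node P_ic (vessels are
distended against the CSF space), Cic and Cve reference ambient pressure
(taken as 0).  The CSF circuit is formation through Rf from the capillary
node P_c into the CSF space P_ic and outflow through Ro into the venous
sinus Pvs.  All elements are linear and time-invariant.

Two solvers are provided:

* :func:`steady_state` -- the purely resistive network (compliances
  open-circuited), solved by nodal analysis.  This is the DC behaviour and
  serves as the analytic oracle for the simple-resistance estimator.
* :func:`simulate` -- the full dynamic circuit.  Because the system is LTI,
  it is integrated exactly on the uniform sample grid by first-order-hold
  matrix-exponential discretization; the per-mode recursions run as IIR
  filters, which keeps 45-s trials at sub-millisecond cost and is immune to
  the stiffness introduced by the CSF resistances (Rf, Ro are ~3 orders of
  magnitude above the vascular resistances).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from functools import lru_cache

import numpy as np
from scipy import linalg, signal

from .core import InputError, NumericalError, WaveformSignal

__all__ = ["UrsinoParams", "SimResult", "steady_state", "simulate"]

# state ordering for the 5 internal pressure nodes
_NODES = ("P1", "P2", "Pv", "Pvs", "Pic")


@dataclass(frozen=True)
class UrsinoParams:
    """Constants of the intracranial circuit.

    Defaults are the standard parameterization of the original model:
    resistances in mmHg·s/ml, compliances in ml/mmHg, Pcv in mmHg.
    """

    R1: float = 2.4      # proximal arterial resistance
    C1: float = 0.03     # proximal arterial compliance
    R2: float = 3.64     # distal arterial resistance
    C2: float = 0.06     # distal arterial compliance
    Rf: float = 2380.0   # CSF formation resistance
    Ro: float = 526.0    # CSF outflow resistance
    Rpv: float = 0.88    # proximal venous resistance
    Cvi: float = 0.46    # proximal venous compliance
    Rdv: float = 0.614   # bridging vein resistance
    Rve: float = 0.16    # extracranial venous resistance
    Cve: float = 2.34    # extracranial venous compliance
    Pcv: float = 4.0     # central venous pressure
    Cic: float = 0.95    # intracranial compliance

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "Pcv" and v <= 0:
                raise InputError(f"UrsinoParams.{f.name} must be > 0, got {v}")


@dataclass
class SimResult:
    """Node-pressure traces and arterial inflow from :func:`simulate`."""

    t: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    Pv: np.ndarray
    Pvs: np.ndarray
    Pic: np.ndarray
    Q_CBF: np.ndarray

    @property
    def Pc(self) -> np.ndarray:
        """Capillary pressure alias: the P2 node."""
        return self.P2


def _conductance(params: UrsinoParams) -> tuple[np.ndarray, np.ndarray]:
    """Nodal conductance matrix G and source-injection matrix B.

    G x = B u with x = (P1, P2, Pv, Pvs, Pic) and u = (Pa, Pcv_effective)
    expresses Kirchhoff current balance of the resistive part.
    """
    p = params
    g1, g2, gpv, gdv, gve = 1 / p.R1, 1 / p.R2, 1 / p.Rpv, 1 / p.Rdv, 1 / p.Rve
    gf, go = 1 / p.Rf, 1 / p.Ro
    G = np.array([
        [g1 + g2, -g2,       0.0,       0.0,            0.0],
        [-g2,     g2 + gpv + gf, -gpv,  0.0,            -gf],
        [0.0,     -gpv,      gpv + gdv, -gdv,           0.0],
        [0.0,     0.0,       -gdv,      gdv + gve + go, -go],
        [0.0,     -gf,       0.0,       -go,            gf + go],
    ])
    B = np.array([
        [g1, 0.0],
        [0.0, 0.0],
        [0.0, 0.0],
        [0.0, gve],
        [0.0, 0.0],
    ])
    return G, B


def _capacitance(params: UrsinoParams) -> np.ndarray:
    """Nodal capacitance matrix (positive definite; Cic, Cve ground it)."""
    p = params
    C = np.zeros((5, 5))
    for node, cap in ((0, p.C1), (1, p.C2), (2, p.Cvi)):  # caps to Pic
        C[node, node] += cap
        C[node, 4] -= cap
        C[4, node] -= cap
        C[4, 4] += cap
    C[3, 3] += p.Cve
    C[4, 4] += p.Cic
    return C


def steady_state(pa: float, params: UrsinoParams | None = None,
                 pvs_offset: float = 0.0) -> dict[str, float]:
    """Resistive (DC) solution of the circuit at constant driving pressures.

    Compliances carry no current at DC, so the node pressures follow from
    nodal analysis of the resistor network alone.

    Parameters
    ----------
    pa : float
        Arterial terminal pressure, mmHg.
    params : UrsinoParams, optional
        Circuit constants; defaults used when omitted.
    pvs_offset : float
        Added to the central venous source (mmHg), e.g. a Valsalva
        intrathoracic pressure rise.

    Returns
    -------
    dict
        Keys ``P1, P2, Pv, Pvs, Pic`` (mmHg) and ``Q_CBF`` (ml/s, the flow
        entering through R1).
    """
    params = params or UrsinoParams()
    G, B = _conductance(params)
    u = np.array([pa, params.Pcv + pvs_offset], dtype=float)
    try:
        x = linalg.solve(G, B @ u, assume_a="sym")
    except linalg.LinAlgError as exc:  # pragma: no cover - needs broken params
        raise NumericalError(f"singular resistive network: {exc}") from exc
    out = {name: float(v) for name, v in zip(_NODES, x)}
    out["Q_CBF"] = (pa - out["P1"]) / params.R1
    return out


@lru_cache(maxsize=16)
def _discretize(params: UrsinoParams, dt: float):
    """First-order-hold discretization of C dx/dt = -G x + B u.

    Returns (Ad, Bd, Cd, Dd) of the equivalent discrete state-space whose
    output y[k] equals the node-pressure vector at sample k, plus the
    eigendecomposition of Ad used for fast filtering.
    """
    G, B = _conductance(params)
    C = _capacitance(params)
    Cinv = linalg.inv(C)
    A = -Cinv @ G
    Bc = Cinv @ B
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete(
        (A, Bc, np.eye(5), np.zeros((5, 2))), dt, method="foh")
    w, V = linalg.eig(Ad)
    if np.linalg.cond(V) > 1e12:  # pragma: no cover - defensive
        raise NumericalError("near-defective state matrix; cannot diagonalize")
    return Ad, Bd, Cd, Dd, w, V


def simulate(abp: WaveformSignal, params: UrsinoParams | None = None,
             pvs_offset: WaveformSignal | np.ndarray | None = None) -> SimResult:
    """Integrate the dynamic circuit driven by an ABP waveform.

    Parameters
    ----------
    abp : WaveformSignal
        Arterial pressure at the input terminal, uniformly sampled, > 2 s.
    params : UrsinoParams, optional
        Circuit constants.
    pvs_offset : WaveformSignal or ndarray, optional
        Time-varying offset (mmHg) added to the central venous source, on
        the same grid as ``abp``.  Used to emulate Valsalva episodes.

    Returns
    -------
    SimResult
        Node pressures and arterial inflow Q_CBF on the input grid.

    Notes
    -----
    The LTI system is advanced with the exact first-order-hold recursion
    (input treated as piecewise linear between samples), diagonalised so the
    five modal recursions run as vectorised IIR filters.  The initial state
    is the resistive steady state at the time-averaged input over the first
    few seconds, so traces start settled rather than at an arbitrary point
    of the pulse.
    """
    params = params or UrsinoParams()
    if abp.duration <= 2.0:
        raise InputError("abp must be longer than 2 s")
    dt = 1.0 / abp.fs
    n = len(abp)

    if pvs_offset is None:
        off = np.zeros(n)
    else:
        off = pvs_offset.values if isinstance(pvs_offset, WaveformSignal) else np.asarray(pvs_offset, float)
        if off.shape != (n,):
            raise InputError("pvs_offset must be on the same grid as abp")
        if isinstance(pvs_offset, WaveformSignal) and not np.isclose(pvs_offset.fs, abp.fs):
            raise InputError("pvs_offset must share abp's sampling rate")

    u = np.column_stack([abp.values, params.Pcv + off])  # (n, 2)

    Ad, Bd, Cd, Dd, w, V = _discretize(params, dt)

    # settle the initial condition at the DC point of the early input
    n0 = max(2, min(n, int(round(5.0 * abp.fs))))
    u0 = u[:n0].mean(axis=0)
    # discrete fixed point for constant input u0
    xd0 = linalg.solve(np.eye(5) - Ad, Bd @ u0)

    # modal recursion z[k+1] = w z[k] + f[k+1], run via lfilter per mode
    f = u @ (linalg.solve(V, Bd)).T            # (n, 5) complex forcing
    z0 = linalg.solve(V, xd0)
    z = np.empty((n, 5), dtype=complex)
    for m in range(5):
        # x[k] = w^k x0 + sum_{j<k} w^(k-1-j) f[j]  -> shift forcing by one
        drive = np.concatenate(([z0[m]], f[:-1, m]))
        z[:, m] = signal.lfilter([1.0], [1.0, -w[m]], drive)
    x = (z @ V.T).real                         # (n, 5) discrete states
    y = x @ Cd.T + u @ Dd.T                    # node pressures

    if not np.all(np.isfinite(y)):
        raise NumericalError("simulation diverged (non-finite node pressures)")

    q = (abp.values - y[:, 0]) / params.R1
    return SimResult(t=abp.t, P1=y[:, 0], P2=y[:, 1], Pv=y[:, 2],
                     Pvs=y[:, 3], Pic=y[:, 4], Q_CBF=q)
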