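"""Deterministic simulation of the combined remimazolam / CNS 7054 PK/PD
system for one subject and one regimen.

The structural model is a linear seven-state system: a three-compartment
model for the parent drug (amounts A1, A2, A3 in mg), a transit compartment
for metabolite formation (A4), a two-compartment model for the metabolite
(A5, A6), and an effect compartment whose concentration Ce (ng/mL) lags the
parent central concentration with rate constant ke0. All parent elimination
feeds the transit compartment (complete first-order conversion to the
metabolite on a mass basis). Plasma concentrations are reported in ng/mL,
i.e. 1000 x amount/volume with amounts in mg and volumes in L.

Two solution routes are provided and cross-checked against each other:

* :func:`simulate` integrates the ODEs numerically (LSODA) with dose events
  inserted as hard breakpoints;
* :func:`analytic_solution` exploits linearity and solves each inter-dose
  segment exactly with the matrix exponential (via eigendecomposition, with
  a dense ``expm`` fallback for defective matrices).

The analytic route is also the fast prediction engine used by the
estimation, diagnostics and dose-design layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .parameters import PKParameters, PDParameters
from .regimen import Regimen

__all__ = [
    "SimulationResult",
    "system_matrix",
    "derivatives",
    "bis_from_ce",
    "steady_state_concentration",
    "simulate",
    "analytic_solution",
    "solve_linear_system",
]

N_PK_STATES = 6   # A1..A6 (mg)
N_STATES = 7      # + Ce (ng/mL)
IDX_CE = 6

MG_PER_L_TO_NG_PER_ML = 1000.0


def system_matrix(pk: PKParameters, ke0: float | None = None) -> np.ndarray:
    """State matrix of the linear system acting on amounts (mg) and,
    if ``ke0`` is given, on the effect-site concentration (ng/mL)."""
    n = N_PK_STATES if ke0 is None else N_STATES
    A = np.zeros((n, n))
    k10 = pk.CL_p / pk.V1
    A[0, 0] = -(pk.CL_p + pk.Q2 + pk.Q3) / pk.V1
    A[0, 1] = pk.Q2 / pk.V2
    A[0, 2] = pk.Q3 / pk.V3
    A[1, 0] = pk.Q2 / pk.V1
    A[1, 1] = -pk.Q2 / pk.V2
    A[2, 0] = pk.Q3 / pk.V1
    A[2, 2] = -pk.Q3 / pk.V3
    A[3, 0] = k10
    A[3, 3] = -pk.K_tr
    A[4, 3] = pk.K_tr
    A[4, 4] = -(pk.CL_m + pk.Q4) / pk.V5
    A[4, 5] = pk.Q4 / pk.V6
    A[5, 4] = pk.Q4 / pk.V5
    A[5, 5] = -pk.Q4 / pk.V6
    if ke0 is not None:
        if not ke0 > 0:
            raise ValueError("ke0 must be > 0")
        A[IDX_CE, 0] = ke0 * MG_PER_L_TO_NG_PER_ML / pk.V1
        A[IDX_CE, IDX_CE] = -ke0
    return A


def derivatives(state: np.ndarray, t: float, pk: PKParameters, ke0: float,
                infusion_rate: float = 0.0) -> np.ndarray:
    """Time derivative of the full 7-state vector.

    ``state`` is (A1..A6 in mg, Ce in ng/mL); ``infusion_rate`` is the
    zero-order input into the parent central compartment, mg/min.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have length {N_STATES}")
    A = system_matrix(pk, ke0)
    dx = A @ state
    dx[0] += infusion_rate
    return dx


def bis_from_ce(pd_params: PDParameters, ce) -> np.ndarray | float:
    """Static inhibitory sigmoid (Hill) response: BIS as a function of the
    effect-site concentration Ce (ng/mL).

    ``BIS = BIS_baseline - Imax * Ce^Hill / (IC50^Hill + Ce^Hill)``
    """
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValueError("Ce must be >= 0")
    # computed via (IC50/Ce)^Hill so large Ce^Hill cannot overflow
    with np.errstate(over="ignore", divide="ignore"):
        ratio = np.where(ce_arr > 0, pd_params.IC50 / np.where(
            ce_arr > 0, ce_arr, 1.0), np.inf)
        frac = 1.0 / (1.0 + ratio ** pd_params.Hill)
    out = pd_params.BIS_baseline - pd_params.Imax * frac
    return out if out.shape else float(out)


def steady_state_concentration(rate: float, clearance: float) -> float:
    """Constant-infusion steady-state plasma concentration, ng/mL
    (rate in mg/min, clearance in L/min)."""
    if not clearance > 0:
        raise ValueError("clearance must be > 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return MG_PER_L_TO_NG_PER_ML * rate / clearance


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories on a time grid: parent and metabolite central plasma
    concentrations, effect-site concentration (all ng/mL) and BIS."""

    time: np.ndarray
    cp: np.ndarray
    cm: np.ndarray
    ce: np.ndarray
    bis: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time_min": self.time,
            "cp_ng_ml": self.cp,
            "cm_ng_ml": self.cm,
            "ce_ng_ml": self.ce,
        }
        if self.bis is not None:
            cols["bis"] = self.bis
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Dose-event bookkeeping
# ---------------------------------------------------------------------------

def _event_schedule(regimen: Regimen, t_end: float):
    """Break [0, t_end] into segments of constant infusion rate.

    Returns (breakpoints, rates, boluses): ``rates[i]`` applies on
    ``[breakpoints[i], breakpoints[i+1])``; ``boluses`` maps a time to the
    total instantaneous amount administered at that time.
    """
    cuts = {0.0, float(t_end)}
    boluses: dict[float, float] = {}
    infusions = []
    for ev in regimen.events:
        if ev.duration == 0:
            boluses[ev.time] = boluses.get(ev.time, 0.0) + ev.amount
            cuts.add(ev.time)
        else:
            infusions.append(ev)
            cuts.add(ev.time)
            cuts.add(min(ev.time + ev.duration, t_end) if ev.time <= t_end
                     else ev.time)
    breakpoints = np.array(sorted(t for t in cuts if t <= t_end))
    if breakpoints[-1] < t_end:
        breakpoints = np.append(breakpoints, t_end)
    rates = np.zeros(len(breakpoints) - 1)
    for ev in infusions:
        active = (breakpoints[:-1] >= ev.time) & \
                 (breakpoints[:-1] < ev.time + ev.duration)
        rates[active] += ev.rate
    return breakpoints, rates, boluses


# ---------------------------------------------------------------------------
# Analytic (matrix-exponential) route
# ---------------------------------------------------------------------------

_PHI_EPS = 1e-10


def _phi(w: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """(exp(w*tau) - 1)/w elementwise, with the tau limit as w*tau -> 0."""
    z = np.multiply.outer(tau, w)
    small = np.abs(z) < _PHI_EPS
    out = np.where(small, np.asarray(tau)[..., None] * (1.0 + z / 2.0),
                   np.expm1(np.where(small, 1.0, z)) /
                   np.where(small, 1.0, w))
    return out


def solve_linear_system(A: np.ndarray, regimen: Regimen,
                        times: np.ndarray) -> np.ndarray:
    """Exact trajectory of ``x' = A x + rate(t) e1`` under the regimen's
    piecewise-constant input, starting from the zero state.

    Evaluation at a bolus time returns the post-dose state. Returns an array
    of shape ``(len(times), n_states)``.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if times.size and times[0] < 0:
        raise ValueError("times must be >= 0")
    t_end = max(regimen.end_time, times[-1] if times.size else 0.0)
    if t_end <= 0.0:    # all doses and observations at t = 0
        t_end = 1.0
    breakpoints, rates, boluses = _event_schedule(regimen, t_end)

    n = A.shape[0]
    try:
        w, V = np.linalg.eig(A)
        Vinv = np.linalg.inv(V)
        ill = (not np.all(np.isfinite(V))) or \
            np.linalg.cond(V) > 1e12
    except np.linalg.LinAlgError:
        ill = True
    if ill:
        return _solve_linear_expm(A, breakpoints, rates, boluses, times)

    out = np.zeros((len(times), n))
    x = np.zeros(n)
    j = 0
    for i in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[i], breakpoints[i + 1]
        if t0 in boluses:
            x = x.copy()
            x[0] += boluses[t0]
        u = np.zeros(n)
        u[0] = rates[i]
        y0 = Vinv @ x
        c = Vinv @ u
        last = i == len(breakpoints) - 2
        hi = len(times) if last else np.searchsorted(times, t1, side="left")
        taus = times[j:hi] - t0
        if taus.size:
            ew = np.exp(np.multiply.outer(taus, w))
            seg = (V @ (ew * y0 + _phi(w, taus) * c).T).T
            out[j:hi] = seg.real
            j = hi
        tau1 = t1 - t0
        x = (V @ (np.exp(w * tau1) * y0 + _phi(w, np.array([tau1]))[0] * c)).real
    return out


def _solve_linear_expm(A, breakpoints, rates, boluses, times):
    """Fallback propagator via the augmented matrix exponential; handles
    defective state matrices."""
    n = A.shape[0]
    out = np.zeros((len(times), n))
    x = np.zeros(n)
    j = 0
    for i in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[i], breakpoints[i + 1]
        if t0 in boluses:
            x = x.copy()
            x[0] += boluses[t0]
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = A
        M[0, n] = rates[i]
        aug0 = np.append(x, 1.0)
        last = i == len(breakpoints) - 2
        hi = len(times) if last else np.searchsorted(times, t1, side="left")
        for k in range(j, hi):
            out[k] = (expm(M * (times[k] - t0)) @ aug0)[:n]
        j = hi
        x = (expm(M * (t1 - t0)) @ aug0)[:n]
    return out


def analytic_solution(pk: PKParameters, ke0: float, regimen: Regimen,
                      grid: np.ndarray,
                      pd_params: PDParameters | None = None) -> SimulationResult:
    """Piecewise matrix-exponential solution of the full linear system.

    Exact up to floating point between dose events; serves as the oracle for
    the numeric integrator and as the fast engine for population work. BIS
    is filled in when ``pd_params`` is given.
    """
    grid = np.asarray(grid, dtype=float)
    A = system_matrix(pk, ke0)
    states = solve_linear_system(A, regimen, grid)
    cp = MG_PER_L_TO_NG_PER_ML * states[:, 0] / pk.V1
    cm = MG_PER_L_TO_NG_PER_ML * states[:, 4] / pk.V5
    ce = states[:, IDX_CE]
    bis = None
    if pd_params is not None:
        bis = bis_from_ce(pd_params, np.clip(ce, 0.0, None))
    return SimulationResult(time=grid, cp=cp, cm=cm, ce=ce, bis=bis)


# ---------------------------------------------------------------------------
# Numeric (ODE) route
# ---------------------------------------------------------------------------

def simulate(pk: PKParameters, pd_params: PDParameters, regimen: Regimen,
             grid: np.ndarray, rtol: float = 1e-8,
             atol: float = 1e-10) -> SimulationResult:
    """Numerically integrate the 7-state system on ``grid`` (min).

    Dose events are hard breakpoints: boluses are instantaneous additions to
    the parent central amount, infusions piecewise-constant inputs, and the
    integrator is restarted at every event so no dose is smoothed over.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if np.any(np.diff(grid) < 0) or grid[0] < 0:
        raise ValueError("grid must be sorted and nonnegative")
    t_end = max(regimen.end_time, grid[-1])
    if t_end <= 0.0:
        t_end = 1.0
    breakpoints, rates, boluses = _event_schedule(regimen, t_end)
    A = system_matrix(pk, pd_params.ke0)

    out = np.zeros((len(grid), N_STATES))
    x = np.zeros(N_STATES)
    j = 0
    for i in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[i], breakpoints[i + 1]
        if t0 in boluses:
            x = x.copy()
            x[0] += boluses[t0]
        u = np.zeros(N_STATES)
        u[0] = rates[i]

        def rhs(t, y, A=A, u=u):
            return A @ y + u

        last = i == len(breakpoints) - 2
        hi = len(grid) if last else np.searchsorted(grid, t1, side="left")
        t_eval = grid[j:hi]
        if t1 > t0:
            need_end = t_eval.size == 0 or t_eval[-1] < t1
            te = np.append(t_eval, t1) if need_end else t_eval
            sol = solve_ivp(rhs, (t0, t1), x, method="LSODA", t_eval=te,
                            rtol=rtol, atol=atol, jac=lambda t, y: A)
            if not sol.success:
                raise RuntimeError(
                    f"ODE integration failed in [{t0}, {t1}] min: {sol.message}")
            out[j:hi] = sol.y.T[:t_eval.size] if need_end else sol.y.T
            x = sol.y[:, -1]
        else:
            out[j:hi] = x
        j = hi
    if j < len(grid):  # grid points at/after the final breakpoint
        out[j:] = x

    cp = MG_PER_L_TO_NG_PER_ML * out[:, 0] / pk.V1
    cm = MG_PER_L_TO_NG_PER_ML * out[:, 4] / pk.V5
    ce = out[:, IDX_CE]
    bis = bis_from_ce(pd_params, np.clip(ce, 0.0, None))
    return SimulationResult(time=grid, cp=cp, cm=cm, ce=ce, bis=bis)
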