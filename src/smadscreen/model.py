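"""Core two-compartment model of TGF-beta/Smad signaling with I-Smad feedback.

The network: extracellular ligand reversibly binds the receptor, which is
then phosphorylated to its fully active form.  The active receptor
phosphorylates cytoplasmic R-Smad; phospho-R-Smad dimerizes with itself or
with Co-Smad, monomers and dimers shuttle between cytoplasm and nucleus
(dimers import only), and the nuclear phospho-R-Smad is dephosphorylated by
a nuclear phosphatase.  The nuclear heterodimer drives Hill-type
transcription of I-Smad mRNA, which is exported, translated, and degraded;
the I-Smad protein closes a negative feedback by sequestering the active
receptor.  Receptor, R-Smad and Co-Smad enter through conserved totals
rather than synthesis/degradation; ligand is a boundary condition and is
never depleted.

Units: concentrations nM, time s.  Ligand inputs are given in pM and
converted internally; the reported output (nuclear heterodimer, ``H_n``) is
in pM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._kinetics import (
    IDX_HN,
    N_PARAM,
    N_STATE,
    STATE_NAMES,
    rhs_core,
    rk4_integrate,
    stable_rk4_step,
)

__all__ = [
    "ParameterSet",
    "TotalConcentrations",
    "LigandProtocol",
    "ResponseTrace",
    "SolverOptions",
    "PARAMETER_NAMES",
    "STATE_NAMES",
    "rhs",
    "simulate",
    "simulate_oracle",
    "conserved_totals",
    "initial_state",
]

PARAMETER_NAMES = tuple(f"k{i}" for i in range(1, 20)) + ("h",)

#: pM per nM
PM_PER_NM = 1000.0

#: near-zero ligand used during equilibration (pM); exactly zero is avoided
#: only to mirror the stimulation protocol's lower bound handling.
EQUILIBRATION_LIGAND_PM = 1e-6

EQUILIBRATION_SECONDS = 3600.0


@dataclass(frozen=True)
class ParameterSet:
    """The 19 kinetic rate constants plus the Hill coefficient.

    Bimolecular rates (k2, k5, k7, k10) are in 1/(nM s); k14 is a maximal
    transcription rate in nM/s; k15 a half-saturation constant in nM; all
    other rates are first order in 1/s.  ``h`` is the dimensionless Hill
    coefficient of transcriptional activation.
    """

    k1: float; k2: float; k3: float; k4: float; k5: float
    k6: float; k7: float; k8: float; k9: float; k10: float
    k11: float; k12: float; k13: float; k14: float; k15: float
    k16: float; k17: float; k18: float; k19: float
    h: float = 2.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v!r}")
        if self.h < 1:
            raise ValueError(f"Hill coefficient h must be >= 1, got {self.h!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAMETER_NAMES}

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_PARAM,):
            raise ValueError(f"expected {N_PARAM} parameters, got shape {arr.shape}")
        return cls(**dict(zip(PARAMETER_NAMES, arr.tolist())))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        unknown = set(d) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def scaled(self, **factors: float) -> "ParameterSet":
        """Return a copy with named parameters multiplied by given factors."""
        return replace(self, **{k: getattr(self, k) * f for k, f in factors.items()})


@dataclass(frozen=True)
class TotalConcentrations:
    """Conserved totals (nM) of receptor, R-Smad and Co-Smad."""

    R_tot: float = 1.0
    S_tot: float = 60.0
    C_tot: float = 100.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"total {f.name} must be finite and positive, got {v!r}")

    def scaled(self, species: str, factor: float) -> "TotalConcentrations":
        key = _SPECIES_TO_FIELD[species]
        return replace(self, **{key: getattr(self, key) * factor})

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


_SPECIES_TO_FIELD = {
    "receptor": "R_tot",
    "r_smad": "S_tot",
    "co_smad": "C_tot",
    "R_tot": "R_tot",
    "S_tot": "S_tot",
    "C_tot": "C_tot",
}


@dataclass(frozen=True)
class LigandProtocol:
    """Piecewise ligand concentration L(t) in pM over the stimulation phase.

    ``kind`` is one of ``constant`` or ``triangle``.  Time is measured from
    stimulation onset (the end of the equilibration phase).
    """

    kind: str
    duration_s: float
    level_pM: float = 0.0          # constant protocols
    peak_pM: float = 0.0           # triangle protocols
    rise_s: float = 0.0
    fall_s: float = 0.0

    @classmethod
    def constant(cls, level_pM: float = 200.0, duration_s: float = 36000.0) -> "LigandProtocol":
        if level_pM < 0:
            raise ValueError("ligand concentration must be >= 0")
        return cls(kind="constant", duration_s=float(duration_s), level_pM=float(level_pM))

    @classmethod
    def triangle(cls, peak_pM: float = 720.0, rise_s: float = 18000.0,
                 fall_s: float = 18000.0) -> "LigandProtocol":
        return cls(kind="triangle", duration_s=float(rise_s + fall_s),
                   peak_pM=float(peak_pM), rise_s=float(rise_s), fall_s=float(fall_s))

    @property
    def is_constant(self) -> bool:
        return self.kind == "constant"

    def value_pM(self, t: float) -> float:
        """Ligand concentration (pM) at time t (s) after stimulation onset."""
        if self.kind == "constant":
            return self.level_pM
        if t <= 0:
            return 0.0
        if t < self.rise_s:
            return self.peak_pM * t / self.rise_s
        if t < self.rise_s + self.fall_s:
            return self.peak_pM * (1.0 - (t - self.rise_s) / self.fall_s)
        return 0.0

    def extended(self, duration_s: float) -> "LigandProtocol":
        return replace(self, duration_s=float(duration_s))


@dataclass
class ResponseTrace:
    """Nuclear heterodimer time course over the stimulation phase.

    ``t`` in seconds from stimulation onset, strictly increasing with
    spacing <= 60 s; ``value`` is H_n in the unit recorded in ``unit``
    (pM by default).  ``success`` is False when the stiff solver failed,
    in which case the series may be empty.
    """

    t: np.ndarray
    value: np.ndarray
    unit: str = "pM"
    success: bool = True
    message: str = ""

    def scaled(self, factor: float) -> "ResponseTrace":
        return ResponseTrace(self.t.copy(), self.value * factor, self.unit,
                             self.success, self.message)


@dataclass(frozen=True)
class SolverOptions:
    """Stiff-solver settings.  ``grid_s`` is the output sampling interval."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12
    grid_s: float = 60.0

    @classmethod
    def screening(cls) -> "SolverOptions":
        """Looser tolerances for large Monte-Carlo screens.

        Classification thresholds live at the pM (1e-3 nM) scale, four
        decades above this atol, so labels are insensitive to the change.
        """
        return cls(rtol=1e-6, atol=1e-10)


def rhs(state: np.ndarray, t: float, params: ParameterSet, ligand_pM: float) -> np.ndarray:
    """Time derivative of the state (nM/s) at ligand concentration L (pM)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} entries")
    if ligand_pM < 0:
        raise ValueError("ligand concentration must be >= 0")
    return rhs_core(t, state, params.as_array(), ligand_pM / PM_PER_NM)


def initial_state(totals: TotalConcentrations) -> np.ndarray:
    """Pre-equilibration state: free receptor, cytoplasmic unphosphorylated Smads."""
    y0 = np.zeros(N_STATE)
    y0[0] = totals.R_tot
    y0[4] = totals.S_tot
    y0[6] = totals.C_tot
    return y0


def _integrate(y0, p, protocol: LigandProtocol, t_end: float, t_eval, opts: SolverOptions):
    if protocol.is_constant:
        L = protocol.level_pM / PM_PER_NM
        fun = lambda t, y: rhs_core(t, y, p, L)
    else:
        fun = lambda t, y: rhs_core(t, y, p, protocol.value_pM(t) / PM_PER_NM)
    return solve_ivp(fun, (0.0, t_end), y0, method=opts.method, t_eval=t_eval,
                     rtol=opts.rtol, atol=opts.atol)


def equilibrate(params: ParameterSet, totals: TotalConcentrations,
                opts: SolverOptions = SolverOptions(),
                duration_s: float = EQUILIBRATION_SECONDS) -> np.ndarray:
    """Phase 1: relax the pre-stimulus system under near-zero ligand (1e-6 pM)."""
    sol = _integrate(initial_state(totals), params.as_array(),
                     LigandProtocol.constant(EQUILIBRATION_LIGAND_PM, duration_s),
                     duration_s, (duration_s,), opts)
    if not sol.success:
        raise RuntimeError(f"equilibration failed: {sol.message}")
    return sol.y[:, -1]


def simulate(params: ParameterSet, totals: TotalConcentrations = TotalConcentrations(),
             protocol: LigandProtocol = LigandProtocol.constant(),
             opts: SolverOptions = SolverOptions(),
             return_states: bool = False):
    """Two-phase simulation: 1 h near-zero-ligand equilibration, then stimulus.

    Returns the nuclear-heterodimer :class:`ResponseTrace` over the
    stimulation phase (time measured from stimulation onset), or
    ``(trace, t, states)`` with the full state matrix when
    ``return_states`` is set.  Solver failures are caught and flagged on
    the trace, never raised, so screens can proceed record by record.
    """
    p = params.as_array()
    t_end = protocol.duration_s
    t_eval = np.arange(0.0, t_end + 0.5 * opts.grid_s, opts.grid_s)
    if t_eval[-1] > t_end:
        t_eval[-1] = t_end
    try:
        y_eq = equilibrate(params, totals, opts)
        sol = _integrate(y_eq, p, protocol, t_end, t_eval, opts)
    except Exception as exc:  # noqa: BLE001 - screens must survive any solver blow-up
        trace = ResponseTrace(np.empty(0), np.empty(0), success=False, message=str(exc))
        return (trace, np.empty(0), np.empty((0, N_STATE))) if return_states else trace
    if not sol.success:
        trace = ResponseTrace(np.empty(0), np.empty(0), success=False, message=sol.message)
        return (trace, np.empty(0), np.empty((0, N_STATE))) if return_states else trace
    hn_pM = sol.y[IDX_HN] * PM_PER_NM
    trace = ResponseTrace(sol.t, hn_pM)
    if return_states:
        return trace, sol.t, sol.y.T
    return trace


def simulate_oracle(params: ParameterSet, totals: TotalConcentrations,
                    ligand_pM: float, duration_s: float,
                    grid_s: float = 60.0, max_dt: float = 0.1,
                    min_dt: float = 2e-3):
    """Independent fixed-step fourth-order (RK4) integration of phase 2.

    Equilibration is run with the same RK4 scheme, so the result shares no
    code path with the adaptive stiff solver beyond the model right-hand
    side.  Returns ``(t, states)`` on the requested grid.

    An explicit fixed-step scheme is only practical when the fastest
    linearized rate is moderate; when the conservative stability estimate
    demands a step below ``min_dt`` the set is outside the oracle's
    validity domain and a ``ValueError`` is raised (callers drawing random
    sets should skip such draws).
    """
    p = params.as_array()
    # I-Smad can overshoot its conserved partners; bound it by its fastest
    # achievable steady state to keep the explicit step stable.
    i_max = p[13] * p[17] / (p[16] * p[18]) if p[16] * p[18] > 0 else 0.0
    cmax = max(totals.R_tot, totals.S_tot, totals.C_tot, i_max, ligand_pM / PM_PER_NM)
    dt = min(max_dt, stable_rk4_step(p, cmax))
    if dt < min_dt:
        raise ValueError(
            f"stiffness bound needs dt={dt:.2e} s < min_dt={min_dt} s; "
            "parameter set is outside the explicit oracle's validity domain")
    # choose dt dividing grid_s exactly
    save_every = max(1, int(math.ceil(grid_s / dt)))
    dt = grid_s / save_every

    n_eq = int(round(EQUILIBRATION_SECONDS / dt))
    eq = rk4_integrate(initial_state(totals), p, EQUILIBRATION_LIGAND_PM / PM_PER_NM,
                       dt, n_eq, n_eq)
    y_eq = eq[-1]
    n_steps = int(round(duration_s / dt))
    states = rk4_integrate(y_eq, p, ligand_pM / PM_PER_NM, dt, n_steps, save_every)
    t = np.arange(states.shape[0]) * (dt * save_every)
    return t, states


def conserved_totals(states: np.ndarray) -> dict[str, np.ndarray]:
    """Receptor, R-Smad and Co-Smad totals at every saved time point.

    ``states`` is the (n_times, 17) matrix returned by
    :func:`simulate` with ``return_states=True``.
    """
    s = np.asarray(states, dtype=float)
    if s.ndim != 2 or s.shape[1] != N_STATE:
        raise ValueError(f"states must be (n, {N_STATE})")
    receptor = s[:, 0] + s[:, 1] + s[:, 2] + s[:, 3]
    r_smad = (s[:, 4] + s[:, 5] + s[:, 11] + s[:, 12]
              + 2.0 * (s[:, 7] + s[:, 14]) + s[:, 8] + s[:, 15])
    co_smad = s[:, 6] + s[:, 13] + s[:, 8] + s[:, 15]
    return {"receptor": receptor, "r_smad": r_smad, "co_smad": co_smad}
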