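"""Downstream analyses of screened parameter sets.

Three questions are addressed for cohorts of parameter sets:

1. *Concentration switching* — can scaling the conserved total of the
   receptor, R-Smad or Co-Smad flip a set between a transient and a
   sustained response, and what is the minimal fold change that does so
   (on the 3**n grid, n = -4..4)?
2. *Dose-response saturation* — how does the peak output grow across a
   12-point ligand dose series, summarised by the exponential-saturation
   fit Opeak(x) = max(Opeak) * (1 - exp(-x/eta))?
3. *Faithfulness* — for sets that respond sustainedly to constant ligand,
   how proportional is the output to a triangular 0 -> 720 pM -> 0 input,
   quantified by the squared residual between max-normalised input and
   output on a shared uniform grid?
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .classify import ClassifierConfig, Label, classify_with_extension
from .model import (
    LigandProtocol,
    ParameterSet,
    SolverOptions,
    TotalConcentrations,
    simulate,
)

__all__ = [
    "SwitchResult",
    "SaturationFit",
    "FaithfulnessResult",
    "SPECIES",
    "DEFAULT_DOSES_PM",
    "FOLD_GRID_EXPONENTS",
    "classify_at_totals",
    "concentration_switch_screen",
    "minimal_switch_fold",
    "dose_response",
    "dose_label_changes",
    "faithfulness",
    "decile_labels",
]

SPECIES = ("receptor", "r_smad", "co_smad")

#: the 12-point ligand dose series (pM)
DEFAULT_DOSES_PM = (0.2, 2.0, 6.0, 10.0, 15.0, 20.0, 50.0, 100.0, 150.0, 200.0, 1000.0, 2000.0)

#: exponents n of the minimal-fold grid c0 * 3**n
FOLD_GRID_EXPONENTS = tuple(range(-4, 5))

_SWITCH_PAIR = frozenset({Label.TRANSIENT, Label.SUSTAINED})


@dataclass
class SwitchResult:
    """Labels of one parameter set across scaled totals of one species."""

    set_id: int
    species: str
    factors: tuple[float, ...]
    labels: tuple[str, ...]
    switched: bool                      # transient at one factor, sustained at another
    minimal_fold: float = math.nan      # 3**|n| of nearest differing label (fold grid only)


@dataclass
class SaturationFit:
    """Exponential-saturation fit of the peak response across a dose series."""

    doses_pM: np.ndarray
    opeaks_pM: np.ndarray
    eta_pM: float = math.nan
    max_opeak_pM: float = math.nan
    residual_norm: float = math.nan
    status: str = "ok"                  # ok | refused | failed


@dataclass
class FaithfulnessResult:
    """Squared residual between normalised triangular input and output."""

    set_id: int
    residual: float
    status: str = "ok"
    decile: str = "neither"             # faithful | unfaithful | neither


def classify_at_totals(
    params: ParameterSet,
    totals: TotalConcentrations,
    protocol: LigandProtocol = LigandProtocol.constant(),
    cfg: ClassifierConfig | None = None,
    opts: SolverOptions = SolverOptions.screening(),
) -> str:
    """Label one set at given totals, re-running the equilibration phase.

    Multi-condition scans use series-mode thresholds (the trace's own peak
    as theta) so criteria stay purely relative across conditions.
    """
    cfg = (cfg or ClassifierConfig()).as_series()
    return classify_with_extension(params, totals, protocol, cfg, opts).label


def concentration_switch_screen(
    paramsets: Sequence[ParameterSet],
    species: str,
    factors: Iterable[float] = (0.01, 1.0, 100.0),
    totals: TotalConcentrations = TotalConcentrations(),
    protocol: LigandProtocol = LigandProtocol.constant(),
    cfg: ClassifierConfig | None = None,
    opts: SolverOptions = SolverOptions.screening(),
) -> list[SwitchResult]:
    """Re-classify each set at each scaled total of one species.

    A set "switches" when it is transient at one tested concentration and
    sustained at another; changes into or out of other labels are visible
    in ``labels`` but do not count as switches.
    """
    if species not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}")
    factors = tuple(float(f) for f in factors)
    if any(f <= 0 for f in factors):
        raise ValueError("concentration factors must be positive")
    out = []
    for i, ps in enumerate(paramsets):
        labels = tuple(
            classify_at_totals(ps, totals.scaled(species, f), protocol, cfg, opts)
            for f in factors
        )
        switched = _SWITCH_PAIR <= set(labels)
        out.append(SwitchResult(i, species, factors, labels, switched))
    return out


def minimal_switch_fold(
    params: ParameterSet,
    species: str,
    totals: TotalConcentrations = TotalConcentrations(),
    protocol: LigandProtocol = LigandProtocol.constant(),
    cfg: ClassifierConfig | None = None,
    opts: SolverOptions = SolverOptions.screening(),
    set_id: int = 0,
) -> SwitchResult:
    """Smallest fold change 3**|n| (n = -4..4) that alters the reference label.

    The minimal fold is undefined (NaN) when the label at every multiple
    equals the label at the reference concentration c0.
    """
    factors = tuple(3.0 ** n for n in FOLD_GRID_EXPONENTS)
    labels = {}
    for n in FOLD_GRID_EXPONENTS:
        labels[n] = classify_at_totals(params, totals.scaled(species, 3.0 ** n),
                                       protocol, cfg, opts)
    ref = labels[0]
    fold = math.nan
    for absn in (1, 2, 3, 4):
        if labels[absn] != ref or labels[-absn] != ref:
            fold = 3.0 ** absn
            break
    ordered = tuple(labels[n] for n in FOLD_GRID_EXPONENTS)
    switched = _SWITCH_PAIR <= set(ordered)
    return SwitchResult(set_id, species, factors, ordered, switched, minimal_fold=fold)


def _saturation_model(x, eta, mx):
    return mx * (1.0 - np.exp(-x / eta))


def fit_saturation(doses_pM: np.ndarray, opeaks_pM: np.ndarray) -> SaturationFit:
    """Constrained least-squares fit of the exponential saturation curve.

    Initial guesses: eta = median dose, max = largest observed peak; both
    parameters constrained positive.  A degenerate all-zero peak series is
    refused rather than fitted.
    """
    x = np.asarray(doses_pM, float)
    y = np.asarray(opeaks_pM, float)
    fit = SaturationFit(doses_pM=x, opeaks_pM=y)
    if len(x) < 4:
        raise ValueError("need at least 4 dose points")
    if not np.all(x > 0):
        raise ValueError("doses must be positive")
    if not np.isfinite(y).all() or y.max() <= 0:
        fit.status = "refused"
        return fit
    p0 = np.array([np.median(x), y.max()])
    try:
        sol = least_squares(
            lambda p: _saturation_model(x, p[0], p[1]) - y,
            p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except Exception as exc:  # noqa: BLE001
        fit.status = f"failed: {exc}"
        return fit
    fit.eta_pM = float(sol.x[0])
    fit.max_opeak_pM = float(sol.x[1])
    fit.residual_norm = float(np.sqrt(2.0 * sol.cost))
    return fit


def dose_response(
    params: ParameterSet,
    totals: TotalConcentrations = TotalConcentrations(),
    doses_pM: Sequence[float] = DEFAULT_DOSES_PM,
    cfg: ClassifierConfig | None = None,
    opts: SolverOptions = SolverOptions.screening(),
    duration_s: float = 36000.0,
    return_labels: bool = False,
):
    """Peak output per dose and the exponential-saturation fit.

    Simulates each constant dose for the observation window, records
    Opeak(x), and fits Opeak = max(Opeak)*(1 - exp(-x/eta)).  With
    ``return_labels`` the per-dose series-mode label is also returned.
    """
    doses = np.asarray(list(doses_pM), float)
    opeaks = np.full(len(doses), np.nan)
    labels = []
    scfg = (cfg or ClassifierConfig()).as_series()
    for i, x in enumerate(doses):
        protocol = LigandProtocol.constant(x, duration_s)
        if return_labels:
            res = classify_with_extension(params, totals, protocol, scfg, opts)
            labels.append(res.label)
            opeaks[i] = res.Opeak
        else:
            trace = simulate(params, totals, protocol, opts)
            if trace.success:
                opeaks[i] = float(np.max(trace.value))
    if np.isnan(opeaks).any():
        fit = SaturationFit(doses_pM=doses, opeaks_pM=opeaks, status="failed: solver")
    else:
        fit = fit_saturation(doses, opeaks)
    return (fit, labels) if return_labels else fit


_CLASSIFIED = (Label.SUSTAINED, Label.TRANSIENT, Label.DAMPENED_OSC, Label.SUSTAINED_OSC)


def dose_label_changes(per_dose_labels: Sequence[Sequence[str]]) -> float:
    """Fraction of classified sets whose defined response type changes with dose.

    A set counts as classified when its label at the reference (largest
    defined) dose falls in a defined responsive type; it counts as changed
    when two doses yield two *different* defined types (transitions through
    unresponsive/undefined at extreme doses do not count as a type change).
    """
    n_classified = 0
    n_changed = 0
    for labels in per_dose_labels:
        defined = [l for l in labels if l in _CLASSIFIED]
        if not defined:
            continue
        n_classified += 1
        if len(set(defined)) > 1:
            n_changed += 1
    if n_classified == 0:
        return math.nan
    return n_changed / n_classified


def faithfulness(
    params: ParameterSet,
    totals: TotalConcentrations = TotalConcentrations(),
    cfg: ClassifierConfig | None = None,
    opts: SolverOptions = SolverOptions.screening(),
    protocol: LigandProtocol | None = None,
    grid_s: float = 60.0,
    set_id: int = 0,
) -> FaithfulnessResult:
    """Squared residual between normalised triangular input and output.

    The triangular stimulus rises linearly 0 -> 720 pM over 5 h and falls
    back to 0 over the next 5 h.  Input and output are linearly
    interpolated onto a shared uniform grid (60 s spacing over 10 h) and
    each normalised by its own maximum, so any proportionality constant
    between them drops out; R = sum_j (input_j - output_j)^2.
    """
    protocol = protocol or LigandProtocol.triangle()
    trace = simulate(params, totals, protocol, opts)
    if not trace.success:
        return FaithfulnessResult(set_id, math.nan, status="solver_failed")
    grid = np.arange(0.0, protocol.duration_s + 0.5 * grid_s, grid_s)
    inp = np.array([protocol.value_pM(t) for t in grid])
    out = np.interp(grid, trace.t, trace.value)
    return FaithfulnessResult(set_id, residual_on_grid(inp, out))


def residual_on_grid(inp: np.ndarray, out: np.ndarray) -> float:
    """R = sum of squared differences of the max-normalised signals."""
    inp = np.asarray(inp, float)
    out = np.asarray(out, float)
    if inp.shape != out.shape:
        raise ValueError("input and output grids must match")
    imax = inp.max()
    omax = out.max()
    ni = inp / imax if imax > 0 else inp
    no = out / omax if omax > 0 else out
    return float(np.sum((ni - no) ** 2))


def decile_labels(residuals: Sequence[float]) -> list[str]:
    """Label the lowest decile ``faithful`` and the highest ``unfaithful``.

    Ties are broken by stable input order; when every residual is equal
    the deciles are degenerate and everything is labelled ``neither``.
    """
    r = np.asarray(list(residuals), float)
    if len(r) < 10:
        raise ValueError("need at least 10 residuals for decile labelling")
    labels = ["neither"] * len(r)
    if np.nanmax(r) == np.nanmin(r):
        return labels
    k = len(r) // 10
    order = np.argsort(r, kind="stable")
    for i in order[:k]:
        labels[i] = "faithful"
    for i in order[len(r) - k:]:
        labels[i] = "unfaithful"
    return labels
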