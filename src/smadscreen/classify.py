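"""Phenotyping of simulated signaling responses.

Each nuclear-heterodimer time course is assigned exactly one label:

``unresponsive``
    the output never exceeds the detection threshold theta within the
    10 h observation window;
``sustained``
    90% of the peak value ``Opeak`` is reached within 2 h and retained
    through the end of the window;
``transient``
    the output drops below 10% of ``Opeak`` within 2 h of stimulation and
    ends below 0.1 * theta;
``dampened_oscillatory`` / ``sustained_oscillatory``
    at least four post-initial-peak amplitudes (local maximum minus the
    preceding local minimum) exceed 0.1 * theta; with peaks numbered from
    the initial peak, the sub-label compares the amplitude of peak 5
    against half that of peak 2;
``undefined``
    responsive but none of the above;
``failed``
    the solver did not produce a usable trace.

For multi-condition series (dose scans, protein-concentration scans) the
threshold convention switches to "series mode": theta is the trace's own
peak, making all sub-criteria purely relative, and responsiveness instead
requires the peak to clear a small absolute floor that rejects numerically
zero traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .model import (
    LigandProtocol,
    ParameterSet,
    ResponseTrace,
    SolverOptions,
    TotalConcentrations,
    simulate,
)

__all__ = [
    "Label",
    "LABELS",
    "ClassifierConfig",
    "ClassificationResult",
    "Extremum",
    "find_extrema",
    "classify",
    "classify_with_extension",
]


class Label:
    """String constants for the seven response labels."""

    UNRESPONSIVE = "unresponsive"
    SUSTAINED = "sustained"
    TRANSIENT = "transient"
    DAMPENED_OSC = "dampened_oscillatory"
    SUSTAINED_OSC = "sustained_oscillatory"
    UNDEFINED = "undefined"
    FAILED = "failed"


LABELS = (
    Label.UNRESPONSIVE,
    Label.SUSTAINED,
    Label.TRANSIENT,
    Label.DAMPENED_OSC,
    Label.SUSTAINED_OSC,
    Label.UNDEFINED,
    Label.FAILED,
)

OSCILLATORY_LABELS = (Label.DAMPENED_OSC, Label.SUSTAINED_OSC)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the response criteria.

    theta_pM: detection threshold for a single constant stimulus (10 pM).
    t_fast_s: window for the "fast" clauses (2 h).
    t_end_s: observation horizon (10 h).
    t_max_s: maximal horizon when extending ongoing oscillations (100 h).
    sustained_fraction / transient_fraction: the 90% retention and 10%
        decay fractions of Opeak.
    amplitude_floor_fraction: oscillation amplitudes must exceed this
        fraction of theta (0.1, i.e. 1 pM at the default theta).
    min_extra_peaks: qualifying amplitudes required for an oscillation (4).
    damp_ratio: sustained oscillation iff amplitude5 >= damp_ratio * amplitude2.
    series_mode: per-trace theta = Opeak, with ``series_floor_pM`` as the
        absolute responsiveness floor.
    """

    theta_pM: float = 10.0
    t_fast_s: float = 7200.0
    t_end_s: float = 36000.0
    t_max_s: float = 360000.0
    sustained_fraction: float = 0.9
    transient_fraction: float = 0.1
    amplitude_floor_fraction: float = 0.1
    min_extra_peaks: int = 4
    damp_ratio: float = 0.5
    series_mode: bool = False
    series_floor_pM: float = 0.1
    rel_tol: float = 1e-9

    def __post_init__(self):
        if self.theta_pM <= 0:
            raise ValueError("theta must be > 0")
        if not (self.t_fast_s < self.t_end_s <= self.t_max_s):
            raise ValueError("need t_fast < t_end <= t_max")
        for name in ("sustained_fraction", "transient_fraction", "amplitude_floor_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")

    def as_series(self) -> "ClassifierConfig":
        return replace(self, series_mode=True)


@dataclass(frozen=True)
class Extremum:
    time: float
    value: float
    kind: str  # "min" | "max"


@dataclass
class ClassificationResult:
    """Label plus the metrics that justify it (all concentrations in pM)."""

    label: str
    Opeak: float = math.nan
    t_peak90: float = math.nan
    Oend: float = math.nan
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_peaks: int = 0
    period_s: float = math.nan
    duration_s: float = math.nan
    theta_pM: float = math.nan

    @property
    def is_oscillatory(self) -> bool:
        return self.label in OSCILLATORY_LABELS


def _merge_plateaus(t: np.ndarray, y: np.ndarray):
    """Collapse runs of exactly-equal consecutive values to their midpoint."""
    if len(y) == 0:
        return t, y
    change = np.empty(len(y), dtype=bool)
    change[0] = True
    change[1:] = y[1:] != y[:-1]
    if change.all():
        return t, y
    run_id = np.cumsum(change) - 1
    n_runs = run_id[-1] + 1
    tm = np.zeros(n_runs)
    counts = np.bincount(run_id)
    np.add.at(tm, run_id, t)
    tm /= counts
    ym = y[change]
    return tm, ym


def find_extrema(trace: ResponseTrace) -> list[Extremum]:
    """Alternating strict local extrema of the sampled series.

    Endpoints are excluded; plateaus of exactly equal consecutive values
    are merged to a single candidate at the plateau midpoint.
    """
    if not trace.success:
        raise ValueError("cannot analyse a failed trace")
    return _extrema(np.asarray(trace.t, float), np.asarray(trace.value, float))


def _extrema(t: np.ndarray, y: np.ndarray) -> list[Extremum]:
    tm, ym = _merge_plateaus(t, y)
    out: list[Extremum] = []
    for i in range(1, len(ym) - 1):
        if ym[i] > ym[i - 1] and ym[i] > ym[i + 1]:
            out.append(Extremum(float(tm[i]), float(ym[i]), "max"))
        elif ym[i] < ym[i - 1] and ym[i] < ym[i + 1]:
            out.append(Extremum(float(tm[i]), float(ym[i]), "min"))
    return out


def _oscillation_metrics(extrema: list[Extremum], theta: float, floor: float,
                         rel_tol: float = 1e-9):
    """Initial peak, ordered post-initial amplitudes and qualifying peak times.

    The initial peak is the first local maximum reaching theta (within the
    comparison tolerance, so series mode — where theta equals the global
    maximum — still recognises it).
    """
    first_peak_idx = None
    for j, e in enumerate(extrema):
        if e.kind == "max" and e.value >= theta * (1 - rel_tol):
            first_peak_idx = j
            break
    amplitudes: list[float] = []
    peak_times: list[float] = []   # all post-initial peaks (timing)
    qual_times: list[float] = []   # peaks whose amplitude clears the floor
    n_peaks = sum(1 for e in extrema if e.kind == "max")
    if first_peak_idx is None:
        return np.empty(0), peak_times, qual_times, n_peaks
    for j in range(first_peak_idx + 1, len(extrema)):
        e = extrema[j]
        if e.kind != "max" or j == 0:
            continue
        prev = extrema[j - 1]
        if prev.kind != "min":
            continue
        amp = e.value - prev.value
        amplitudes.append(amp)
        peak_times.append(e.time)
        if amp > floor:
            qual_times.append(e.time)
    return np.asarray(amplitudes), peak_times, qual_times, n_peaks


def classify(trace: ResponseTrace, cfg: ClassifierConfig = ClassifierConfig()) -> ClassificationResult:
    """Assign one of the seven labels to a response trace.

    Peak/end/sustained/transient clauses are evaluated on the window
    [0, t_end]; oscillation amplitudes are counted on the whole trace, so a
    horizon-extended trace may be passed directly.
    """
    if not trace.success:
        return ClassificationResult(Label.FAILED)
    t = np.asarray(trace.t, float)
    y = np.asarray(trace.value, float)
    if len(t) < 3 or t[-1] < cfg.t_end_s * (1 - cfg.rel_tol):
        raise ValueError(f"trace must cover the full observation horizon ({cfg.t_end_s} s)")

    win = t <= cfg.t_end_s * (1 + cfg.rel_tol)
    tw, yw = t[win], y[win]
    Opeak = float(yw.max())
    Oend = float(yw[-1])

    if cfg.series_mode:
        theta = Opeak
        responsive = Opeak >= cfg.series_floor_pM
    else:
        theta = cfg.theta_pM
        responsive = Opeak >= theta
    floor = cfg.amplitude_floor_fraction * theta

    extrema = _extrema(t, y)
    amplitudes, peak_times, qual_times, n_peaks = _oscillation_metrics(
        extrema, theta, floor, cfg.rel_tol)

    retain_level = cfg.sustained_fraction * Opeak * (1 - cfg.rel_tol)
    idx90 = int(np.argmax(yw >= retain_level))
    t_peak90 = float(tw[idx90])

    res = ClassificationResult(
        Label.UNDEFINED, Opeak=Opeak, t_peak90=t_peak90, Oend=Oend,
        amplitudes=amplitudes, n_peaks=n_peaks, theta_pM=theta,
    )

    if not responsive:
        res.label = Label.UNRESPONSIVE
        return res

    # sustained: fast rise and retention of 90% of the peak until t_end
    if t_peak90 <= cfg.t_fast_s and yw[idx90:].min() >= retain_level:
        res.label = Label.SUSTAINED
        return res

    # oscillatory (checked before transient, per the criteria precedence)
    n_qual = int(np.sum(amplitudes > floor))
    if n_qual >= cfg.min_extra_peaks:
        # peaks are numbered from the initial peak (peak 1), so the damp /
        # sustain comparison of peaks 2 and 5 uses the 1st and 4th
        # post-initial amplitudes; the initial peak itself is excluded
        # because it can be disproportionately high
        amp2 = amplitudes[0] if len(amplitudes) >= 1 else 0.0
        amp5 = amplitudes[3] if len(amplitudes) >= 4 else 0.0
        res.label = Label.SUSTAINED_OSC if amp5 >= cfg.damp_ratio * amp2 else Label.DAMPENED_OSC
        # timing uses every post-initial peak (the amplitude floor only
        # gates counting), so the period estimate does not depend on how
        # many peaks clear the floor at a given input strength
        if len(peak_times) >= 2:
            res.period_s = float(np.median(np.diff(peak_times)))
        if qual_times:
            res.duration_s = float(qual_times[-1])
        return res

    # transient: collapse below 10% of the peak within t_fast of onset,
    # and a final value below 0.1 * theta
    t_peak = float(tw[int(np.argmax(yw))])
    decay_level = cfg.transient_fraction * Opeak
    fast = (tw > t_peak) & (tw <= cfg.t_fast_s)
    if fast.any() and yw[fast].min() < decay_level and Oend < cfg.transient_fraction * theta:
        res.label = Label.TRANSIENT
        return res

    return res


def classify_with_extension(
    params: ParameterSet,
    totals: TotalConcentrations = TotalConcentrations(),
    protocol: LigandProtocol = LigandProtocol.constant(),
    cfg: ClassifierConfig = ClassifierConfig(),
    opts: SolverOptions = SolverOptions(),
    simulate_fn: Callable = simulate,
) -> ClassificationResult:
    """Simulate, classify, and extend the horizon while oscillations persist.

    The run first covers [0, t_end].  If post-initial-peak amplitudes are
    present and the last one still exceeds the amplitude floor, the
    simulation horizon doubles (capped at ``t_max_s``, 100 h) and the trace
    is re-classified, so slow oscillations are characterised without period
    length biasing the damp/sustain call (always amplitudes 2 vs 5).
    Period and vanishing time are recorded for oscillatory labels.
    """
    horizon = cfg.t_end_s
    trace = simulate_fn(params, totals, protocol.extended(horizon), opts)
    res = classify(trace, cfg)
    if res.label == Label.FAILED or not protocol.is_constant:
        return res
    extendable = (Label.UNDEFINED,) + OSCILLATORY_LABELS
    floor = cfg.amplitude_floor_fraction * res.theta_pM
    while (
        horizon < cfg.t_max_s
        and res.label in extendable
        and len(res.amplitudes) > 0
        and res.amplitudes[-1] > floor
    ):
        horizon = min(2 * horizon, cfg.t_max_s)
        trace = simulate_fn(params, totals, protocol.extended(horizon), opts)
        res = classify(trace, cfg)
        if res.label == Label.FAILED:
            return res
    return res
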