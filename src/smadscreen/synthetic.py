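"""Analytic fixture traces and vetted fixture parameter sets.

The trace families mirror the canonical response shapes — a saturating
exponential (sustained), a biexponential pulse (transient), a damped
raised-cosine (oscillatory), the triangular morphogen-like input, and a
constant — so the classifier and downstream analyses can be tested against
closed forms without running the ODE model.  Fixture *parameter* sets (one
per response family) were found once by rejection-sampling the default
ranges, confirmed against the independent fixed-step integrator, and frozen
as plain-text files shipped with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .model import ParameterSet, ResponseTrace

__all__ = ["FixtureSpec", "make_trace", "make_parameter_fixtures", "FIXTURE_FAMILIES"]

FIXTURE_FAMILIES = (
    "sustained_exponential",
    "transient_biexponential",
    "damped_sinusoid",
    "triangle_input",
    "constant",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Closed-form trace recipe with its analytically implied label.

    Families and their shape parameters (times s, amplitudes pM):

    * ``sustained_exponential``: A*(1 - exp(-t/tau)) — sustained whenever
      A >= theta and tau small enough that 0.9*A is reached inside the
      fast window (tau * ln 10 < t_fast).
    * ``transient_biexponential``: peak-normalised A*(exp(-t/tau_slow) -
      exp(-t/tau_fast)) — transient when the decay undercuts 0.1*peak
      within the fast window and the end value is below 0.1*theta.
    * ``damped_sinusoid``: A*exp(-t/tau_damp)*(1 - cos(2*pi*t/period)) —
      oscillatory when >= 4 amplitudes exceed 0.1*theta; sustained-
      oscillatory iff exp(-3*period/tau_damp) >= 0.5.
    * ``triangle_input``: piecewise-linear 0 -> A over rise, -> 0 over fall.
    * ``constant``: flat at A (A = 0 gives an unresponsive trace).
    """

    family: str
    amplitude_pM: float = 20.0
    tau_s: float = 600.0
    tau_fast_s: float = 150.0
    period_s: float = 5400.0
    tau_damp_s: float = 40000.0
    rise_s: float = 18000.0
    fall_s: float = 18000.0
    duration_s: float = 36000.0
    grid_s: float = 60.0
    expected_label: str = ""

    def __post_init__(self):
        if self.family not in FIXTURE_FAMILIES:
            raise ValueError(f"unknown fixture family {self.family!r}")
        if self.grid_s <= 0 or self.grid_s > 60.0:
            raise ValueError("grid spacing must be in (0, 60] s")


def make_trace(spec: FixtureSpec) -> ResponseTrace:
    """Evaluate the closed form on the grid; deterministic and seed-free."""
    t = np.arange(0.0, spec.duration_s + 0.5 * spec.grid_s, spec.grid_s)
    A = spec.amplitude_pM
    if spec.family == "sustained_exponential":
        y = A * (1.0 - np.exp(-t / spec.tau_s))
    elif spec.family == "transient_biexponential":
        raw = np.exp(-t / spec.tau_s) - np.exp(-t / spec.tau_fast_s)
        # normalise so the analytic peak equals A
        r = spec.tau_fast_s / spec.tau_s
        t_pk = spec.tau_fast_s * math.log(1.0 / r) / (1.0 - r)
        peak = math.exp(-t_pk / spec.tau_s) - math.exp(-t_pk / spec.tau_fast_s)
        y = A * raw / peak
    elif spec.family == "damped_sinusoid":
        y = A * np.exp(-t / spec.tau_damp_s) * (1.0 - np.cos(2.0 * math.pi * t / spec.period_s))
    elif spec.family == "triangle_input":
        y = np.where(
            t < spec.rise_s,
            A * t / spec.rise_s,
            np.clip(A * (1.0 - (t - spec.rise_s) / spec.fall_s), 0.0, None),
        )
    else:  # constant
        y = np.full_like(t, A)
    return ResponseTrace(t, y)


def default_fixture_specs() -> dict[str, FixtureSpec]:
    """One canonical spec per family, with its expected label under defaults."""
    return {
        "sustained_exponential": FixtureSpec(
            "sustained_exponential", amplitude_pM=20.0, tau_s=600.0,
            expected_label="sustained"),
        "transient_biexponential": FixtureSpec(
            "transient_biexponential", amplitude_pM=30.0, tau_s=900.0,
            tau_fast_s=150.0, expected_label="transient"),
        "damped_sinusoid": FixtureSpec(
            "damped_sinusoid", amplitude_pM=15.0, period_s=5400.0,
            tau_damp_s=40000.0, expected_label="sustained_oscillatory"),
        "triangle_input": FixtureSpec(
            "triangle_input", amplitude_pM=720.0, expected_label="undefined"),
        "constant": FixtureSpec(
            "constant", amplitude_pM=0.0, expected_label="unresponsive"),
    }


def make_parameter_fixtures() -> dict[str, ParameterSet]:
    """Vetted kinetic parameter sets, one per simulated response family.

    Loaded from the plain-text fixture files shipped with the package;
    each was found by rejection sampling over the default ranges (see
    ``scripts/find_fixtures.py``) and its label confirmed with the
    independent fixed-step oracle at freeze time.
    """
    path = resources.files("smadscreen") / "fixtures" / "parameter_fixtures.yaml"
    data = yaml.safe_load(path.read_text())
    out = {}
    for family, entry in data["fixtures"].items():
        out[family] = ParameterSet.from_dict(entry["parameters"])
    return out


def fixture_metadata() -> dict:
    """Raw fixture file contents, including expected labels and provenance."""
    path = resources.files("smadscreen") / "fixtures" / "parameter_fixtures.yaml"
    return yaml.safe_load(path.read_text())
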