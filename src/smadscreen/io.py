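"""Configuration files, result tables and trace serialization.

One YAML config format drives every pipeline command; all classifier
thresholds and protocol values are exposed as keys with the canonical
defaults (theta = 10 pM, 200 pM constant stimulus, totals 1/60/100 nM).
Result tables are TSV with a stable, documented column order and full
float precision, and reading is the exact inverse of writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import ClassifierConfig, LABELS
from .model import (
    LigandProtocol,
    ParameterSet,
    ResponseTrace,
    SolverOptions,
    TotalConcentrations,
)
from .screen import RangeTable, default_ranges

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_results",
    "read_results",
    "read_trace_tsv",
    "write_trace_tsv",
    "write_parameters",
    "read_parameters",
]


@dataclass
class RunConfig:
    """Fully resolved settings for one screen/analysis run."""

    n: int
    seed: int
    ranges: RangeTable = field(default_factory=default_ranges)
    totals: TotalConcentrations = field(default_factory=TotalConcentrations)
    protocol: LigandProtocol = field(default_factory=LigandProtocol.constant)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    solver: SolverOptions = field(default_factory=SolverOptions.screening)
    workers: int = 1
    out: str = "screen.tsv"

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be a non-negative 31-bit integer")


_PROTOCOL_KEYS = {"kind", "ligand_pM", "duration_s", "peak_pM", "rise_s", "fall_s"}
_CLASSIFIER_KEYS = {
    "theta_pM", "t_fast_s", "t_end_s", "t_max_s", "sustained_fraction",
    "transient_fraction", "amplitude_floor_fraction", "min_extra_peaks",
    "damp_ratio", "series_mode", "series_floor_pM",
}
_SOLVER_KEYS = {"method", "rtol", "atol", "grid_s"}
_TOP_KEYS = {"n", "seed", "ranges", "totals", "protocol", "classifier", "solver",
             "workers", "out"}


def _check_keys(d: dict, allowed: set, where: str):
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown {where} keys: {sorted(unknown)}")


def _protocol_from_dict(d: dict) -> LigandProtocol:
    _check_keys(d, _PROTOCOL_KEYS, "protocol")
    kind = d.get("kind", "constant")
    if kind == "constant":
        return LigandProtocol.constant(d.get("ligand_pM", 200.0), d.get("duration_s", 36000.0))
    if kind == "triangle":
        return LigandProtocol.triangle(d.get("peak_pM", 720.0), d.get("rise_s", 18000.0),
                                       d.get("fall_s", 18000.0))
    raise ValueError(f"unknown protocol kind {kind!r}")


def _protocol_to_dict(p: LigandProtocol) -> dict:
    if p.kind == "constant":
        return {"kind": "constant", "ligand_pM": p.level_pM, "duration_s": p.duration_s}
    return {"kind": "triangle", "peak_pM": p.peak_pM, "rise_s": p.rise_s, "fall_s": p.fall_s}


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys(raw, _TOP_KEYS, "config")
    for key in ("n", "seed"):
        if key not in raw:
            raise ValueError(f"config is missing required key {key!r}")
    ranges = default_ranges()
    if "ranges" in raw:
        ranges = RangeTable({**{k: tuple(v) for k, v in ranges.to_dict().items()},
                             **{k: tuple(v) for k, v in raw["ranges"].items()}},
                            provenance="user")
    totals = TotalConcentrations(**raw.get("totals", {}))
    protocol = _protocol_from_dict(raw.get("protocol", {}))
    cls_raw = raw.get("classifier", {})
    _check_keys(cls_raw, _CLASSIFIER_KEYS, "classifier")
    classifier = ClassifierConfig(**cls_raw)
    sol_raw = raw.get("solver", {})
    _check_keys(sol_raw, _SOLVER_KEYS, "solver")
    solver = SolverOptions.screening() if not sol_raw else SolverOptions(
        **{**{"rtol": 1e-6, "atol": 1e-10}, **sol_raw})
    return RunConfig(
        n=int(raw["n"]), seed=int(raw["seed"]), ranges=ranges, totals=totals,
        protocol=protocol, classifier=classifier, solver=solver,
        workers=int(raw.get("workers", 1)), out=str(raw.get("out", "screen.tsv")),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    c = cfg.classifier
    s = cfg.solver
    return {
        "n": cfg.n,
        "seed": cfg.seed,
        "ranges": cfg.ranges.to_dict(),
        "totals": cfg.totals.to_dict(),
        "protocol": _protocol_to_dict(cfg.protocol),
        "classifier": {
            "theta_pM": c.theta_pM, "t_fast_s": c.t_fast_s, "t_end_s": c.t_end_s,
            "t_max_s": c.t_max_s, "sustained_fraction": c.sustained_fraction,
            "transient_fraction": c.transient_fraction,
            "amplitude_floor_fraction": c.amplitude_floor_fraction,
            "min_extra_peaks": c.min_extra_peaks, "damp_ratio": c.damp_ratio,
            "series_mode": c.series_mode, "series_floor_pM": c.series_floor_pM,
        },
        "solver": {"method": s.method, "rtol": s.rtol, "atol": s.atol, "grid_s": s.grid_s},
        "workers": cfg.workers,
        "out": cfg.out,
    }


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def _fmt_float(v) -> str:
    """Shortest decimal string that round-trips the float64 exactly."""
    return repr(float(v))


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV (header, stable column order, full precision)."""
    # repr gives the shortest decimal string that round-trips a float64
    table.to_csv(path, sep="\t", index=False, float_format=_fmt_float)


def read_results(path) -> pd.DataFrame:
    """Exact inverse of :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "label" in df.columns:
        bad = set(df["label"].dropna()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels in result file: {sorted(bad)}")
    return df


def write_trace_tsv(trace: ResponseTrace, path) -> None:
    """Two-column time/value TSV of a response trace."""
    pd.DataFrame({"time_s": trace.t, f"value_{trace.unit}": trace.value}).to_csv(
        path, sep="\t", index=False, float_format=_fmt_float)


def read_trace_tsv(path) -> ResponseTrace:
    """Read any two-column time/value TSV as a response trace."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("trace file must have two columns: time and value")
    unit = "pM"
    name = df.columns[1]
    if "_" in name:
        unit = name.rsplit("_", 1)[1]
    return ResponseTrace(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), unit=unit)


def write_parameters(params: ParameterSet, path, totals: TotalConcentrations | None = None) -> None:
    """Flat key-value file (YAML) with k1..k19, h and optionally the totals."""
    data = params.to_dict()
    if totals is not None:
        data.update(totals.to_dict())
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_parameters(path) -> tuple[ParameterSet, TotalConcentrations | None]:
    data = yaml.safe_load(Path(path).read_text())
    totals = None
    tot_keys = {"R_tot", "S_tot", "C_tot"}
    if tot_keys & set(data):
        totals = TotalConcentrations(**{k: data.pop(k) for k in tot_keys if k in data})
    return ParameterSet.from_dict(data), totals
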