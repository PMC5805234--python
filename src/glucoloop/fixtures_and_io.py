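"""Configuration parsing, serialization and synthetic test fixtures.

The parameter and initial-value tables live in a plain YAML config, one key
per model symbol, with a ``conditions:`` section in which the T2DM entries
override the NGR defaults (the alternate parameter sets are expressed as
diffs).  Trajectories serialize to CSV with a ``time_min`` column; reports
serialize to JSON.  All serialization is lossless at double precision and
all fixture randomness is seed-controlled.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adipocyte_signaling import CELLULAR_STATE_NAMES, CellularParams
from .parameter_workflow import DERIVED_PARAM_NAMES, PhysiologicalRanges
from .whole_body import WHOLE_BODY_STATE_NAMES, WholeBodyParams

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "read_config",
    "load_condition_tables",
    "load_ranges",
    "write_trajectory",
    "read_trajectory",
    "write_report",
]

_CONDITION_TAGS = ("NGR", "T2DM")
_SECTION_NAMES = ("whole_body", "cellular", "initial_whole_body",
                  "initial_cellular")

# Whole-body parameters expected in the config: everything except the eight
# steady-state-derived ones and kgluc (which is supplied by the cellular
# table, being shared between the layers).
_WB_CONFIG_KEYS = frozenset(WholeBodyParams.__dataclass_fields__) \
    - set(DERIVED_PARAM_NAMES) - {"kgluc"}
_CELL_CONFIG_KEYS = frozenset(CellularParams.__dataclass_fields__) \
    - {"irs1_printed_variant"}


def _default_config_path() -> Path:
    return Path(importlib.resources.files("glucoloop") / "data" / "defaults.yaml")


def _default_ranges_path() -> Path:
    return Path(importlib.resources.files("glucoloop") / "data" / "ranges.yaml")


def read_config(source=None) -> dict:
    """Load and structurally validate a condition config file.

    Unknown symbols are rejected with the offending key named; every
    non-derived whole-body parameter, cellular parameter and whole-body
    initial value must be present in the NGR base tables.
    """
    path = Path(source) if source is not None else _default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"malformed config {path}: top level must be a mapping")
    unknown = set(raw) - {"conditions", "steady_state"}
    if unknown:
        raise KeyError(f"unknown top-level config key {sorted(unknown)[0]!r}")
    conditions = raw.get("conditions")
    if not isinstance(conditions, dict) or "NGR" not in conditions:
        raise KeyError("config must provide conditions with an NGR base")
    for tag, sections in conditions.items():
        if tag not in _CONDITION_TAGS:
            raise KeyError(f"unknown condition tag {tag!r}")
        unknown = set(sections) - set(_SECTION_NAMES)
        if unknown:
            raise KeyError(f"unknown config section {sorted(unknown)[0]!r} "
                           f"under condition {tag}")
        _check_symbols(sections.get("whole_body", {}), _WB_CONFIG_KEYS,
                       f"{tag}.whole_body")
        _check_symbols(sections.get("cellular", {}), _CELL_CONFIG_KEYS,
                       f"{tag}.cellular")
        _check_symbols(sections.get("initial_whole_body", {}),
                       set(WHOLE_BODY_STATE_NAMES), f"{tag}.initial_whole_body")
        _check_symbols(sections.get("initial_cellular", {}),
                       set(CELLULAR_STATE_NAMES), f"{tag}.initial_cellular")
    base = conditions["NGR"]
    for key in sorted(_WB_CONFIG_KEYS - set(base.get("whole_body", {}))):
        raise KeyError(f"config missing whole-body parameter {key!r}")
    for key in sorted(_CELL_CONFIG_KEYS - set(base.get("cellular", {}))):
        raise KeyError(f"config missing cellular parameter {key!r}")
    for key in sorted(set(WHOLE_BODY_STATE_NAMES)
                      - set(base.get("initial_whole_body", {}))):
        raise KeyError(f"config missing initial value {key!r}")
    return raw


def _check_symbols(mapping: dict, allowed: set, where: str) -> None:
    for key, value in mapping.items():
        if key not in allowed:
            raise KeyError(f"unknown symbol {key!r} in {where}")
        if not isinstance(value, (int, float)) or not math.isfinite(value):
            raise ValueError(f"symbol {key!r} in {where} must be a finite "
                             f"number, got {value!r}")


def load_condition_tables(tag: str, source=None) -> dict:
    """Resolve the tables for one condition: NGR base with the requested
    condition's entries overriding, section by section."""
    if tag not in _CONDITION_TAGS:
        raise KeyError(f"unknown condition tag {tag!r}; expected one of "
                       f"{_CONDITION_TAGS}")
    raw = read_config(source)
    base = raw["conditions"]["NGR"]
    tables = {section: dict(base.get(section, {}))
              for section in _SECTION_NAMES}
    if tag != "NGR":
        if tag not in raw["conditions"]:
            raise KeyError(f"config has no condition {tag!r}")
        for section, overrides in raw["conditions"][tag].items():
            tables[section].update(overrides)
    tables["steady_state"] = dict(raw.get("steady_state", {}))
    return tables


def load_ranges(source=None) -> PhysiologicalRanges:
    """Load the physiological band table (LL/HL per variable)."""
    path = Path(source) if source is not None else _default_ranges_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"malformed ranges file {path}")
    return PhysiologicalRanges.from_mapping(raw)


# ---------------------------------------------------------------------------
# Trajectory / report serialization
# ---------------------------------------------------------------------------

def write_trajectory(traj, path) -> None:
    """CSV with a ``time_min`` column plus one named column per state,
    written at full double precision (column order is stable)."""
    traj.frame.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path):
    from .coupling import Trajectory

    frame = pd.read_csv(path, float_precision="round_trip")
    if "time_min" not in frame.columns:
        raise ValueError(f"trajectory file {path} lacks a time_min column")
    time = frame["time_min"].to_numpy()
    cols = {c: frame[c].to_numpy() for c in frame.columns if c != "time_min"}
    return Trajectory(time, cols, metadata={"source": str(path)})


def write_report(report, path) -> None:
    """Serialize an estimation/validation report (dataclass or dict) to JSON."""
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        payload = dataclasses.asdict(report)
    else:
        payload = report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic trace with analytically known ground truth.

    kind:
      * ``multi_bump`` — baseline plus Gaussian bumps at ``centers`` with
        ``widths`` and ``amplitudes``; ground truth = peak count/times.
      * ``monotone`` — strictly decreasing exponential-like trace; ground
        truth = zero peaks.
      * ``range_violation`` — flat trace at ``baseline`` with rectangular
        excursions over ``violation_windows`` (t0, t1, level); ground truth
        = the window list.
    """

    kind: str
    duration: float = 1000.0
    dt: float = 1.0
    column: str = "S"
    baseline: float = 10.0
    centers: tuple[float, ...] = ()
    widths: tuple[float, ...] = ()
    amplitudes: tuple[float, ...] = ()
    decay_rate: float = 0.005
    violation_windows: tuple[tuple[float, float, float], ...] = ()
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multi_bump", "monotone", "range_violation"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.kind == "multi_bump" and not (
                len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("centers, widths and amplitudes must align")


def generate_fixture(spec: FixtureSpec):
    """Deterministic synthetic trajectory with ground truth in metadata.

    A multi-bump spec whose bumps merge (the clean trace has fewer local
    maxima than bumps) is rejected with an explanation rather than silently
    producing a wrong ground truth.
    """
    from .coupling import Trajectory

    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    meta: dict = {"spec": dataclasses.asdict(spec)}

    if spec.kind == "multi_bump":
        x = np.full_like(t, spec.baseline)
        for c, w, a in zip(spec.centers, spec.widths, spec.amplitudes):
            x += a * np.exp(-0.5 * ((t - c) / w) ** 2)
        interior = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
        n_peaks = int(interior.sum())
        if n_peaks != len(spec.centers):
            raise ValueError(
                f"bump spec rejected: {len(spec.centers)} bumps produce "
                f"{n_peaks} distinct peaks (bumps overlap and merge); "
                "space the centers further apart or narrow the widths")
        meta["expected_peak_times"] = list(spec.centers)
    elif spec.kind == "monotone":
        x = spec.baseline + 100.0 * np.exp(-spec.decay_rate * t)
        meta["expected_peak_times"] = []
    else:  # range_violation
        x = np.full_like(t, spec.baseline)
        for t0, t1, level in spec.violation_windows:
            x[(t >= t0) & (t <= t1)] = level
        meta["violation_windows"] = [list(w) for w in spec.violation_windows]

    if spec.noise > 0:
        x = x + rng.normal(scale=spec.noise, size=x.shape)

    return Trajectory(t, {spec.column: x}, meta)
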