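"""Coupled 41-state simulator: whole-body hormones + adipocyte signaling.

The two layers share five quantities: plasma insulin I and glucose G set the
interstitial deviations INS_A and Gt_A, INS_A drives the receptor cascade,
and the GLUT1/GLUT4-mediated uptake flux returns to the whole-body adipose
glucose mass A.  Each shared variable appears exactly once in the combined
state vector (14 whole-body components followed by 27 cellular species).

Integration uses a stiff multistep (BDF) solver.  The glucagon gate is an
exact Heaviside by default; its discontinuity is handled by locating the
threshold crossing ``G = Ge`` with an event and restarting the integrator
there.  A smoothed (tanh) gate is available through the configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .adipocyte_signaling import (
    CELLULAR_STATE_NAMES,
    CellularParams,
    CellularState,
    adipose_glucose_uptake,
    cellular_rhs,
    conserved_totals,
    relax_to_steady_state,
)
from .whole_body import (
    NEGATIVE_GUARD,
    WHOLE_BODY_STATE_NAMES,
    WholeBodyParams,
    WholeBodyState,
    heaviside_switch,
    smoothed_heaviside,
    whole_body_rhs,
)

__all__ = [
    "FULL_STATE_NAMES",
    "SimulationConfig",
    "Trajectory",
    "ConditionPreset",
    "assemble_full_rhs",
    "solve_trajectory",
    "simulate",
    "simulate_clamped",
    "detect_meals",
    "condition_preset",
]

#: Column order of the combined state: whole-body first, then cellular.
FULL_STATE_NAMES: tuple[str, ...] = WHOLE_BODY_STATE_NAMES + CELLULAR_STATE_NAMES

_N_WB = len(WHOLE_BODY_STATE_NAMES)
_IDX_G = WHOLE_BODY_STATE_NAMES.index("G")
_IDX_INS_A = WHOLE_BODY_STATE_NAMES.index("INS_A")
_IDX_GT_A = WHOLE_BODY_STATE_NAMES.index("Gt_A")
_IDX_GLUT4M = _N_WB + CELLULAR_STATE_NAMES.index("GLUT4m")


@dataclass(frozen=True)
class SimulationConfig:
    """Solver and experiment settings.

    duration : minutes simulated (default 1000, three meal cycles).
    rtol, atol : BDF tolerances.
    output_dt : spacing of the output grid in minutes.
    heaviside_mode : "exact" (event-located restarts) or "smoothed"
        (tanh with ``heaviside_steepness`` per mg/dL).
    """

    duration: float = 1000.0
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = np.inf
    condition: str = "NGR"
    heaviside_mode: str = "exact"
    heaviside_steepness: float = 10.0
    output_dt: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.heaviside_mode not in ("exact", "smoothed"):
            raise ValueError(f"unknown heaviside_mode {self.heaviside_mode!r}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def heaviside(self):
        if self.heaviside_mode == "exact":
            return heaviside_switch
        return smoothed_heaviside(self.heaviside_steepness)


class Trajectory:
    """Time grid plus named state columns; the unit of downstream analysis.

    Thin wrapper over a :class:`pandas.DataFrame` whose first column is
    ``time_min``; metadata carries the condition tag, a configuration echo
    and integration diagnostics (conserved-total drift, raw state minima).
    """

    def __init__(self, time: np.ndarray, columns: dict[str, np.ndarray],
                 metadata: dict | None = None) -> None:
        time = np.asarray(time, dtype=float)
        if time.ndim != 1 or np.any(np.diff(time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        data = {"time_min": time}
        for name, values in columns.items():
            values = np.asarray(values, dtype=float)
            if values.shape != time.shape:
                raise ValueError(f"column {name!r} length mismatch")
            data[name] = values
        self.frame = pd.DataFrame(data)
        self.metadata = dict(metadata or {})

    @property
    def time(self) -> np.ndarray:
        return self.frame["time_min"].to_numpy()

    @property
    def columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "time_min"]

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise KeyError(f"no state column {name!r}; have {self.columns}")
        return self.frame[name].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def final_state(self) -> dict[str, float]:
        return {c: float(self.frame[c].iloc[-1]) for c in self.columns}


@dataclass(frozen=True)
class ConditionPreset:
    """Fully populated parameter set and fasting initial state for one
    condition (NGR or T2DM)."""

    name: str
    whole_body: WholeBodyParams
    cellular: CellularParams
    initial_whole_body: WholeBodyState
    initial_cellular: CellularState
    metadata: dict = field(default_factory=dict, compare=False)

    def initial_array(self) -> np.ndarray:
        return np.concatenate([self.initial_whole_body.as_array(),
                               self.initial_cellular.as_array()])


def assemble_full_rhs(wstate, cstate, preset: ConditionPreset,
                      heaviside=heaviside_switch) -> np.ndarray:
    """Derivatives of the 41 combined states.

    The cellular uptake flux (GLUT4m, Gt_A) is computed first and passed
    into the whole-body adipose balance; the whole-body interstitial
    insulin INS_A drives the cascade.
    """
    w = np.asarray(wstate, dtype=float)
    c = np.asarray(cstate, dtype=float)
    if w.shape != (_N_WB,) or c.shape != (len(CELLULAR_STATE_NAMES),):
        raise ValueError("state length mismatch: expected 14 whole-body and "
                         f"27 cellular components, got {w.shape} and {c.shape}")
    gt_a = max(w[_IDX_GT_A], 0.0)
    ins_a = max(w[_IDX_INS_A], 0.0)
    glut4m = max(c[CELLULAR_STATE_NAMES.index("GLUT4m")], 0.0)
    uptake = adipose_glucose_uptake(glut4m, gt_a, preset.cellular)
    dw = whole_body_rhs(w, uptake, preset.whole_body, heaviside)
    dc = cellular_rhs(c, ins_a, preset.cellular)
    return np.concatenate([dw, dc])


def solve_trajectory(rhs, y0, names, config: SimulationConfig,
                     event=None, metadata: dict | None = None) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y)`` with BDF on the configured grid.

    ``event``, if given, is a scalar crossing function ``g(t, y)``; the
    integration stops at each root of g and restarts there, so an exact
    discontinuity in the right-hand side at ``g = 0`` never sits inside a
    solver step.  Raises ``RuntimeError`` with the failure time if the
    integrator cannot proceed (step-size collapse).
    """
    y0 = np.asarray(y0, dtype=float)
    t_grid = np.arange(0.0, config.duration + 0.5 * config.output_dt,
                       config.output_dt)
    t_grid = t_grid[t_grid <= config.duration]

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    t0, y = 0.0, y0.copy()
    events = None
    if event is not None:
        event.terminal = True
        events = [event]
    n_restarts = 0
    while True:
        mask = (t_grid >= t0) & (t_grid <= config.duration)
        t_eval = t_grid[mask]
        sol = solve_ivp(rhs, (t0, config.duration), y, method="BDF",
                        rtol=config.rtol, atol=config.atol,
                        max_step=config.max_step,
                        t_eval=t_eval if len(t_eval) else None,
                        events=events, dense_output=False)
        if sol.status == -1:
            raise RuntimeError(
                f"integrator failure at t = {sol.t[-1] if len(sol.t) else t0:.3f}"
                f" min: {sol.message}")
        if len(sol.t):
            # drop a grid point duplicated across a restart
            start = 1 if (times and len(sol.t) and sol.t[0] <= times[-1][-1]) else 0
            times.append(sol.t[start:])
            states.append(sol.y[:, start:])
        if sol.status == 1:  # event: restart exactly at the crossing
            t0 = float(sol.t_events[0][0])
            y = sol.y_events[0][0]
            n_restarts += 1
            if t0 >= config.duration:
                break
            continue
        break

    t = np.concatenate(times) if times else np.array([0.0])
    ymat = np.hstack(states) if states else y0[:, None]
    if t[0] > 0.0:  # ensure the initial point is present
        t = np.concatenate([[0.0], t])
        ymat = np.hstack([y0[:, None], ymat])

    raw_min = {n: float(ymat[i].min()) for i, n in enumerate(names)}
    # integrator noise below zero is clipped; anything beyond the guard is
    # surfaced through the raw minima diagnostic
    ymat = np.where((ymat < 0) & (ymat > NEGATIVE_GUARD), 0.0, ymat)

    meta = dict(metadata or {})
    meta.update({
        "config": dataclasses.asdict(config),
        "raw_min": raw_min,
        "n_event_restarts": n_restarts,
    })
    return Trajectory(t, {n: ymat[i] for i, n in enumerate(names)}, meta)


def _make_event(preset: ConditionPreset):
    Ge = preset.whole_body.Ge

    def crossing(t, y):
        return Ge - y[_IDX_G]

    return crossing


def simulate(preset: ConditionPreset, config: SimulationConfig) -> Trajectory:
    """Run the closed-loop coupled model from the fasting initial state.

    Deterministic for fixed preset and configuration.  The returned
    trajectory's metadata records conserved-total drift of the ten cellular
    protein cycles and the raw (pre-clipping) minimum of every state.
    """
    heaviside = config.heaviside()

    def rhs(t, y):
        # the solver legitimately probes slightly out-of-domain trial
        # states; evaluate rate laws on the physical orthant and surface
        # genuine negativity through the raw-minimum diagnostic instead
        y = np.clip(y, 0.0, None)
        return assemble_full_rhs(y[:_N_WB], y[_N_WB:], preset, heaviside)

    event = _make_event(preset) if config.heaviside_mode == "exact" else None
    traj = solve_trajectory(rhs, preset.initial_array(), FULL_STATE_NAMES,
                            config, event=event,
                            metadata={"condition": preset.name})
    traj.metadata["conserved_drift"] = _conserved_drift(traj)
    return traj


def _conserved_drift(traj: Trajectory) -> dict[str, float]:
    """Max relative drift of each conserved cellular total along the run."""
    cmat = np.vstack([traj[n] for n in CELLULAR_STATE_NAMES])
    totals0 = conserved_totals(cmat[:, 0])
    drift = {}
    for group, ref in totals0.items():
        series = np.zeros(cmat.shape[1])
        from .adipocyte_signaling import CONSERVED_GROUPS
        for sp in CONSERVED_GROUPS[group]:
            series += traj[sp]
        if ref == 0:
            drift[group] = float(np.abs(series).max())
        else:
            drift[group] = float(np.abs(series - ref).max() / abs(ref))
    return drift


def simulate_clamped(preset: ConditionPreset, config: SimulationConfig,
                     clamps: dict[str, float]) -> Trajectory:
    """Integrate with selected state variables frozen at constant values.

    Useful for isolating single equations (e.g. clamping G above Ge and I
    constant makes plasma glucagon relax exponentially to c0/c3).
    """
    unknown = set(clamps) - set(FULL_STATE_NAMES)
    if unknown:
        raise ValueError(f"unknown state variables in clamps: {sorted(unknown)}")
    idx = {FULL_STATE_NAMES.index(k): float(v) for k, v in clamps.items()}
    heaviside = config.heaviside()

    def rhs(t, y):
        y = np.clip(y, 0.0, None)
        for i, v in idx.items():
            y[i] = v
        d = assemble_full_rhs(y[:_N_WB], y[_N_WB:], preset, heaviside)
        for i in idx:
            d[i] = 0.0
        return d

    y0 = preset.initial_array()
    for i, v in idx.items():
        y0[i] = v
    event = _make_event(preset) if (config.heaviside_mode == "exact"
                                    and _IDX_G not in idx) else None
    traj = solve_trajectory(rhs, y0, FULL_STATE_NAMES, config, event=event,
                            metadata={"condition": preset.name,
                                      "clamps": dict(clamps)})
    traj.metadata["conserved_drift"] = _conserved_drift(traj)
    return traj


def detect_meals(traj: Trajectory, variable: str = "S",
                 prominence_fraction: float = 0.2) -> np.ndarray:
    """Meal-episode times: prominent local maxima of one trajectory column.

    A peak counts as a meal when its prominence exceeds
    ``prominence_fraction * (column max - column min)``.  Stomach glucose S
    is the default marker; the hunger signal H is an accepted alternative.
    Returns an empty array for a flat trace.
    """
    x = traj[variable]
    span = float(x.max() - x.min())
    if span == 0.0:
        return np.array([])
    peaks, _ = find_peaks(x, prominence=prominence_fraction * span)
    return traj.time[peaks]


def condition_preset(tag: str, config_source=None,
                     rho: float | None = None) -> ConditionPreset:
    """Build a fully populated NGR or T2DM preset.

    Reads the parameter/initial-value tables (packaged defaults, or a
    user-supplied config file), derives the eight steady-state-constrained
    parameters at the fasting state, and relaxes the signaling cascade to
    its unstimulated steady state for the fasting cellular initial values.

    Raises ``KeyError`` naming any missing symbol.
    """
    from .fixtures_and_io import load_condition_tables
    from .parameter_workflow import derive_steady_state_params

    tables = load_condition_tables(tag, config_source)
    wb_kwargs = dict(tables["whole_body"])
    cell_kwargs = dict(tables["cellular"])
    init_wb = dict(tables["initial_whole_body"])
    init_cell_seed = dict(tables["initial_cellular"])
    if rho is None:
        rho = float(tables.get("steady_state", {}).get("rho", 0.5))

    cell_kwargs.setdefault("irs1_printed_variant", False)
    cp = CellularParams(**cell_kwargs)
    cp.validate()

    # fasting cellular state: unstimulated steady state of the cascade
    seed_state = np.zeros(len(CELLULAR_STATE_NAMES))
    for name, value in init_cell_seed.items():
        seed_state[CELLULAR_STATE_NAMES.index(name)] = float(value)
    cell0 = CellularState.from_array(
        _cached_unstimulated(cp, tuple(seed_state.tolist())))

    wstate0 = WholeBodyState(**{k: float(v) for k, v in init_wb.items()})

    # placeholders for the derived parameters; filled right below
    partial = WholeBodyParams(**{**wb_kwargs, "kgluc": cp.kgluc,
                                 **{k: 1.0 for k in
                                    ("b4", "b5", "b12", "b13", "b17", "b27",
                                     "c", "c3")}})
    derived = derive_steady_state_params(wstate0, partial, rho)
    wp = partial.replace(**derived)
    wp.validate()

    return ConditionPreset(
        name=tag, whole_body=wp, cellular=cp,
        initial_whole_body=wstate0, initial_cellular=cell0,
        metadata={"rho": rho, "derived_params": derived,
                  "config_source": str(config_source) if config_source else
                  "packaged defaults"},
    )


_UNSTIMULATED_CACHE: dict[tuple, np.ndarray] = {}


def _cached_unstimulated(cp: CellularParams, seed_state: tuple) -> np.ndarray:
    key = (cp, seed_state)
    if key not in _UNSTIMULATED_CACHE:
        _UNSTIMULATED_CACHE[key] = relax_to_steady_state(
            np.array(seed_state), cp, INS_A=0.0)
    return _UNSTIMULATED_CACHE[key]
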