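"""Scenario construction and time integration.

Scenarios describe a cell pair (or an arbitrary cell graph) with per-cell
initial conditions and a list of timed environment events — the mutation
studies switch the APC multiplier ``rho_apc`` (1 -> 0.5 -> 0, the single-
and two-hit knockouts) or the local Wnt stimulus ``W`` (1 -> 2,
hyperstimulation) on one cell mid-simulation. Events change environment
parameters only; the state is continuous across them, which the integrator
honours by stopping and restarting at each event time.

Deterministic runs use a stiff solver (LSODA by default) with tight
tolerances because the oscillation-period measurements downstream are
tolerance-sensitive. The stochastic extension perturbs the Hes1 production
term with additive Gaussian noise on a fixed-step Euler scheme, either with
Wiener scaling (``sigma*sqrt(dt)`` on the state, step-size consistent) or
in a literal per-step mode (``N(0, sigma^2)`` added to the Hes1 equation at
every step).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InputError, IntegrationError
from .model import IDX, N_SPECIES, NOTCH_SPECIES, SPECIES
from .multicell import CellEnv, CellGraph, coupled_rhs, pair_graph
from .params import ModelParams, default_params
from .steady import wnt_steady_state

__all__ = [
    "Event", "Scenario", "Trajectory", "build_scenario",
    "run_deterministic", "run_stochastic", "standard_initial_state",
]

_H1 = IDX["H1"]

#: scenario kinds implemented by :func:`build_scenario`
SCENARIO_KINDS = ("healthy_pair", "apc_mutant_pair", "wnt_hyper_pair")


@dataclass(frozen=True)
class Event:
    """Timed change of one environment field on one cell."""

    time_h: float
    cell: str
    fieldname: str  # "W" | "rho_apc" | "theta2"
    value: float


@dataclass
class Scenario:
    """A runnable experiment: graph, initial state, horizon and events."""

    graph: CellGraph
    y0: np.ndarray                  # (n_cells, 12)
    horizon_h: float
    events: list = field(default_factory=list)
    kind: str = "custom"

    def __post_init__(self):
        self.y0 = np.asarray(self.y0, dtype=float)
        if self.y0.shape != (len(self.graph), N_SPECIES):
            raise InputError(
                f"y0 must have shape ({len(self.graph)}, {N_SPECIES}), got {self.y0.shape}")
        if np.any(self.y0 < 0):
            raise InputError("initial concentrations must be >= 0")
        for ev in self.events:
            if not 0.0 <= ev.time_h <= self.horizon_h:
                raise InputError(f"event at t={ev.time_h} h outside [0, {self.horizon_h}] h")
            if ev.fieldname not in ("W", "rho_apc", "theta2"):
                raise InputError(f"unknown event field {ev.fieldname!r}")
            self.graph.index(ev.cell)  # raises for unknown cells
        self.events = sorted(self.events, key=lambda e: e.time_h)


@dataclass
class Trajectory:
    """Time grid x cells x species concentrations, with run metadata."""

    t_min: np.ndarray               # (n_t,)
    data: np.ndarray                # (n_t, n_cells, n_species)
    cells: list
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    species: tuple = SPECIES

    @property
    def t_h(self) -> np.ndarray:
        return self.t_min / 60.0

    def series(self, cell, species) -> np.ndarray:
        """Concentration time series for one cell and species."""
        ci = self.cells.index(cell)
        return self.data[:, ci, self.species.index(species)]

    def window(self, t0_h, t1_h):
        """Boolean mask selecting ``t0_h <= t <= t1_h``."""
        return (self.t_h >= t0_h) & (self.t_h <= t1_h)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format table (time_min, cell, species, value)."""
        n_t, n_c, n_s = self.data.shape
        return pd.DataFrame({
            "time_min": np.repeat(self.t_min, n_c * n_s),
            "cell": np.tile(np.repeat(self.cells, n_s), n_t),
            "species": np.tile(list(self.species), n_t * n_c),
            "value": self.data.reshape(-1),
        })

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "cells": list(self.cells),
            "events": [vars(e) if not isinstance(e, dict) else e for e in
                       ({"time_h": ev.time_h, "cell": ev.cell,
                         "field": ev.fieldname, "value": ev.value}
                        for ev in self.events)],
            **self.meta,
        }

    def save_manifest(self, path):
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=str)


def _params_hash(params: ModelParams) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def standard_initial_state(params: ModelParams, W, notch_value=0.5) -> np.ndarray:
    """Standard starting conditions: Notch species at ``notch_value`` nM and
    the Wnt species at the decoupled Wnt submodel's steady state for the
    given stimulus ``W`` (a self-consistent start for the tissue context)."""
    y = np.zeros(N_SPECIES)
    for s in NOTCH_SPECIES:
        y[IDX[s]] = notch_value
    y[[IDX["B"], IDX["A"], IDX["G"], IDX["C"], IDX["I2"]]] = wnt_steady_state(params, W)
    return y


def build_scenario(kind, theta2=None, W=1.0, params: ModelParams | None = None,
                   horizon_h=36.0, notch_ic=(0.5, 0.51), overrides=None) -> Scenario:
    """Construct one of the named cell-pair experiments.

    ``healthy_pair`` — two coupled cells, no events; the first cell starts
    all Notch species at 0.50 nM, the second at 0.51 nM (the asymmetry that
    lets heterogeneous states emerge), Wnt species at standard conditions.

    ``apc_mutant_pair`` — the second cell acquires a single-hit APC knockout
    (``rho_apc = 0.5``) at t = 12 h and the second hit (``rho_apc = 0``) at
    t = 24 h.

    ``wnt_hyper_pair`` — the second cell switches to a hyperstimulated
    ``W = 2`` state at t = 12 h.

    ``overrides`` may patch any :class:`Scenario` attribute after
    construction (e.g. ``{"horizon_h": 48.0}``).
    """
    if kind not in SCENARIO_KINDS:
        raise InputError(f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
    params = params or default_params()
    th = params.theta2 if theta2 is None else float(theta2)
    if not 0.0 <= th <= 1.0:
        raise InputError(f"theta2 must lie in [0, 1], got {th}")

    env1 = CellEnv(W=W, theta2=th)
    env2 = CellEnv(W=W, theta2=th)
    graph = pair_graph(W=W, env1=env1, env2=env2)

    y0 = np.stack([
        standard_initial_state(params, W, notch_value=notch_ic[0]),
        standard_initial_state(params, W, notch_value=notch_ic[1]),
    ])

    events = []
    if kind == "apc_mutant_pair":
        events = [Event(12.0, "cell2", "rho_apc", 0.5),
                  Event(24.0, "cell2", "rho_apc", 0.0)]
    elif kind == "wnt_hyper_pair":
        events = [Event(12.0, "cell2", "W", 2.0)]

    scen = Scenario(graph=graph, y0=y0, horizon_h=horizon_h, events=events, kind=kind)
    for k, v in (overrides or {}).items():
        setattr(scen, k, v)
    return scen


def _env_schedule(scenario: Scenario, params: ModelParams):
    """Event times (min) and the per-segment environment arrays."""
    graph = scenario.graph
    W, rho, th = (a.astype(float).copy() for a in graph.env_arrays(params))
    horizon_min = scenario.horizon_h * 60.0
    times = sorted({ev.time_h * 60.0 for ev in scenario.events
                    if 0.0 < ev.time_h * 60.0 < horizon_min})
    breakpoints = [0.0] + times + [horizon_min]
    segments = []
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        for ev in scenario.events:
            if abs(ev.time_h * 60.0 - t0) < 1e-9 or ev.time_h * 60.0 <= t0:
                i = graph.index(ev.cell)
                if ev.fieldname == "W":
                    W[i] = ev.value
                elif ev.fieldname == "rho_apc":
                    rho[i] = ev.value
                else:
                    th[i] = ev.value
        segments.append((t0, t1, W.copy(), rho.copy(), th.copy()))
    return segments


def run_deterministic(scenario: Scenario, params: ModelParams | None = None,
                      method="LSODA", rtol=1e-8, atol=1e-10,
                      grid_min=1.0, max_step=np.inf) -> Trajectory:
    """Integrate the coupled deterministic system.

    The integration is split at every event time and restarted with the
    updated environment; output is reported on a uniform grid of spacing
    ``grid_min`` minutes. Concentrations falling below zero by no more than
    the solver tolerance are clipped to zero (and the clip magnitude is
    recorded in the metadata).
    """
    params = params or default_params()
    graph = scenario.graph
    n_cells = len(graph)

    segments = _env_schedule(scenario, params)
    horizon_min = scenario.horizon_h * 60.0
    t_grid = np.arange(0.0, horizon_min + 0.5 * grid_min, grid_min)
    t_grid[-1] = min(t_grid[-1], horizon_min)

    ts, ys = [], []
    y = scenario.y0.reshape(-1).copy()
    clip_worst = 0.0
    for t0, t1, W, rho, th in segments:
        def rhs(t, yflat):
            # solver trial steps may dip microscopically below zero
            states = np.clip(yflat, 0.0, None).reshape(n_cells, N_SPECIES)
            return coupled_rhs(states, graph, params,
                               env_override=(W, rho, th)).reshape(-1)

        t_eval = t_grid[(t_grid >= t0 - 1e-9) & (t_grid <= t1 + 1e-9)]
        if len(t_eval) == 0 or abs(t_eval[0] - t0) > 1e-9:
            t_eval = np.concatenate([[t0], t_eval])
        if abs(t_eval[-1] - t1) > 1e-9:
            t_eval = np.concatenate([t_eval, [t1]])
        sol = solve_ivp(rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, max_step=max_step)
        if not sol.success:
            raise IntegrationError(f"solver failed in segment [{t0}, {t1}] min: {sol.message}",
                                   t_last=sol.t[-1] if len(sol.t) else t0,
                                   y_last=sol.y[:, -1] if sol.y.size else y)
        clip_worst = max(clip_worst, float(max(0.0, -sol.y.min(initial=0.0))))
        keep = np.isin(sol.t, t_grid)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1].copy()

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    t_uniq, idx = np.unique(t_all, return_index=True)
    data = np.clip(y_all[:, idx].T.reshape(len(t_uniq), n_cells, N_SPECIES), 0.0, None)

    return Trajectory(
        t_min=t_uniq, data=data, cells=list(graph.cells), events=list(scenario.events),
        meta={"kind": scenario.kind, "method": method, "rtol": rtol, "atol": atol,
              "grid_min": grid_min, "params_hash": _params_hash(params),
              "negative_clip_max": clip_worst, "stochastic": False},
    )


def run_notch_pair(params: ModelParams | None = None, ic=(0.5, 0.5), W=1.0,
                   theta2=None, b_ref=None, horizon_h=16.0, method="LSODA",
                   rtol=1e-8, atol=1e-10, grid_min=0.5) -> Trajectory:
    """Integrate a coupled two-cell *decoupled Notch* submodel.

    Both cells run the seven-species Notch system with beta-catenin fixed at
    ``b_ref``; cell 1 starts all Notch species at ``ic[0]`` nM and cell 2 at
    ``ic[1]`` nM. This is the configuration used for period calibration and
    the initial-condition period surface (homogeneous starts give damped
    synchronous oscillations; off-diagonal starts give heterogeneous
    evolution).
    """
    from .model import notch_rhs

    params = params or default_params()
    n_sp = len(NOTCH_SPECIES)
    y0 = np.empty((2, n_sp))
    y0[0, :] = ic[0]
    y0[1, :] = ic[1]
    d_idx = NOTCH_SPECIES.index("D")

    def rhs(t, yflat):
        y = np.clip(yflat, 0.0, None).reshape(2, n_sp)
        dbar = y[::-1, d_idx]  # each cell sees the other's Delta
        return notch_rhs(y, dbar, W, params, b_ref=b_ref, theta2=theta2).reshape(-1)

    horizon_min = horizon_h * 60.0
    t_eval = np.arange(0.0, horizon_min + 0.5 * grid_min, grid_min)
    sol = solve_ivp(rhs, (0.0, horizon_min), y0.reshape(-1), method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}",
                               t_last=sol.t[-1] if len(sol.t) else 0.0,
                               y_last=sol.y[:, -1] if sol.y.size else y0)
    data = np.clip(sol.y.T.reshape(len(sol.t), 2, n_sp), 0.0, None)
    return Trajectory(
        t_min=sol.t, data=data, cells=["cell1", "cell2"],
        species=tuple(NOTCH_SPECIES),
        meta={"kind": "notch_pair", "ic": tuple(ic), "W": W,
              "theta2": params.theta2 if theta2 is None else theta2,
              "b_ref": params.b_ref if b_ref is None else b_ref,
              "method": method, "rtol": rtol, "atol": atol,
              "params_hash": _params_hash(params), "stochastic": False},
    )


def run_stochastic(scenario: Scenario, params: ModelParams | None = None,
                   sigma=1.0, dt=0.1, n_runs=10, seed=0,
                   noise_mode="literal", save_every_min=1.0) -> list[Trajectory]:
    """Fixed-step Euler integration with additive noise on Hes1 production.

    At every step of size ``dt`` (minutes) each cell's Hes1 equation
    receives an independent Gaussian perturbation:

    * ``noise_mode="wiener"`` — the state increment is ``sigma*sqrt(dt)*Z``
      (Euler–Maruyama; results are step-size consistent);
    * ``noise_mode="literal"`` — ``N(0, sigma^2)`` is added to the Hes1
      time derivative at each step (state increment ``dt*sigma*Z``), the
      plain per-step recipe.

    Negative intermediate concentrations are clipped to zero. Runs are
    independent and the whole ensemble is reproducible from ``seed``. With
    ``sigma = 0`` the scheme reduces to deterministic fixed-step Euler.
    """
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    if dt <= 0:
        raise InputError("dt must be > 0")
    if noise_mode not in ("literal", "wiener"):
        raise InputError(f"unknown noise_mode {noise_mode!r}")
    params = params or default_params()
    graph = scenario.graph
    n_cells = len(graph)
    rng = np.random.default_rng(seed)

    segments = _env_schedule(scenario, params)
    horizon_min = scenario.horizon_h * 60.0
    n_steps = int(round(horizon_min / dt))
    save_stride = max(1, int(round(save_every_min / dt)))

    state = np.broadcast_to(scenario.y0, (n_runs, n_cells, N_SPECIES)).copy()
    scale = sigma * dt if noise_mode == "literal" else sigma * np.sqrt(dt)

    saved_t = [0.0]
    saved = [state.copy()]
    seg_iter = iter(segments)
    t0, t1, W, rho, th = next(seg_iter)
    for step in range(1, n_steps + 1):
        t = step * dt
        f = coupled_rhs(state, graph, params, env_override=(W, rho, th))
        state = state + dt * f
        if sigma > 0:
            state[..., _H1] += scale * rng.standard_normal((n_runs, n_cells))
        np.clip(state, 0.0, None, out=state)
        while t >= t1 - 1e-9 and t1 < horizon_min - 1e-9:
            t0, t1, W, rho, th = next(seg_iter)
        if step % save_stride == 0 or step == n_steps:
            saved_t.append(t)
            saved.append(state.copy())

    t_arr = np.asarray(saved_t)
    arr = np.stack(saved)  # (n_t, n_runs, n_cells, 12)
    meta_common = {"kind": scenario.kind, "sigma": sigma, "dt": dt,
                   "noise_mode": noise_mode, "seed": seed,
                   "params_hash": _params_hash(params), "stochastic": True}
    return [
        Trajectory(t_min=t_arr.copy(), data=arr[:, r], cells=list(graph.cells),
                   events=list(scenario.events), meta={**meta_common, "run": r})
        for r in range(n_runs)
    ]
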