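"""Sensitivity analysis and sequential one-dimensional parameter fitting.

The fitting protocol is deliberately simple and literature-anchored:

1. a local sensitivity analysis ranks the free parameters by the magnitude
   of their *normalised sensitivity index* ``NS_k = (k / X(k)) * S_k`` with
   ``S_k = (X(k + dk) - X(k)) / dk`` a forward difference, where the scalar
   output ``X`` is the beta-catenin steady state ``B*`` (Wnt submodel) or
   the Hes1 oscillation period ``T`` (Notch submodel);
2. parameters are then fitted one at a time in ranking order: each is swept
   over a linear grid of 1000 values within +/-100% of its current value
   (the other parameters held fixed) and updated to the grid value that
   minimises the objective, looping over the ranking until the objective
   falls below a target tolerance.

A closed-form two-point pre-fit for the beta-catenin production
coefficients is also provided: given two target steady states
``B*(W_i) = b_i``, the destruction flux at each target is computable
without ``alpha3``/``alpha4``, so the two balance equations are linear in
the pair.

``generate_synthetic_target`` produces noisy sampled timecourses from a
known parameter set for the parameter-recovery tests that stand in for
experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FittingError, InputError, ParameterError
from .params import ModelParams, default_params
from .steady import _wnt_complex_given_b, bstar_decoupled
from .simulate import Scenario, run_deterministic, run_notch_pair
from .dynamics import measure_period

__all__ = [
    "sensitivity_index", "sensitivity_report", "SensitivityReport",
    "sequential_fit", "FitResult", "mse", "generate_synthetic_target",
    "fit_bstar_two_point", "bstar_output", "period_output",
    "WNT_PARAMETERS",
]

#: the Wnt-side parameters ranked in the shipped sensitivity analysis:
#: every constant of the Wnt-submodel ODEs plus kappa7, the dissociation
#: constant of the beta-catenin (Wnt-mediated) route at the Hes1 promoter.
#: kappa_psi belongs to the promoter machinery (Dsh repression) and is not
#: part of the Wnt pathway submodel.
WNT_PARAMETERS = ("alpha3", "alpha4", "kappa7", "alpha_A", "mu_A", "kappa_A",
                  "c_GC", "kappa_GA", "kappa_GW", "k_CB", "k_rev", "k_I2",
                  "mu_B")


def bstar_output(W=1.0):
    """Scalar output X(params): decoupled beta-catenin steady state at W."""
    def output(params: ModelParams) -> float:
        return bstar_decoupled(params, W)
    output.__name__ = f"bstar_W{W:g}"
    return output


def period_output(W=1.0, theta2=None, ic=(0.5, 0.5), horizon_h=16.0,
                  rtol=1e-8, atol=1e-10, use_bstar_ref=True):
    """Scalar output X(params): Hes1 period (h) of the coupled Notch pair.

    Runs the decoupled Notch submodel for a cell pair and measures the Hes1
    period over 12 h after a 2 h transient. With ``use_bstar_ref`` the
    beta-catenin reference tracks the decoupled Wnt steady state at ``W``
    (so Wnt parameters influence the period through ``B*``); otherwise the
    frozen ``params.b_ref`` is used. Non-oscillating outputs raise
    :class:`FittingError` so the fit can reject that region.
    """
    def output(params: ModelParams) -> float:
        b_ref = bstar_decoupled(params, W) if use_bstar_ref else params.b_ref
        traj = run_notch_pair(params, ic=ic, W=W, theta2=theta2, b_ref=b_ref,
                              horizon_h=horizon_h, rtol=rtol, atol=atol)
        meas = measure_period(traj)
        if not meas.oscillating:
            raise FittingError("no Hes1 oscillation at this parameter set")
        return meas.period_h
    output.__name__ = f"period_W{W:g}"
    return output


def sensitivity_index(output_fn, params: ModelParams, k: str,
                      delta_frac=0.01) -> tuple[float, float]:
    """Forward-difference sensitivity ``S_k`` and normalised index ``NS_k``.

    ``S_k = (X(k + dk) - X(k)) / dk`` with ``dk = delta_frac * k``;
    ``NS_k = (k / X(k)) * S_k``. ``NS_k`` is ``nan`` when ``X(k) = 0``
    (undefined) and the parameter must be nonzero to admit a relative
    increment.
    """
    if delta_frac <= 0:
        raise InputError("delta_frac must be > 0")
    k0 = getattr(params, k)
    if k0 == 0:
        raise ParameterError(f"cannot take a relative increment of {k!r} = 0")
    x0 = output_fn(params)
    dk = delta_frac * k0
    x1 = output_fn(params.replace(**{k: k0 + dk}))
    s = (x1 - x0) / dk
    ns = (k0 / x0) * s if x0 != 0 else float("nan")
    return float(s), float(ns)


@dataclass
class SensitivityReport:
    """Per-parameter sensitivities for one scalar output, ranked by |NS|."""

    output_name: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def ranking(self) -> list:
        return list(self.table.sort_values("abs_NS", ascending=False)["parameter"])

    @property
    def most_sensitive(self) -> str:
        return self.ranking[0]


def sensitivity_report(output_fn, params: ModelParams | None = None,
                       parameters=WNT_PARAMETERS, delta_frac=0.01) -> SensitivityReport:
    """Rank ``parameters`` by |NS| for the given scalar output."""
    params = params or default_params()
    rows = []
    for k in parameters:
        try:
            s, ns = sensitivity_index(output_fn, params, k, delta_frac)
        except (FittingError, ParameterError):
            s, ns = float("nan"), float("nan")
        rows.append({"parameter": k, "S": s, "NS": ns,
                     "abs_NS": abs(ns) if np.isfinite(ns) else -np.inf})
    table = pd.DataFrame(rows)
    name = getattr(output_fn, "__name__", "output")
    return SensitivityReport(output_name=name, table=table)


@dataclass
class FitResult:
    """Outcome of the sequential 1D grid fit."""

    params: ModelParams
    objective: float
    trace: list = field(default_factory=list)   # objective after each accepted update
    termination: str = "max_loops"
    n_evaluations: int = 0


def _eval_objective(objective, params):
    try:
        v = objective(params)
    except (FittingError, ParameterError, InputError):
        return np.inf
    return v if np.isfinite(v) else np.inf


def sequential_fit(objective, params0: ModelParams, ranking,
                   grid_points=1000, tolerance_frac=1.0,
                   target_tol=0.01, max_loops=3) -> FitResult:
    """Sensitivity-ranked sequential one-dimensional grid search.

    For each parameter in ``ranking`` (most sensitive first) the objective
    is evaluated on ``grid_points`` evenly spaced values spanning
    ``[max(0, (1 - tolerance_frac) k0), (1 + tolerance_frac) k0]`` around
    the current value ``k0`` (+/-100% by default) while all other
    parameters are held fixed; the parameter moves to the grid value with
    the smallest objective (ties broken toward the value closest to
    ``k0``). The loop over the ranking repeats until the objective drops
    below ``target_tol`` or ``max_loops`` is reached. The accepted-update
    trace is non-increasing by construction.
    """
    if grid_points < 2:
        raise InputError("grid_points must be >= 2")
    params = params0.copy()
    best = _eval_objective(objective, params)
    trace = [best]
    n_eval = 1
    termination = "max_loops"
    for loop in range(max_loops):
        if best < target_tol:
            termination = "tolerance"
            break
        for name in ranking:
            k0 = getattr(params, name)
            lo = max(0.0, (1.0 - tolerance_frac) * k0)
            hi = (1.0 + tolerance_frac) * k0
            grid = np.linspace(lo, hi, grid_points)
            vals = np.empty(grid_points)
            for i, g in enumerate(grid):
                try:
                    cand = params.replace(**{name: float(g)})
                except ParameterError:
                    vals[i] = np.inf
                    continue
                vals[i] = _eval_objective(objective, cand)
            n_eval += grid_points
            if not np.any(np.isfinite(vals)):
                raise FittingError(
                    f"objective non-finite over the whole grid for {name!r}",
                    parameter=name)
            vmin = np.min(vals)
            if vmin <= best:
                # tie-break toward the smallest change from k0
                near = np.flatnonzero(vals <= vmin + 1e-15)
                pick = near[np.argmin(np.abs(grid[near] - k0))]
                new_val = float(grid[pick])
                if vmin < best or new_val != k0:
                    params = params.replace(**{name: new_val})
                if vmin < best:
                    best = vmin
                    trace.append(best)
            if best < target_tol:
                break
    else:
        loop = max_loops - 1
    if best < target_tol:
        termination = "tolerance"
    return FitResult(params=params, objective=float(best), trace=trace,
                     termination=termination, n_evaluations=n_eval)


def mse(predicted, observed) -> float:
    """Mean squared error between two equal-length scalar series."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise InputError(
            f"series must be 1-D with equal length, got {predicted.shape} vs {observed.shape}")
    if predicted.size < 1:
        raise InputError("series must contain at least one observation")
    return float(np.mean((predicted - observed) ** 2))


def generate_synthetic_target(params_true: ModelParams, scenario: Scenario,
                              species="B", sample_times_h=None, noise_sd=0.0,
                              seed=0, cell=None) -> pd.DataFrame:
    """Sampled deterministic timecourse plus i.i.d. Gaussian noise.

    Returns a two-column table (time_h, value) reproducible from ``seed``;
    this is the stand-in for an experimental timecourse in the
    parameter-recovery studies.
    """
    sample_times_h = np.asarray(
        [0.5, 1.0, 1.5, 2.0, 2.5, 3.0] if sample_times_h is None else sample_times_h,
        dtype=float)
    if np.any(sample_times_h < 0) or np.any(sample_times_h > scenario.horizon_h):
        raise InputError("sample times must lie within the scenario horizon")
    traj = run_deterministic(scenario, params_true)
    cell = cell if cell is not None else traj.cells[0]
    clean = np.interp(sample_times_h * 60.0, traj.t_min, traj.series(cell, species))
    rng = np.random.default_rng(seed)
    noisy = clean + noise_sd * rng.standard_normal(len(clean))
    return pd.DataFrame({"time_h": sample_times_h, "value": noisy})


def fit_bstar_two_point(params: ModelParams, targets) -> tuple[float, float]:
    """Solve ``B*(W_1) = b_1`` and ``B*(W_2) = b_2`` for ``(alpha3, alpha4)``.

    At a pinned steady state the total destruction flux
    ``b_i * (mu_B + k_CB * C*(b_i, W_i))`` does not involve the production
    coefficients, so the two steady-state balances are linear in
    ``(alpha3, alpha4)`` and solve in closed form.
    """
    (w1, b1), (w2, b2) = targets
    if w1 == w2:
        raise InputError("the two target stimuli must differ")
    if b1 <= 0 or b2 <= 0:
        raise InputError("target steady states must be positive")
    flux = []
    for w, b in ((w1, b1), (w2, b2)):
        c_star, _ = _wnt_complex_given_b(b, w, params)
        flux.append(b * (params.mu_B + params.k_CB * c_star))
    A = np.array([[1.0, w1], [1.0, w2]])
    alpha3, alpha4 = np.linalg.solve(A, np.asarray(flux))
    if alpha3 < 0 or alpha4 < 0:
        raise FittingError(
            f"two-point pre-fit yields negative production (alpha3={alpha3:.4g}, "
            f"alpha4={alpha4:.4g}); targets are inconsistent with the destruction kinetics")
    return float(alpha3), float(alpha4)
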