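"""Steady states of the model: the decoupled beta-catenin steady state
``B*``, multistart steady-state search for the homogeneous full model, and
linear stability via the Jacobian spectrum.

The homogeneous ("single cell") reduction identifies the mean neighbouring
Delta with the cell's own Delta, which decouples the cell from the graph.
Because the closed GSK3beta pool ``G + C + I2`` is conserved, the steady
states of the raw vector field form a one-parameter family indexed by the
pool size; the root search therefore replaces the (redundant) destruction-
complex balance equation with the pool constraint ``G + C + I2 =
gsk_total``, and the stability label ignores the structural zero eigenvalue
contributed by the conservation law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from . import kinetics as kin
from .errors import InputError, SteadyStateError
from .model import IDX, N_SPECIES, SPECIES, full_rhs
from .params import ModelParams

__all__ = [
    "bstar_decoupled", "wnt_steady_state", "find_steady_states",
    "jacobian_eigenvalues", "SteadyStateReport",
]

#: order-of-magnitude species scales for drawing multistart points (nM)
_SPECIES_SCALE = np.array([2.0, 2.0, 2.0, 1.0, 2.0, 2.0, 2.0,
                           50.0, 3.0, 30.0, 30.0, 30.0])

_GSK = [IDX["G"], IDX["C"], IDX["I2"]]


def _wnt_complex_given_b(B, W, params, rho_apc=None):
    """Destruction-complex level C* consistent with beta-catenin B at
    stimulus W (closed pool of size gsk_total)."""
    p = params
    rho = p.rho_apc if rho_apc is None else rho_apc
    a_star = p.alpha_A * kin.hill_act(B, p.kappa_A, p.n) / p.mu_A
    psi = rho * kin.psi_wa(W, a_star, p)
    if psi <= 0:
        return 0.0, float(a_star)
    c_star = p.gsk_total / (1.0 + p.k_rev / psi + p.k_CB * B / p.k_I2)
    return float(c_star), float(a_star)


def bstar_decoupled(params: ModelParams, W, rho_apc=None, f_ref=0.0) -> float:
    """Steady state of beta-catenin in the decoupled Wnt submodel (nM).

    Solves the scalar implicit equation obtained after eliminating Axin,
    free GSK3beta, the destruction complex and the bound complex: the
    production ``alpha3 + alpha4*W`` balances destruction through complex
    binding, NICD binding (at the fixed reference ``f_ref``) and dilution.
    The balance is strictly decreasing in ``B``, so the positive root is
    unique.
    """
    p = params
    if W < 0:
        raise InputError("W must be >= 0")
    production = p.alpha3 + p.alpha4 * W
    if production <= 0:
        raise SteadyStateError("no positive production of beta-catenin; B* = 0 only")

    def residual(B):
        c_star, _ = _wnt_complex_given_b(B, W, p, rho_apc)
        return production - B * (p.mu_B + p.k_CB * c_star + p.k3 * f_ref)

    hi = production / p.mu_B if p.mu_B > 0 else None
    if hi is None or not np.isfinite(hi):
        hi = 1e12
    lo = 1e-12
    if residual(hi) > 0:
        raise SteadyStateError("beta-catenin balance has no positive root")
    return float(brentq(residual, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=200))


def wnt_steady_state(params: ModelParams, W, rho_apc=None, f_ref=0.0) -> np.ndarray:
    """Full steady state of the decoupled Wnt submodel ``(B, A, G, C, I2)``."""
    p = params
    B = bstar_decoupled(p, W, rho_apc=rho_apc, f_ref=f_ref)
    C, A = _wnt_complex_given_b(B, W, p, rho_apc)
    I2 = p.k_CB * C * B / p.k_I2
    G = p.gsk_total - C - I2
    return np.array([B, A, G, C, I2])


@dataclass
class SteadyStateReport:
    """Outcome of a multistart steady-state search."""

    states: list = field(default_factory=list)          # full state vectors
    eigenvalues: list = field(default_factory=list)     # complex spectra
    labels: list = field(default_factory=list)          # stability labels
    counts: list = field(default_factory=list)          # converged multistarts per state
    residuals: list = field(default_factory=list)       # max-norm of rhs
    n_starts: int = 0
    converged: int = 0

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def found_any(self) -> bool:
        return self.n_states > 0

    def summary(self) -> str:
        if not self.found_any:
            return "no steady state found"
        lines = [f"{self.n_states} steady state(s) from {self.converged}/{self.n_starts} converged starts"]
        for s, lab, c in zip(self.states, self.labels, self.counts):
            h1 = s[IDX["H1"]] if len(s) == N_SPECIES else float("nan")
            lines.append(f"  H1={h1:.4g} nM [{lab}] (basin hits: {c})")
        return "\n".join(lines)


def _homogeneous_rhs(params, W, rho_apc, theta2):
    def fun(y):
        y = np.asarray(y, dtype=float)
        return full_rhs(y, y[..., IDX["D"]], W, params, rho_apc=rho_apc, theta2=theta2)
    return fun


def _constrained(fun, pool_total):
    """Replace the destruction-complex balance with the pool constraint."""
    def wrapped(y):
        r = fun(np.abs(y))
        r = np.array(r, dtype=float)
        r[IDX["C"]] = np.abs(y)[_GSK].sum() - pool_total
        return r
    return wrapped


def multistart_roots(fun, starts, residual_fn=None, residual_tol=1e-10,
                     dedup_tol=1e-4, dedup_atol=1e-6):
    """Generic deduplicated multistart root search.

    ``fun`` is the residual handed to the solver; ``residual_fn`` (default
    ``fun``) is re-evaluated at candidate roots for acceptance. Solutions
    are reflected into the non-negative orthant (the solver runs on ``|y|``)
    and deduplicated with relative tolerance ``dedup_tol`` and absolute
    floor ``dedup_atol`` (which also suppresses sub-precision phantom
    distinctions on near-zero coordinates).
    """
    residual_fn = residual_fn or fun
    roots, counts = [], []
    n_conv = 0
    for y0 in starts:
        sol = root(fun, y0, method="hybr", options={"xtol": 1e-12, "maxfev": 4000})
        if not sol.success:
            continue
        y = np.clip(np.abs(sol.x), 0.0, None)
        if np.max(np.abs(residual_fn(y))) > residual_tol:
            continue
        n_conv += 1
        for i, r in enumerate(roots):
            if np.allclose(y, r, rtol=dedup_tol, atol=dedup_atol):
                counts[i] += 1
                break
        else:
            roots.append(y)
            counts.append(1)
    return roots, counts, n_conv


def _draw_starts(rng, n_starts, scale, lo_frac=1e-3):
    """Log-uniform starts over a physiological box around ``scale``."""
    d = len(scale)
    lo = np.log(np.asarray(scale) * lo_frac)
    hi = np.log(np.asarray(scale) * 10.0)
    return np.exp(rng.uniform(lo, hi, size=(n_starts, d)))


def find_steady_states(params: ModelParams, W=1.0, rho_apc=None, theta2=None,
                       n_starts=200, seed=0, dedup_tol=1e-4,
                       residual_tol=1e-10, n_integrations=4) -> SteadyStateReport:
    """Locate the steady states of the homogeneous full model.

    Multistart root finding from log-uniform draws over a physiological box
    (GSK species rescaled onto the pool ``gsk_total``) plus the endpoints of
    a few long integrations. Every reported state satisfies
    ``max|full_rhs| < residual_tol`` on re-evaluation and is labelled by its
    Jacobian spectrum. Zero converged starts yield an explicit empty report
    rather than an exception.
    """
    if n_starts < 1:
        raise InputError("n_starts must be >= 1")
    p = params
    rng = np.random.default_rng(seed)
    raw = _homogeneous_rhs(p, W, rho_apc, theta2)
    fun = _constrained(raw, p.gsk_total) if not p.gsk_open else (lambda y: raw(np.abs(y)))

    starts = _draw_starts(rng, n_starts, _SPECIES_SCALE)
    # project GSK species onto the conserved pool
    if not p.gsk_open:
        pool = starts[:, _GSK].sum(axis=1)
        starts[:, _GSK] *= (p.gsk_total / pool)[:, None]

    # long-time integration endpoints as extra starts
    extra = []
    for k in range(min(n_integrations, n_starts)):
        y0 = starts[k]
        sol = solve_ivp(lambda t, y: raw(np.clip(y, 0, None)), (0.0, 5000.0), y0,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        if sol.success:
            extra.append(np.clip(sol.y[:, -1], 0, None))
    all_starts = list(starts) + extra

    roots, counts, n_conv = multistart_roots(
        fun, all_starts, residual_fn=raw,
        residual_tol=residual_tol, dedup_tol=dedup_tol)

    report = SteadyStateReport(n_starts=len(all_starts), converged=n_conv)
    order = np.argsort([-c for c in counts])
    for i in order:
        y = roots[i]
        eig = jacobian_eigenvalues(y, p, W=W, rho_apc=rho_apc, theta2=theta2,
                                   _skip_check=True)
        report.states.append(y)
        report.eigenvalues.append(eig)
        report.labels.append(_stability_label(eig, drop_conserved=not p.gsk_open))
        report.counts.append(counts[i])
        report.residuals.append(float(np.max(np.abs(raw(y)))))
    return report


def _stability_label(eig, drop_conserved=True, zero_tol=1e-9):
    eig = np.asarray(eig)
    if drop_conserved:
        # remove one structural zero mode from the closed GSK pool
        k = int(np.argmin(np.abs(eig)))
        if np.abs(eig[k]) < zero_tol:
            eig = np.delete(eig, k)
    dominant = eig[np.argmax(eig.real)]
    if dominant.real < 0:
        return "oscillatory-focus" if abs(dominant.imag) > 1e-12 else "stable"
    return "unstable"


def numerical_jacobian(fun, y, rel_step=1e-6):
    """Central finite-difference Jacobian with step ``max(1e-6, 1e-6|x|)``."""
    y = np.asarray(y, dtype=float)
    d = len(y)
    J = np.zeros((d, d))
    for j in range(d):
        h = max(rel_step, rel_step * abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] = max(ym[j] - h, 0.0)
        J[:, j] = (np.asarray(fun(yp)) - np.asarray(fun(ym))) / (yp[j] - ym[j])
    return J


def jacobian_eigenvalues(state, params: ModelParams, W=1.0, rho_apc=None,
                         theta2=None, residual_tol=1e-8, _skip_check=False):
    """Eigenvalues of the homogeneous-model Jacobian at a steady state.

    Raises :class:`InputError` if ``state`` is not a steady state to within
    ``residual_tol`` (the closed-pool reduction makes non-steady spectra
    meaningless for stability).
    """
    raw = _homogeneous_rhs(params, W, rho_apc, theta2)
    state = np.asarray(state, dtype=float)
    if not _skip_check and np.max(np.abs(raw(state))) > residual_tol:
        raise InputError("jacobian_eigenvalues requires a steady state "
                         f"(residual {np.max(np.abs(raw(state))):.3g} > {residual_tol})")
    J = numerical_jacobian(raw, state)
    return np.linalg.eigvals(J)
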