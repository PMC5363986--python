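"""Kinetic building blocks: Hill activation, hyperbolic inhibition and the
Wnt-dependent composite rates used throughout the model.

All regulated production terms in the model are built from two primitives:

* ``hill_act(x, kappa, n) = x**n / (kappa**n + x**n)`` — saturating
  activation, half-maximal at ``x = kappa``;
* ``hill_inh(x, kappa, m) = 1 / (1 + (x/kappa)**m)`` — hyperbolic
  inhibition, the exact complement of ``hill_act`` for matching arguments.

Two composites encode the Wnt-dependent interventions:

* ``psi_w`` — Dishevelled-mediated repression of the Hes1 promoter as a
  decreasing function of the extracellular Wnt stimulus ``W``;
* ``psi_wa`` — the rate (min^-1) at which free GSK3beta is incorporated
  into the beta-catenin destruction complex, increasing in the Axin level
  ``A`` and decreasing in ``W``.

``hes1_production`` assembles the Hes1 promoter crosstalk hub: a convex
combination (weight ``theta2``) of the Notch-mediated route (NICD:beta-
catenin complex ``I1`` binding the promoter) and the Wnt-mediated route
(beta-catenin ``B`` binding directly), scaled by ``psi_w`` and by Hes1
autorepression. beta-catenin is *not* consumed by the Wnt-mediated route.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError, ParameterError

__all__ = ["hill_act", "hill_inh", "psi_w", "psi_wa", "hes1_production"]


def hill_act(x, kappa, n):
    """Hill activation ``x^n / (kappa^n + x^n)``, in ``[0, 1)``.

    Parameters
    ----------
    x : array_like
        Activator concentration(s), >= 0 (nM).
    kappa : float
        Half-saturation constant, > 0 (nM).
    n : float
        Hill exponent, >= 1.
    """
    if kappa <= 0:
        raise ParameterError(f"Hill constant must be positive, got kappa={kappa}")
    if n < 1:
        raise ParameterError(f"Hill exponent must be >= 1, got n={n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InputError("hill_act requires non-negative concentrations")
    xn = (x / kappa) ** n
    return xn / (1.0 + xn)


def hill_inh(x, kappa, m):
    """Hyperbolic inhibition ``1 / (1 + (x/kappa)^m)``, in ``(0, 1]``.

    Complementary to :func:`hill_act`: for matching ``(x, kappa, exponent)``
    the two sum to one.
    """
    if kappa <= 0:
        raise ParameterError(f"Hill constant must be positive, got kappa={kappa}")
    if m < 1:
        raise ParameterError(f"Hill exponent must be >= 1, got m={m}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InputError("hill_inh requires non-negative concentrations")
    return 1.0 / (1.0 + (x / kappa) ** m)


def psi_w(W, params):
    """Dsh-mediated downregulation of Hes1 production by the Wnt stimulus.

    Returns ``hill_inh(W, kappa_psi, n)``: equals 1 in the absence of Wnt
    and decreases monotonically with ``W``. Dimensionless.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise InputError("Wnt stimulus W must be non-negative")
    return hill_inh(W, params.kappa_psi, params.n)


def psi_wa(W, A, params):
    """Rate of incorporation of free GSK3beta into the destruction complex.

    ``c_GC * hill_act(A, kappa_GA, n) * hill_inh(W, kappa_GW, n)`` in
    min^-1: zero without the Axin scaffold, increasing in Axin ``A`` and
    suppressed by the Wnt stimulus ``W`` (Dsh acting on the complex).
    """
    W = np.asarray(W, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(W < 0) or np.any(A < 0):
        raise InputError("psi_wa requires non-negative W and A")
    return (
        params.c_GC
        * hill_act(A, params.kappa_GA, params.n)
        * hill_inh(W, params.kappa_GW, params.n)
    )


def hes1_production(I1, B, H1, W, params, theta2=None):
    """Hes1 production rate (nM min^-1) at the promoter crosstalk hub.

    ``alpha_H1 * [theta2*hill_act(I1, kappa4, n) + (1-theta2)*hill_act(B,
    kappa7, n)] * psi_w(W) * hill_inh(H1, kappa5, m)``.

    ``theta2`` is the proportion of Notch-mediated control of the promoter;
    ``theta2=1`` makes the rate independent of beta-catenin, ``theta2=0``
    independent of the NICD:beta-catenin complex. beta-catenin is a pure
    transcriptional regulator here and is not consumed.
    """
    th = params.theta2 if theta2 is None else theta2
    th = np.asarray(th, dtype=float)
    if np.any(th < 0) or np.any(th > 1):
        raise ParameterError(f"theta2 must lie in [0, 1], got {theta2}")
    notch_route = hill_act(I1, params.kappa4, params.n)
    wnt_route = hill_act(B, params.kappa7, params.n)
    return (
        params.alpha_H1
        * (th * notch_route + (1.0 - th) * wnt_route)
        * psi_w(W, params)
        * hill_inh(H1, params.kappa5, params.m)
    )
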