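"""Per-cell state and the twelve-equation right-hand side.

The model couples a seven-species Notch submodel (Notch receptor ``N``,
Delta ligand ``D``, NICD ``F``, NICD:beta-catenin complex ``I1``, Hes1
``H1``, Hath1 ``H2``, Ngn3 ``P``) to a five-species Wnt submodel
(beta-catenin ``B``, Axin ``A``, free GSK3beta ``G``, destruction complex
``C``, complex-bound beta-catenin ``I2``) through three crosstalk points:
NICD sequesters beta-catenin into ``I1``; ``I1`` drives the Notch-mediated
route of Hes1 transcription; and beta-catenin drives the Wnt-mediated route
directly (without being consumed).

The GSK3beta pool is closed by default: ``G + C + I2`` is conserved along
any trajectory, and the pool size is set by the initial condition. Setting
``params.gsk_open = True`` adds first-order decay to ``G`` and ``C`` for
users who want every species to turn over.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields

import numpy as np

from . import kinetics as kin
from .errors import InputError
from .params import ModelParams

__all__ = [
    "SPECIES", "NOTCH_SPECIES", "WNT_SPECIES", "CellState",
    "full_rhs", "notch_rhs", "wnt_rhs", "export_model_json",
]

#: canonical species ordering used by every array in the package
SPECIES = ("N", "D", "F", "I1", "H1", "H2", "P", "B", "A", "G", "C", "I2")
NOTCH_SPECIES = ("N", "D", "F", "I1", "H1", "H2", "P")
WNT_SPECIES = ("B", "A", "G", "C", "I2")

IDX = {s: i for i, s in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)


@dataclass
class CellState:
    """Concentrations (nM) of the twelve per-cell species."""

    N: float = 0.0
    D: float = 0.0
    F: float = 0.0
    I1: float = 0.0
    H1: float = 0.0
    H2: float = 0.0
    P: float = 0.0
    B: float = 0.0
    A: float = 0.0
    G: float = 0.0
    C: float = 0.0
    I2: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise InputError(f"concentration {f.name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CellState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_SPECIES,):
            raise InputError(f"expected a length-{N_SPECIES} state vector, got shape {arr.shape}")
        return cls(**{s: float(arr[i]) for i, s in enumerate(SPECIES)})

    def gsk_pool(self) -> float:
        """Total GSK3beta pool ``G + C + I2`` (conserved when closed)."""
        return self.G + self.C + self.I2


def _check_rhs_inputs(y, dbar, W):
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != N_SPECIES:
        raise InputError(f"state must have {N_SPECIES} species on the last axis, got {y.shape}")
    dbar = np.asarray(dbar, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(dbar < 0):
        raise InputError("mean neighbouring Delta must be >= 0")
    if np.any(W < 0):
        raise InputError("Wnt stimulus W must be >= 0")
    return y, dbar, W


def full_rhs(y, dbar, W, params: ModelParams, rho_apc=None, theta2=None):
    """Time derivatives (nM/min) of the twelve species for one cell.

    Vectorised over any leading axes of ``y`` (shape ``(..., 12)``);
    ``dbar``, ``W``, ``rho_apc`` and ``theta2`` broadcast against them.

    ``dbar`` is the mean Delta concentration over the cell's neighbours
    (juxtacrine input to Notch production). ``rho_apc`` scales the rate of
    destruction-complex formation (APC mutation: 1 healthy, 0.5 single hit,
    0 two hits) and defaults to ``params.rho_apc``.
    """
    y, dbar, W = _check_rhs_inputs(y, dbar, W)
    p = params
    rho = p.rho_apc if rho_apc is None else np.asarray(rho_apc, dtype=float)

    N, D, F, I1, H1, H2, P, B, A, G, C, I2 = (y[..., i] for i in range(N_SPECIES))

    psi_gc = rho * kin.psi_wa(W, A, p)

    dN = p.alpha_N * kin.hill_act(dbar, p.kappa1, p.n) - p.k_cl * N - p.mu_N * N
    dD = p.alpha_D * kin.hill_act(P, p.kappa3, p.n) - p.mu_D * D
    dF = p.k_cl * N - p.k3 * F * B - p.mu_F * F
    dI1 = p.k3 * F * B - p.mu_I1 * I1
    dH1 = kin.hes1_production(I1, B, H1, W, p, theta2=theta2) - p.mu_H1 * H1
    dH2 = p.alpha_H2 * kin.hill_inh(H1, p.kappa6, p.m) - p.mu_H2 * H2
    dP = p.alpha_P * kin.hill_inh(H1, p.kappa2, p.m) - p.mu_P * P
    dB = p.alpha3 + p.alpha4 * W - p.k3 * F * B - p.k_CB * C * B - p.mu_B * B
    dA = p.alpha_A * kin.hill_act(B, p.kappa_A, p.n) - p.mu_A * A
    dG = p.k_rev * C - psi_gc * G
    dC = psi_gc * G - p.k_rev * C - p.k_CB * C * B + p.k_I2 * I2
    dI2 = p.k_CB * C * B - p.k_I2 * I2

    if p.gsk_open:
        dG = dG - p.mu_G * G
        dC = dC - p.mu_C * C

    return np.stack([dN, dD, dF, dI1, dH1, dH2, dP, dB, dA, dG, dC, dI2], axis=-1)


def notch_rhs(y, dbar, W, params: ModelParams, b_ref=None, theta2=None):
    """Decoupled Notch submodel: the seven Notch species with beta-catenin
    held at the constant reference ``b_ref`` (default ``params.b_ref``).

    ``y`` has shape ``(..., 7)`` ordered as :data:`NOTCH_SPECIES`.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != len(NOTCH_SPECIES):
        raise InputError(f"decoupled Notch state must have 7 species, got {y.shape}")
    p = params
    B = p.b_ref if b_ref is None else float(b_ref)
    N, D, F, I1, H1, H2, P = (y[..., i] for i in range(7))

    dN = p.alpha_N * kin.hill_act(dbar, p.kappa1, p.n) - p.k_cl * N - p.mu_N * N
    dD = p.alpha_D * kin.hill_act(P, p.kappa3, p.n) - p.mu_D * D
    dF = p.k_cl * N - p.k3 * F * B - p.mu_F * F
    dI1 = p.k3 * F * B - p.mu_I1 * I1
    dH1 = kin.hes1_production(I1, B, H1, W, p, theta2=theta2) - p.mu_H1 * H1
    dH2 = p.alpha_H2 * kin.hill_inh(H1, p.kappa6, p.m) - p.mu_H2 * H2
    dP = p.alpha_P * kin.hill_inh(H1, p.kappa2, p.m) - p.mu_P * P

    return np.stack([dN, dD, dF, dI1, dH1, dH2, dP], axis=-1)


def wnt_rhs(y, W, params: ModelParams, f_ref=0.0, rho_apc=None):
    """Decoupled Wnt submodel: the five Wnt species with NICD held at the
    constant reference ``f_ref`` (default 0, i.e. no Notch activity).

    ``y`` has shape ``(..., 5)`` ordered as :data:`WNT_SPECIES`.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != len(WNT_SPECIES):
        raise InputError(f"decoupled Wnt state must have 5 species, got {y.shape}")
    p = params
    rho = p.rho_apc if rho_apc is None else rho_apc
    B, A, G, C, I2 = (y[..., i] for i in range(5))

    psi_gc = rho * kin.psi_wa(W, A, p)

    dB = p.alpha3 + p.alpha4 * W - p.k3 * f_ref * B - p.k_CB * C * B - p.mu_B * B
    dA = p.alpha_A * kin.hill_act(B, p.kappa_A, p.n) - p.mu_A * A
    dG = p.k_rev * C - psi_gc * G
    dC = psi_gc * G - p.k_rev * C - p.k_CB * C * B + p.k_I2 * I2
    dI2 = p.k_CB * C * B - p.k_I2 * I2

    if p.gsk_open:
        dG = dG - p.mu_G * G
        dC = dC - p.mu_C * C

    return np.stack([dB, dA, dG, dC, dI2], axis=-1)


def export_model_json(params: ModelParams, path=None) -> str:
    """Machine-readable model description (species, reactions, rates).

    Returns the JSON text; writes it to ``path`` when given. The reaction
    list mirrors the terms of :func:`full_rhs` one-to-one and is what the
    structural-analysis module consumes.
    """
    p = params
    reactions = [
        {"label": "notch_production", "reactants": {}, "products": {"N": 1},
         "promoters": ["D"], "inhibitors": [],
         "rate": "alpha_N * hill_act(Dbar, kappa1, n)"},
        {"label": "notch_cleavage", "reactants": {"N": 1}, "products": {"F": 1},
         "promoters": [], "inhibitors": [], "rate": "k_cl * N"},
        {"label": "nicd_bcat_binding", "reactants": {"F": 1, "B": 1},
         "products": {"I1": 1}, "promoters": [], "inhibitors": [],
         "rate": "k3 * F * B"},
        {"label": "hes1_production", "reactants": {}, "products": {"H1": 1},
         "promoters": ["I1", "B"], "inhibitors": ["H1"],
         "rate": ("alpha_H1 * (theta2*hill_act(I1,kappa4,n)"
                  " + (1-theta2)*hill_act(B,kappa7,n))"
                  " * psi_w(W) * hill_inh(H1,kappa5,m)")},
        {"label": "hath1_production", "reactants": {}, "products": {"H2": 1},
         "promoters": [], "inhibitors": ["H1"],
         "rate": "alpha_H2 * hill_inh(H1, kappa6, m)"},
        {"label": "ngn3_production", "reactants": {}, "products": {"P": 1},
         "promoters": [], "inhibitors": ["H1"],
         "rate": "alpha_P * hill_inh(H1, kappa2, m)"},
        {"label": "delta_production", "reactants": {}, "products": {"D": 1},
         "promoters": ["P"], "inhibitors": [],
         "rate": "alpha_D * hill_act(P, kappa3, n)"},
        {"label": "bcat_production_basal", "reactants": {}, "products": {"B": 1},
         "promoters": [], "inhibitors": [], "rate": "alpha3"},
        {"label": "bcat_production_wnt", "reactants": {}, "products": {"B": 1},
         "promoters": [], "inhibitors": [], "rate": "alpha4 * W"},
        {"label": "axin_production", "reactants": {}, "products": {"A": 1},
         "promoters": ["B"], "inhibitors": [],
         "rate": "alpha_A * hill_act(B, kappa_A, n)"},
        {"label": "complex_formation", "reactants": {"G": 1}, "products": {"C": 1},
         "promoters": ["A"], "inhibitors": [],
         "rate": "rho_apc * psi_wa(W, A) * G"},
        {"label": "complex_release", "reactants": {"C": 1}, "products": {"G": 1},
         "promoters": [], "inhibitors": [], "rate": "k_rev * C"},
        {"label": "complex_bcat_binding", "reactants": {"C": 1, "B": 1},
         "products": {"I2": 1}, "promoters": [], "inhibitors": [],
         "rate": "k_CB * C * B"},
        {"label": "bound_bcat_degradation", "reactants": {"I2": 1},
         "products": {"C": 1}, "promoters": [], "inhibitors": [],
         "rate": "k_I2 * I2"},
    ]
    decaying = ["N", "D", "F", "I1", "H1", "H2", "P", "B", "A"]
    if p.gsk_open:
        decaying += ["G", "C"]
    for s in decaying:
        mu_name = f"mu_{s}"
        reactions.append({
            "label": f"decay_{s}", "reactants": {s: 1}, "products": {},
            "promoters": [], "inhibitors": [], "rate": f"{mu_name} * {s}",
        })
    doc = {
        "species": list(SPECIES),
        "reactions": reactions,
        "parameters": p.to_dict(),
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
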