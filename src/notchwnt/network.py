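"""Structural reaction-network representation and the numerical
multistability surrogate.

The model's 14 regulated steps plus first-order decays are exported as a
reaction network: species, reactant/product complexes with integer
stoichiometry, and an *influence specification* naming the species that
promote or inhibit each reaction (regulators that are not consumed).
Inflows and outflows are pseudo-reactions against the empty complex ``0``.

Formal concordance analysis is delegated to the external Chemical Reaction
Network Toolbox: :func:`export_crn_toolbox` writes the network in a
parseable one-line-per-reaction dialect so users can run the real thing.
In its place, :func:`multistability_probe` provides a *numerical
surrogate*: it instantiates the network with the package's kinetics, draws
parameter sets log-uniformly around the defaults, and multistarts a
steady-state search. Finding two or more distinct steady states for any
draw is positive evidence of multistability; a "monostable" verdict is
one-sided (marked with a caveat) because the probe can only sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from . import kinetics as kin
from .errors import InputError
from .model import IDX, SPECIES
from .params import ModelParams, default_params
from .steady import _SPECIES_SCALE, _draw_starts, multistart_roots

__all__ = [
    "Reaction", "ReactionNetwork", "build_network", "stoichiometric_matrix",
    "is_conservative", "is_weakly_reversible", "export_crn_toolbox",
    "parse_crn_toolbox", "multistability_probe", "ProbeResult",
]

VARIANTS = ("notch_only", "wnt_only", "full")
COUPLINGS = ("step4_only", "step4_and_14")
WNT_FLAGS = ("on", "off")

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class Reaction:
    """One reaction: reactant/product complexes plus influence annotations."""

    reactants: tuple = ()     # ((species, coeff), ...) sorted
    products: tuple = ()
    promoters: tuple = ()
    inhibitors: tuple = ()
    label: str = ""

    @staticmethod
    def make(reactants=None, products=None, promoters=(), inhibitors=(), label=""):
        def norm(side):
            side = side or {}
            for sp, c in side.items():
                if int(c) != c or c <= 0:
                    raise InputError(f"stoichiometric coefficient must be a positive integer ({sp}: {c})")
            return tuple(sorted((sp, int(c)) for sp, c in side.items()))
        return Reaction(norm(reactants), norm(products),
                        tuple(sorted(promoters)), tuple(sorted(inhibitors)), label)

    def key(self):
        return (self.reactants, self.products, self.promoters, self.inhibitors)


@dataclass
class ReactionNetwork:
    species: list
    reactions: list = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        declared = set(self.species)
        for r in self.reactions:
            for sp, _ in r.reactants + r.products:
                if sp not in declared:
                    raise InputError(f"reaction {r.label!r} uses undeclared species {sp!r}")
            for sp in r.promoters + r.inhibitors:
                if sp not in declared:
                    raise InputError(f"influence species {sp!r} of {r.label!r} is undeclared")

    def __eq__(self, other):
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (sorted(self.species) == sorted(other.species)
                and sorted(r.key() for r in self.reactions)
                == sorted(r.key() for r in other.reactions))


def _model_reactions(coupling, wnt, wnt_side=True, notch_side=True, bcat_io=False):
    """Reactions mirroring the model terms, restricted to the chosen sides."""
    R = Reaction.make
    rxns = []
    if notch_side:
        hes1_prom = ["I1"] if coupling == "step4_only" else ["I1", "B"]
        rxns += [
            R(products={"N": 1}, promoters=["D"], label="notch_production"),
            R(reactants={"N": 1}, products={"F": 1}, label="notch_cleavage"),
            R(reactants={"F": 1, "B": 1}, products={"I1": 1}, label="nicd_bcat_binding"),
            R(products={"H1": 1}, promoters=hes1_prom, inhibitors=["H1"],
              label="hes1_production"),
            R(products={"H2": 1}, inhibitors=["H1"], label="hath1_production"),
            R(products={"P": 1}, inhibitors=["H1"], label="ngn3_production"),
            R(products={"D": 1}, promoters=["P"], label="delta_production"),
        ]
        for s in ("N", "D", "F", "I1", "H1", "H2", "P"):
            rxns.append(R(reactants={s: 1}, label=f"decay_{s}"))
    if wnt_side:
        rxns += [
            R(products={"B": 1}, label="bcat_production_basal"),
            R(products={"A": 1}, promoters=["B"], label="axin_production"),
            R(reactants={"G": 1}, products={"C": 1}, promoters=["A"],
              label="complex_formation"),
            R(reactants={"C": 1}, products={"G": 1}, label="complex_release"),
            R(reactants={"C": 1, "B": 1}, products={"I2": 1}, label="complex_bcat_binding"),
            R(reactants={"I2": 1}, products={"C": 1}, label="bound_bcat_degradation"),
            R(reactants={"B": 1}, label="decay_B"),
            R(reactants={"A": 1}, label="decay_A"),
        ]
        if wnt == "on":
            rxns.append(R(products={"B": 1}, label="bcat_production_wnt"))
    if bcat_io:
        # crosstalk species as a full reactant with its own inflow and outflow
        rxns += [
            R(products={"B": 1}, label="bcat_inflow"),
            R(reactants={"B": 1}, label="bcat_outflow"),
        ]
    return rxns


def build_network(variant, coupling=None, wnt="on") -> ReactionNetwork:
    """Assemble the reaction network for a model variant.

    ``variant`` is one of ``notch_only``, ``wnt_only`` or ``full``;
    ``coupling`` selects the Hes1 promoter inputs (``step4_only`` for the
    purely Notch-mediated route, ``step4_and_14`` to add direct beta-catenin
    binding) and does not apply to ``wnt_only`` (beta-catenin is not
    consumed by the promoter, so the coupling choice is vacuous there);
    ``wnt`` toggles the Wnt-coupled beta-catenin production.
    """
    if variant not in VARIANTS:
        raise InputError(f"unknown variant {variant!r}")
    if wnt not in WNT_FLAGS:
        raise InputError(f"wnt must be 'on' or 'off', got {wnt!r}")
    if variant == "wnt_only":
        if coupling is not None:
            raise InputError("the coupling choice does not apply to the Wnt-only network")
        species = ["B", "A", "G", "C", "I2"]
        rxns = _model_reactions(None, wnt, wnt_side=True, notch_side=False)
    else:
        if coupling not in COUPLINGS:
            raise InputError(f"coupling must be one of {COUPLINGS}, got {coupling!r}")
        if variant == "notch_only":
            species = ["N", "D", "F", "I1", "H1", "H2", "P", "B"]
            rxns = _model_reactions(coupling, wnt, wnt_side=False, notch_side=True,
                                    bcat_io=True)
        else:
            species = list(SPECIES)
            rxns = _model_reactions(coupling, wnt, wnt_side=True, notch_side=True)
    return ReactionNetwork(species=species, reactions=rxns,
                           name=f"{variant}/{coupling}/wnt_{wnt}")


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer species-by-reactions matrix of net stoichiometric changes."""
    if not network.reactions:
        raise InputError("network has no reactions")
    idx = {s: i for i, s in enumerate(network.species)}
    S = np.zeros((len(network.species), len(network.reactions)), dtype=int)
    for j, r in enumerate(network.reactions):
        for sp, c in r.reactants:
            S[idx[sp], j] -= c
        for sp, c in r.products:
            S[idx[sp], j] += c
    return S


def is_conservative(network: ReactionNetwork) -> bool:
    """True iff a strictly positive mass vector m with m.S = 0 exists."""
    S = stoichiometric_matrix(network)
    n = S.shape[0]
    # feasibility LP: m >= 1 (scale-free proxy for m > 0), S^T m = 0
    res = linprog(c=np.zeros(n), A_eq=S.T.astype(float),
                  b_eq=np.zeros(S.shape[1]), bounds=[(1.0, None)] * n,
                  method="highs")
    return bool(res.status == 0)


def _complex_key(side):
    return tuple(side) if side else (("0", 0),)


def is_weakly_reversible(network: ReactionNetwork) -> bool:
    """True iff every connected component of the complexes digraph is
    strongly connected (inflow/outflow share the empty pseudo-complex)."""
    G = nx.DiGraph()
    for r in network.reactions:
        G.add_edge(_complex_key(r.reactants), _complex_key(r.products))
    for comp in nx.weakly_connected_components(G):
        if not nx.is_strongly_connected(G.subgraph(comp)):
            return False
    return True


# -- text dialect -------------------------------------------------------


def _render_side(side):
    if not side:
        return "0"
    return " + ".join((f"{c}{sp}" if c > 1 else sp) for sp, c in side)


def _render_arrow(promoters, inhibitors):
    if not promoters and not inhibitors:
        return "->"
    parts = [f"+{s}" for s in promoters] + [f"-{s}" for s in inhibitors]
    return "-(" + ", ".join(parts) + ")->"


def export_crn_toolbox(network: ReactionNetwork) -> str:
    """Serialise the network, one reaction per line, influences above the
    arrow: ``F + B -> I1``; ``0 -(+I1, -H1)-> H1``; coefficients prefix the
    species (``2C``). Line order is deterministic (sorted by reaction key).
    """
    for sp in network.species:
        if not _NAME_RE.match(sp):
            raise InputError(f"species name {sp!r} contains dialect-reserved characters")
    lines = [f"# species: {' '.join(network.species)}"]
    for r in sorted(network.reactions, key=lambda r: r.key()):
        lines.append(f"{_render_side(r.reactants)} "
                     f"{_render_arrow(r.promoters, r.inhibitors)} "
                     f"{_render_side(r.products)}")
    return "\n".join(lines) + "\n"


_LINE_RE = re.compile(
    r"^(?P<lhs>[^-]+?)\s*(?:->|-\((?P<infl>[^)]*)\)->)\s*(?P<rhs>.+)$")
_TERM_RE = re.compile(r"^(?P<coeff>\d*)(?P<sp>[A-Za-z_][A-Za-z0-9_]*)$")


def _parse_side(text):
    text = text.strip()
    if text == "0":
        return {}
    side = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise InputError(f"cannot parse complex term {term.strip()!r}")
        side[m.group("sp")] = int(m.group("coeff") or 1)
    return side


def parse_crn_toolbox(text: str) -> ReactionNetwork:
    """Inverse of :func:`export_crn_toolbox` (round-trips all networks)."""
    species = []
    reactions = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# species:"):
                species = line.split(":", 1)[1].split()
            continue
        # split on the arrow (which may carry the influence annotation)
        m = re.match(r"^(.*?)\s(->|-\([^)]*\)->)\s(.*)$", line)
        if not m:
            raise InputError(f"cannot parse reaction line {line!r}")
        lhs, arrow, rhs = m.groups()
        promoters, inhibitors = [], []
        im = re.match(r"^-\((.*)\)->$", arrow)
        if im:
            for tok in im.group(1).split(","):
                tok = tok.strip()
                if tok.startswith("+"):
                    promoters.append(tok[1:])
                elif tok.startswith("-"):
                    inhibitors.append(tok[1:])
                elif tok:
                    raise InputError(f"influence token {tok!r} must start with + or -")
        reactions.append(Reaction.make(_parse_side(lhs), _parse_side(rhs),
                                       promoters, inhibitors))
    if not species:
        seen = []
        for r in reactions:
            for sp, _ in r.reactants + r.products:
                if sp not in seen:
                    seen.append(sp)
            for sp in r.promoters + r.inhibitors:
                if sp not in seen:
                    seen.append(sp)
        species = seen
    return ReactionNetwork(species=species, reactions=reactions)


# -- numerical multistability surrogate ---------------------------------


#: parameters perturbed by the probe (rates and constants, not exponents,
#: mixing fractions or mutation multipliers)
_PROBE_DRAWN = [
    "alpha_N", "alpha_D", "alpha_P", "alpha_H1", "alpha_H2", "alpha_A",
    "alpha3", "alpha4", "mu_N", "mu_D", "mu_F", "mu_I1", "mu_H1", "mu_H2",
    "mu_P", "mu_B", "mu_A", "k3", "k_CB", "k_cl", "k_rev", "k_I2",
    "kappa1", "kappa2", "kappa3", "kappa4", "kappa5", "kappa6", "kappa7",
    "kappa_psi", "kappa_GA", "kappa_GW", "kappa_A", "c_GC", "gsk_total",
    "b_ref",
]

_NOTCH8 = ("N", "D", "F", "I1", "H1", "H2", "P", "B")
_WNT5 = ("B", "A", "G", "C", "I2")


@dataclass
class ProbeResult:
    """Verdict of the multistability probe, with the witnessing evidence."""

    variant: str
    coupling: str | None
    wnt: str
    multistable: bool
    n_draws: int
    witness: dict | None = None     # draw index, factors, steady-state H1/B values
    caveat: str | None = None

    @property
    def verdict(self) -> str:
        return "multistable" if self.multistable else "monostable"


def _variant_system(variant, coupling, wnt, p: ModelParams):
    """(solver residual, raw rhs, start scales) for one Table-1 cell."""
    W = 1.0 if wnt == "on" else 0.0
    if coupling == "step4_only":
        th = 1.0
    else:
        th = p.theta2 if 0.0 < p.theta2 < 1.0 else 0.75

    if variant == "full":
        from .model import full_rhs

        def raw(y):
            y = np.asarray(y, dtype=float)
            return full_rhs(y, y[..., IDX["D"]], W, p, theta2=th)
        gsk = [IDX["G"], IDX["C"], IDX["I2"]]

        def fun(y):
            r = np.array(raw(np.abs(y)), dtype=float)
            r[IDX["C"]] = np.abs(y)[gsk].sum() - p.gsk_total
            return r
        scale = _SPECIES_SCALE.copy()
        scale[gsk] = max(p.gsk_total, 1e-6)
        return fun, raw, scale, gsk

    if variant == "notch_only":
        b_in = p.alpha3 + p.alpha4 * W
        mu_out = (p.alpha3 + p.alpha4) / p.b_ref

        def raw(y):
            y = np.asarray(y, dtype=float)
            N, D, F, I1, H1, H2, P, B = (y[..., i] for i in range(8))
            dN = p.alpha_N * kin.hill_act(D, p.kappa1, p.n) - p.k_cl * N - p.mu_N * N
            dD = p.alpha_D * kin.hill_act(P, p.kappa3, p.n) - p.mu_D * D
            dF = p.k_cl * N - p.k3 * F * B - p.mu_F * F
            dI1 = p.k3 * F * B - p.mu_I1 * I1
            dH1 = kin.hes1_production(I1, B, H1, W, p, theta2=th) - p.mu_H1 * H1
            dH2 = p.alpha_H2 * kin.hill_inh(H1, p.kappa6, p.m) - p.mu_H2 * H2
            dP = p.alpha_P * kin.hill_inh(H1, p.kappa2, p.m) - p.mu_P * P
            dB = b_in - mu_out * B - p.k3 * F * B
            return np.stack([dN, dD, dF, dI1, dH1, dH2, dP, dB], axis=-1)

        def fun(y):
            return raw(np.abs(y))
        scale = np.array([2.0, 2.0, 2.0, 1.0, 2.0, 2.0, 2.0, max(p.b_ref, 1e-6)])
        return fun, raw, scale, None

    # wnt_only
    from .model import wnt_rhs

    def raw(y):
        return wnt_rhs(np.asarray(y, dtype=float), W, p)

    def fun(y):
        r = np.array(raw(np.abs(y)), dtype=float)
        r[3] = np.abs(y)[2:5].sum() - p.gsk_total  # C balance -> pool constraint
        return r
    g = max(p.gsk_total, 1e-6)
    scale = np.array([50.0, 3.0, g, g, g])
    return fun, raw, scale, [2, 3, 4]


def _draw_params(base: ModelParams, rng, factor=10.0) -> ModelParams:
    d = base.to_dict()
    for name in _PROBE_DRAWN:
        if d[name] > 0:
            d[name] = float(d[name] * factor ** rng.uniform(-1.0, 1.0))
    return ModelParams.from_dict(d)


def multistability_probe(variant, coupling=None, wnt="on", n_parameter_draws=50,
                         n_starts=40, seed=0, params: ModelParams | None = None,
                         factor=10.0, residual_tol=1e-8,
                         dedup_tol=1e-3) -> ProbeResult:
    """Numerically probe a network variant for multiple steady states.

    For each parameter draw (every rate and constant multiplied by an
    independent log-uniform factor in ``[1/factor, factor]``) the
    corresponding homogeneous system is multistarted from log-uniform
    initial points; the verdict is ``multistable`` as soon as any draw
    yields two or more distinct non-negative steady states. The base
    (undrawn) parameter set is always probed first.
    """
    if n_parameter_draws < 1:
        raise InputError("n_parameter_draws must be >= 1")
    if variant == "wnt_only" and coupling is not None:
        raise InputError("the coupling choice does not apply to the Wnt-only network")
    if variant != "wnt_only" and coupling not in COUPLINGS:
        raise InputError(f"coupling must be one of {COUPLINGS} for {variant!r}")
    base = params or default_params()
    rng = np.random.default_rng(seed)

    for draw in range(n_parameter_draws):
        p = base if draw == 0 else _draw_params(base, rng, factor)
        fun, raw, scale, pool_idx = _variant_system(variant, coupling, wnt, p)
        starts = _draw_starts(rng, n_starts, scale)
        if pool_idx is not None:
            tot = starts[:, pool_idx].sum(axis=1)
            starts[:, pool_idx] *= (p.gsk_total / tot)[:, None]
        roots, counts, _ = multistart_roots(
            fun, starts, residual_fn=raw,
            residual_tol=residual_tol, dedup_tol=dedup_tol, dedup_atol=1e-4)
        if len(roots) >= 2:
            h1_idx = 4 if variant != "wnt_only" else 0
            witness = {
                "draw": draw,
                "params": p.to_dict(),
                "states": [list(map(float, r)) for r in roots],
                "marker_values": [float(r[h1_idx]) for r in roots],
                "basin_counts": counts,
            }
            return ProbeResult(variant, coupling, wnt, True,
                               n_draws=draw + 1, witness=witness)
    return ProbeResult(variant, coupling, wnt, False, n_draws=n_parameter_draws,
                       caveat=("numerical surrogate: absence of a second steady "
                               "state across sampled draws is one-sided evidence"))
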