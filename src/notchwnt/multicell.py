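"""Coupling of per-cell models on a cell-contact graph.

Cells are coupled juxtacrinely: the Notch production of each cell is driven
by the arithmetic mean of the Delta ligand concentration over its graph
neighbours (the "mean neighbouring Delta"). The graph is undirected, has no
self-loops, and carries a per-cell environment: the local Wnt stimulus
``W``, the APC multiplier ``rho_apc`` and an optional ``theta2`` override.
An isolated cell receives no juxtacrine input (``Dbar = 0``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import GraphError, InputError
from .model import IDX, N_SPECIES, full_rhs
from .params import ModelParams

__all__ = ["CellEnv", "CellGraph", "mean_neighbour_delta", "coupled_rhs"]

ENV_FIELDS = ("W", "rho_apc", "theta2")


@dataclass
class CellEnv:
    """Per-cell environment: Wnt stimulus and promoter/mutation multipliers.

    ``theta2`` and ``rho_apc`` of ``None`` defer to the global parameter
    set; ``W`` must always be given (it is a property of the cell's
    position in the tissue, not of the biochemistry).
    """

    W: float = 1.0
    rho_apc: float | None = None
    theta2: float | None = None

    def resolved(self, params: ModelParams) -> tuple[float, float, float]:
        return (
            float(self.W),
            params.rho_apc if self.rho_apc is None else float(self.rho_apc),
            params.theta2 if self.theta2 is None else float(self.theta2),
        )


class CellGraph:
    """Undirected cell-contact graph with a per-cell environment."""

    def __init__(self, cells, edges, env=None):
        self.cells = list(cells)
        if len(set(self.cells)) != len(self.cells):
            raise InputError("duplicate cell identifiers")
        self._index = {c: i for i, c in enumerate(self.cells)}
        self.neighbours = {c: set() for c in self.cells}
        for a, b in edges:
            if a == b:
                raise InputError(f"self-loop on cell {a!r}")
            if a not in self._index or b not in self._index:
                raise GraphError(f"edge ({a!r}, {b!r}) references unknown cell")
            self.neighbours[a].add(b)
            self.neighbours[b].add(a)
        env = env or {}
        unknown = set(env) - set(self.cells)
        if unknown:
            raise GraphError(f"environment given for unknown cell(s): {sorted(unknown)}")
        self.env = {c: env.get(c, CellEnv()) for c in self.cells}

    # -- basic queries ---------------------------------------------------

    def __len__(self):
        return len(self.cells)

    def index(self, cell) -> int:
        try:
            return self._index[cell]
        except KeyError:
            raise GraphError(f"unknown cell {cell!r}") from None

    def edges(self):
        seen = set()
        for a in self.cells:
            for b in self.neighbours[a]:
                key = (min(self._index[a], self._index[b]), max(self._index[a], self._index[b]))
                if key not in seen:
                    seen.add(key)
                    yield (self.cells[key[0]], self.cells[key[1]])

    def mean_matrix(self) -> np.ndarray:
        """Row-stochastic neighbour-averaging matrix (zero rows for
        isolated cells), so ``M @ delta`` is the mean neighbouring Delta."""
        n = len(self)
        M = np.zeros((n, n))
        for c in self.cells:
            i = self._index[c]
            nb = self.neighbours[c]
            if nb:
                for b in nb:
                    M[i, self._index[b]] = 1.0 / len(nb)
        return M

    def env_arrays(self, params: ModelParams):
        """Per-cell ``(W, rho_apc, theta2)`` arrays resolved against
        ``params`` defaults."""
        vals = [self.env[c].resolved(params) for c in self.cells]
        W, rho, th = map(np.array, zip(*vals))
        return W, rho, th

    # -- IO ---------------------------------------------------------------

    def to_csv(self, edges_path, env_path):
        """Write the edge list and the per-cell environment table."""
        with open(edges_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_a", "cell_b"])
            for a, b in self.edges():
                w.writerow([a, b])
        with open(env_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell", "W", "rho_apc", "theta2"])
            for c in self.cells:
                e = self.env[c]
                w.writerow([c, e.W,
                            "" if e.rho_apc is None else e.rho_apc,
                            "" if e.theta2 is None else e.theta2])

    @classmethod
    def from_csv(cls, edges_path, env_path):
        env = {}
        cells = []
        with open(env_path, newline="") as fh:
            for row in csv.DictReader(fh):
                c = row["cell"]
                cells.append(c)
                env[c] = CellEnv(
                    W=float(row["W"]),
                    rho_apc=float(row["rho_apc"]) if row.get("rho_apc") else None,
                    theta2=float(row["theta2"]) if row.get("theta2") else None,
                )
        edges = []
        with open(edges_path, newline="") as fh:
            for row in csv.DictReader(fh):
                edges.append((row["cell_a"], row["cell_b"]))
        return cls(cells, edges, env)


def pair_graph(W=1.0, env1=None, env2=None) -> CellGraph:
    """The canonical two-cell graph used throughout the cell-pair studies."""
    env = {
        "cell1": env1 or CellEnv(W=W),
        "cell2": env2 or CellEnv(W=W),
    }
    return CellGraph(["cell1", "cell2"], [("cell1", "cell2")], env)


def mean_neighbour_delta(graph: CellGraph, delta, cell) -> float:
    """Arithmetic mean of Delta over the neighbours of ``cell``.

    ``delta`` maps cells to Delta concentrations (dict, or array in graph
    order). Isolated cells receive 0.
    """
    i = graph.index(cell)  # raises GraphError for unknown cells
    nb = graph.neighbours[cell]
    if not nb:
        return 0.0
    if isinstance(delta, dict):
        vals = [delta[b] for b in nb]
    else:
        delta = np.asarray(delta, dtype=float)
        vals = [delta[graph.index(b)] for b in nb]
    return float(np.mean(vals))


def coupled_rhs(states, graph: CellGraph, params: ModelParams,
                env_override=None, homogeneous=False):
    """Stacked derivatives for all cells on the graph.

    ``states`` has shape ``(n_cells, 12)`` (leading run axes allowed:
    ``(..., n_cells, 12)``). With ``homogeneous=True`` every cell sees its
    *own* Delta (``Dbar := D``), reproducing the single-cell reduction used
    for steady-state and structural analysis.

    ``env_override``, when given, is a ``(W, rho_apc, theta2)`` triple of
    per-cell arrays that replaces the graph environment (used by the event
    machinery during simulations).
    """
    states = np.asarray(states, dtype=float)
    if states.shape[-2] != len(graph) or states.shape[-1] != N_SPECIES:
        raise InputError(
            f"states must have shape (..., {len(graph)}, {N_SPECIES}), got {states.shape}")
    if env_override is None:
        W, rho, th = graph.env_arrays(params)
    else:
        W, rho, th = (np.asarray(v, dtype=float) for v in env_override)

    delta = states[..., IDX["D"]]
    if homogeneous:
        dbar = delta
    else:
        M = graph.mean_matrix()
        dbar = delta @ M.T
    return full_rhs(states, dbar, W, params, rho_apc=rho, theta2=th)
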