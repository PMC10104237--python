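"""Maximum-likelihood state free energies from noisy edge differences.

Given measured free-energy differences dG_ij with uncertainties sigma_ij on
the edges of a connected state graph, the state free energies {G_i} that
maximize the Gaussian likelihood are the weighted-least-squares solution of

    minimize  sum_(i,j) ((G_j - G_i - dG_ij) / sigma_ij)^2 .

The normal equations involve the graph Laplacian weighted by 1/sigma^2 —
the Fisher information matrix of the estimator.  Its covariance is the
Moore-Penrose pseudoinverse (the single zero mode is the free additive
constant of the potentials).  The solved edge differences G_j - G_i form a
*potential graph*: path independent, hence every cycle closes exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph import Condition, GraphError, Process, StateGraph, edge_free_energy, edge_sigma

#: relative singular-value cutoff for the pseudoinverse
SVD_RCOND = 1e-12


def incidence_matrix(graph: StateGraph) -> np.ndarray:
    """Edge-by-state incidence matrix: -1 at the source, +1 at the target."""
    idx = graph.index
    B = np.zeros((len(graph.processes), len(graph.states)))
    for e, p in enumerate(graph.processes):
        B[e, idx[p.source]] = -1.0
        B[e, idx[p.target]] = 1.0
    return B


def edge_values(graph: StateGraph, condition: Condition) -> tuple[np.ndarray, np.ndarray]:
    """Condition-evaluated (dG, sigma) arrays over the processes [kT]."""
    dg = np.array([edge_free_energy(p, condition) for p in graph.processes])
    sg = np.array([edge_sigma(p) for p in graph.processes])
    if np.any(sg <= 0):
        raise GraphError("all edge uncertainties must be strictly positive")
    return dg, sg


def fisher_information(graph: StateGraph, condition: Condition | None = None) -> np.ndarray:
    """Fisher information of the potential estimate.

    This is the graph Laplacian with edge weights 1/sigma_ij^2: symmetric,
    zero row sums, rank M-1 on a connected graph.
    """
    _, sg = edge_values(graph, condition or Condition())
    B = incidence_matrix(graph)
    return B.T @ (B / sg[:, None] ** 2)


def state_uncertainties(I: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Covariance and per-state sigma from the Fisher information.

    C is the Moore-Penrose pseudoinverse of I (SVD, relative cutoff
    ``SVD_RCOND``); sigma_i = sqrt(C_ii).  The per-state values are reported
    in the minimum-norm gauge of the pseudoinverse; only combinations such
    as the edge variance C_ii + C_jj - 2 C_ij are gauge invariant.  A
    warning names any null vectors beyond the expected single zero mode.
    """
    u, s, vt = np.linalg.svd(I, hermitian=True)
    cutoff = SVD_RCOND * s[0] if s.size else 0.0
    null = int(np.sum(s <= cutoff))
    if null > 1:
        extra = vt[s <= cutoff][1:]
        warnings.warn(
            f"Fisher information has {null} null modes (expected 1); "
            f"extra null vectors: {np.round(extra, 6).tolist()}",
            RuntimeWarning,
        )
    inv = np.where(s > cutoff, 1.0 / np.where(s > cutoff, s, 1.0), 0.0)
    C = (vt.T * inv) @ vt
    return C, np.sqrt(np.clip(np.diag(C), 0.0, None))


@dataclass
class PotentialGraph:
    """Solved state free energies with covariance, anchored at a reference.

    ``G`` is ordered like ``graph.states`` with ``G[reference] = 0``.
    ``covariance`` is the pseudoinverse of the Fisher information in the
    minimum-norm gauge; ``sigma`` its diagonal square roots.
    """

    graph: StateGraph
    condition: Condition
    G: np.ndarray
    sigma: np.ndarray
    covariance: np.ndarray
    reference: str

    def free_energy(self, name: str) -> float:
        return float(self.G[self.graph.index[name]])

    def dg(self, source: str, target: str) -> float:
        """Consistent free-energy difference G_target - G_source [kT]."""
        idx = self.graph.index
        return float(self.G[idx[target]] - self.G[idx[source]])

    def edge_dg(self, process: Process) -> float:
        return self.dg(process.source, process.target)

    def edge_sigma(self, process: Process) -> float:
        """Reported edge uncertainty: per-state sigmas in quadrature [kT]."""
        idx = self.graph.index
        i, j = idx[process.source], idx[process.target]
        C = self.covariance
        return float(np.sqrt(C[i, i] + C[j, j]))

    def edge_variance(self, process: Process) -> float:
        """Gauge-invariant variance of G_j - G_i [kT^2]."""
        idx = self.graph.index
        i, j = idx[process.source], idx[process.target]
        C = self.covariance
        return float(C[i, i] + C[j, j] - 2.0 * C[i, j])

    def consistent_edges(self) -> list[tuple[Process, float, float]]:
        """Per process: (process, consistent dG, reported sigma)."""
        return [(p, self.edge_dg(p), self.edge_sigma(p)) for p in self.graph.processes]


def solve_potentials(
    graph: StateGraph,
    condition: Condition | None = None,
    reference: str | None = None,
) -> PotentialGraph:
    """Maximum-likelihood potential graph at the given condition.

    The solution is unique up to an additive constant; the state named by
    *reference* (default: the first state) is pinned to zero.  Pairwise
    differences and edge variances do not depend on that choice.
    """
    condition = condition or Condition()
    reference = reference or graph.states[0].name
    if reference not in graph.index:
        raise GraphError(f"unknown reference state {reference!r}")
    dg, sg = edge_values(graph, condition)
    B = incidence_matrix(graph)
    w = 1.0 / sg**2
    I = B.T @ (B * w[:, None])
    C, sigma = state_uncertainties(I)
    G = C @ (B.T @ (w * dg))
    G = G - G[graph.index[reference]]
    return PotentialGraph(graph, condition, G, sigma, C, reference)


def solve_many(
    graph: StateGraph,
    conditions: list[Condition],
    reference: str | None = None,
) -> np.ndarray:
    """State free energies over many conditions, shape (n_conditions, M).

    The edge uncertainties are condition independent, so the least-squares
    solve matrix is factored once and applied to each condition's edge
    vector.  Used by condition scans and the Monte Carlo inverse solver.
    """
    reference = reference or graph.states[0].name
    _, sg = edge_values(graph, conditions[0] if conditions else Condition())
    B = incidence_matrix(graph)
    w = 1.0 / sg**2
    C, _ = state_uncertainties(B.T @ (B * w[:, None]))
    S = C @ (B.T * w)  # maps edge dG vector -> state potentials
    dgs = np.array([
        [edge_free_energy(p, c) for p in graph.processes] for c in conditions
    ])
    G = dgs @ S.T
    return G - G[:, [graph.index[reference]]]
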