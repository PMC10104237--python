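"""Non-equilibrium machinery: master equation, fluxes, cycle drives.

A :class:`KineticModel` stores *intrinsic* (concentration-independent) rate
constants per edge.  Evaluating the model at a :class:`Condition`
reconstructs pseudo-first-order rates ``k = k0 * [X]`` for binding edges
and applies membrane-voltage factors to charged edges: a kinetic barrier
halfway through the membrane multiplies the forward rate by
``exp(-q * V / 2)`` and the backward rate by ``exp(+q * V / 2)``, where
``V`` is the membrane potential in kT/e and ``q`` the charge moved
source -> target (outward positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import Condition, GraphError, StateGraph
from .rates import ConsistentRateSet, _binding_forward, intrinsic_rates


def apply_voltage(
    kf: float, kb: float, q: float, voltage_mV: float, kT_mV: float = 25.693
) -> tuple[float, float]:
    """Voltage-modified rate pair for an edge moving charge *q*."""
    v = q * voltage_mV / kT_mV
    return kf * math.exp(-0.5 * v), kb * math.exp(+0.5 * v)


@dataclass
class RateMatrix:
    """Master-equation generator A with dp/dt = A p.

    Off-diagonal ``A[j, i]`` is the rate i -> j; each column sums to zero.
    """

    matrix: np.ndarray
    names: list[str]
    condition: Condition


@dataclass
class CycleDrive:
    """Thermodynamic driving potential of a closed cycle [kT].

    ``chi = intrinsic + extrinsic``; the intrinsic part is the log ratio of
    intrinsic forward/backward rate products (zero for a consistent rate
    set), the extrinsic part collects concentration and voltage terms.
    """

    cycle: list[str]
    chi: float
    intrinsic: float
    extrinsic: float


@dataclass
class KineticModel:
    """Intrinsic rates on a state graph, evaluable at any condition."""

    graph: StateGraph
    intrinsic: pd.DataFrame  # columns kf0, kb0 indexed by process key

    @classmethod
    def from_rate_set(cls, rate_set: ConsistentRateSet) -> "KineticModel":
        """Strip the reference-condition concentrations from consistent rates."""
        table = intrinsic_rates(rate_set)
        return cls(rate_set.graph, table[["kf0", "kb0"]])

    @classmethod
    def from_graph(cls, graph: StateGraph, condition: Condition) -> "KineticModel":
        """Intrinsic rates from raw (possibly inconsistent) input rate pairs.

        *condition* is the condition at which the input rates were stated.
        """
        rows = []
        for p in graph.processes:
            if p.kind != "ratepair":
                raise GraphError(f"process {p.key} carries no rates")
            kf0, kb0 = p.value, p.value2
            if p.is_binding:
                x = condition.concentration(p.ligand, p.compartment)
                if _binding_forward(graph, p):
                    kf0 /= x
                else:
                    kb0 /= x
            rows.append({"key": p.key, "kf0": kf0, "kb0": kb0})
        return cls(graph, pd.DataFrame(rows).set_index("key"))

    def rates_at(self, condition: Condition) -> pd.DataFrame:
        """Pseudo-first-order, voltage-modified rates at *condition*."""
        rows = []
        for p in self.graph.processes:
            kf, kb = self.intrinsic.loc[p.key, ["kf0", "kb0"]]
            if p.is_binding:
                x = condition.concentration(p.ligand, p.compartment)
                if x < 0:
                    raise GraphError(f"negative concentration for edge {p.key}")
                if _binding_forward(self.graph, p):
                    kf = kf * x
                else:
                    kb = kb * x
            if p.charge != 0.0 and condition.voltage_mV != 0.0:
                kf, kb = apply_voltage(kf, kb, p.charge,
                                       condition.voltage_mV, condition.kT_mV)
            rows.append({"key": p.key, "source": p.source, "target": p.target,
                         "kf": kf, "kb": kb})
        return pd.DataFrame(rows).set_index("key")

    def rate_matrix(self, condition: Condition) -> RateMatrix:
        idx = self.graph.index
        M = len(self.graph.states)
        A = np.zeros((M, M))
        for key, row in self.rates_at(condition).iterrows():
            i, j = idx[row.source], idx[row.target]
            A[j, i] += row.kf
            A[i, j] += row.kb
        A[np.diag_indices_from(A)] -= A.sum(axis=0)
        return RateMatrix(A, self.graph.names, condition)


def steady_state(rate_matrix: RateMatrix) -> np.ndarray:
    """Stationary distribution: A p = 0, sum p = 1, p >= 0.

    Solved via the SVD null space of the generator, with a fallback to the
    linear system with one row replaced by normalization.  Raises for
    reducible dynamics, naming the absorbing components.
    """
    A = rate_matrix.matrix
    g = nx.DiGraph()
    g.add_nodes_from(range(A.shape[0]))
    for j, i in zip(*np.nonzero(A)):
        if i != j and A[j, i] > 0:
            g.add_edge(i, j)
    if not nx.is_strongly_connected(g):
        cond = nx.condensation(g)
        sinks = [sorted(rate_matrix.names[i] for i in cond.nodes[n]["members"])
                 for n in cond.nodes if cond.out_degree(n) == 0]
        raise GraphError(f"reducible rate matrix; absorbing components: {sinks}")
    _, s, vt = np.linalg.svd(A)
    p = vt[-1]
    if s[-2] <= 1e-12 * s[0] or np.abs(p.sum()) < 1e-12:
        M = A.shape[0]
        B = A.copy()
        B[0] = 1.0
        rhs = np.zeros(M)
        rhs[0] = 1.0
        p = np.linalg.solve(B, rhs)
    p = p / p.sum()
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def edge_flux(p: np.ndarray, model: KineticModel, condition: Condition) -> pd.DataFrame:
    """Net flux J_ij = kf p_i - kb p_j per edge [1/s].

    At a steady state the fluxes satisfy Kirchhoff balance at every node.
    """
    idx = model.graph.index
    rates = model.rates_at(condition)
    J = [row.kf * p[idx[row.source]] - row.kb * p[idx[row.target]]
         for _, row in rates.iterrows()]
    out = rates[["source", "target"]].copy()
    out["J"] = J
    return out


def node_balance(flux: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    """Net outflow per node; zero everywhere at steady state."""
    bal = dict.fromkeys(names, 0.0)
    for _, row in flux.iterrows():
        bal[row.source] += row.J
        bal[row.target] -= row.J
    return np.array([bal[n] for n in names])


def turnover(
    model: KineticModel, condition: Condition, marker_edge: str
) -> float:
    """Signed steady-state flux through the designated marker edge [1/s].

    Positive means net flow along the stored source -> target direction of
    the marker process.
    """
    if marker_edge not in model.intrinsic.index:
        raise GraphError(f"unknown marker edge {marker_edge!r}")
    p = steady_state(model.rate_matrix(condition))
    flux = edge_flux(p, model, condition)
    return float(flux.loc[marker_edge, "J"])


def _walk_edges(graph: StateGraph, cycle: Sequence[str]) -> list[tuple]:
    nodes = list(cycle)
    if nodes[0] != nodes[-1]:
        nodes = nodes + [nodes[0]]
    if len(nodes) < 3:
        raise GraphError("a cycle needs at least two distinct states")
    steps = []
    for a, b in zip(nodes[:-1], nodes[1:]):
        hits = [(p, +1) for p in graph.processes if (p.source, p.target) == (a, b)]
        hits += [(p, -1) for p in graph.processes if (p.source, p.target) == (b, a)]
        if not hits:
            raise GraphError(f"no process connects {a!r} and {b!r}: open walk")
        if len(hits) > 1:
            raise GraphError(f"ambiguous parallel edges between {a!r} and {b!r}")
        steps.append(hits[0])
    return steps


def cycle_drive(
    model: KineticModel, condition: Condition, cycle: Sequence[str]
) -> CycleDrive:
    """Driving potential chi of a closed walk at the given condition [kT].

    chi is the log ratio of forward to backward rate products with
    pseudo-first-order, voltage-modified rates.  The intrinsic term uses
    the concentration-independent rates only and vanishes for consistent
    rate sets; the extrinsic term carries the chemical-gradient and
    membrane-voltage contributions.
    """
    steps = _walk_edges(model.graph, cycle)
    rates = model.rates_at(condition)
    chi = 0.0
    intr = 0.0
    for p, sign in steps:
        row = rates.loc[p.key]
        chi += sign * math.log(row.kf / row.kb)
        kf0, kb0 = model.intrinsic.loc[p.key, ["kf0", "kb0"]]
        intr += sign * math.log(kf0 / kb0)
    return CycleDrive(list(cycle), chi, intr, chi - intr)
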