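"""Zero-temperature Monte Carlo inference of microscopic edge parameters.

The forward model maps microscopic edge parameters (pKas or standard-state
free-energy differences) through the maximum-likelihood potential solve to
macroscopic curves such as site occupancy versus pH.  The inverse problem —
find edge parameters whose curves match training data — is solved with a
zero-temperature Metropolis scheme: every iteration perturbs each symmetry
group of edges by one shared uniform draw from [-Delta, +Delta], re-solves
the full consistent model, and accepts the move only if the pooled RMSD to
the training data decreases.  Collective moves are used because a single
edge change would typically break thermodynamic consistency before the
solve re-imposes it; symmetry groups keep chemically equivalent edges
exactly equal throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .graph import LN10, Condition, GraphError, StateGraph
from .potentials import incidence_matrix, edge_values, state_uncertainties


@dataclass
class TrainingCurve:
    """A macroscopic observable sampled over conditions.

    ``conditions`` are pH values (sorted ascending); ``values`` the
    observed curve.  The observable is the mean fractional occupancy of
    the listed ``sites`` (binary state labels), or, when ``sites`` is
    None, the total mean count of ``ligand`` bound.  Optional per-point
    weights enter the pooled RMSD.
    """

    conditions: np.ndarray
    values: np.ndarray
    sites: tuple[str, ...] | None = None
    ligand: str = "H+"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.conditions.shape != self.values.shape:
            raise GraphError("curve conditions and values differ in length")
        if np.any(np.diff(self.conditions) < 0):
            raise GraphError("curve conditions must be sorted ascending")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise GraphError("curve weights differ in length")


@dataclass
class MCResult:
    """Outcome of a Monte Carlo inference run."""

    graph: StateGraph            # fitted graph (copy, updated edge values)
    params: dict[str, float]     # fitted per-edge parameters
    rmsd: float
    initial_rmsd: float
    n_steps: int
    n_accepted: int
    trace: np.ndarray            # accepted RMSD after each iteration
    converged: bool
    seed: int


class _CurveModel:
    """Vectorized curve evaluator for a graph with affine edge parameters.

    For pKa and deltaG edges the condition-evaluated edge free energy is
    affine in the edge parameter v: dG_e(c) = a_e(c) + b_e * v_e (slope
    -ln 10 for pKa edges, +1 for deltaG).  With fixed uncertainties the
    potential solve is a fixed linear map, so curves for a trial parameter
    vector cost two small matrix products.
    """

    def __init__(self, graph: StateGraph, curves: Sequence[TrainingCurve],
                 reference: str | None = None):
        if not curves:
            raise GraphError("at least one training curve is required")
        self.graph = graph
        self.curves = list(curves)
        ref = reference or graph.states[0].name
        self.ref_idx = graph.index[ref]

        B = incidence_matrix(graph)
        _, sg = edge_values(graph, Condition())
        w = 1.0 / sg**2
        C, _ = state_uncertainties(B.T @ (B * w[:, None]))
        self.S = C @ (B.T * w)  # edge dG vector -> state potentials

        pH_all = np.concatenate([c.conditions for c in self.curves])
        self.slices = []
        start = 0
        for c in self.curves:
            self.slices.append(slice(start, start + c.conditions.size))
            start += c.conditions.size
        self.pH = pH_all

        offs, slopes = [], []
        for p in graph.processes:
            if p.kind == "pKa":
                offs.append(LN10 * pH_all)
                slopes.append(-LN10)
            elif p.kind == "deltaG" and p.order == 1:
                offs.append(np.zeros_like(pH_all))
                slopes.append(1.0)
            else:
                raise GraphError(
                    f"edge {p.key}: Monte Carlo inference supports pKa and "
                    "first-order deltaG edges"
                )
        self.offsets = np.column_stack(offs)      # (P, E)
        self.slopes = np.asarray(slopes)          # (E,)

        self.obs_weights = []
        for c in self.curves:
            if c.sites is not None:
                w_obs = np.array([
                    np.mean([float(s.labels[site]) for site in c.sites])
                    if all(site in s.labels for site in c.sites)
                    else self._missing(s, c.sites)
                    for s in graph.states
                ])
            else:
                w_obs = np.array([s.count(c.ligand) for s in graph.states],
                                 dtype=float)
            self.obs_weights.append(w_obs)

        self.data = np.concatenate([c.values for c in self.curves])
        wts = [c.weights if c.weights is not None else np.ones_like(c.values)
               for c in self.curves]
        self.weights = np.concatenate(wts)

    @staticmethod
    def _missing(state, sites):
        raise GraphError(f"state {state.name!r} lacks a site label in {sites}")

    def initial_params(self) -> np.ndarray:
        return np.array([p.value for p in self.graph.processes], dtype=float)

    def predict(self, params: np.ndarray) -> np.ndarray:
        dg = self.offsets + self.slopes * params      # (P, E)
        G = dg @ self.S.T                             # (P, M)
        G -= G[:, [self.ref_idx]]
        logp = -G - logsumexp(-G, axis=1, keepdims=True)
        probs = np.exp(logp)
        out = np.empty(self.pH.size)
        for sl, w_obs in zip(self.slices, self.obs_weights):
            out[sl] = probs[sl] @ w_obs
        return out

    def rmsd(self, params: np.ndarray) -> float:
        r = self.predict(params) - self.data
        return float(np.sqrt(np.sum(self.weights * r**2) / self.weights.sum()))


def predict_curves(graph: StateGraph, curves: Sequence[TrainingCurve],
                   reference: str | None = None) -> list[np.ndarray]:
    """Model curves for the graph's current edge parameters."""
    m = _CurveModel(graph, curves, reference)
    out = m.predict(m.initial_params())
    return [out[sl] for sl in m.slices]


def curve_rmsd(graph: StateGraph, curves: Sequence[TrainingCurve],
               reference: str | None = None) -> float:
    """Pooled root-mean-square deviation of model curves from the data.

    All points of all curves enter one mean (per-point pooling).
    """
    m = _CurveModel(graph, curves, reference)
    return m.rmsd(m.initial_params())


def _normalize_groups(graph: StateGraph,
                      groups: Sequence[Sequence[str]] | None) -> list[list[int]]:
    keys = [p.key for p in graph.processes]
    pos = {k: i for i, k in enumerate(keys)}
    out: list[list[int]] = []
    seen: set[str] = set()
    for grp in groups or []:
        idxs = []
        for key in grp:
            if key not in pos:
                raise GraphError(f"unknown edge {key!r} in symmetry group")
            if key in seen:
                raise GraphError(f"edge {key!r} appears in two groups")
            seen.add(key)
            idxs.append(pos[key])
        if idxs:
            out.append(idxs)
    out.extend([pos[k]] for k in keys if k not in seen)
    return out


def mc_infer(
    graph: StateGraph,
    curves: Sequence[TrainingCurve],
    groups: Sequence[Sequence[str]] | None = None,
    delta: float = 2.0,
    eps: float = 1e-3,
    seed: int = 0,
    max_steps: int = 10_000,
    reference: str | None = None,
) -> MCResult:
    """Zero-temperature Metropolis fit of edge parameters to curves.

    Each iteration draws one uniform shift in [-delta, +delta] per symmetry
    group, applies it to every member edge, re-solves the consistent model
    and accepts the move only if the RMSD strictly decreases.  Iteration
    stops once RMSD < eps or after *max_steps* trials; the result is
    flagged non-converged in the latter case.  The run is reproducible for
    a given seed.
    """
    if delta <= 0:
        raise GraphError("delta must be positive")
    if eps < 0:
        raise GraphError("eps must be non-negative")
    work = graph.copy()
    model = _CurveModel(work, curves, reference)
    group_idx = _normalize_groups(work, groups)
    rng = np.random.default_rng(seed)

    params = model.initial_params()
    rmsd = model.rmsd(params)
    initial_rmsd = rmsd
    trace = [rmsd]
    n_accepted = 0
    step = 0
    while rmsd > eps and step < max_steps:
        step += 1
        trial = params.copy()
        for idxs in group_idx:
            shift = rng.uniform(-delta, delta)
            for i in idxs:
                trial[i] += shift
        new_rmsd = model.rmsd(trial)
        if new_rmsd < rmsd:
            params, rmsd = trial, new_rmsd
            n_accepted += 1
        trace.append(rmsd)

    for p, v in zip(work.processes, params):
        p.value = float(v)
    return MCResult(
        graph=work,
        params={p.key: float(v) for p, v in zip(work.processes, params)},
        rmsd=rmsd,
        initial_rmsd=initial_rmsd,
        n_steps=step,
        n_accepted=n_accepted,
        trace=np.asarray(trace),
        converged=bool(rmsd <= eps),
        seed=seed,
    )
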