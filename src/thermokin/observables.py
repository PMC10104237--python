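"""Equilibrium observables of a potential graph.

All partition sums are evaluated with log-sum-exp shifting, since state
free energies can span tens of kT across condition scans.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import xarray as xr
from scipy.special import logsumexp

from .graph import Condition, GraphError, StateGraph, macrostate_partition
from .potentials import PotentialGraph, solve_many


def microstate_probabilities(potentials: PotentialGraph) -> dict[str, float]:
    """Boltzmann probabilities P(i) = exp(-G_i) / sum_k exp(-G_k)."""
    G = potentials.G
    p = np.exp(-(G - G.min()))
    p /= p.sum()
    return dict(zip(potentials.graph.names, p))


def macrostate_probabilities(
    potentials: PotentialGraph, key: str
) -> dict[object, float]:
    """Macrostate probabilities: sums of member microstate probabilities."""
    micro = microstate_probabilities(potentials)
    groups = macrostate_partition(potentials.graph, key)
    return {val: sum(micro[n] for n in members) for val, members in groups.items()}


def macrostate_dg(
    potentials: PotentialGraph,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> float:
    """Macroscopic free-energy difference G(B) - G(A) [kT].

    dG = -ln( sum_{i in B} exp(-G_i) / sum_{i in A} exp(-G_i) ).
    """
    if not group_a or not group_b:
        raise GraphError("macrostate groups must be non-empty")
    idx = potentials.graph.index
    ga = np.array([potentials.G[idx[n]] for n in group_a])
    gb = np.array([potentials.G[idx[n]] for n in group_b])
    return float(logsumexp(-ga) - logsumexp(-gb))


def mean_occupancy(potentials: PotentialGraph, ligand: str) -> float:
    """Mean number of *ligand* molecules bound, sum_i count_i P(i)."""
    counts = []
    for s in potentials.graph.states:
        if ligand not in s.composition:
            raise GraphError(
                f"state {s.name!r} does not declare a {ligand!r} count"
            )
        counts.append(s.count(ligand))
    probs = microstate_probabilities(potentials)
    return float(sum(c * probs[s.name] for c, s in zip(counts, potentials.graph.states)))


def site_occupancy(potentials: PotentialGraph, sites: Sequence[str]) -> float:
    """Mean fractional occupancy of a group of sites (0..1).

    Each site is a binary state label (0 = empty, 1 = occupied); the value
    is the probability-weighted occupancy averaged over the listed sites.
    """
    probs = microstate_probabilities(potentials)
    total = 0.0
    for s in potentials.graph.states:
        for site in sites:
            if site not in s.labels:
                raise GraphError(f"state {s.name!r} lacks site label {site!r}")
            total += float(s.labels[site]) * probs[s.name]
    return total / len(sites)


def occupancy_curve(
    graph: StateGraph,
    pH_grid: Sequence[float],
    ligand: str = "H+",
    condition: Condition | None = None,
) -> np.ndarray:
    """Mean ligand occupancy over a pH grid (vectorized solve)."""
    base = condition or Condition()
    conds = [Condition(pH=ph, concentrations=base.concentrations,
                       voltage_mV=base.voltage_mV, c0=base.c0) for ph in pH_grid]
    G = solve_many(graph, conds)
    counts = np.array([s.count(ligand) for s in graph.states], dtype=float)
    logp = -G - logsumexp(-G, axis=1, keepdims=True)
    return np.exp(logp) @ counts


def uptake_rate(x_bar: Sequence[float], pH_grid: Sequence[float]) -> np.ndarray:
    """d(mean occupancy)/d(pH) on a uniform grid of at least 3 points.

    Central differences in the interior, one-sided at the ends.
    """
    x_bar = np.asarray(x_bar, dtype=float)
    pH_grid = np.asarray(pH_grid, dtype=float)
    if x_bar.shape != pH_grid.shape or x_bar.size < 3:
        raise GraphError("uptake rate needs matching grids of >= 3 points")
    return np.gradient(x_bar, pH_grid)


def condition_scan(
    graph: StateGraph,
    axes: Mapping[str, Iterable[float]],
    base: Condition | None = None,
    reference: str | None = None,
) -> xr.Dataset:
    """Solve the potential graph on a grid of conditions.

    *axes* maps axis names to value arrays; an axis is either ``"pH"``,
    ``"voltage_mV"``, or a ligand name (molar concentrations).  The output
    dimension order is fixed as (pH, ligands..., voltage) for reproducible
    files.  Variables: per-state free energy ``G`` and probability ``P``
    with a leading ``state`` dimension.
    """
    base = base or Condition()
    order = [a for a in ("pH",) if a in axes]
    order += [a for a in axes if a not in ("pH", "voltage_mV")]
    order += [a for a in ("voltage_mV",) if a in axes]
    grids = {a: np.asarray(list(axes[a]), dtype=float) for a in order}
    if any(g.size == 0 for g in grids.values()):
        raise GraphError("every scan axis must have at least one point")

    shape = tuple(g.size for g in grids.values())
    conds = []
    for idx in np.ndindex(*shape):
        pH = base.pH
        conc = dict(base.concentrations)
        volt = base.voltage_mV
        for a, i in zip(order, idx):
            v = grids[a][i]
            if a == "pH":
                pH = v
            elif a == "voltage_mV":
                volt = v
            else:
                conc[a] = v
        conds.append(Condition(pH=pH, concentrations=conc, voltage_mV=volt,
                               c0=base.c0, kT_mV=base.kT_mV))
    G = solve_many(graph, conds, reference).reshape(shape + (len(graph.states),))
    G = np.moveaxis(G, -1, 0)
    logp = -G - logsumexp(-G, axis=0, keepdims=True)
    coords = {"state": graph.names, **grids}
    dims = ("state",) + tuple(order)
    return xr.Dataset(
        {"G": (dims, G), "P": (dims, np.exp(logp))}, coords=coords
    )
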