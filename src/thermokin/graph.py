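"""States, processes and condition-dependent edge free energies.

A kinetic or thermodynamic model is a multigraph whose nodes are
*microstates* (distinct chemical configurations: protonation states,
conformers, ligand-bound forms) and whose edges are elementary processes.
Each process carries either a thermodynamic parameter (a standard-state
free-energy difference, a pKa, or a dissociation constant KD) or a pair of
forward/backward rate constants, together with uncertainties.

Free energies are expressed in units of kT throughout (beta = 1).  The sign
convention is dG_ij = G_j - G_i for a process source -> target, and k_ij is
the rate for source -> target.  For a binding process the *target* is the
bound state; release is the implicit reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

import networkx as nx
import pandas as pd

LN10 = math.log(10.0)

#: thermal voltage kT/e at 298.15 K in millivolts
KT_OVER_E_MV = 25.693

PROCESS_KINDS = ("deltaG", "pKa", "KD", "ratepair")

#: default uncertainty assigned to thermodynamic edges that do not state one
#: (0.1 pKa units for pKa edges, 0.1 kT otherwise).  Any uniform sigma leaves
#: the solved potentials of an already-consistent graph unchanged.
DEFAULT_SIGMA_PKA = 0.1
DEFAULT_SIGMA_KT = 0.1


class GraphError(ValueError):
    """Structural problem with states or processes."""


class ConditionError(ValueError):
    """A required environmental quantity is missing or out of domain."""


@dataclass(frozen=True)
class State:
    """A microstate of the model.

    Parameters
    ----------
    name
        Unique identifier within a graph.
    labels
        Macrostate keys, e.g. ``{"Nprotons": 1, "conformation": "IF"}``.
        Grouping by a key requires the key on every state.
    composition
        Ligand name -> number bound in this state, used for occupancy
        observables and for orienting binding edges.
    """

    name: str
    labels: Mapping[str, Any] = field(default_factory=dict)
    composition: Mapping[str, int] = field(default_factory=dict)

    def count(self, ligand: str) -> int:
        return int(self.composition.get(ligand, 0))


@dataclass
class Process:
    """An elementary process (edge) between two states.

    ``kind`` selects the parameterization:

    - ``"deltaG"``: ``value`` is the standard-state dG [kT], ``sigma`` its
      uncertainty [kT].
    - ``"pKa"``: ``value`` is the microscopic pKa; ``sigma`` is in pKa
      units.  The ligand is implicitly the proton.
    - ``"KD"``: ``value`` is the molar dissociation constant; ``sigma`` is
      the uncertainty of the implied dG [kT].
    - ``"ratepair"``: ``(value, sigma)`` are the forward rate and its
      standard error, ``(value2, sigma2)`` the backward ones [1/s].

    ``order`` is the reaction order: 2 for pseudo-first-order binding of
    ``ligand`` (present in excess), 1 for conformational or other
    concentration-independent steps.  ``charge`` is the net charge moved
    source -> target across the membrane (elementary charges, outward
    positive).  ``compartment`` optionally names the reservoir ("in"/"out")
    a binding edge draws from when concentrations differ across a membrane.
    """

    source: str
    target: str
    kind: str
    value: float | None = None
    sigma: float | None = None
    value2: float | None = None
    sigma2: float | None = None
    ligand: str | None = None
    order: int = 1
    charge: float = 0.0
    compartment: str | None = None
    key: str | None = None  # unique edge id, assigned by build_graph

    def __post_init__(self) -> None:
        if self.kind not in PROCESS_KINDS:
            raise GraphError(f"unknown process kind {self.kind!r}")
        if self.source == self.target:
            raise GraphError(f"self-edge on state {self.source!r}")
        if self.kind == "pKa":
            self.ligand = self.ligand or "H+"
            self.order = 2
        if self.kind == "KD":
            self.order = 2
        if self.order not in (1, 2):
            raise GraphError(f"reaction order must be 1 or 2, got {self.order}")
        if self.order == 2 and self.ligand is None:
            raise GraphError(
                f"{self.source}->{self.target}: order-2 process requires a ligand"
            )
        if self.kind == "ratepair":
            vals = (self.value, self.sigma, self.value2, self.sigma2)
            if any(v is None or v <= 0 for v in vals):
                raise GraphError(
                    f"{self.source}->{self.target}: rate pair needs four "
                    "strictly positive numbers (kf, sigma_f, kb, sigma_b)"
                )
        elif self.value is None:
            raise GraphError(f"{self.source}->{self.target}: missing value")

    @property
    def is_binding(self) -> bool:
        return self.order == 2


@dataclass(frozen=True)
class Condition:
    """External conditions at which a graph is evaluated.

    pH applies to proton-binding edges; ``concentrations`` maps ligand
    names to molar concentrations.  ``voltage_mV`` is the membrane
    potential Psi_in - Psi_out.  Two-compartment systems may override the
    bulk values per side via ``pH_in``/``pH_out`` and
    ``concentrations_in``/``concentrations_out``; edges pick their side
    through :attr:`Process.compartment`.
    """

    pH: float = 7.0
    concentrations: Mapping[str, float] = field(default_factory=dict)
    voltage_mV: float = 0.0
    c0: float = 1.0
    kT_mV: float = KT_OVER_E_MV
    pH_in: float | None = None
    pH_out: float | None = None
    concentrations_in: Mapping[str, float] = field(default_factory=dict)
    concentrations_out: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ConditionError("standard concentration c0 must be positive")
        for conc in (self.concentrations, self.concentrations_in,
                     self.concentrations_out):
            for name, c in conc.items():
                if c < 0:
                    raise ConditionError(f"negative concentration for {name!r}")

    @property
    def beta_e_voltage(self) -> float:
        """Membrane potential in kT per elementary charge."""
        return self.voltage_mV / self.kT_mV

    def concentration(self, ligand: str, compartment: str | None = None) -> float:
        """Molar concentration of *ligand*, optionally side-resolved."""
        if compartment == "in":
            if ligand in self.concentrations_in:
                return self.concentrations_in[ligand]
            if ligand == "H+" and self.pH_in is not None:
                return 10.0 ** (-self.pH_in)
        elif compartment == "out":
            if ligand in self.concentrations_out:
                return self.concentrations_out[ligand]
            if ligand == "H+" and self.pH_out is not None:
                return 10.0 ** (-self.pH_out)
        if ligand in self.concentrations:
            return self.concentrations[ligand]
        if ligand == "H+":
            return 10.0 ** (-self.pH)
        raise ConditionError(f"no concentration given for ligand {ligand!r}")

    def effective_pH(self, compartment: str | None = None) -> float:
        if compartment == "in" and self.pH_in is not None:
            return self.pH_in
        if compartment == "out" and self.pH_out is not None:
            return self.pH_out
        return self.pH


@dataclass
class StateGraph:
    """A validated collection of states and processes."""

    states: list[State]
    processes: list[Process]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.states)}

    def state(self, name: str) -> State:
        for s in self.states:
            if s.name == name:
                return s
        raise GraphError(f"unknown state {name!r}")

    def process(self, key: str) -> Process:
        for p in self.processes:
            if p.key == key:
                return p
        raise GraphError(f"unknown process {key!r}")

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.names)
        for p in self.processes:
            g.add_edge(p.source, p.target, key=p.key, process=p)
        return g

    def copy(self) -> "StateGraph":
        return StateGraph(list(self.states), [replace(p) for p in self.processes])


def build_graph(states: Iterable[State], processes: Iterable[Process]) -> StateGraph:
    """Validate states and processes and assemble a :class:`StateGraph`.

    Raises :class:`GraphError` for duplicate state names, unknown edge
    endpoints, fewer than two states, or a disconnected graph (the error
    message names the components).
    """
    states = list(states)
    processes = [replace(p) for p in processes]
    if len(states) < 2:
        raise GraphError("a graph needs at least two states")
    names = [s.name for s in states]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise GraphError(f"duplicate state names: {sorted(dupes)}")
    known = set(names)
    for p in processes:
        for endpoint in (p.source, p.target):
            if endpoint not in known:
                raise GraphError(
                    f"process {p.source}->{p.target} references unknown "
                    f"state {endpoint!r}"
                )
    seen: dict[str, int] = {}
    for p in processes:
        if p.key is None:
            base = f"{p.source}->{p.target}"
            n = seen.get(base, 0)
            seen[base] = n + 1
            p.key = base if n == 0 else f"{base}#{n + 1}"
    keys = [p.key for p in processes]
    if len(set(keys)) != len(keys):
        raise GraphError("duplicate process keys")
    graph = StateGraph(states, processes)
    g = graph.to_networkx()
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise GraphError(f"graph is disconnected; components: {comps}")
    return graph


def edge_free_energy(process: Process, condition: Condition) -> float:
    """Condition-dependent free-energy difference of a process [kT].

    For proton binding, ``dG(pH) = ln(10) * (pH - pKa)``; for ligand
    binding, ``dG([X]) = ln(KD/c0) - ln([X]/c0)``; a ``deltaG`` edge of
    order 2 is its standard-state value plus ``-ln([X]/c0)``; order-1 edges
    are concentration independent.  Rate-pair edges return
    ``-ln(kf/kb)``, the difference at the condition the rates describe.
    """
    if process.kind == "pKa":
        pH = condition.effective_pH(process.compartment)
        return LN10 * (pH - process.value)
    if process.kind == "ratepair":
        return -math.log(process.value / process.value2)
    dg = process.value if process.kind == "deltaG" else math.log(
        process.value / condition.c0
    )
    if process.order == 2:
        x = condition.concentration(process.ligand, process.compartment)
        if x <= 0:
            raise ConditionError(
                f"nonpositive concentration of {process.ligand!r} for edge "
                f"{process.key or process.source + '->' + process.target}"
            )
        dg -= math.log(x / condition.c0)
    return dg


def edge_sigma(process: Process) -> float:
    """Uncertainty of the edge free-energy difference [kT].

    pKa uncertainties are converted with the factor ln(10); rate pairs use
    first-order error propagation sqrt((sf/kf)^2 + (sb/kb)^2).  Edges
    without a stated uncertainty get a small default so that uniform-weight
    solves of already-consistent graphs are exact.
    """
    if process.kind == "ratepair":
        return math.hypot(process.sigma / process.value,
                          process.sigma2 / process.value2)
    if process.kind == "pKa":
        s = process.sigma if process.sigma is not None else DEFAULT_SIGMA_PKA
        return LN10 * s
    return process.sigma if process.sigma is not None else DEFAULT_SIGMA_KT


def macrostate_partition(graph: StateGraph, key: str) -> dict[Any, list[str]]:
    """Group state names by the value of label *key*.

    Every state must carry the label; the groups are disjoint and cover all
    states.  Group insertion order follows the state list.
    """
    groups: dict[Any, list[str]] = {}
    for s in graph.states:
        if key not in s.labels:
            raise GraphError(f"state {s.name!r} lacks label {key!r}")
        groups.setdefault(s.labels[key], []).append(s.name)
    return groups


# ---------------------------------------------------------------------------
# CSV dialect
#
# states.csv:  name,<label1>,<label2>,...     (labels parsed as int if possible)
# graph.csv:   source,target,kind,value,sigma,value2,sigma2,ligand,order,charge
#              plus an optional trailing `compartment` column.
# Composition columns are labels prefixed with "n_" (e.g. n_H+ -> count of H+).
# ---------------------------------------------------------------------------

def _coerce(v: str):
    try:
        f = float(v)
    except (TypeError, ValueError):
        return v
    return int(f) if f == int(f) else f


def read_states(path) -> list[State]:
    df = pd.read_csv(path, dtype=str).fillna("")
    states = []
    for _, row in df.iterrows():
        labels, comp = {}, {}
        for col in df.columns[1:]:
            if row[col] == "":
                continue
            if col.startswith("n_"):
                comp[col[2:]] = int(float(row[col]))
            else:
                labels[col] = _coerce(row[col])
        states.append(State(row[df.columns[0]], labels, comp))
    return states


def write_states(states: Iterable[State], path) -> None:
    rows = []
    for s in states:
        row = {"name": s.name, **s.labels}
        row.update({f"n_{k}": v for k, v in s.composition.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_processes(path) -> list[Process]:
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    procs = []
    for _, row in df.iterrows():
        def get(col, cast=float):
            v = row.get(col)
            return None if v is None or pd.isna(v) or v == "" else cast(v)
        procs.append(Process(
            source=str(row["source"]), target=str(row["target"]),
            kind=str(row["kind"]),
            value=get("value"), sigma=get("sigma"),
            value2=get("value2"), sigma2=get("sigma2"),
            ligand=get("ligand", str), order=int(get("order") or 1),
            charge=get("charge") or 0.0,
            compartment=get("compartment", str),
        ))
    return procs


def write_processes(processes: Iterable[Process], path) -> None:
    cols = ["source", "target", "kind", "value", "sigma", "value2",
            "sigma2", "ligand", "order", "charge", "compartment"]
    rows = [{c: getattr(p, c) for c in cols} for p in processes]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
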