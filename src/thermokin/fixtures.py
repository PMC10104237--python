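"""Programmatic model generators used throughout the tests and examples.

Three study systems plus a randomized-graph generator:

- a two-proton binding site (four states, one cycle) whose pKa shifts
  produce independent, cooperative, or anti-cooperative binding;
- the triprotic chelator DTPA as a 3-site / 8-state cube with the inferred
  microscopic pKas and the terminal-site symmetry groups;
- a six-state alternating-access sodium/proton antiporter with order-of-
  magnitude rate estimates at 100 mM Na+ and pH 8, including a leak edge;
- random connected graphs with known ground-truth potentials for solver
  recovery tests.
"""

from __future__ import annotations

import numpy as np

from .graph import Condition, Process, State, StateGraph, build_graph
from .inference import TrainingCurve, predict_curves


def make_two_site(pKa_base: float = 7.0, shift: float = 0.0) -> StateGraph:
    """Two-site proton binding model.

    States are labeled ``site1``/``site2`` (0 empty, 1 occupied) and
    ``Nprotons``.  Both first-binding pKas equal *pKa_base*; both
    second-binding pKas are shifted by *shift* (symmetric sites), which
    also closes the single cycle exactly: shift > 0 is cooperative,
    shift < 0 anti-cooperative, 0 independent.  Only three of the four
    pKas are free; the fourth is fixed by cycle closure.
    """
    def st(code: str) -> State:
        s1, s2 = int(code[0]), int(code[1])
        return State(code, {"site1": s1, "site2": s2, "Nprotons": s1 + s2},
                     {"H+": s1 + s2})

    states = [st(c) for c in ("00", "10", "01", "11")]
    second = pKa_base + shift
    processes = [
        Process("00", "10", "pKa", value=pKa_base),
        Process("00", "01", "pKa", value=pKa_base),
        Process("10", "11", "pKa", value=second),
        # closes the cycle: pKa(00->10) + pKa(10->11) = pKa(00->01) + pKa(01->11)
        Process("01", "11", "pKa", value=pKa_base + second - pKa_base),
    ]
    return build_graph(states, processes)


#: microscopic pKas of the DTPA 3-site model inferred from titration data;
#: digits are (terminal, central, terminal), 1 = proton bound
DTPA_PKAS: dict[tuple[str, str], float] = {
    ("000", "001"): 9.0, ("000", "010"): 10.1, ("000", "100"): 9.0,
    ("001", "011"): 9.0, ("001", "101"): 9.8,
    ("010", "011"): 7.9, ("010", "110"): 7.9,
    ("100", "101"): 9.8, ("100", "110"): 9.0,
    ("011", "111"): 5.5, ("101", "111"): 4.7, ("110", "111"): 5.5,
}


def make_dtpa() -> tuple[StateGraph, list[list[str]]]:
    """DTPA 8-state protonation cube with terminal-site symmetry groups.

    States are 3-digit binary strings ordered (terminal, central,
    terminal).  The twelve protonation edges carry the inferred
    microscopic pKas; the symmetry groups pair edges equivalent under
    swapping the two terminal sites (digit-string reversal), so that a
    grouped Monte Carlo move keeps terminal-equivalent pKas exactly equal.
    """
    states = []
    for i in range(8):
        code = format(i, "03b")
        d = [int(c) for c in code]
        states.append(State(code, {"terminal1": d[0], "central": d[1],
                                   "terminal2": d[2], "Nprotons": sum(d)},
                            {"H+": sum(d)}))
    processes = [Process(a, b, "pKa", value=v) for (a, b), v in DTPA_PKAS.items()]
    graph = build_graph(states, processes)

    groups: list[list[str]] = []
    seen: set[tuple[str, str]] = set()
    for (a, b) in DTPA_PKAS:
        if (a, b) in seen:
            continue
        mirror = (a[::-1], b[::-1])
        orbit = [(a, b)] if mirror == (a, b) else [(a, b), mirror]
        seen.update(orbit)
        groups.append([f"{s}->{t}" for s, t in orbit])
    return graph, groups


#: condition at which the antiporter input rates are stated
ANTIPORTER_CONDITION = Condition(pH=8.0, concentrations={"Na+": 0.1})

#: marker edge for turnover: positive flux = proton-loaded site moves
#: from inward-facing to outward-facing, i.e. proton transport out
ANTIPORTER_MARKER = "IF(H+)->OF(H+)"

#: outer transport cycle, oriented so positive drive pumps protons out
ANTIPORTER_CYCLE = ["IF(0)", "IF(H+)", "OF(H+)", "OF(0)", "OF(Na+)", "IF(Na+)"]

_ANTIPORTER_RATES = [
    # source, target, kf, sf, kb, sb, ligand, order, compartment
    ("IF(H+)", "OF(H+)", 8000.0, 100.0, 5000.0, 100.0, None, 1, None),
    ("OF(H+)", "OF(0)", 6000.0, 100.0, 200.0, 15.0, "H+", 2, "out"),
    ("OF(0)", "OF(Na+)", 3.2e8, 1.7e6, 1.7e8, 1.0e7, "Na+", 2, "out"),
    ("OF(Na+)", "IF(Na+)", 8000.0, 100.0, 5000.0, 100.0, None, 1, None),
    ("IF(Na+)", "IF(0)", 7.0e7, 9.5e6, 3.2e8, 1.7e6, "Na+", 2, "in"),
    ("IF(0)", "IF(H+)", 200.0, 25.0, 8000.0, 400.0, "H+", 2, "in"),
]
_ANTIPORTER_LEAK = ("OF(0)", "IF(0)", 100.0, 31.62, 135.0, 31.62)


def make_antiporter(electrogenic: bool = False, leak_scale: float = 1.0) -> StateGraph:
    """Six-state alternating-access antiporter with rate-pair edges.

    The binding site faces out in OF states and in in IF states; protons
    and the driving cation compete for it.  Input rates are order-of-
    magnitude estimates at 100 mM cation and pH 8
    (:data:`ANTIPORTER_CONDITION`) and are *not* thermodynamically
    consistent until projected.

    Charges follow the convention that q is the charge moved outward along
    source -> target: +1 on the proton-bound conformational edge and -1
    (Na+, electroneutral cycle) or -2 (divalent driving cation,
    electrogenic cycle) on the cation-bound one.  The electrogenic flag
    changes only these charge annotations, never the rates.  The leak
    edge's rates (and uncertainties, preserving relative error) are scaled
    by *leak_scale*; zero removes the leak edge entirely.
    """
    def st(conf: str, bound: str) -> State:
        name = f"{conf}({'0' if bound == 'empty' else bound})"
        return State(name,
                     {"conformation": conf, "bound": bound,
                      "Nprotons": int(bound == "H+")},
                     {"H+": int(bound == "H+"), "Na+": int(bound == "Na+")})

    states = [st("IF", "H+"), st("OF", "H+"), st("OF", "empty"),
              st("OF", "Na+"), st("IF", "Na+"), st("IF", "empty")]

    cation_q = -2.0 if electrogenic else -1.0
    charges = {"IF(H+)->OF(H+)": +1.0, "OF(Na+)->IF(Na+)": cation_q}
    processes = []
    for s, t, kf, sf, kb, sb, ligand, order, side in _ANTIPORTER_RATES:
        processes.append(Process(
            s, t, "ratepair", value=kf, sigma=sf, value2=kb, sigma2=sb,
            ligand=ligand, order=order, compartment=side,
            charge=charges.get(f"{s}->{t}", 0.0),
        ))
    if leak_scale > 0:
        s, t, kf, sf, kb, sb = _ANTIPORTER_LEAK
        processes.append(Process(
            s, t, "ratepair", value=kf * leak_scale, sigma=sf * leak_scale,
            value2=kb * leak_scale, sigma2=sb * leak_scale, order=1,
        ))
    return build_graph(states, processes)


def make_random_graph(
    n: int, cycles: int = 2, noise: float = 0.1, seed: int = 0
) -> tuple[StateGraph, np.ndarray]:
    """Random connected graph with known ground-truth potentials.

    A random spanning tree over *n* states plus *cycles* extra edges; each
    edge carries the true potential difference plus Gaussian noise of
    standard deviation *noise* (also used as the edge sigma, floored at a
    small positive value).  Returns the graph and the true potentials
    anchored at state 0.
    """
    if n < 2:
        raise ValueError("need at least two states")
    rng = np.random.default_rng(seed)
    g_true = rng.normal(0.0, 2.0, size=n)
    g_true -= g_true[0]
    names = [f"s{i}" for i in range(n)]
    states = [State(name) for name in names]

    edges: set[tuple[int, int]] = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.add((j, i))
    tries = 0
    while len(edges) < n - 1 + cycles and tries < 100 * (cycles + 1):
        tries += 1
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        if (i, j) not in edges:
            edges.add((i, j))

    sigma = max(noise, 1e-6)
    processes = []
    for i, j in sorted(edges):
        dg = g_true[j] - g_true[i] + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        processes.append(Process(names[i], names[j], "deltaG",
                                 value=float(dg), sigma=sigma))
    return build_graph(states, processes), g_true


def make_training_curves(
    graph: StateGraph,
    pH_grid: np.ndarray,
    site_groups: list[tuple[str, ...]] | None = None,
) -> list[TrainingCurve]:
    """Synthetic titration curves computed from the graph's own parameters.

    With *site_groups* given, one fractional-occupancy curve per group;
    otherwise a single total proton-occupancy curve.  These serve as
    self-consistent training targets for the inverse Monte Carlo solver.
    """
    pH_grid = np.asarray(pH_grid, dtype=float)
    if site_groups:
        curves = [TrainingCurve(pH_grid, np.zeros_like(pH_grid), sites=g)
                  for g in site_groups]
    else:
        curves = [TrainingCurve(pH_grid, np.zeros_like(pH_grid))]
    for curve, values in zip(curves, predict_curves(graph, curves)):
        curve.values = values
    return curves
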