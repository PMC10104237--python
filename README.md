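# thermokin

Thermodynamically consistent potential graphs, rates and kinetics for
molecular state models.

Kinetic and thermodynamic models of biomolecular systems — proton-binding
networks, transporters, enzymes — are graphs of discrete states connected
by elementary processes. Their parameters (free-energy differences ΔḠᵢⱼ,
pKas, dissociation constants, or forward/backward rate pairs k̄ᵢⱼ, k̄ⱼᵢ) come
from different experiments or simulations, each with its own error. Naively
combined, such parameters violate two fundamental constraints:

- **equilibrium cycle closure** (Wegscheider): Σ ΔGᵢⱼ = 0 around every
  closed cycle, and
- **kinetic cycle closure** (Hill): the product of intrinsic forward rates
  around any cycle equals the product of backward rates,
  ln(Π₊°/Π₋°) = 0.

A model that violates these embeds spurious driving forces and produces
physically meaningless predictions. `thermokin` repairs this by maximum
likelihood:

1. **Potential solve.** State free energies {Gᵢ} (in kT, one state pinned
   to 0) maximize the Gaussian likelihood
   ℒ ∝ Π exp(−((Gⱼ−Gᵢ−ΔḠᵢⱼ)²/2σ̄ᵢⱼ²)), a weighted least-squares problem
   whose Fisher information is the 1/σ̄² -weighted graph Laplacian; the
   covariance is its Moore–Penrose pseudoinverse. The solved differences
   Gⱼ−Gᵢ close every cycle exactly.
2. **Rate projection.** Each measured rate pair is projected onto the
   detailed-balance line kᵢⱼ = kⱼᵢ·exp(−ΔGᵢⱼ) of its solved edge with the
   constrained maximum-likelihood estimator
   kⱼᵢ = (k̄ⱼᵢ + (σⱼᵢ²/σᵢⱼ²)Kk̄ᵢⱼ)/(1 + (σⱼᵢ²/σᵢⱼ²)K²), K = e^(−ΔGᵢⱼ), so
   edges with larger relative errors move more.
3. **Observables and kinetics.** From the potential graph: Boltzmann state
   probabilities, macrostate free energies, titration curves and their pH
   derivative, condition scans over pH/concentration/voltage. From the
   consistent rates: master-equation steady states, edge fluxes, transporter
   turnover, and cycle driving potentials χ = ln(Π₊/Π₋) with their
   intrinsic/extrinsic decomposition and membrane-voltage factors
   exp(∓qΔΨ/2).
4. **Inverse inference.** A zero-temperature Metropolis Monte Carlo
   (collective, symmetry-grouped moves; full consistency re-solve every
   step) infers microscopic edge parameters — e.g. microscopic pKas of a
   polyprotic acid — from macroscopic training curves.

## Worked example

The bundled six-state alternating-access Na⁺/H⁺ antiporter carries seven
input rate pairs (stated at 100 mM Na⁺, pH 8) that are *not* consistent:
around the transport cycle their rate products imply a spurious drive of
−0.235 kT at equilibrium conditions. The pipeline removes it:

```python
import thermokin as tk
from thermokin.fixtures import make_antiporter, ANTIPORTER_CONDITION

graph = make_antiporter()
rs = tk.consistent_rate_set(graph, ANTIPORTER_CONDITION)
print(rs.table[["kf", "kb", "dG_kT", "sigma_dG_kT"]].round(2))
```

```
                            kf            kb  dG_kT  sigma_dG_kT
key
IF(H+)->OF(H+)    8.006210e+03  4.990040e+03  -0.47         0.07
OF(H+)->OF(0)     6.007960e+03  1.944700e+02  -3.43         0.07
OF(0)->OF(Na+)    3.200441e+08  1.670795e+08  -0.65         0.06
OF(Na+)->IF(Na+)  8.006240e+03  4.989980e+03  -0.47         0.07
IF(Na+)->IF(0)    7.676085e+07  3.199481e+08   1.43         0.09
IF(0)->IF(H+)     2.158500e+02  7.889020e+03   3.60         0.09
OF(0)->IF(0)      9.970000e+01  1.352200e+02   0.30         0.09
```

Every pair now satisfies kᵢⱼ/kⱼᵢ = e^(−ΔGᵢⱼ) to machine precision and all
cycles close. The consistent sodium-binding free energies at 100 mM imply
KD = 24 mM (inward-facing) and 52 mM (outward-facing):

```python
import math
pot = rs.potentials
print(round(0.1 * math.exp(pot.dg("IF(0)", "IF(Na+)")) * 1000))   # 24 mM
print(round(0.1 * math.exp(pot.dg("OF(0)", "OF(Na+)")) * 1000))   # 52 mM
```

Under a sodium gradient (10 mM in / 100 mM out, pH 7.4 in / 7.0 out) the
steady-state turnover through the proton-bound conformational edge is
positive — the sodium gradient pumps protons out of the cell — and stalls
at large membrane potentials:

```python
from thermokin.kinetics import KineticModel, turnover
from thermokin.fixtures import ANTIPORTER_MARKER

model = KineticModel.from_rate_set(rs)
cond = tk.Condition(pH=7.0, pH_in=7.4, pH_out=7.0,
                    concentrations={"Na+": 0.1},
                    concentrations_in={"Na+": 0.01},
                    concentrations_out={"Na+": 0.1})
print(round(turnover(model, cond, ANTIPORTER_MARKER), 1))   # 106.1 per s
```

## Command line

Each subcommand is a thin wrapper over the library and works on a states
CSV plus a graph CSV (see `docs/methods.md` for the schema):

```sh
thermokin fixture antiporter --out demo
thermokin rates demo/states.csv demo/graph.csv --pH 8 --conc Na+=0.1
thermokin fixture dtpa --out dtpa
thermokin infer dtpa/states.csv dtpa/graph.csv dtpa/training.csv \
    --groups dtpa/groups.txt --delta 0.25 --eps 1e-3
```

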