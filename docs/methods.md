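# Methods

## Model and assumptions

A model is an undirected multigraph of microstates (distinct chemical
configurations) connected by elementary processes: conformational changes
(first order) or binding of a single ligand present in excess
(pseudo-first order, order 2). All free energies are in units of kT
(β = 1). The sign convention throughout is ΔGᵢⱼ = Gⱼ − Gᵢ for a process
source → target, and kᵢⱼ is the source → target rate; detailed balance
reads kᵢⱼ = kⱼᵢ·e^(−ΔGᵢⱼ). For a binding process the target is the bound
state; release is the implicit reverse direction.

Condition-dependent edge free energies:

- proton binding: ΔG(pH) = ln 10 · (pH − pKa);
- ligand binding: ΔG([X]) = ln(KD/c₀) − ln([X]/c₀), c₀ = 1 M;
- rate pairs: ΔḠ = −ln(k̄f/k̄b) at the condition the rates were stated,
  with first-order error propagation σ̄ΔG = √((σf/kf)² + (σb/kb)²).

Measurement errors are assumed Gaussian and independent across edges.
Parallel edges between the same state pair are kept as independent
measurements, each contributing its own likelihood factor.

## Potential solve and uncertainties

The state free energies maximize the Gaussian likelihood of the
condition-evaluated edge differences, i.e. minimize
Σ ((Gⱼ−Gᵢ−ΔḠᵢⱼ)/σ̄ᵢⱼ)². The normal equations use the Fisher information
I = Bᵀ W B (B the edge incidence matrix, W = diag(1/σ̄²)) — the weighted
graph Laplacian, symmetric with zero row sums and rank M−1 on a connected
graph. The solution is the minimum-norm pseudoinverse solution shifted so
the reference state (user-selectable, default the first state) sits at
zero; pairwise differences are independent of that choice. The covariance
is C = I⁺ computed by SVD with a relative singular-value cutoff of 10⁻¹²;
more than one null mode triggers a warning naming the extra null vectors
(it indicates a disconnected or degenerate weighting).

Per-state uncertainties σᵢ = √Cᵢᵢ are reported in the minimum-norm gauge
of the pseudoinverse, and the per-edge uncertainty reported in rate tables
is the quadrature sum √(Cᵢᵢ+Cⱼⱼ). Only the combination
var(ΔGᵢⱼ) = Cᵢᵢ+Cⱼⱼ−2Cᵢⱼ is gauge invariant; it is exposed separately as
`PotentialGraph.edge_variance`. Conflicting exact measurements (σ → 0 on
parallel edges) are rejected rather than silently averaged.

## Rate projection

Rates are treated as normally distributed. This is an approximation — the
quotient K = kᵢⱼ/kⱼᵢ of the detailed-balance constraint is lognormal, so
strictly the rates should be too — valid when σ²/k² ≪ 1; a warning is
emitted whenever any edge exceeds 30% relative error. Under the Gaussian
model, maximizing the likelihood subject to kᵢⱼ = K·kⱼᵢ gives the closed
form

    kⱼᵢ = (k̄ⱼᵢ + (σⱼᵢ²/σᵢⱼ²) K k̄ᵢⱼ) / (1 + (σⱼᵢ²/σᵢⱼ²) K²),  kᵢⱼ = K kⱼᵢ,

with uncertainties carried over unchanged. Geometrically this is an
error-ellipse-weighted projection onto the consistency line: the rate with
the smaller relative error barely moves. With strictly positive inputs the
projected rates are positive by construction. The projection uses the
consistent ΔGᵢⱼ solved at the same condition at which the input rates were
stated; the rates must describe an equilibrium (no gradients, no voltage).

Intrinsic rates divide the binding-direction rate of an order-2 edge by
its ligand concentration at the stated condition (per-molar convention);
the binding direction is the one along which the ligand count of the
endpoint compositions grows.

## Observables

All partition sums use log-sum-exp shifting, since Gᵢ spans tens of kT
across scans. Macrostate probabilities sum member microstates; the
macrostate free-energy difference is −ln of the ratio of the two restricted
partition sums. Titration derivatives ∂X̄/∂pH use central finite
differences in the interior and one-sided stencils at the ends (grids are
user-controlled, so analytic differentiation is deliberately avoided).
Condition scans fix the output dimension order as (pH, ligands…, voltage)
for reproducible files and exploit that edge σ̄ are condition independent:
the least-squares solve operator is factored once and applied per grid
point. NetCDF output uses the scipy engine (netCDF3).

## Kinetics

The master-equation generator has A[j,i] = kᵢⱼ with columns summing to
zero. Steady states come from the SVD null space, with a fallback to the
linear system with one row replaced by normalization; reducible dynamics
raise an error naming the absorbing components. Membrane voltage enters
through a symmetric barrier placed halfway through the membrane: an edge
declaring charge q (in elementary charges, counted positive when moved
outward along source → target) has its forward rate multiplied by
exp(−qV/2) and its backward rate by exp(+qV/2), where V = ΔΨ/(kT/e) and
ΔΨ = Ψin − Ψout; kT/e = 25.693 mV at 298.15 K. Consequently the drive χ of
a cycle with net outward charge Δq is affine in ΔΨ with slope −Δq per
thermal voltage, and an electroneutral cycle is voltage independent.

The cycle driving potential χ = ln(Π₊/Π₋) is evaluated with
pseudo-first-order, voltage-modified rates and decomposed into an
intrinsic part (intrinsic rates only; exactly zero after projection) and
an extrinsic part (chemical gradients plus voltage). Turnover is the
signed steady-state flux through a user-designated marker edge; for the
bundled antiporter the marker is the proton-bound IF → OF transition, so
positive turnover means proton transport out of the cell.

Two-compartment conditions override bulk values per side
(`pH_in`/`pH_out`, `concentrations_in`/`concentrations_out`); each binding
edge declares the reservoir it draws from via its `compartment` attribute.

## Inverse Monte Carlo

Edge parameters are perturbed in their native space (pKa units for
protonation edges, kT for first-order ΔG° edges); the condition dependence
is re-applied at every evaluation, and the full potential solve runs
before each RMSD evaluation, so every model ever compared to data is
exactly cycle closed. Each iteration draws one uniform shift in
[−Δ, +Δ] per symmetry group and applies it to all member edges (edges
without a declared symmetry are singleton groups); the move is accepted
only if the pooled per-point RMSD over all training curves strictly
decreases, and on rejection parameters and RMSD are restored exactly.
The stream is seeded and groups iterate in deterministic order, so runs
are bit-reproducible. Acceptance is zero temperature; a finite-temperature
variant would only require replacing the acceptance rule and is
deliberately out of scope.

The default step Δ = 2 pKa units suits exploration from a distant start.
Because zero-temperature acceptance requires a single collective move to
improve the fit, large steps stall near an optimum (the 8-state model
plateaus near RMSD ≈ 0.02 with Δ = 2); refining to tolerances of 10⁻² or
better uses Δ ≈ 0.25. Δ should be chosen on the scale of the expected
remaining parameter error.

Only the *consistent* (post-solve) edge parameters are identifiable — raw
edge values can drift along directions the solve projects out — so fitted
models are compared via their consistent pKas, recovered as
pKa = −ΔGᵢⱼ(pH=0)/ln 10. Training on a single site's curve constrains the
model only partially: the held-out site's qualitative shape (e.g. the
non-monotonic central-site titration of the 3-site model) is recovered for
most but not all Monte Carlo seeds, which is the expected behavior of a
zero-temperature point estimate on an under-determined problem.

## Synthetic data and what the tests show

The bundled generators define the study conditions:

- `make_two_site(pKa_base=7, shift)`: four states, four pKa edges; both
  first-binding pKas at 7, both second-binding pKas shifted symmetrically
  (shift > 0 cooperative, < 0 anti-cooperative); the fourth pKa is fixed
  by cycle closure, so only three are free.
- `make_dtpa()`: the 3-site, 8-state protonation cube of the triprotic
  chelator DTPA with its inferred microscopic pKas (terminal sites 9.0,
  central 10.1, down to 4.7/5.5 for the third protonation) and the
  terminal-swap symmetry groups. Training curves for the inverse solver
  are generated from these pKas (synthetic self-consistency); the
  experimentally digitized NMR curves are not bundled, but a user-supplied
  file follows the identical code path through the `infer` CLI.
- `make_antiporter(electrogenic, leak_scale)`: six states
  ({IF, OF} × {H⁺, Na⁺, empty}), seven rate-pair edges with
  order-of-magnitude input estimates at 100 mM Na⁺, pH 8 — diffusion-limited
  on-rates (binding-site pKas 6.4/6.5, KDs tens of mM), sub-millisecond
  conformational rates, and a slow leak edge (100/135 s⁻¹ ± 31.62,
  a deliberately uncertain estimate). `leak_scale` scales the leak rates
  (0 removes the edge); the electrogenic variant changes only the charge
  annotations (+1 proton-bound edge; −1 or −2 on the cation-bound edge),
  never the rates.
- `make_random_graph(n, cycles, noise, seed)`: random connected graphs
  with known ground-truth potentials for solver-recovery and oracle tests.

Synthetic curves are noise free; passing the recovery tests therefore
demonstrates correctness of the forward model, the consistency machinery
and the optimizer, not robustness to experimental noise, digitization
error, or model misspecification (missing states), which real data add.
Problem sizes used in the tests — graphs of ≤ 10 states, 30-point pH
grids, ≤ 2·10⁴ Monte Carlo steps — keep the full suite under a minute
while being comfortably past the point where the algorithms' behavior
stops depending on size.

## Numerical choices and degenerate inputs

- Pseudoinverse cutoff 10⁻¹² × largest singular value (exactly one zero
  mode expected).
- Steady-state solver falls back from the SVD null space to a pinned
  linear solve if the null space is ambiguous; probabilities are clipped
  at zero and renormalized to absorb roundoff.
- Edges without a stated uncertainty receive a default σ (0.1 pKa units /
  0.1 kT); for already-consistent inputs any uniform σ leaves the solution
  unchanged, which is what the thermodynamic fixtures rely on.
- Zero or negative concentrations, missing ligand concentrations, open
  cycle walks, unknown marker edges, empty macrostate groups and
  disconnected graphs all raise typed errors early.

## CSV dialect

`states.csv`: `name,<label columns>`, with composition columns prefixed
`n_` (e.g. `n_H+`). `graph.csv`:
`source,target,kind,value,sigma,value2,sigma2,ligand,order,charge`
plus an optional `compartment` column; `kind ∈ {deltaG, pKa, KD,
ratepair}`, with `(value, sigma)` the forward rate and error and
`(value2, sigma2)` the backward ones for rate pairs. State name columns
are read as strings so numeric-looking names like `000` survive round
trips. The dialect is this package's own.
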