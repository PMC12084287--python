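# Methods

## The model

`hesnotch` models fate decisions in neural progenitor populations driven
by the Hes1–Notch lateral-inhibition circuit.  Each cell carries five
concentrations (µM): Dll1 `D`, Notch `N`, Hes1 mRNA `M`, Hes1 protein `P`
and Ngn2 `n`.  Within a cell, Ngn2 is constitutively produced and drives
Dll1; Dll1 presented by *neighbouring* cells activates Notch; Notch
induces Hes1 mRNA; Hes1 protein represses both its own mRNA and Ngn2
through Hill functions:

    dD/dt = α_D n − μ_D D
    dN/dt = α_N ⟨D_in⟩ − μ_N N
    dM/dt = α_M N / (1 + (P/K_M)^k) − μ_M M
    dP/dt = α_P M − μ_P P
    dn/dt = α_n / (1 + (P/K_n)^h) − μ_n n

with `⟨D_in⟩ = Σ_i w_i D_i` the weighted average Dll1 of the neighbours.
The negative feedback produces damped population-level oscillations of
Hes1 (period ≈ 3.3 h under the default parameters, mRNA leading protein
by ≈ 20–30 min); the lateral coupling then destabilises the uniform state
and the population resolves into a salt-and-pepper pattern of
high-Hes1 (prospective glial) and low-Hes1 (prospective neuronal) cells.

### Parameters

Degradation rates derive from published component half-lives (Dll1
50 min, Notch1 40 min, Hes1 protein 24.1 min, Hes1 mRNA 22.3 min, Ngn2
21.9 min).  Dll1 and Notch are transmembrane proteins consumed by the
act of signalling; assuming 80% of each is bound, the measured (free
fraction) rates are multiplied fivefold.  Production rates `α_i` were
calibrated to relative component abundances; the Hill constants
`K_M = 0.050 µM`, `K_n = 0.030 µM` and coefficients `k = 1`, `h = 4` are
fixed design constants (the smallest integer coefficients that support
oscillations).  The `α` and `µ` entries ship with 68% uncertainty
intervals.

`sample_perturbed_parameters` draws each uncertain entry from a uniform
distribution *widened* so that its central 68% probability mass coincides
with the printed interval (the 16th/84th percentiles of the draws
reproduce the interval endpoints).  A uniform restricted to the interval
itself would put 100% of its mass inside what is documented as a 68%
band, which the sampler's quantile contract rejects.  Hill constants and
coefficients are never perturbed.

## Lattices

Cells sit on regular hexagonal grids indexed by axial (rhombic)
coordinates; the six neighbours of `(r, c)` are `(r, c±1)`, `(r±1, c)`,
`(r+1, c+1)` and `(r−1, c−1)`.  This is the coordinate system in which
the Fourier dispersion analysis is phrased, and its periodic wrap is an
exact hexagonal torus for every grid size (offset-style indexings are
only consistent under wrap for even row counts).  Degenerate wraps
(one- and two-cell grids) drop self-loops and renormalise, recovering
the classical mutually-coupled two-cell system and the all-to-all
three-cell system.

Two readings of "zero boundary conditions" are implemented.  The default
keeps every existing neighbour at weight 1/6 and lets missing neighbours
contribute zero signal, so boundary cells receive weaker total input —
this makes the "zero" qualifier meaningful.  `normalise_boundary=True`
renormalises boundary weights to one instead.

## Quasi-steady-state reductions

Setting three of the five species to quasi-steady state yields planar
dynamics in a retained pair `(x, y)`; the seven closed-form-reducible
choices (those retaining `M` or `P`) share the effective parameters

    a = (K_M/R)^(k/(k+1)),   b = (K_M^(k/(k+1)) R^(1/(k+1)) / K_n)^h,
    R = Π_i α_i/μ_i  (µM),

and differ only through `v = μ_y/μ_x`, the relative speed of the `y`
relaxation after time is rescaled by `μ_x`.  At the central parameters
`R ≈ 7.41 µM`, `a ≈ 0.082`, `b ≈ 1.70 × 10⁵`.  The `v` ratios follow
directly from the half-life table; the two reductions retaining Ngn2
disagree with their published three-decimal values by ≈ 0.4% (a rounding
inconsistency in the source table), so their tests carry a 1% tolerance
while the other five are checked at printed precision.

The protein scale linking reduced units to µM is fixed by requiring that
the reduced fixed-point relation `x (a + x^k)(1 + b x^h) = 1` map onto
the full-model homogeneous stationarity `P (1+(P/K_M)^k)(1+(P/K_n)^h) = R`:

    P = (R K_M^k)^(1/(k+1)) · x.

This derivation is verified in the tests by substituting the mapped state
into the full right-hand side (residual < 1e−8 in relative units).

## Stability analysis

All analysis uses `f(x) = 1/(a+x^k)`, `g(x) = 1/(1+b x^h)`.

* **Homogeneous state.** `φ = g·f` is decreasing with `φ(0) > 0`,
  `φ(1) < 1`, so a unique fixed point `x̄₀ ∈ (0,1)` exists; it is found by
  bracketed root solving to 1e−12.
* **Two-cell instability.** The anti-phase mode destabilises iff
  `f g′ − f′ g < −1` at `x̄₀`.  In protein units the same condition reads
  `−h H/(1+H) + k P₀ (P₀/K_M)^k (1+H) / R < −1` with `H = (P₀/K_n)^h`;
  the two margins are numerically identical because the state reduction
  preserves the constant term of the characteristic polynomial up to a
  positive factor.  Tests verify the sign equivalence, together with the
  numeric spectrum of the 10-dimensional two-cell Jacobian, across
  parameter draws spanning both regimes.
* **Patterned pair.** Anti-phase stationary pairs are fixed points of the
  second iterate of `γ = h⁻¹∘g`, `h(x) = x/f(x)`; the pair furthest from
  `x̄₀` satisfies the stability inequality
  `0 < f′₁f′₂g₁g₂ − f₁f₂g′₁g′₂ − f′₁g₂ − f′₂g₁ + 1` and is stable
  whenever it exists.
* **Dispersion.** On rings the growth rate of mode `s` is
  `g′f cos(2πs/N) + gf′ − 1` (most unstable at `s/N = 1/2`); on hexagonal
  tori the coupling factor is `A = [cos(2πs/N) + cos(2πr/M) +
  cos(2πs/N + 2πr/M)]/3` with minimum −1/2 at `r = s = N/3`, matching the
  period-3 uniform colouring that simulations select.
* **Three-cell system.** The smallest faithful model of the period-3
  pattern couples three cells all-to-all with weight 1/2.  Stationary
  triples `(x₁, x₂, x₂)` solve `h(x₁) = g(x₂)`, `H(x₂) = g(x₁)/2` with
  `H(x) = x/f(x) − g(x)/2`; their `x₁` components are fixed points of
  `Γ₂ = γ∘Γ`.  Stability is classified by the 3×3 Jacobian eigenvalues.
  The naive two-cell coupling (`W₂ = [[0,1],[½,½]]`) shares the same
  stationary states but misclassifies a near-homogeneous pair as stable;
  it is kept behind a flag for demonstration.
* **Existence boundary.** Weakening the trans-activation (`α_N ↦ α_N/s`)
  annihilates the patterned branches in a fold.  The boundary `s*` is
  located by bisection on the count of patterned triples; near `s*` the
  double-root condition `Γ₂′(x̄₁) = 1` is satisfied to within the scan
  resolution.  Under the default parameters `s* ≈ 46`, well above the
  homogeneous-instability threshold, so a window exists where the uniform
  state is linearly stable yet patterned solutions persist.

Numerical choices: scalar inversions use dense monotone interpolation
tables (4000 points, log-refined near zero) to localise roots, each
polished by bisection to 1e−12 on the exact functions; numeric Jacobians
use central differences with relative step 1e−6; eigenvalues with real
part below 1e−9 count as stable; root finders cannot certify that no
further non-homogeneous solutions exist outside the scanned brackets.

## Deterministic lattice simulation

`simulate_ode` integrates the coupled system with LSODA
(stiffness-switching; the dynamics are only mildly stiff) at
`rtol = 1e−8`, `atol = 1e−10`, sampling on a uniform 1-minute grid.
Initial conditions are uniform random per cell and species on
`[0, reference]`; by default the reference scales are the homogeneous
stationary concentrations, which places the random data in the
dynamically relevant range (the source concentration table for initial
scaling is not reproduced here; the self-consistent scale is documented
and overridable, and the emergent pattern statistics are insensitive to
scale factors between 0.01× and 10×).

Fate classification thresholds each cell's final level against the
population mean over the *pre-decision window*, taken as the interval up
to the last zero-crossing of the detrended (200-min moving average)
population-mean signal, falling back to the first half of the horizon.
Oscillation metrics: period = mean inter-peak interval of the detrended
mRNA mean; lag = argmax of the mRNA→protein cross-correlation over the
oscillatory window; damping = mean ratio of successive detrended peak
heights.  The default horizon of 3000 min comfortably contains the
transient (≈ 5 oscillation cycles) and the fate decision (complete by
≈ 1200–1500 min).

## Stochastic (RDME-style) simulation

Each cell is one well-mixed voxel of volume `V` µm³ with integer counts.
Concentration-level Hill constants convert to molecule units through
`K·V·602.214` (1 µM in 1 µm³ ≡ 602.214 molecules).  The nine intra-voxel
reactions mirror the deterministic model; signalling is a species-change
transport: `D → D + D_in` at rate `α_N D`, then `D_in(k) → N(l)` at rate
`α_N q_kl D_in` with `q_kl = 1/6` between hexagonal neighbours.  `D_in`
has no independent degradation channel.  On zero-boundary lattices the
proportion aimed at missing neighbours goes to a sink, which reproduces
the deterministic boundary treatment in the mean-field limit.  (The rate
constant `α_N` appears in both transport steps, as specified by the
source model; at quasi-steady state `D_in ≈ D` and the delivered Notch
flux is `α_N ⟨D_in⟩`, matching the ODE.)

The simulator is an exact direct-method SSA with per-voxel propensity
grouping: a binary sum tree over voxel totals selects the voxel, a
traffic-ordered linear scan selects the channel, and only the one or two
affected voxels are updated per event.  This is statistically identical
to next-subvolume-method simulation.  Uniform variates come from a
seeded xorshift128+ generator (SplitMix64-initialised); the tree is
rebuilt every 8×10⁶ events to curb floating-point drift.  Exactness is
validated against closed-form birth–death moments (3σ), transport
conservation, causal activation order from the empty state, and
system-size convergence of the mean to the ODE over `V ∈ {1, 10, 50}` µm³.
No approximate (tau-leaping) accelerator is provided; all results use
the exact kernel.

Initial counts are the concentration-level initial conditions converted
to molecules by stochastic rounding (floor plus a Bernoulli on the
fractional part), which preserves expected concentrations exactly.  The
stationary window is the final 20% of the horizon.

A patterned 10×10 lattice at `V = 50 µm³` generates ≈ 1.6×10⁹ events
over 3000 min (the committed low-Hes1 cells sustain heavy Dll1/transport
traffic); one replicate takes roughly two minutes of CPU.

## Patterning statistics

Stationary per-cell Hes1 protein levels are classified high/low by the
midpoint between the top-quartile and bottom-quartile means.  The field
is called bimodal when the gap between the two quartile samples exceeds
the sum of their diameters (a literal "neither quartile range crosses
the midpoint" rule is satisfied by any spread-out unimodal sample and is
therefore not a bimodality test).  The patterning coefficient `p̂` is the
fraction of directed high→neighbour couplings that land on another high
cell, pooled across replicates and wrapped in a Wald (optionally
Clopper–Pearson) Bernoulli interval.  The ideal period-3 colouring gives
exactly 1/2; spatially random fates with high-fraction `q` give `q` in
expectation.

### What the simulations do and do not reproduce

Emergent patterns in this model — deterministic or stochastic, periodic
or zero boundaries, any tested initial-condition scale — carry isolated
low cells at density ≈ 0.27–0.30 rather than the ideal 1/3.  Cells whose
neighbourhood froze with only one or two low neighbours settle on
intermediate stationary levels (the stationary value of a high cell is
set by its count of low neighbours), and these defect states are stable
equilibria: intrinsic noise at `V = 50 µm³` does not anneal them within
the simulated horizon (`p̂` is frozen from ≈ 1200 min on).  The pooled
patterning coefficient under the default conditions is therefore
≈ 0.62–0.65, above the published point estimate of 0.50 whose 95% CI
width corresponds to a sample of only ≈ 200 couplings.  The package
reports the value its simulations actually produce; see the decisions
record accompanying the development history for the full investigation.

The synthetic-data path (random uniform initial conditions; seeded SSA)
emulates intrinsic reaction noise only: there is no extrinsic parameter
variability between cells, no cell division or growth, no delay terms,
and each cell is a single well-mixed voxel.  Passing tests therefore
validate the mathematical machinery and its internal consistency, not
the biological completeness of the circuit.

## Problem sizes used in the shipped checks

The acceptance script runs five SSA replicates (10×10, `V = 50 µm³`,
3000 min) for the patterning coefficient — the pooled estimate is stable
to well under a percentage point across replicate counts, every
replicate individually landing near 0.63 — plus one 20×20 ODE run for
the oscillation lag and the closed-form reduced-parameter evaluation.
The in-suite patterning check uses three replicates.  Monte-Carlo tests
use 10⁴ draws (parameter quantiles), 2000 trials (interval coverage) and
a 3×10⁴-minute single-voxel run (birth–death moments).
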