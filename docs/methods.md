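# Methods

## Model

An enzyme with n ∈ {2, 3, 4} functional states is a single reversible
cycle.  Transition i joins state i to state i+1 (cyclically) with forward
pseudo-first-order constant k₂ᵢ₋₁ and backward constant k₂ᵢ, both in s⁻¹.
Binding transitions carry a concentration: in the standard schemes
substrate binds in step 1 (k₁ = k₁*·[S]) and product in the backward
direction of the last step (k₂ₙ = k₂ₙ*·[P]).  The carbonic anhydrase
(`ca_buffer`) scheme differs: CO₂ binds in step 1, bicarbonate leaves in
step 2 (so k₄ = k₄*·[P]), and the proton-shuttling buffer B enters both
directions of step 4 (k₇ = k₇*·[B], k₈ = k₈*·[B]).  Temperature never
enters numerically — all forces are expressed per RT — so it is carried
only as a text label.

### Steady state

Occupancies come from the diagram (King–Altman/Hill) method: Σᵢ is the
sum over the n spanning trees of the cycle graph of the product of rate
constants along edges oriented toward state i, pᵢ = Σᵢ/Σ, and

    J = (k₁k₃…k₂ₙ₋₁ − k₂k₄…k₂ₙ)/Σ .

A cycle has exactly n spanning trees (delete one transition), so the
enumeration is generated programmatically per n, never transcribed.  The
transitions are kept distinct by index rather than by endpoint pair —
essential for n = 2, where both transitions join the same two states.
A widely reproduced printed form of the four-state Σ₄ double-counts two
of the Σ₁ diagrams; the tree enumeration (Σ₄ = k₁k₃k₅ + k₂k₄k₈ + k₂k₅k₈ +
k₃k₅k₈) is the normative definition here, and a regression test pins the
fact that only this form reproduces the published four-state flux and
dissipation values.

An independent oracle solves the stationary master equation (the rate
matrix's null space, normalized).  Because occupancies can span many
decades, the oracle solves the normalization-augmented linear system by
Gaussian elimination in extended (80-bit) precision; float64 SVD null
spaces lose relative accuracy on occupancies below ~10⁻⁶.  Near
equilibrium the net flux is a small difference of large one-way fluxes,
so flux comparisons between the two routes use a relative tolerance of
10⁻¹⁰ with an absolute floor proportional to the gross one-way flux —
the cancellation-limited accuracy attainable in double precision.

### Observables

Per-transition forces Xᵢ/RT = ln(k₂ᵢ₋₁pᵢ/(k₂ᵢpᵢ₊₁)) sum exactly to the
total force; entropy production per R is P = J·X/RT = Σᵢ J·Xᵢ/RT ≥ 0.
Forward performance parameters use the closed forms of the reversible
Michaelis–Menten schemes; kcat is implemented as the saturating-substrate
limit of the cycle flux (for four states
kcat = k₃k₅k₇/(k₃k₅+k₃k₆+k₃k₇+k₄k₆+k₄k₇+k₅k₇)), which is algebraically
identical to the textbook nested expressions but immune to their
typographic ambiguity; a test verifies the identity.  K_M is kcat divided
by kcat/K_M; the explicit two-state K_M = [S](k₂+k₃)/k₁ is kept as a
cross-check.  kcat, K_M and kcat/K_M are forward-direction quantities and
are reported for negative total force too, flagged by `forward_force` —
experimental compilations only ever measure the forward direction, and
the flag lets downstream filters drop (or keep) backward-running states
explicitly.

Two overall equilibrium-constant conventions coexist in the source
tables and both are first-class outputs: `k_app` = ΠKᵢ from
pseudo-first-order constants (concentration-dependent; identically
exp(X/RT)), and `k_chem` with second-order constants in the binding steps
(concentration-independent; equal to k_app·[P]/[S] for every scheme
here).  The isomerase tables print `k_chem`; the β-lactamase,
β-galactosidase, glucose-isomerase and carbonic-anhydrase tables print
`k_app`.

## Enzyme registry

Parameter values are stored exactly as published, with one exception:
the β-galactosidase product-binding constant is published as
k₄* = 10 M⁻¹s⁻¹ alongside [P] = 10⁻⁷ M and k₄ = 10⁻⁵ s⁻¹, which are
mutually inconsistent; every derived published quantity (K_eq = 2.0×10⁷,
X/RT = 16.81, P = 2.55×10³ s⁻¹) follows from k₄ = 10⁻⁵ s⁻¹, so the
registry stores the back-derived k₄* = 10² M⁻¹s⁻¹ (noted in the data
file).  The ketosteroid isomerase record keeps both published rate
columns; the globally-optimized column is the default.

## Noise engine

Multiplicative noise g = √(−2 ln s₁)·cos(2π s₂) + shift (Box–Muller, or
the sine variant, or U(0,2) uniform — the uniform range is a documented
assumption, configurable).  Shifts of +1 or +2 bias multipliers positive.
One draw per step may be shared across all masked constants or drawn per
constant.  Constraints, applied after multiplication:

- **fixed_step_equilibria** — backward constants recomputed from the
  observed Kᵢ, pinning every step equilibrium and hence the total force
  to 10⁻¹² or better.  With a *shared* draw this rescales the entire rate
  vector by one factor, which is the exact mechanism behind the perfect
  efficiency–dissipation proportionality: every ratio of rate constants,
  and therefore the (kcat/K_M)/P slope, is invariant draw by draw.
- **fixed_total_force(i, j)** — the equilibrium constant of step i is
  scaled by the draw and step j counter-scaled so ΠKᵢ is untouched.  The
  variation is carried by the backward constants (k₂ᵢ /= g, k₂ⱼ *= g);
  carrying it on the forward pair is the mirror-image choice and gives
  the same invariant.  The published best fixed-force state for
  triosephosphate isomerase is reported through its changed backward
  constants, which motivated this choice.
- **replace_nonpositive_with_observed** — a draw pushing a constant to
  ≤ 0 reverts that constant to its observed value (the default; shift-0
  normal noise goes nonpositive about half the time).
- **none** — raw multiplication; nonpositive results raise.

All randomness flows from one seeded `numpy.random.Generator`
(PCG64), so identical seeds give bit-identical sample tables; every
output manifest records the seed.

## Exploration

Scans and samplers emit tidy tables (one row per quasi-steady state, all
rate constants, occupancies, forces, dissipation and performance columns)
whose rows are recomputable from their own stored rate constants — a
recompute-and-compare test enforces the absence of stale caching.
`noisy_sample` draws independently from the base set by default; a
`cumulative` mode turns the sampler into a multiplicative random walk
(each step perturbs the previous state, constraints still enforced
against the observed set).  The walk mode exists because unit-scale
independent draws concentrate within a few fold of the starting point,
while the interesting structure — e.g. the interior dissipation maximum
under a pinned total force, which sits near K₄ ≈ 10 for triosephosphate
isomerase against an observed K₄ = 156 — lives an order of magnitude
away.

Least-squares fits report R² = 1 − SS_res/SS_tot, with intercept by
default.  For the 1000-step product-release scan restricted to the
positive-force branch this pipeline obtains R² = 0.952 against a
published 0.9442; the published fit's exact row subset is not
recoverable, and the intercept-free alternative is far worse (0.55), so
the with-intercept convention stands and the discrepancy is documented
rather than tuned away.  Note the scan's near-collinearity is *not*
exact: with only one step's pair rescaled, specificity and dissipation
are distinct Möbius functions of the scanned constant and their ratio
retains a ~1% drift across the scan (R² ≈ 0.99998 through the origin).
Exact collinearity to machine precision requires the whole-vector
rescaling of the shared-draw fixed-equilibria sampler.

Best-point extraction breaks ties by the earliest step for reproducible
reports; fold reports are ratios of the best row to the observed row for
specificity, dissipation, turnover and flux.

## Stochastic simulator

Integer molecule counts (one pool per enzyme form, free S, free P; the
buffer is an unchanging reservoir) advance in ticks of dt seconds.  Each
tick, each state's molecules jump forward, backward or stay via one
multinomial draw with probabilities k·dt — binomial thinning, a
fixed-step tau-leaping scheme that converges to the master equation as
dt → 0.  A stability bound max kᵢ·dt ≤ 0.1 is enforced.  Enzyme
conservation is exact by construction; ligand conservation
([S]+[P]+bound forms) is asserted every tick.  Binding rates are rebuilt
from the instantaneous free-ligand counts each tick, so product
accumulation feeds back on the force; a depleted pool zeroes the
corresponding binding propensity, and binding events exceeding the free
pool are clamped and counted (zero clamps in all shipped runs).  One
global counts-per-molar factor converts counts to concentrations — the
published count examples imply different factors for enzymes and
ligands, so a single factor plus an explicit `initial_counts` override is
used instead.  Per-tick observables are evaluated from the nominal
(possibly noisy) rates and instantaneous concentrations through the
deterministic quasi-steady-state formulas, mirroring tick-based
simulators that report Hill-formula quantities rather than estimating
them from counts; for observable rows only, ligand concentrations are
floored at one count to keep logarithmic forces defined.

Convergence testing uses 10⁶ enzymes, dt = 10⁻⁶ s and 2×10⁴ ticks,
discarding the first 8×10³ ticks while the complex pools fill from the
all-free initial condition; the realized net product release per enzyme
per second is compared with the diagram-method flux evaluated at the
measurement window's mean concentrations, within three Monte-Carlo
standard errors estimated by batch means.  These sizes give ~0.5%
statistical resolution with sub-second runtimes.

## What the built-in parameter sets do and do not show

The shipped fixtures are real published kinetic constants, so the
reference blocks are genuine predictions about those enzymes'
steady-state thermodynamics.  The noise exploration, however, is a
mathematical probe of rate-constant space, not a physical model of any
mutational or dynamic-disorder process: a 30-fold specificity gain found
by noise says that such a rate-constant combination exists and what it
would dissipate, not that it is reachable by protein evolution.
Stochastic best-point values depend on the generator seed; the published
stochastic-run numbers are reproduced only as properties (severalfold
co-increase of efficiency and dissipation), since the original generator
seeds are unavailable.

## Known limitations

- Single cycles only; multi-cycle free-energy transducers (pumps,
  motors) are out of scope.
- The buffer reservoir approximation fixes [B]; buffer depletion is not
  modeled.
- kcat/K_M closed forms assume the standard binding topology; for the
  buffer-assisted scheme they are applied as published, though their
  interpretation there is less clean (the published tables do the same).
- The stochastic simulator has no spatial structure, crowding or
  per-molecule identity.
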