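# Methods

## Model and assumptions

`nichebranch` simulates a consumer population structured into juveniles and
adults, competing for *n* substitutable food resources arranged along a
one-dimensional niche axis. The model's assumptions:

* Resources renew semi-chemostatically (dF_i/dt = ρ(F_i^max − F_i)) and are
  depleted by consumption; there is no direct interference among consumers —
  all competition is mediated by the shared resources.
* A consumer phenotype is a pair (η, ℓ): the niche trait η fixes a Gaussian
  attack-rate profile over the resource optima θ_i (width τ), and the
  offspring size ℓ trades offspring number (birth rate ∝ 1/ℓ) against
  juvenile survival (mortality δ_max e^{−ℓ}) and a shorter juvenile growth
  trajectory (ℓ → w).
* Juveniles feed at a fraction γ < 1 of the adult rate and allocate net
  assimilated energy (ε c_J − ν, floored at zero) to growth; the maturation
  rate is the stage-structured cohort expression
  Φ = (φ − δ_J)/(1 − (ℓ/w)^{1−δ_J/φ}), zero when growth cannot outpace
  mortality.
* Evolution proceeds by adaptive dynamics: ecological dynamics reach
  equilibrium between trait updates (timescale separation), mutations are
  rare and small, and invasion fitness is the dominant eigenvalue of the
  rare mutant's juvenile/adult stage matrix in the resident environment.
  At the mutant's stationary stage distribution this eigenvalue equals the
  per-capita growth rate written with the mutant's own adult fraction; the
  equivalence is asserted in the test suite.

## Default parameters

All defaults live in `nichebranch.scenarios` and are used by every preset.

| parameter | value | units | meaning |
|---|---|---|---|
| D | 1 | trait | spacing of resource optima |
| τ | 0.35 | trait | niche breadth (D/τ ≈ 2.86 > 2) |
| ρ | 0.1 | 1/time | resource renewal rate |
| F_i^max | 2 | mass/volume | carrying capacity per resource |
| α | 3 | volume/time | maximum attack rate |
| γ | 0.7 | – | juvenile feeding scale |
| ε | 0.5 | – | assimilation efficiency |
| ν | 0.05 | 1/time | metabolic maintenance cost |
| w | 30 | mass | maturation size |
| δ_max | 1.4 | 1/time | juvenile mortality scale |
| δ_A | 0.3 | 1/time | adult mortality |

With ten resources the total productivity is exactly
P = ρ Σ F_i^max = 2 g L⁻¹ per unit time; the two-resource landscape has
P = 0.4.

**Calibration.** The organismal constants are not tied to a particular
organism; they were calibrated once, before any acceptance measurement, so
that the two-resource scenario exhibits the full diversification sequence
and then frozen. The calibration exploits two structural facts:

1. At a single-resident equilibrium the adult intake must equal the scalar
   break-even value c*(ℓ) at which the stage-structured growth rate is
   zero; c* is independent of the resource landscape. The
   convergence-stability threshold is proportional to c*(ℓ), so the
   productivity threshold P_min(ℓ) inherits the depletion valley of c*,
   with its minimum at the offspring-size optimum ℓ*.
2. The branching sequence needs, at the initial offspring size ℓ = 1, a
   near-specialist attractor whose basin contains the colonizing trait
   η = 1.3, and, near ℓ*, the disappearance (fold) of that specialist so
   the niche trait can travel to the midpoint.

Within these constraints the feasible region is narrow: the valley of
c*(ℓ) is intrinsically shallow (the exponential survival gain between
ℓ = 1 and ℓ* is bounded), and pushing the juvenile stage harder runs into
the maturation threshold φ = δ_J, where the "else 0" branch of Φ creates a
discontinuity on which trajectories chatter (a sliding mode; see
*Numerical choices*). The chosen set places the offspring-size optimum at
ℓ* ≈ 1.75 — somewhat above the nominal 1.5 of the original two-resource
illustration — because demanding ℓ* ≈ 1.5 together with the fold structure
left no parameter set clear of the sliding regime. The branching niche
trait, which is the quantitative target, is symmetry-forced to the
midpoint (1.5) and does not depend on this choice.

**Trait-update rates.** The engine's canonical-equation constants default
to k_η = 0.5 and k_ℓ = 0.1 (per-lineage overrides allowed); the
ten-resource race uses k_ℓ = 0.1 vs 0.05 (2:1), representing lineages with
different evolvability of the life-history trait. The constants absorb
mutation rate and variance and set only the evolutionary clock; k_η was
chosen large relative to k_ℓ so that the niche trait tracks its
quasi-equilibrium between life-history updates, which keeps the race
between lineages interpretable (the faster-evolving lineage's head start
is not erased by slow niche dynamics).

## What the presets emulate — and what they do not

The presets are synthetic experiments, not data: `two_resource` is the
canonical two-niche colonization; `ten_resource` seeds two lineages at
trait 0.8 and 10.2 (offspring size 1) on ten equally productive niches;
the threshold map sweeps offspring size × productivity under three
juvenile-mortality regimes. They emulate the qualitative structure of
niche-filling adaptive radiations (salmonid- or cichlid-like scenarios in
the broadest sense): discrete resources, Gaussian niche use, stage
structure. They omit, among much else, stochastic demography and genetics
(branching is a deterministic threshold event; no drift, no linkage),
spatial structure, seasonality, and any saturating functional response.
Passing tests therefore demonstrate internal consistency of the
deterministic model and its analytic conditions, not fidelity to any
empirical system.

## Numerical choices

* **Equilibria.** The ecological attractor is found by LSODA integration in
  bounded chunks with a Newton (hybr) polish attempted after every chunk;
  a polished root is accepted only if it satisfies the residual tolerance
  (default 1e−12), stays in the positive cone, does not resurrect an
  ecomorph the integration had driven below the extinction threshold
  (default 1e−9 density), and is locally stable (max Re eig < 1e−6). This
  last check prevents returning an unstable focus inside a limit cycle.
  Residual stagnation with a moving state raises `OscillationDetected`
  rather than averaging — that regime is flagged, never simulated through.
* **Maturation threshold.** Φ has a removable 0/0 at φ = δ_J; within a
  relative band of 1e−7 it switches to the analytic limit δ_J/ln(w/ℓ).
  The exponent is evaluated as exp((1 − δ_J/φ) ln(ℓ/w)) for stability.
  Below the threshold, Φ = 0 exactly: equilibria that would sit on the
  resulting discontinuity are Filippov sliding states; default parameters
  keep all visited equilibria clear of it (break-even margin ≥ 20% at the
  optimum), and the solver's stagnation guard catches the chatter if a
  user's parameters do not.
* **Differentiation.** Selection gradients and curvature use central
  differences with one Richardson level, steps 1e−5·max(1, |trait|)
  (curvature 1e−4); invasion fitness is smooth and cheap, and equilibrium
  noise is bounded by the 1e−12 polish.
* **Convergence stability** differences the niche gradient across resident
  equilibria at η ± 1e−4 (one-trait criterion at fixed ℓ; ecological
  opportunity exists only along the niche axis, so the two-trait strong
  convergence analysis is out of scope).
* **Evolutionary stepping.** Explicit Euler with dt halved until no niche
  displacement exceeds 1% of D. Cessation is a per-step displacement test
  (|Δη| < 1e−8), exactly as specified by the branching protocol, not a
  gradient test. Ecomorphs qualifying simultaneously branch in the same
  step in id order (deterministic tie-break). Same-lineage ecomorphs
  closer than 1e−4·D in both traits are merged, densities summed.
  Offspring size is clipped to (1e−6, w(1 − 1e−6)) since Φ requires
  ℓ < w.
* **Degenerate inputs.** Empty communities return F = F_max exactly;
  non-viable (starving) ecomorphs are culled and reported in
  `EquilibriumResult.removed`; grid cells with equilibrium failures are
  flagged in the threshold map rather than dropped.

## Design choices where the design was open

* The branching protocol's update rule is not fully pinned down by the
  cessation/branching description alone; we use a canonical-equation-style
  ODE (Δtrait = k N* g Δt), which preserves the protocol's event structure
  and is deterministic.
* Uniqueness of the positive ecological equilibrium is not established;
  the solver documents that it returns the attractor reached from the
  supplied initial state (default: resources at capacity, a 0.01-density
  inoculum per ecomorph).
* E and G in the productivity threshold are evaluated at the singular
  resident's own equilibrium (the evaluation point is otherwise
  ambiguous); the numeric/analytic agreement tests validate this choice,
  and with it the reconstructed threshold formula
  ρ G D² e^{D²/(8τ²)}/(4 E τ² α) and the D/τ > 2 condition.
* The command-line `preset fig4a` grid (ℓ ∈ [1, 3] × P ∈ [0.25, 0.6],
  9 × 8 cells, three δ_max scenarios) was sized for desk-scale runtimes;
  all grids are flags.

## Known limitations

* The offspring-size optimum sits at ℓ* ≈ 1.75 under the shipped
  calibration (see above); users wanting a different optimum can move
  δ_max and δ_A but should re-check the sliding-margin and fold
  diagnostics.
* Small offspring sizes (ℓ ≲ 0.9 at default parameters) put the resident
  on or near the maturation threshold; depending on the remaining
  parameters this yields extinction or flagged oscillation/sliding, and
  sweeps should treat that band as outside the model's smooth regime.
* Oscillatory (limit-cycle) ecological regimes are detected and reported,
  not analyzed; cycle-averaged invasion fitness is out of scope.
* Each sweep point is solved independently; there is no continuation of
  equilibrium branches, so bistable ecological regimes return whichever
  attractor the default initial state reaches.
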