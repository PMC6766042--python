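# Methods

## Model

The simulator couples three components.

**Cognition.** A population-wide cognitive ability σ ∈ (0, 1) fixes the
cognitive deviation β = 1/σ − 1, the standard deviation of each agent's
perception error around the innovation's true value μ₀ ∈ (0, 1). Agent
cognition levels μᵢ are i.i.d. draws from N(μ₀, β²) truncated to (0, 1]
(density f₁(x) / (F₁(1) − F₁(0)) on the support, 0 elsewhere). Cognition is
*static*: agents are sampled once at t = 0 and never update their perceived
value; belief updating is out of scope.

**Network.** The group structure is an undirected Barabási–Albert graph:
a star on l + 1 nodes, then each new node attaches l edges to distinct
existing nodes with probability proportional to current degree. The star
seed is a documented convention that makes the edge count deterministic,
l·(n − l). "Observation" is symmetric: agent i's neighborhood Bᵢ is its
adjacency set, and its signal is the adoption fraction qᵢ = |adopting
neighbors| / |Bᵢ|, with qᵢ := 0 for an isolated node (such a node adopts
only if μᵢ = 1; BA graphs never produce one, imported edge lists might).

**Dynamics.** A non-adopter adopts when μᵢ ≥ 1 − qᵢ (non-strict at the
boundary). This is the best response in a pairwise coordination game with
payoffs a (both adopt) and b (neither adopts): adopting beats holding out
when q > b/(a + b), and the perceived value μᵢ is identified with
a/(a + b), so payoffs and degree never appear as free parameters. Adoption
is irreversible, which makes the cascade monotone: Rₜ is non-decreasing and
the state is a fixed point after at most n steps (at least one adoption
occurs per active step). Updates are **synchronous**: every agent evaluates
the previous step's state, so a step is independent of node evaluation
order and runs are reproducible from (parameters, seed) alone.

## Indicators

R_t is the acceptance proportion at step t; the value at the horizon
t_total is the final acceptance proportion. T = inf{t : Rₜ = … = R_total}
is the stabilization time; it is computed on integer adopter counts, so the
equality comparisons in its definition carry no floating-point risk. T is
an integer per run; fractional reported values are replication averages.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| n | population size | 100 | sweeps use 50–400 |
| l | BA attachment parameter | 2 | mean degree ≈ 2l; sweeps use 2–8 |
| p | seeding probability | 0.3 | i.i.d. Bernoulli at t = 0 |
| σ | cognitive ability | 0.5 | grid: 1e-5, 0.3, 0.5, 0.7, 1 − 1e-5 |
| μ₀ | true value | 0.9 | grid: 0.1, 0.3, 0.5, 0.7, 0.9 |
| t_total | horizon (steps) | 100 | fixed point is reached long before |
| reps | replications per cell | 50 | each redraws network, cognition, seeds |

σ = 0.00001 and σ = 0.99999 are accepted literally, not clamped. Default
σ = 0.5, μ₀ = 0.9 is the headline scenario: moderate ability, high-value
innovation. Replication r of a cell uses the RNG stream
`numpy.random.default_rng([seed, r])`, which drives the network, the
cognition draws and the seeding in that fixed order; cells are therefore
bit-reproducible and independently recomputable.

## Numerical choices

- **Sampling.** Cognition draws use the inverse-CDF truncated-normal
  sampler. When β > 10³ the truncated density equals the uniform density on
  (0, 1] to within O(β⁻²) (total-variation distance < 10⁻⁵ at β = 99999,
  verified against a quadrature oracle in the tests), and exact uniform
  draws are substituted; this avoids precision loss when the CDF difference
  across the unit window underflows toward zero. Draws that round to
  exactly 0 — a probability-zero event kept only for floating-point
  robustness — are nudged to the smallest positive float.
- **Degenerate normalizer.** If F₁(1) − F₁(0) underflows to 0 the density
  and sampler raise an error naming σ and μ₀ rather than returning NaNs.
- **Threshold ties.** The rule is evaluated with ≥, exactly as derived, so
  μᵢ equal to 1 − qᵢ adopts.
- **Early exit.** A cascade stops as soon as a sweep changes nothing and
  pads the constant tail; this is exact, not an approximation, because the
  dynamics are monotone.

## Design choices where the design was open

- **Update schedule.** The dynamics are run synchronously. A sequential
  in-place sweep (agents updated one at a time, seeing same-sweep
  adoptions) reaches the *same* final state — monotone threshold cascades
  have a schedule-independent fixed point — but needs fewer rounds, so
  stabilization times are schedule-dependent: at σ = 0.5, μ₀ = 0.9 the
  50-rep mean T is ≈ 5.3 synchronous versus ≈ 3.0 sequential. Synchrony was
  chosen for order-independence and reproducibility; all acceptance-extent
  results are unaffected, and reported stabilization times should be read
  as synchronous-round counts.
- **Structure sweeps.** The degree sweep (l = 2, 4, 6, 8) and size sweep
  (n = 50, 100, 200, 400) bracket the default network at desk scale. They
  are run at σ = 0.7, μ₀ = 0.9, the high-ability regime in which the
  cascade nearly saturates for every degree. This matters: the two expected
  degree trends — acceptance rising and stabilization time falling as
  connectivity grows — can hold jointly only when the acceptance ceiling is
  (nearly) flat in l. At σ = 0.5 the ceiling itself rises with degree
  (≈ 0.79 → 0.94) and reaching the higher plateau takes *longer*
  (mean T ≈ 5.3 → 7.0, under either schedule), reversing the time trend.
  Trend conclusions use the sign of an OLS slope across the sweep, not
  per-step monotonicity, since individual cells are Monte-Carlo noisy.
- **Seeded adopters' cognition** is sampled like everyone else's; with
  irreversible adoption those draws are inert.
- **Directedness.** Observation is modeled as symmetric adjacency; the
  standard BA generator produces undirected graphs and the dynamics only
  need neighbor sets.

## What the generator emulates — and what it does not

The synthetic experiments emulate the study conditions end to end: there is
no external data, so the "generator" is the simulator itself (BA network +
truncated-normal cognition + Bernoulli seeding). Features of real diffusion
it deliberately omits: cognition updating and social learning, reversible
or decaying adoption, heterogeneous per-agent σ, degree–cognition
correlation, community structure beyond the BA degree tail, and any
strategic seeding. Passing tests therefore show internal consistency of the
model and reproducibility of its reported statistics — not external
validity for any real adoption campaign.

## Known limitations

- Stabilization times are schedule-dependent (see above); only their
  qualitative trends, not their absolute values, transfer across schedules.
- At σ near 0 the uniform substitution makes results independent of μ₀ by
  construction (the flat-row behavior is exact rather than approximate).
- A 100-node BA graph is small enough that hub effects dominate; size-sweep
  trends are gentle and need ≥ 50 replications to resolve.
- The coordination-game derivation assumes all-or-nothing payoffs with a
  common ratio absorbed into μᵢ; heterogeneous payoffs would decouple μ
  from the threshold and are not supported.
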