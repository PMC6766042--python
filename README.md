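# innodiff

Agent-based simulation of how an innovation (a new practice, policy or
product — the motivating case is a municipal garbage-classification scheme)
spreads through a population of *bounded-rational* agents connected by a
scale-free social network.

The package is for computational social scientists and epidemiological
modelers who want a small, fully reproducible threshold-cascade simulator
in which the agents' imperfect perception of the innovation's value is the
first-class modeling object.

## Model

Each agent *i* perceives the innovation's true value μ₀ ∈ (0, 1) with an
error controlled by the population's cognitive ability σ ∈ (0, 1):

- cognitive deviation: **β = 1/σ − 1**
- cognition level: **μᵢ ~ N(μ₀, β²) truncated to (0, 1]**, drawn once at
  t = 0 (as σ → 1 the draws concentrate at μ₀; as σ → 0 they flatten to
  uniform on (0, 1]).

Agents sit on a Barabási–Albert preferential-attachment graph (star seed on
l + 1 nodes, l edges per new node) and observe their neighbors' adoption
states. With qᵢ the fraction of i's neighbors that have adopted, a
non-adopter adopts when

**μᵢ ≥ 1 − qᵢ**,

the best-response condition of a two-strategy coordination game whose payoff
ratio is absorbed into μᵢ. Updates are synchronous and adoption is
irreversible, so the acceptance proportion Rₜ = (1/n) Σ wᵢ,ₜ is
non-decreasing and reaches a fixed point within n steps. The two outcome
indicators are the final acceptance proportion R at the horizon and the
stabilization time T = inf{t : Rₜ = Rₜ₊₁ = … = R_total}.

Experiments seed adopters with independent Bernoulli(p) draws and average R
and T over independent replications, each of which redraws the network, the
cognition levels and the seeds. Defaults: n = 100, l = 2, p = 0.3,
t_total = 100, 50 replications.

## Worked example

```python
import numpy as np
from innodiff import (CognitionSpec, SimulationConfig, generate_ba,
                      replicate, run_cascade, sample_cognition, seed_adopters)

rng = np.random.default_rng(1)
net = generate_ba(n=100, l=2, rng=rng)
cognition = sample_cognition(100, CognitionSpec(sigma=0.5, mu0=0.9), rng)
init = seed_adopters(100, p=0.3, rng=rng)
traj = run_cascade(net, cognition, init, t_total=100)
print("acceptance series head:", np.round(traj.acceptance_series[:8], 2))
print("final acceptance:      ", traj.acceptance_series[-1])
print("stabilization time:    ", traj.stabilization_time)

cell = replicate(SimulationConfig(sigma=0.5, mu0=0.9, seed=1))
print(f"50-replication means:   R = {cell.mean_R:.3f}, T = {cell.mean_T:.2f}")
```

prints

```
acceptance series head: [0.42 0.75 0.89 0.93 0.94 0.94 0.94 0.94]
final acceptance:       0.94
stabilization time:     4
50-replication means:   R = 0.788, T = 4.94
```

This single run seeded 42 agents, cascaded to 94% adoption and was stable
from step 4 on; averaged over 50 independent replications, moderate
cognitive ability (σ = 0.5) paired with a high-value innovation (μ₀ = 0.9)
settles at about 79% adoption in about five synchronous rounds.

The same experiments are available from the shell:

```bash
innodiff simulate --seed 1 --sigma 0.5 --mu0 0.9 --out-dir results/run1
innodiff grid --seed 1 --out-dir results/grid        # 5x5 sigma x mu0 table
innodiff sweep --axis degree --sigma 0.7 --seed 1 --out-dir results/deg
```

Every command writes CSV/JSON results plus a `manifest.json` recording the
resolved configuration and seed, so each file is traceable.

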