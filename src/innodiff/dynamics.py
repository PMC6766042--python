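"""Coordination-game threshold dynamics of adoption.

A non-adopter i adopts when its perceived value of the innovation is at
least the fraction of its neighbors who have NOT adopted:

    mu_i >= 1 - q_i,

the best-response condition of a two-strategy coordination game whose
payoff ratio is absorbed into mu_i.  Updates are synchronous (every agent
evaluates the previous step's state) and adoption is irreversible, so the
acceptance proportion R_t is non-decreasing and the cascade reaches a fixed
point within n steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cognition import as_cognition_array
from .network import ObservationNetwork

__all__ = ["PopulationState", "Trajectory", "seed_adopters", "step", "run_cascade"]


@dataclass
class PopulationState:
    """Binary adoption vector w over all agents at time index t."""

    w: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.int8)
        if not np.isin(self.w, (0, 1)).all():
            raise ValueError("adoption indicators must be 0 or 1")

    @property
    def n(self) -> int:
        return self.w.size


@dataclass
class Trajectory:
    """One run: acceptance series R_0..R_total, stabilization time, final state."""

    acceptance_series: np.ndarray
    stabilization_time: int
    final_state: PopulationState
    state_snapshots: list[PopulationState] | None = None
    adopter_counts: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "acceptance_series": [float(r) for r in self.acceptance_series],
            "stabilization_time": int(self.stabilization_time),
            "final_acceptance": float(self.acceptance_series[-1]),
            "n": int(self.final_state.n),
        }


def seed_adopters(n: int, p: float, rng: np.random.Generator) -> PopulationState:
    """Independent Bernoulli(p) adoption indicator per node at t = 0."""
    if n < 1:
        raise ValueError(f"population size n must be >= 1, got {n!r}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"seeding probability p must lie in [0, 1], got {p!r}")
    return PopulationState(w=(rng.random(n) < p).astype(np.int8), t=0)


def _advance(a, deg: np.ndarray, w: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """One synchronous sweep; returns the next adoption vector."""
    counts = a @ w.astype(float)
    q = np.divide(counts, deg, out=np.zeros_like(counts), where=deg > 0)
    return np.where((w == 0) & (mu >= 1.0 - q), 1, w).astype(np.int8)


def _check_sizes(net: ObservationNetwork, w: np.ndarray, mu: np.ndarray) -> None:
    if not (net.n == w.size == mu.size):
        raise ValueError(
            f"inconsistent sizes: network n={net.n}, state n={w.size}, "
            f"cognition n={mu.size}"
        )


def step(net: ObservationNetwork, states: PopulationState, cognition) -> PopulationState:
    """Synchronous threshold update from the input state; time advances by 1.

    Every non-adopter evaluates q from the INPUT state, so the result does
    not depend on any node evaluation order; adopters never revert.
    """
    mu = as_cognition_array(cognition)
    _check_sizes(net, states.w, mu)
    a, deg = net.adjacency()
    return PopulationState(w=_advance(a, deg, states.w, mu), t=states.t + 1)


def run_cascade(
    net: ObservationNetwork,
    cognition,
    init: PopulationState,
    t_total: int,
    record_states: bool = False,
) -> Trajectory:
    """Iterate the threshold rule for ``t_total`` steps from the seeded state.

    The cascade is monotone, so once a sweep changes nothing the state is a
    fixed point and the remaining acceptance values are the constant tail;
    iteration stops there and the series is padded.  The stabilization time
    is the first index from which the adopter count is constant through the
    horizon (an integer-count comparison, immune to float noise).
    """
    if t_total < 1:
        raise ValueError(f"horizon t_total must be >= 1, got {t_total!r}")
    mu = as_cognition_array(cognition)
    _check_sizes(net, init.w, mu)
    a, deg = net.adjacency()
    n = net.n

    w = init.w.copy()
    counts = [int(w.sum())]
    snapshots = [PopulationState(w=w.copy(), t=0)] if record_states else None
    for t in range(1, t_total + 1):
        w_next = _advance(a, deg, w, mu)
        changed = int(w_next.sum()) != counts[-1]
        w = w_next
        counts.append(int(w.sum()))
        if record_states:
            snapshots.append(PopulationState(w=w.copy(), t=t))
        if not changed:
            break
    # constant tail after the fixed point
    while len(counts) < t_total + 1:
        counts.append(counts[-1])
        if record_states:
            snapshots.append(PopulationState(w=w.copy(), t=len(counts) - 1))

    counts_arr = np.asarray(counts, dtype=int)
    changes = np.flatnonzero(counts_arr[1:] != counts_arr[:-1])
    stab = int(changes[-1] + 1) if changes.size else 0
    return Trajectory(
        acceptance_series=counts_arr / n,
        stabilization_time=stab,
        final_state=PopulationState(w=w, t=t_total),
        state_snapshots=snapshots,
        adopter_counts=counts_arr,
    )
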