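"""Replicated Monte-Carlo experiments over parameter grids.

A *cell* is one parameter configuration.  Each cell is simulated ``reps``
times; every replication redraws the network, the cognition levels and the
seed adopters from an independent RNG stream derived from (base seed,
replication index), then runs the cascade and records the final acceptance
proportion R and the stabilization time T.  Cell summaries are arithmetic
means over replications.

Default configuration: n = 100 agents, attachment parameter l = 2, seeding
probability p = 0.3, horizon t_total = 100 steps, 50 replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cognition import CognitionSpec, sample_cognition
from .dynamics import run_cascade, seed_adopters
from .network import generate_ba

__all__ = [
    "SimulationConfig",
    "CellSummary",
    "GridResult",
    "replicate",
    "grid_sigma_mu0",
    "sweep_degree",
    "sweep_size",
    "trend_slope",
    "DEFAULT_SIGMAS",
    "DEFAULT_MU0S",
    "DEFAULT_DEGREES",
    "DEFAULT_SIZES",
]

DEFAULT_SIGMAS = (0.00001, 0.3, 0.5, 0.7, 0.99999)
DEFAULT_MU0S = (0.1, 0.3, 0.5, 0.7, 0.9)
# Sweep axes bracketing the default network (l = 2, n = 100).
DEFAULT_DEGREES = (2, 4, 6, 8)
DEFAULT_SIZES = (50, 100, 200, 400)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one experiment cell."""

    n: int = 100
    l: int = 2
    p: float = 0.3
    sigma: float = 0.5
    mu0: float = 0.9
    t_total: int = 100
    reps: int = 50
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n <= self.l:
            raise ValueError(f"n must exceed l, got n={self.n}, l={self.l}")
        if self.l < 1:
            raise ValueError(f"l must be >= 1, got {self.l}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if not (0.0 < self.sigma < 1.0):
            raise ValueError(f"sigma must lie in (0, 1), got {self.sigma}")
        if not (0.0 < self.mu0 < 1.0):
            raise ValueError(f"mu0 must lie in (0, 1), got {self.mu0}")
        if self.t_total < 1:
            raise ValueError(f"t_total must be >= 1, got {self.t_total}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed}")
        return self


@dataclass(frozen=True)
class CellSummary:
    """Replication-mean indicators and the raw per-replication values."""

    mean_R: float
    mean_T: float
    R: np.ndarray
    T: np.ndarray


def replicate(config: SimulationConfig) -> CellSummary:
    """Run one cell: ``reps`` independent replications, averaged.

    Replication r uses the RNG stream seeded by (config.seed, r), so cells
    can be recomputed independently without changing results.
    """
    config.validate()
    spec = CognitionSpec(sigma=config.sigma, mu0=config.mu0)
    finals = np.empty(config.reps)
    times = np.empty(config.reps, dtype=int)
    for r in range(config.reps):
        rng = np.random.default_rng([config.seed, r])
        net = generate_ba(config.n, config.l, rng)
        cognition = sample_cognition(config.n, spec, rng)
        init = seed_adopters(config.n, config.p, rng)
        traj = run_cascade(net, cognition, init, config.t_total)
        finals[r] = traj.acceptance_series[-1]
        times[r] = traj.stabilization_time
    return CellSummary(
        mean_R=float(finals.mean()), mean_T=float(times.mean()), R=finals, T=times
    )


@dataclass
class GridResult:
    """Replication-averaged (mean_R, mean_T) per parameter cell.

    ``axes`` maps axis name -> swept values; ``mean_R`` and ``mean_T`` have
    one entry per cell in row-major axis order.
    """

    axes: dict[str, tuple]
    mean_R: np.ndarray
    mean_T: np.ndarray
    reps: int
    seed: int
    per_rep: dict[tuple, CellSummary] | None = field(default=None, repr=False)

    def to_tidy_frame(self) -> pd.DataFrame:
        """One row per cell: axis values, mean_R, mean_T, reps, seed."""
        names = list(self.axes)
        grids = np.meshgrid(*[np.asarray(v) for v in self.axes.values()], indexing="ij")
        data = {name: g.ravel() for name, g in zip(names, grids)}
        data["mean_R"] = self.mean_R.ravel()
        data["mean_T"] = self.mean_T.ravel()
        data["reps"] = self.reps
        data["seed"] = self.seed
        return pd.DataFrame(data)

    def to_wide_frame(self, which: str = "R") -> pd.DataFrame:
        """Row/column table (first axis x second axis); two-axis grids only."""
        if len(self.axes) != 2:
            raise ValueError("wide layout needs exactly two axes")
        values = self.mean_R if which == "R" else self.mean_T
        (rname, rvals), (cname, cvals) = self.axes.items()
        frame = pd.DataFrame(values, index=list(rvals), columns=list(cvals))
        frame.index.name = rname
        frame.columns.name = cname
        return frame

    def per_rep_frame(self) -> pd.DataFrame:
        """Raw per-replication values, one row per (cell, replication)."""
        if self.per_rep is None:
            raise ValueError("per-replication values were not kept")
        rows = []
        names = list(self.axes)
        for key, cell in self.per_rep.items():
            for r, (rv, tv) in enumerate(zip(cell.R, cell.T)):
                row = dict(zip(names, key))
                row.update({"rep": r, "R_final": rv, "T": int(tv)})
                rows.append(row)
        return pd.DataFrame(rows)


def _run_grid(
    base: SimulationConfig,
    axes: dict[str, tuple],
    keep_per_rep: bool,
) -> GridResult:
    names = list(axes)
    shape = tuple(len(v) for v in axes.values())
    mean_r = np.empty(shape)
    mean_t = np.empty(shape)
    per_rep: dict[tuple, CellSummary] = {}
    for idx in np.ndindex(*shape):
        overrides = {name: axes[name][k] for name, k in zip(names, idx)}
        cell = replicate(replace(base, **overrides))
        mean_r[idx] = cell.mean_R
        mean_t[idx] = cell.mean_T
        if keep_per_rep:
            per_rep[tuple(overrides.values())] = cell
    return GridResult(
        axes=axes,
        mean_R=mean_r,
        mean_T=mean_t,
        reps=base.reps,
        seed=base.seed,
        per_rep=per_rep if keep_per_rep else None,
    )


def grid_sigma_mu0(
    base: SimulationConfig,
    sigmas: Sequence[float] = DEFAULT_SIGMAS,
    mu0s: Sequence[float] = DEFAULT_MU0S,
    keep_per_rep: bool = False,
) -> GridResult:
    """Cross cognitive ability with true value: the 5 x 5 headline grid."""
    if not sigmas or not mu0s:
        raise ValueError("axes must be nonempty")
    return _run_grid(base, {"sigma": tuple(sigmas), "mu0": tuple(mu0s)}, keep_per_rep)


def sweep_degree(
    base: SimulationConfig,
    l_values: Sequence[int] = DEFAULT_DEGREES,
    keep_per_rep: bool = False,
) -> GridResult:
    """Sweep the attachment parameter at fixed population size."""
    if not l_values:
        raise ValueError("l_values must be nonempty")
    for l in l_values:
        if l >= base.n:
            raise ValueError(f"every l must be < n, got l={l}, n={base.n}")
    return _run_grid(base, {"l": tuple(l_values)}, keep_per_rep)


def sweep_size(
    base: SimulationConfig,
    n_values: Sequence[int] = DEFAULT_SIZES,
    keep_per_rep: bool = False,
) -> GridResult:
    """Sweep the population size at fixed attachment parameter."""
    if not n_values:
        raise ValueError("n_values must be nonempty")
    for n in n_values:
        if n <= base.l:
            raise ValueError(f"every n must be > l, got n={n}, l={base.l}")
    return _run_grid(base, {"n": tuple(n_values)}, keep_per_rep)


def trend_slope(x, y) -> float:
    """Ordinary-least-squares slope of y on x; the sweeps' trend statistic."""
    return float(np.polyfit(np.asarray(x, float), np.asarray(y, float), 1)[0])
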