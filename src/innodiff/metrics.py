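"""Diffusion indicators: acceptance proportion R_t and stabilization time T.

R_t is the fraction of agents adopting at step t; the value at the horizon
is the final acceptance proportion.  T is the earliest step from which the
acceptance series stays constant through the horizon,

    T = inf { t : R_t = R_{t+1} = ... = R_total },

so a constant series has T = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IndicatorPair", "acceptance_proportion", "stabilization_time"]


@dataclass(frozen=True)
class IndicatorPair:
    """Final acceptance proportion and stabilization time of one run."""

    final_acceptance: float
    stabilization_time: int


def acceptance_proportion(states) -> float:
    """Mean of the adoption indicators, in [0, 1]."""
    w = np.asarray(getattr(states, "w", states))
    if w.size == 0:
        raise ValueError("acceptance proportion of an empty state is undefined")
    return float(w.mean())


def stabilization_time(acceptance_series) -> int:
    """Smallest index t such that all later series values equal R_t.

    The series values are adopter counts divided by a common n, so exact
    equality comparisons reduce to integer-count equality and carry no
    floating-point risk.
    """
    series = np.asarray(acceptance_series, dtype=float)
    if series.size == 0:
        raise ValueError("stabilization time of an empty series is undefined")
    changes = np.flatnonzero(series[1:] != series[:-1])
    return int(changes[-1] + 1) if changes.size else 0
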