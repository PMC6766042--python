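"""Bounded-rational cognition of an innovation's value.

Each agent perceives the innovation's true value ``mu0`` with an error whose
standard deviation (the *cognitive deviation* ``beta``) shrinks as the
agent's *cognitive ability* ``sigma`` grows:

    beta = 1 / sigma - 1,    sigma in (0, 1).

Individual cognition levels are i.i.d. draws from a normal distribution
N(mu0, beta^2) truncated to the unit interval (0, 1], so that a cognition
level of 0 means no awareness of the innovation and 1 means complete
awareness.  As sigma -> 1 the draws concentrate at mu0; as sigma -> 0 the
truncated distribution flattens to uniform on (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CognitionSpec",
    "CognitionVector",
    "cognitive_deviation",
    "truncated_normal_pdf",
    "sample_cognition",
]

# Above this deviation the truncated normal is uniform on (0,1] to within
# O(beta^-2) ~ 1e-6 in density, far below Monte-Carlo noise; sampling then
# uses exact uniform draws for numerical robustness.
UNIFORM_SUBSTITUTION_BETA = 1e3


def cognitive_deviation(sigma: float) -> float:
    """Cognitive deviation ``beta = 1/sigma - 1`` for ability ``sigma``.

    Strictly positive and strictly decreasing on the open interval (0, 1):
    the stronger the cognitive ability, the smaller the perception error.

    Raises
    ------
    ValueError
        If ``sigma`` lies outside the open interval (0, 1).
    """
    if not (0.0 < sigma < 1.0):
        raise ValueError(f"cognitive ability sigma must lie in (0, 1), got {sigma!r}")
    return 1.0 / sigma - 1.0


@dataclass(frozen=True)
class CognitionSpec:
    """The pair (sigma, mu0) with the derived deviation beta.

    Parameters
    ----------
    sigma : float
        Cognitive ability, in (0, 1).
    mu0 : float
        True value of the innovation, in (0, 1).
    """

    sigma: float
    mu0: float
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.mu0 < 1.0):
            raise ValueError(f"true value mu0 must lie in (0, 1), got {self.mu0!r}")
        object.__setattr__(self, "beta", cognitive_deviation(self.sigma))


@dataclass(frozen=True)
class CognitionVector:
    """Per-agent cognition levels mu_i, each in (0, 1].

    Cognition is static over a simulation: agents are sampled once at t = 0
    and keep their perceived value for the whole cascade.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


def _normalizer(spec: CognitionSpec) -> float:
    """F1(1) - F1(0) for the parent normal N(mu0, beta^2)."""
    z = stats.norm.cdf((1.0 - spec.mu0) / spec.beta) - stats.norm.cdf(
        (0.0 - spec.mu0) / spec.beta
    )
    if z <= 0.0 or not np.isfinite(z):
        raise FloatingPointError(
            "degenerate truncation normalizer for "
            f"sigma={spec.sigma!r}, mu0={spec.mu0!r}: F1(1) - F1(0) = {z!r}"
        )
    return float(z)


def truncated_normal_pdf(x, spec: CognitionSpec):
    """Density g(x) of the cognition distribution.

    ``g(x) = f1(x) / (F1(1) - F1(0))`` on 0 < x <= 1 and 0 elsewhere, where
    f1 is the N(mu0, beta^2) density and F1 its CDF.  Accepts scalars or
    arrays; returns the same shape.
    """
    x = np.asarray(x, dtype=float)
    z = _normalizer(spec)
    inside = (x > 0.0) & (x <= 1.0)
    dens = np.zeros_like(x)
    dens[inside] = stats.norm.pdf(x[inside], loc=spec.mu0, scale=spec.beta) / z
    if dens.ndim == 0:
        return float(dens)
    return dens


def sample_cognition(
    n: int, spec: CognitionSpec, rng: np.random.Generator
) -> CognitionVector:
    """Draw ``n`` i.i.d. cognition levels from g, all in (0, 1].

    Uses the inverse-CDF sampler of the truncated normal.  When beta exceeds
    ``UNIFORM_SUBSTITUTION_BETA`` the distribution is uniform on (0, 1] to
    within O(beta^-2) and exact uniform draws are used instead, which avoids
    the precision loss of CDF differences across a vanishingly small window.
    Values that round to exactly 0 (a probability-zero event) are nudged to
    the smallest positive float so the open lower endpoint holds.
    """
    if n < 1:
        raise ValueError(f"population size n must be >= 1, got {n!r}")
    _normalizer(spec)  # fail fast on degenerate parameters
    if spec.beta > UNIFORM_SUBSTITUTION_BETA:
        values = 1.0 - rng.random(n)  # uniform on (0, 1]
    else:
        a = (0.0 - spec.mu0) / spec.beta
        b = (1.0 - spec.mu0) / spec.beta
        values = stats.truncnorm.rvs(
            a, b, loc=spec.mu0, scale=spec.beta, size=n, random_state=rng
        )
        values = np.asarray(values, dtype=float)
        values[values <= 0.0] = np.nextafter(0.0, 1.0)
        values[values > 1.0] = 1.0
    return CognitionVector(values)


def as_cognition_array(cognition: "CognitionVector | Sequence[float]") -> np.ndarray:
    """Coerce a CognitionVector or plain sequence to a float array."""
    values = getattr(cognition, "values", cognition)
    return np.asarray(values, dtype=float)
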