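"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest


def brute_force_fixed_point(adj: dict[int, set[int]], w0, mu) -> list[int]:
    """Iterate the threshold rule naively until nothing changes.

    Pure-Python synchronous sweeps over an adjacency dict; independent of the
    package's vectorized implementation.  Returns the fixed-point adoption
    vector.
    """
    w = [int(v) for v in w0]
    n = len(w)
    while True:
        new = list(w)
        for i in range(n):
            if w[i] == 1:
                continue
            neighbors = adj[i]
            q = sum(w[j] for j in neighbors) / len(neighbors) if neighbors else 0.0
            if mu[i] >= 1.0 - q:
                new[i] = 1
        if new == w:
            return w
        w = new


def truncnorm_cdf_by_quadrature(x: float, mu0: float, beta: float) -> float:
    """CDF of the cognition distribution computed by direct quadrature.

    Integrates the written-out normal density over (0, x] and normalizes by
    the integral over (0, 1]; shares no code with the package's sampler.
    """
    from scipy.integrate import quad

    def f1(u):
        return math.exp(-((u - mu0) ** 2) / (2 * beta**2)) / (
            math.sqrt(2 * math.pi) * beta
        )

    z, _ = quad(f1, 0.0, 1.0, epsabs=1e-13, limit=200)
    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    num, _ = quad(f1, 0.0, x, epsabs=1e-13, limit=200)
    return num / z


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
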