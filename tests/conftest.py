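"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


class BetaMixtureOracle:
    """Exact mixture-of-Betas posterior for expectation-based trust.

    A Beta(a, b) reliability prior updated with the linear likelihood
    b_c * tau + (1 - b_c) * (1 - tau) stays a finite Beta mixture: each
    component Beta(a, b) splits into Beta(a+1, b) with weight
    proportional to b_c * a/(a+b) and Beta(a, b+1) with weight
    proportional to (1 - b_c) * b/(a+b).  Grows 2^k components after k
    updates; exact, so it is the independent check for the grid
    implementation.
    """

    def __init__(self, a: float = 2.0, b: float = 1.0):
        self.components = [(1.0, float(a), float(b))]

    @property
    def mean(self) -> float:
        return sum(w * a / (a + b) for w, a, b in self.components)

    def update(self, b_c: float) -> "BetaMixtureOracle":
        new = []
        for w, a, b in self.components:
            m = a / (a + b)
            new.append((w * b_c * m, a + 1.0, b))
            new.append((w * (1.0 - b_c) * (1.0 - m), a, b + 1.0))
        z = sum(w for w, _, _ in new)
        self.components = [(w / z, a, b) for w, a, b in new]
        return self


def brute_force_mean_clustering(edges, n: int) -> float:
    """Triangle-counting local clustering, averaged over all n nodes.

    Deliberately naive (adjacency sets and pair enumeration) so it is
    independent of any graph library.
    """
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    total = 0.0
    for v in range(n):
        neigh = sorted(adj[v])
        d = len(neigh)
        if d < 2:
            continue
        links = sum(
            1
            for i in range(d)
            for j in range(i + 1, d)
            if neigh[j] in adj[neigh[i]]
        )
        total += 2.0 * links / (d * (d - 1))
    return total / n


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
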