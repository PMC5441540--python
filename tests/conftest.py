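"""Shared fixtures and independent oracles.

The reachability oracle here is deliberately primitive: boolean adjacency
matrices and transitive closure by repeated squaring. It shares no code
path with the package (which uses networkx components and an iterative
Tarjan fast path), so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from speechdisorg.synthetic import GeneratorConfig, generate_cohort


def closure_lcc_lsc(tokens) -> tuple[int, int]:
    """Brute-force LCC/LSC of a token trajectory via transitive closure."""
    words = sorted(set(tokens))
    idx = {w: i for i, w in enumerate(words)}
    n = len(words)
    A = np.zeros((n, n), dtype=bool)
    for u, v in zip(tokens[:-1], tokens[1:]):
        A[idx[u], idx[v]] = True
    # reach = I + A + A^2 + ... via repeated squaring of (I | A)
    R = A | np.eye(n, dtype=bool)
    while True:
        R2 = R @ R
        if (R2 == R).all():
            break
        R = R2
    mutual = R & R.T
    lsc = max(int(mutual[i].sum()) for i in range(n))
    U = A | A.T | np.eye(n, dtype=bool)
    W = U
    while True:
        W2 = W @ W
        if (W2 == W).all():
            break
        W = W2
    lcc = max(int(W[i].sum()) for i in range(n))
    return lcc, lsc


def random_token_sequence(rng: np.random.Generator, max_distinct: int = 12) -> list[str]:
    """A random word sequence with a bounded distinct vocabulary."""
    k = int(rng.integers(1, max_distinct + 1))
    n = int(rng.integers(1, 40))
    return [f"w{i}" for i in rng.integers(0, k, size=n)]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at reduced surrogate count (test speed)."""
    cfg = GeneratorConfig(n_surrogates=200, seed=101)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth
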