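"""Similarity of a report to randomly ordered speech with the same words.

Each report is compared against surrogate reports obtained by uniformly
permuting its token sequence (1000 surrogates by default) and rebuilding
the trajectory graph. Every surrogate therefore preserves the node set and
the number of edges E exactly — the null controls verbosity by
construction and asks only whether the *ordering* of the words carries
structure. The z-scores

    LCCz = (LCC - LCCmr) / LCCsdr,    LSCz = (LSC - LSCmr) / LSCsdr

locate the original graph inside the surrogate distributions (``mr``/
``sdr`` = mean / standard deviation over the surrogates; population
formula, divisor n). A report is *random-like* when the designated z-score
falls within a closed +/-2 band: its connectedness is indistinguishable
from its own shuffles — the structural proxy for disorganized speech.

Note that a trajectory graph built from one contiguous sequence is always
weakly connected, so LCC is invariant under sequence permutation: LCCsdr
is exactly 0 and LCCz resolves to 0 through the degenerate-variance rule.
All discriminative signal under this null lives in LSCz.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import ConnectednessAttributes, encode_tokens, max_scc_size_codes
from .stats import TestResult, chi_square_2x2

__all__ = [
    "SurrogateDistribution",
    "RandomnessScores",
    "make_surrogates",
    "z_scores",
    "classify_random_like",
    "random_like_rate",
]

logger = logging.getLogger(__name__)

DEFAULT_N_SURROGATES = 1000
RANDOM_LIKE_K_SD = 2.0


class SurrogateMismatchError(ValueError):
    """Original attributes and surrogate distribution disagree on node set or E."""


@dataclass
class SurrogateDistribution:
    """Empirical LCC/LSC distributions over shuffled surrogates of one report."""

    n_surrogates: int
    lcc_values: np.ndarray
    lsc_values: np.ndarray
    n_nodes: int
    n_edges: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.lcc_values = np.asarray(self.lcc_values, dtype=np.int64)
        self.lsc_values = np.asarray(self.lsc_values, dtype=np.int64)
        if len(self.lcc_values) != self.n_surrogates or len(self.lsc_values) != self.n_surrogates:
            raise ValueError("value sequences must have length n_surrogates")

    @property
    def LCCmr(self) -> float:
        return float(self.lcc_values.mean())

    @property
    def LSCmr(self) -> float:
        return float(self.lsc_values.mean())

    @property
    def LCCsdr(self) -> float:
        return float(self.lcc_values.std())  # population formula (divisor n)

    @property
    def LSCsdr(self) -> float:
        return float(self.lsc_values.std())


@dataclass(frozen=True)
class RandomnessScores:
    """z-scores of a report against its surrogate distribution."""

    LCCz: float
    LSCz: float
    random_like: bool


def make_surrogates(
    tokens,
    n: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.Generator | None = None,
    *,
    keep_sequences: bool = False,
):
    """Build ``n`` shuffled surrogates of a token sequence.

    Each surrogate is a uniform random permutation of the token sequence
    rebuilt into a trajectory graph; its LCC and LSC are recorded. The node
    set and edge count of every surrogate equal the original's.
    Reproducible given ``seed`` (an int or a numpy Generator).

    With ``keep_sequences=True`` returns ``(distribution, sequences)``
    where ``sequences`` holds every shuffled integer-coded token sequence
    (useful for auditing the conservation property).
    """
    if len(tokens) < 2:
        raise ValueError("need at least 2 tokens to build surrogates")
    if n < 2:
        raise ValueError("need n >= 2 surrogates (no standard deviation otherwise)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codes = encode_tokens(tokens)
    n_nodes = int(codes.max()) + 1
    # A contiguous trajectory is weakly connected: LCC = number of distinct
    # words for every permutation.
    lcc = np.full(n, n_nodes, dtype=np.int64)
    lsc = np.empty(n, dtype=np.int64)
    sequences: list[np.ndarray] = []
    for i in range(n):
        perm = rng.permutation(codes)
        lsc[i] = max_scc_size_codes(perm.tolist())
        if keep_sequences:
            sequences.append(perm)
    dist = SurrogateDistribution(
        n_surrogates=n,
        lcc_values=lcc,
        lsc_values=lsc,
        n_nodes=n_nodes,
        n_edges=len(tokens) - 1,
        rng_seed=seed if isinstance(seed, int) else None,
    )
    if keep_sequences:
        return dist, sequences
    return dist


def _z(value: float, mean: float, sd: float, name: str) -> float:
    if sd > 0:
        return (value - mean) / sd
    if value == mean:
        return 0.0
    warnings.warn(
        f"{name}: zero surrogate variance but original ({value}) differs from "
        f"the degenerate value ({mean}); reporting signed infinity",
        RuntimeWarning,
        stacklevel=3,
    )
    return math.copysign(math.inf, value - mean)


def z_scores(
    original: ConnectednessAttributes,
    dist: SurrogateDistribution,
    *,
    attribute: str = "LSCz",
    k_sd: float = RANDOM_LIKE_K_SD,
) -> RandomnessScores:
    """z-scores of the original attributes against the surrogate distribution.

    When the surrogate standard deviation is zero and the original equals
    the degenerate value, z := 0 (an all-distinct-word report is
    indistinguishable from its own shuffles and is classified random-like);
    when it differs, z is a signed infinity and the report is never
    random-like.
    """
    if original.E != dist.n_edges:
        raise SurrogateMismatchError(
            f"edge count mismatch: original E={original.E}, surrogates E={dist.n_edges}"
        )
    # A contiguous report's graph is weakly connected, so LCC equals its
    # distinct-word count; a mismatch means a different token multiset.
    if original.LCC != dist.n_nodes:
        raise SurrogateMismatchError(
            f"node count mismatch: original has {original.LCC} nodes, "
            f"surrogates have {dist.n_nodes}"
        )
    lccz = _z(original.LCC, dist.LCCmr, dist.LCCsdr, "LCCz")
    lscz = _z(original.LSC, dist.LSCmr, dist.LSCsdr, "LSCz")
    return RandomnessScores(
        LCCz=lccz,
        LSCz=lscz,
        random_like=classify_random_like(lccz, lscz, attribute=attribute, k_sd=k_sd),
    )


def classify_random_like(
    lccz: float,
    lscz: float,
    *,
    attribute: str = "LSCz",
    k_sd: float = RANDOM_LIKE_K_SD,
) -> bool:
    """True iff the designated z-score(s) lie in the closed band [-k_sd, k_sd].

    The band is closed (z = -2 exactly is random-like). ``attribute`` is
    ``"LSCz"`` (default), ``"LCCz"``, or ``"both"`` (both must be inside).
    Infinite (sentinel) z-scores are never random-like.
    """
    if attribute == "LSCz":
        zs = (lscz,)
    elif attribute == "LCCz":
        zs = (lccz,)
    elif attribute == "both":
        zs = (lccz, lscz)
    else:
        raise ValueError("attribute must be 'LSCz', 'LCCz' or 'both'")
    return all(math.isfinite(z) and abs(z) <= k_sd for z in zs)


def random_like_rate(
    groups: dict[str, list[bool]],
) -> tuple[dict[str, float], TestResult | None]:
    """Per-group proportion of random-like reports, with a 2x2 chi-square.

    With exactly two groups the proportions are compared by Pearson
    chi-square on the (random-like x group) contingency table; with one
    group the test is skipped with a warning; with more than two groups the
    proportions are returned and the test is left to the caller (pairwise
    or pooled comparisons are a modelling choice).
    """
    if not groups:
        raise ValueError("no groups given")
    for name, flags in groups.items():
        if len(flags) == 0:
            raise ValueError(f"group {name!r} is empty")
    props = {name: float(np.mean(flags)) for name, flags in groups.items()}
    if len(groups) == 1:
        warnings.warn("single group: chi-square comparison skipped", UserWarning)
        return props, None
    if len(groups) != 2:
        return props, None
    (fa, fb) = groups.values()
    table = np.array(
        [[sum(fa), len(fa) - sum(fa)], [sum(fb), len(fb) - sum(fb)]], dtype=np.int64
    )
    try:
        test = chi_square_2x2(table)
    except ValueError:
        warnings.warn("degenerate contingency table: chi-square skipped", UserWarning)
        test = None
    return props, test
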