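"""Nonparametric statistics battery for group comparisons and correlations.

The connectedness attributes are not normally distributed, so group
contrasts use rank-based tests (Kruskal-Wallis across groups, two-sided
Wilcoxon rank-sum pairwise), categorical contrasts use Pearson chi-square,
and attribute-symptom relations use Spearman correlations, optionally
partialled for confounders (age, education, medication dose, word rate).
Multiplicity is handled by Bonferroni thresholds: raw p-values are
compared against alpha / m rather than being inflated.

Most tests delegate to scipy.stats; this module fixes the conventions
(tie corrections, exact small-sample paths, mean-centered Levene) and
returns a uniform :class:`TestResult`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "wilcoxon_ranksum",
    "chi_square_2x2",
    "spearman",
    "partial_spearman",
    "bonferroni",
    "round_alpha",
    "distribution_checks",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    corrected_alpha: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def significant(self, alpha: float = 0.05) -> bool:
        """Compare raw p against the Bonferroni-corrected threshold if set."""
        threshold = self.corrected_alpha if self.corrected_alpha is not None else alpha
        return self.p_value < threshold

    def with_correction(self, alpha: float, m: int) -> "TestResult":
        return TestResult(self.statistic, self.p_value, self.n, self.method,
                          corrected_alpha=bonferroni(alpha, m))


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p, df = #groups - 1."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    ns = tuple(len(g) for g in arrays)
    if np.all(pooled == pooled[0]):
        # all observations identical: H = 0 by convention, p = 1
        return TestResult(0.0, 1.0, ns, "kruskal-wallis")
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), ns, "kruskal-wallis")


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p for small samples without ties, normal approximation with tie
    correction otherwise (scipy's ``method="auto"``). The statistic is the
    rank sum W of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    w = float(u) + a.size * (a.size + 1) / 2.0  # U -> rank-sum of sample a
    return TestResult(w, float(min(p, 1.0)), (a.size, b.size), "wilcoxon-ranksum")


def chi_square_2x2(table, continuity: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table (df = 1).

    ``continuity=True`` applies the Yates correction (off by default,
    matching the common numeric-environment default). All four marginals
    must be positive.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square undefined")
    stat, p, _, _ = sps.chi2_contingency(t, correction=continuity)
    return TestResult(float(stat), float(p), (int(t.sum()),), "chi-square-2x2")


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact p by enumeration of all rank permutations (no ties)."""
    ranks = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1) / 6.0
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        d2 = float(np.sum((ranks - ranks[list(perm)]) ** 2))
        r = 1.0 - d2 / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with tie handling.

    p is exact (full enumeration) for n <= 9 without ties, otherwise by the
    t approximation with df = n - 2. Constant input makes Rho undefined and
    raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman Rho undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    n = x.size
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and no_ties:
        p = _spearman_exact_p(rho, n)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(rho, float(min(p, 1.0)), (n,), "spearman")


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates=None,
) -> TestResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks on ties); the Pearson
    partial correlation of rank-x and rank-y given the rank covariates is
    computed by residualizing both on [1, rank covariates]; p via t with
    df = n - 2 - #covariates. With no covariates this reduces exactly to
    :func:`spearman`. Several non-equivalent definitions of "partial
    Spearman" exist; this rank-then-partial-Pearson form is the one used
    throughout the package.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if x.size != y.size or cov.shape[0] != x.size:
        raise ValueError("x, y and covariates must have equal length")
    if cov.shape[1] == 0:
        return spearman(x, y)
    k = cov.shape[1]
    n = x.size
    if n < k + 4:
        raise ValueError("too few observations for the requested covariates")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rc = np.column_stack([np.ones(n)] + [sps.rankdata(cov[:, j]) for j in range(k)])
    if np.linalg.matrix_rank(rc) < rc.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    ex = rx - rc @ np.linalg.lstsq(rc, rx, rcond=None)[0]
    ey = ry - rc @ np.linalg.lstsq(rc, ry, rcond=None)[0]
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    if denom == 0:
        raise ValueError("residual variance is zero: partial Rho undefined")
    rho = float(ex @ ey) / denom
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df=df)
    return TestResult(rho, float(min(p, 1.0)), (n,), "partial-spearman")


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected threshold alpha / m."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def round_alpha(threshold: float, decimals: int = 4) -> float:
    """Half-up rounding for reporting thresholds (0.00625 -> 0.0063)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(threshold)).quantize(q, rounding=ROUND_HALF_UP))


def distribution_checks(
    groups: dict[str, Sequence[float]],
    *,
    levene_center: str = "mean",
    lilliefors: bool = False,
) -> dict[str, object]:
    """Normality and variance-homogeneity checks preceding test selection.

    Per group, a one-sample Kolmogorov-Smirnov test against a normal with
    the sample mean/sd (approximate because parameters are estimated;
    ``lilliefors=True`` applies the Lilliefors correction instead). Across
    groups, the Levene test (mean-centered by default; ``levene_center=
    "median"`` gives Brown-Forsythe). Groups smaller than 3 are skipped
    with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for variance homogeneity")
    normality: dict[str, TestResult] = {}
    usable = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            warnings.warn(f"group {name!r} has n={v.size} < 3: skipped", UserWarning)
            continue
        usable[name] = v
        if lilliefors:
            from statsmodels.stats.diagnostic import lilliefors as _lf

            stat, p = _lf(v, dist="norm")
            normality[name] = TestResult(float(stat), float(p), (v.size,), "lilliefors")
        else:
            sd = v.std(ddof=1)
            if sd == 0:
                normality[name] = TestResult(1.0, 0.0, (v.size,), "ks-normal")
                continue
            stat, p = sps.kstest(v, "norm", args=(v.mean(), sd))
            normality[name] = TestResult(float(stat), float(p), (v.size,), "ks-normal")
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable groups after size filtering")
    vals = list(usable.values())
    if all(np.all(v == vals[0][0]) for v in vals):
        lev = TestResult(0.0, 1.0, tuple(len(v) for v in vals), f"levene-{levene_center}")
    else:
        stat, p = sps.levene(*vals, center=levene_center)
        lev = TestResult(float(stat), float(p), tuple(len(v) for v in vals),
                         f"levene-{levene_center}")
    return {"normality": normality, "variance_homogeneity": lev}
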