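"""The Disorganization Index: a symptom-anchored affine combination of
connectedness attributes.

The index is built by ordinary least squares of the negative-symptom total
(PANSS negative subscale, range 7-49) on a candidate set of connectedness
attributes, after a Belsley-style collinearity pruning step: attribute
columns (plus the intercept) are scaled to unit length, the condition
indices of the scaled design are computed from its singular values, and
whenever any condition index exceeds 10 the variable with the largest
variance-decomposition proportion on an offending component is dropped;
the loop repeats until the design is non-collinear. Higher index values
mean more disorganized speech (the surviving coefficients anti-correlate
the index with connectedness).

The module follows the statsmodels model/results idiom:

>>> model = DisorganizationIndex.from_cohort(cohort, ["LSC_negative", "LSCz_negative"])
>>> res = model.fit()
>>> res.params, res.rsquared, res.observed_power
>>> print(res.summary())

Reference coefficient sets estimated on clinical cohorts (a recent-onset
psychosis sample and a chronic validation sample) ship with the package in
:data:`REFERENCE_INDICES` and can be applied to new attribute tables
without refitting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special
from scipy import stats as sps

from .stats import spearman

__all__ = [
    "IndexModel",
    "CollinearityReport",
    "DisorganizationIndex",
    "DisorgIndexResults",
    "REFERENCE_INDICES",
    "apply_index",
    "collinearity_prune",
    "fit_index",
    "observed_power",
    "sample_size",
    "AllVariablesPrunedError",
]

CONDITION_THRESHOLD = 10.0


class AllVariablesPrunedError(RuntimeError):
    """Every candidate was dropped by the collinearity loop."""


# ---------------------------------------------------------------------------
# Index model container
# ---------------------------------------------------------------------------

@dataclass
class IndexModel:
    """Affine index: score = intercept + sum(coefficient * attribute).

    ``provenance`` is "reference" for the packaged clinically estimated
    coefficient sets and "fitted" for models produced by
    :class:`DisorganizationIndex`.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    source_reports: tuple[str, ...] = ()
    provenance: str = "fitted"
    fit_stats: dict | None = None

    def score(self, attributes: Mapping[str, float]) -> float:
        """Evaluate the index on one attribute vector.

        Raises ``KeyError`` naming the first missing attribute, supporting
        the fallback of switching to a negative-image-only index when a
        subject cannot recall a dream.
        """
        total = self.intercept
        for name, coef in self.coefficients.items():
            if name not in attributes:
                raise KeyError(
                    f"attribute {name!r} required by index {self.name!r} is missing"
                )
            total += coef * float(attributes[name])
        return total

    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Evaluate the index on every row of an attribute table."""
        missing = [c for c in self.coefficients if c not in table.columns]
        if missing:
            raise KeyError(f"attribute columns missing from table: {missing}")
        out = pd.Series(self.intercept, index=table.index, dtype=float)
        for name, coef in self.coefficients.items():
            out += coef * table[name].astype(float)
        out.name = f"disorganization_index_{self.name}"
        return out

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "source_reports": list(self.source_reports),
            "provenance": self.provenance,
            "fit_stats": self.fit_stats,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IndexModel":
        d = json.loads(text)
        return cls(
            name=d["name"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            source_reports=tuple(d.get("source_reports", ())),
            provenance=d.get("provenance", "fitted"),
            fit_stats=d.get("fit_stats"),
        )


def _load_reference_indices() -> dict[str, IndexModel]:
    out = {}
    pkg = resources.files("speechdisorg") / "data"
    for entry in sorted(pkg.iterdir()):
        if entry.name.startswith("index_") and entry.name.endswith(".json"):
            model = IndexModel.from_json(entry.read_text(encoding="utf-8"))
            out[model.name] = model
    return out


#: Packaged reference indices: "negative_dream", "negative", "dream",
#: "dream_chronic". Immutable constants; refitting produces new objects.
REFERENCE_INDICES: dict[str, IndexModel] = _load_reference_indices()


def apply_index(model: IndexModel, attributes: Mapping[str, float]) -> float:
    """Functional alias for :meth:`IndexModel.score`."""
    return model.score(attributes)


# ---------------------------------------------------------------------------
# Collinearity diagnosis
# ---------------------------------------------------------------------------

@dataclass
class CollinearityIteration:
    condition_indices: np.ndarray
    variance_decomposition: pd.DataFrame  # rows = components, cols = variables
    dropped_variable: str | None


@dataclass
class CollinearityReport:
    threshold: float
    iterations: list[CollinearityIteration] = field(default_factory=list)

    @property
    def dropped(self) -> list[str]:
        return [it.dropped_variable for it in self.iterations if it.dropped_variable]

    @property
    def final_condition_index(self) -> float:
        return float(self.iterations[-1].condition_indices.max())


def _belsley(design: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Condition indices and variance-decomposition proportions.

    Columns are scaled to unit length (intercept included, per the standard
    diagnostic); the SVD of the scaled design gives condition indices
    s_max / s_j and, per variable, the proportion of its coefficient
    variance attributable to each singular component.
    """
    X = design.to_numpy(dtype=float)
    norms = np.sqrt((X ** 2).sum(axis=0))
    if np.any(norms == 0):
        zero = design.columns[norms == 0][0]
        raise ValueError(f"column {zero!r} is identically zero")
    Xs = X / norms
    _, s, vt = np.linalg.svd(Xs, full_matrices=False)
    s_safe = np.where(s > 0, s, 1e-300)
    ci = s.max() / s_safe
    phi = (vt.T ** 2) / (s_safe ** 2)  # variables x components
    pi = phi / phi.sum(axis=1, keepdims=True)
    vdp = pd.DataFrame(pi.T, columns=design.columns)  # components x variables
    return ci, vdp


def collinearity_prune(
    design: pd.DataFrame,
    *,
    threshold: float = CONDITION_THRESHOLD,
    intercept_col: str = "const",
) -> tuple[list[str], CollinearityReport]:
    """Iteratively drop collinear variables until all condition indices <= threshold.

    At each iteration the variable with the largest variance-decomposition
    proportion on any component whose condition index exceeds the
    threshold is dropped (ties broken by the larger proportion summed over
    all offending components, then by input order). The intercept column is
    never dropped. Raises :class:`AllVariablesPrunedError` if no
    non-intercept variable survives.
    """
    if intercept_col not in design.columns:
        raise ValueError(f"design must contain the intercept column {intercept_col!r}")
    if design.shape[1] < 2:
        raise ValueError("need at least one candidate variable besides the intercept")
    current = design.copy()
    report = CollinearityReport(threshold=threshold)
    while True:
        ci, vdp = _belsley(current)
        offending = np.where(ci > threshold)[0]
        droppable = [c for c in current.columns if c != intercept_col]
        if offending.size == 0 or not droppable:
            report.iterations.append(CollinearityIteration(ci, vdp, None))
            if offending.size > 0:
                raise AllVariablesPrunedError(
                    "design remains collinear with only the intercept left"
                )
            break
        sub = vdp.iloc[offending][droppable]
        peak = sub.max(axis=0)
        best = peak.max()
        tied = [c for c in droppable if peak[c] >= best - 1e-12]
        if len(tied) > 1:
            sums = sub[tied].sum(axis=0)
            tied = [c for c in tied if sums[c] >= sums.max() - 1e-12]
        victim = tied[0]  # remaining ties: input order
        report.iterations.append(CollinearityIteration(ci, vdp, victim))
        current = current.drop(columns=[victim])
        if current.shape[1] == 1:
            raise AllVariablesPrunedError(
                "all candidate variables were dropped by the collinearity loop"
            )
    kept = [c for c in current.columns if c != intercept_col]
    return kept, report


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------

class DisorganizationIndex:
    """OLS index model for symptom scores on connectedness attributes.

    Parameters
    ----------
    endog : array-like
        Symptom scores (e.g. PANSS negative totals), patients only.
    exog : DataFrame
        Candidate attribute columns (no intercept; one is added).
    prune : bool
        Run the collinearity loop before fitting (default True).
    condition_threshold : float
        Condition-index threshold for the pruning loop.
    """

    def __init__(
        self,
        endog,
        exog: pd.DataFrame,
        *,
        prune: bool = True,
        condition_threshold: float = CONDITION_THRESHOLD,
        name: str = "fitted",
        source_reports: Sequence[str] = (),
    ) -> None:
        endog = pd.Series(np.asarray(endog, dtype=float), name="symptom_score")
        exog = pd.DataFrame(exog).astype(float).reset_index(drop=True)
        if len(endog) != len(exog):
            raise ValueError("endog and exog lengths differ")
        mask = endog.notna() & exog.notna().all(axis=1)
        self.endog = endog[mask.to_numpy()].reset_index(drop=True)
        self.exog = exog[mask.to_numpy()].reset_index(drop=True)
        self.prune = prune
        self.condition_threshold = condition_threshold
        self.name = name
        self.source_reports = tuple(source_reports)
        if self.exog.shape[1] < 1:
            raise ValueError("need at least one candidate attribute")
        if len(self.endog) < self.exog.shape[1] + 2:
            raise ValueError(
                f"n={len(self.endog)} complete cases is too small for "
                f"{self.exog.shape[1]} candidates (need >= candidates + 2)"
            )

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        candidate_attributes: Sequence[str],
        symptom_score: str = "panss_negative",
        **kwargs,
    ) -> "DisorganizationIndex":
        """Build from a per-subject cohort table (complete-case on the columns used).

        Rows without a symptom score (e.g. non-clinical controls) are
        excluded automatically by the complete-case mask.
        """
        missing = [c for c in [*candidate_attributes, symptom_score] if c not in cohort.columns]
        if missing:
            raise KeyError(f"cohort table lacks columns: {missing}")
        return cls(
            cohort[symptom_score],
            cohort[list(candidate_attributes)],
            **kwargs,
        )

    def fit(self) -> "DisorgIndexResults":
        design = sm.add_constant(self.exog, prepend=True, has_constant="add")
        if self.prune:
            try:
                kept, report = collinearity_prune(
                    design, threshold=self.condition_threshold
                )
            except AllVariablesPrunedError as exc:
                suggestion = self._best_single()
                raise AllVariablesPrunedError(
                    f"{exc}; consider the single best-correlated attribute "
                    f"{suggestion!r}"
                ) from exc
        else:
            kept = list(self.exog.columns)
            ci, vdp = _belsley(design)
            report = CollinearityReport(threshold=self.condition_threshold)
            report.iterations.append(CollinearityIteration(ci, vdp, None))
        ols = sm.OLS(self.endog, design[["const", *kept]]).fit()
        return DisorgIndexResults(self, ols, kept, report)

    def _best_single(self) -> str:
        best, best_rho = None, -1.0
        for c in self.exog.columns:
            try:
                rho = abs(spearman(self.exog[c], self.endog).statistic)
            except ValueError:
                continue
            if rho > best_rho:
                best, best_rho = c, rho
        return best if best is not None else "<none>"


class DisorgIndexResults:
    """Fit results: coefficients, uncertainty, diagnostics, and the index itself."""

    def __init__(self, model, ols_results, kept, collinearity):
        self.model = model
        self._ols = ols_results
        self.kept: list[str] = list(kept)
        self.collinearity: CollinearityReport = collinearity

    # -- statsmodels-style accessors -------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._ols.params

    @property
    def bse(self) -> pd.Series:
        return self._ols.bse

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    @property
    def f_pvalue(self) -> float:
        return float(self._ols.f_pvalue)

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    @property
    def df_model(self) -> int:
        return int(self._ols.df_model)

    @property
    def observed_power(self) -> float:
        return observed_power(self.rsquared, self.nobs, self.df_model)

    def predict(self, table: pd.DataFrame) -> pd.Series:
        return self.to_model().predict(table)

    def to_model(self) -> IndexModel:
        coefs = {k: float(self.params[k]) for k in self.kept}
        return IndexModel(
            name=self.model.name,
            intercept=float(self.params["const"]),
            coefficients=coefs,
            source_reports=self.model.source_reports,
            provenance="fitted",
            fit_stats={
                "r_squared": self.rsquared,
                "p_value": self.f_pvalue,
                "observed_power": self.observed_power,
                "n": self.nobs,
                "dropped": self.collinearity.dropped,
            },
        )

    def summary(self) -> str:
        lines = [
            f"Disorganization Index ({self.model.name})",
            "=" * 46,
            f"n (complete cases)      {self.nobs}",
            f"candidates              {list(self.model.exog.columns)}",
            f"dropped (collinearity)  {self.collinearity.dropped or 'none'}",
            f"final condition index   {self.collinearity.final_condition_index:.2f}",
            f"R-squared               {self.rsquared:.4f}",
            f"F-test p-value          {self.f_pvalue:.4g}",
            f"observed power          {self.observed_power:.4f}",
            "-" * 46,
            f"{'term':<16}{'coef':>10}{'se':>10}{'p':>10}",
        ]
        for term in self.params.index:
            lines.append(
                f"{term:<16}{self.params[term]:>10.4f}{self.bse[term]:>10.4f}"
                f"{self._ols.pvalues[term]:>10.4f}"
            )
        return "\n".join(lines)


def fit_index(
    cohort: pd.DataFrame,
    candidate_attributes: Sequence[str],
    symptom_score: str = "panss_negative",
    **kwargs,
) -> IndexModel:
    """One-call convenience: build, fit, and return the :class:`IndexModel`."""
    return (
        DisorganizationIndex.from_cohort(cohort, candidate_attributes, symptom_score, **kwargs)
        .fit()
        .to_model()
    )


# ---------------------------------------------------------------------------
# Power and planning
# ---------------------------------------------------------------------------

def observed_power(R2: float, n: int, k: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the overall regression F-test.

    Effect size f^2 = R^2 / (1 - R^2); noncentrality lambda = f^2 * n;
    power = P(noncentral F(k, n-k-1, lambda) > F_crit(alpha)). The
    lambda = f^2 * n convention is used (the f^2 * (n-k-1) alternative
    differs negligibly at these sizes).
    """
    if not (0.0 <= R2 <= 1.0):
        raise ValueError("R2 must be in [0, 1]")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    if R2 >= 1.0:
        warnings.warn("R2 = 1: observed power reported as 1", RuntimeWarning)
        return 1.0
    df1, df2 = k, n - k - 1
    lam = (R2 / (1.0 - R2)) * n
    crit = sps.f.isf(alpha, df1, df2)
    if lam == 0.0:
        return float(alpha)  # null effect: rejection rate is the test size
    # scipy.special.ncfdtr is numerically reliable where stats.ncf.sf is not
    return float(1.0 - special.ncfdtr(df1, df2, lam, crit))


def sample_size(Z: float, P: float, d: float) -> int:
    """Prevalence-based sample-size formula N = Z^2 P (1 - P) / d^2, rounded up.

    Returns at least 1.
    """
    if not (0.0 < P < 1.0):
        raise ValueError("P must be in (0, 1)")
    if d <= 0:
        raise ValueError("d must be positive")
    return max(1, math.ceil(Z * Z * P * (1.0 - P) / (d * d)))
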