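"""Disorganization Index: reference equations, collinearity pruning, fitting,
observed power, and the sample-size formula."""

import numpy as np
import pandas as pd
import pytest

from speechdisorg.index import (
    REFERENCE_INDICES,
    AllVariablesPrunedError,
    DisorganizationIndex,
    IndexModel,
    apply_index,
    collinearity_prune,
    fit_index,
    observed_power,
    sample_size,
)


class TestReferenceIndices:
    def test_all_four_reference_models_packaged(self):
        assert set(REFERENCE_INDICES) == {
            "negative_dream", "negative", "dream", "dream_chronic",
        }
        for m in REFERENCE_INDICES.values():
            assert m.provenance == "reference"

    @pytest.mark.parametrize(
        "name,attrs,expected",
        [
            ("dream", {"LCC": 0, "LSC": 0}, 27.82),
            ("dream", {"LCC": 10, "LSC": 5}, 27.82 - 3.2 - 0.06),
            ("negative_dream",
             {"LSC_negative": 0, "LSCz_negative": 0, "LCC_dream": 0}, 30.78),
            ("negative_dream",
             {"LSC_negative": 10, "LSCz_negative": -2, "LCC_dream": 20},
             30.78 + 0.15 + 4.66 - 4.0),
            ("negative", {"LCC": 0, "LSC": 0, "LSCz": 0}, 31.43),
            ("negative", {"LCC": 30, "LSC": 4, "LSCz": 1.5},
             31.43 - 9.0 + 0.32 - 3.18),
            ("dream_chronic", {"E": 0, "LSC": 0}, 93.91),
            ("dream_chronic", {"E": 29.0, "LSC": 10.0},
             93.91 - 3.08 * 29 + 0.21 * 10),
        ],
    )
    def test_printed_equations_evaluate_exactly(self, name, attrs, expected):
        assert apply_index(REFERENCE_INDICES[name], attrs) == pytest.approx(
            expected, abs=1e-9
        )

    def test_missing_attribute_error_names_it(self):
        with pytest.raises(KeyError, match="LCC_dream"):
            REFERENCE_INDICES["negative_dream"].score(
                {"LSC_negative": 1, "LSCz_negative": 0}
            )

    def test_affine_in_the_attribute_vector(self, rng):
        m = REFERENCE_INDICES["negative"]
        for _ in range(20):
            a = {k: rng.normal() for k in m.coefficients}
            b = {k: rng.normal() for k in m.coefficients}
            lam = rng.uniform()
            mix = {k: lam * a[k] + (1 - lam) * b[k] for k in a}
            assert m.score(mix) == pytest.approx(
                lam * m.score(a) + (1 - lam) * m.score(b)
            )

    def test_json_round_trip(self):
        m = REFERENCE_INDICES["negative_dream"]
        back = IndexModel.from_json(m.to_json())
        assert back.intercept == m.intercept
        assert back.coefficients == m.coefficients


class TestCollinearityPrune:
    def test_orthonormal_columns_survive_in_one_iteration(self, rng):
        n = 40
        q, _ = np.linalg.qr(rng.normal(size=(n, 2)))
        design = pd.DataFrame(
            {"const": np.ones(n) / np.sqrt(n), "x1": q[:, 0], "x2": q[:, 1]}
        )
        kept, report = collinearity_prune(design)
        assert kept == ["x1", "x2"]
        assert len(report.iterations) == 1
        assert report.final_condition_index <= 10

    def test_duplicated_column_dropped_first(self, rng):
        n = 50
        x = rng.normal(size=n)
        design = pd.DataFrame(
            {"const": 1.0, "x1": x, "x2": x.copy(), "y": rng.normal(size=n)}
        )
        kept, report = collinearity_prune(design)
        assert report.iterations[0].dropped_variable in ("x1", "x2")
        assert len(kept) == 2 and "y" in kept

    def test_near_duplicate_drop_follows_the_variance_decomposition_rule(self, rng):
        n = 60
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(scale=1e-6, size=n)
        design = pd.DataFrame(
            {"const": 1.0, "x1": x1, "x2": x2, "z": rng.normal(size=n)}
        )
        kept, report = collinearity_prune(design)
        first = report.iterations[0]
        # the stated rule: the victim has the largest variance-decomposition
        # proportion on a component with condition index > 10
        offending = first.condition_indices > 10
        sub = first.variance_decomposition.loc[offending, ["x1", "x2", "z"]]
        assert first.dropped_variable == sub.max(axis=0).idxmax()
        assert len([c for c in kept if c in ("x1", "x2")]) == 1
        assert "z" in kept

    def test_intercept_never_dropped_and_total_failure_raises(self):
        n = 30
        design = pd.DataFrame({"const": 1.0, "x1": np.full(n, 2.0)})
        with pytest.raises((AllVariablesPrunedError, ValueError)):
            collinearity_prune(design)


class TestFitIndex:
    def test_noiseless_recovery_is_exact_after_pruning_a_collinear_column(self, rng):
        n = 40
        lsc = rng.normal(10, 4, n)
        lscz = rng.normal(0, 2, n)
        y = 27.82 - 0.32 * lsc - 0.012 * lscz
        cohort = pd.DataFrame(
            {
                "LSC": lsc,
                "LSCz": lscz,
                "LSC_copy": lsc.copy(),  # deliberately collinear
                "panss_negative": y,
            }
        )
        res = DisorganizationIndex.from_cohort(
            cohort, ["LSC", "LSCz", "LSC_copy"]
        ).fit()
        model = res.to_model()
        assert set(model.coefficients) == {"LSC", "LSCz"} or set(
            model.coefficients
        ) == {"LSC_copy", "LSCz"}
        kept_lsc = "LSC" if "LSC" in model.coefficients else "LSC_copy"
        assert model.intercept == pytest.approx(27.82, rel=1e-8)
        assert model.coefficients[kept_lsc] == pytest.approx(-0.32, rel=1e-8)
        assert model.coefficients["LSCz"] == pytest.approx(-0.012, rel=1e-8)
        assert res.rsquared == pytest.approx(1.0)

    def test_controls_without_scores_are_excluded_as_complete_cases(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = 5 + 2 * x
        y[:10] = np.nan  # controls
        cohort = pd.DataFrame({"a": x, "panss_negative": y})
        res = DisorganizationIndex.from_cohort(cohort, ["a"]).fit()
        assert res.nobs == 20
        assert res.params["a"] == pytest.approx(2.0)

    def test_too_small_sample_rejected(self):
        cohort = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0],
                               "panss_negative": [3.0, 4.0]})
        with pytest.raises(ValueError, match="too small"):
            DisorganizationIndex.from_cohort(cohort, ["a", "b"])

    def test_fit_index_convenience_returns_a_scoring_model(self, rng):
        n = 25
        x = rng.normal(10, 3, n)
        cohort = pd.DataFrame({"LSC": x, "panss_negative": 30 - x})
        model = fit_index(cohort, ["LSC"])
        assert model.provenance == "fitted"
        assert model.score({"LSC": 10.0}) == pytest.approx(20.0, abs=1e-8)
        assert model.fit_stats["r_squared"] == pytest.approx(1.0)

    def test_summary_mentions_diagnostics(self, small_cohort):
        cohort, _ = small_cohort
        res = DisorganizationIndex.from_cohort(
            cohort, ["LSC_negative", "LSCz_negative"]
        ).fit()
        text = res.summary()
        assert "condition index" in text and "observed power" in text
        assert res.nobs == 21  # patients only


class TestObservedPower:
    def test_null_effect_power_is_the_alpha_level(self):
        assert observed_power(0.0, 50, 3) == pytest.approx(0.05)

    def test_strong_fit_has_power_near_one(self):
        # R^2 = 0.88 with n = 15, k = 3 predictors
        assert observed_power(0.88, 15, 3) > 0.99

    def test_deterministic_and_monotone_in_r2(self):
        p1 = observed_power(0.3, 30, 3)
        assert p1 == observed_power(0.3, 30, 3)
        assert p1 < observed_power(0.5, 30, 3)

    def test_perfect_fit_warns_and_returns_one(self):
        with pytest.warns(RuntimeWarning):
            assert observed_power(1.0, 20, 2) == 1.0

    def test_agrees_with_monte_carlo(self, rng):
        R2, n, k = 0.4, 25, 2
        lam = R2 / (1 - R2) * n
        from scipy import stats as sps

        crit = sps.f.isf(0.05, k, n - k - 1)
        draws = (rng.noncentral_chisquare(k, lam, 200_000) / k) / (
            rng.chisquare(n - k - 1, 200_000) / (n - k - 1)
        )
        assert observed_power(R2, n, k) == pytest.approx(
            float((draws > crit).mean()), abs=0.01
        )


class TestSampleSize:
    @pytest.mark.parametrize(
        "Z,P,d,expected",
        [
            (1.96, 0.0057, 0.05, 9),  # prevalence-based planning value
            (1.96, 0.5, 0.05, 385),  # textbook worst case
            (1.96, 0.5, 1e9, 1),  # vanishing precision term floors at 1
        ],
    )
    def test_formula_rounds_up(self, Z, P, d, expected):
        assert sample_size(Z, P, d) == expected

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sample_size(1.96, 0.0, 0.05)
        with pytest.raises(ValueError):
            sample_size(1.96, 0.5, 0.0)
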