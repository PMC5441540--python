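"""Nonparametric statistics battery against enumeration and hand-computed
oracles."""

import itertools
import math

import numpy as np
import pytest

from speechdisorg.stats import (
    bonferroni,
    chi_square_2x2,
    distribution_checks,
    kruskal_wallis,
    partial_spearman,
    round_alpha,
    spearman,
    wilcoxon_ranksum,
)


def kruskal_h(groups):
    """Textbook tie-corrected H for the oracle side."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset:offset + len(g)]
        h += r.sum() ** 2 / len(g)
        offset += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_groups_give_zero_statistic(self):
        res = kruskal_wallis([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    @staticmethod
    def _exact_permutation_p(groups):
        """Enumerate all distinct assignments of the pooled values into the
        group sizes (1680 for sizes 3/3/3) and count H >= observed."""
        pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
        observed = kruskal_h([np.asarray(g, dtype=float) for g in groups])
        idx = range(len(pooled))
        count = total = 0
        for g1 in itertools.combinations(idx, len(groups[0])):
            rest = [i for i in idx if i not in g1]
            for g2 in itertools.combinations(rest, len(groups[1])):
                g3 = [i for i in rest if i not in g2]
                parts = [pooled[list(g1)], pooled[list(g2)], pooled[g3]]
                if kruskal_h(parts) >= observed - 1e-12:
                    count += 1
                total += 1
        return count / total

    def test_p_matches_exact_permutation_enumeration(self):
        # mid-range configuration: the chi-square approximation is accurate
        groups = ([1, 5, 9], [2, 6, 7], [3, 4, 8])
        res = kruskal_wallis(*groups)
        assert res.p_value == pytest.approx(
            self._exact_permutation_p(groups), abs=0.01
        )

    def test_tail_p_is_conservative_but_close_to_enumeration(self):
        # maximally separated groups: the asymptotic p overshoots the exact
        # tail at n = 9, but stays within a few hundredths
        groups = ([1, 2, 3], [4, 5, 6], [7, 8, 9])
        res = kruskal_wallis(*groups)
        exact = self._exact_permutation_p(groups)  # 6/1680
        assert exact == pytest.approx(6 / 1680)
        assert res.statistic == pytest.approx(7.2)
        assert abs(res.p_value - exact) < 0.03

    def test_tie_corrected_statistic_matches_hand_formula(self):
        groups = ([1.0, 2.0, 2.0], [2.0, 3.0, 3.0])
        res = kruskal_wallis(*groups)
        assert res.statistic == pytest.approx(
            kruskal_h([np.array(g) for g in groups])
        )

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0])


class TestWilcoxonRanksum:
    def test_identical_samples_sit_at_the_null_center(self):
        res = wilcoxon_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.9

    def test_exact_small_sample_p(self):
        # all C(4,2)=6 rank splits; the observed split is the most extreme
        res = wilcoxon_ranksum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.statistic == 3.0  # rank-sum of sample a

    def test_power_against_reference_implementation(self, rng):
        from scipy.stats import ranksums

        rejections_ours = rejections_ref = 0
        n_sim = 300
        for _ in range(n_sim):
            a = rng.normal(0.0, 1.0, 50)
            b = rng.normal(0.6, 1.0, 50)
            rejections_ours += wilcoxon_ranksum(a, b).p_value < 0.05
            rejections_ref += ranksums(a, b).pvalue < 0.05
        assert rejections_ours / n_sim == pytest.approx(
            rejections_ref / n_sim, abs=0.05
        )

    def test_monotone_relabeling_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=15)
        res1 = wilcoxon_ranksum(a, b)
        res2 = wilcoxon_ranksum(np.exp(a), np.exp(b))
        assert res1.p_value == pytest.approx(res2.p_value)
        assert res1.statistic == pytest.approx(res2.statistic)


class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = chi_square_2x2([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_evaluated_statistic(self):
        # N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 32*136^2/44352
        res = chi_square_2x2([[7, 4], [1, 20]])
        assert res.statistic == pytest.approx(32 * 136**2 / 44352, abs=1e-9)
        assert res.statistic == pytest.approx(13.34, abs=0.01)

    def test_continuity_correction_shrinks_the_statistic(self):
        plain = chi_square_2x2([[7, 4], [1, 20]])
        yates = chi_square_2x2([[7, 4], [1, 20]], continuity=True)
        assert yates.statistic < plain.statistic

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, x).statistic == 1.0
        assert spearman(x, [-v for v in x]).statistic == -1.0

    def test_hand_computed_rho(self):
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.statistic == pytest.approx(0.8)  # 1 - 6*2/(5*24)

    def test_exact_p_matches_enumeration(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        res = spearman(x, y)
        # enumerate all 120 rank pairings
        rhos = []
        for perm in itertools.permutations(range(5)):
            yy = [y[i] for i in perm]
            d2 = sum((a - b) ** 2 for a, b in zip(
                np.argsort(np.argsort(x)), np.argsort(np.argsort(yy))))
            rhos.append(1 - 6 * d2 / (5 * 24))
        exact = np.mean([abs(r) >= 0.8 - 1e-12 for r in rhos])
        assert res.p_value == pytest.approx(exact)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert spearman(x, y).statistic == pytest.approx(
            spearman(np.exp(x), y).statistic
        )


class TestPartialSpearman:
    def test_empty_covariates_reduce_to_marginal(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert partial_spearman(x, y).statistic == pytest.approx(
            spearman(x, y).statistic
        )

    def test_perfect_confounding_removed(self, rng):
        z = rng.normal(size=40)
        x = rng.normal(size=40)
        res = partial_spearman(x, z, covariates=z)
        # y's rank residuals are numerically ~0; the ratio is noise near zero
        assert abs(res.statistic) < 0.05
        assert res.p_value > 0.5

    def test_independent_covariate_leaves_rho_close_to_marginal(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        marg = spearman(x, y).statistic
        part = partial_spearman(x, y, covariates=z).statistic
        assert part == pytest.approx(marg, abs=0.05)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_spearman(x, y, covariates=np.column_stack([z, z]))


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,rounded",
        [(8, 0.0063), (3, 0.0167), (4, 0.0125), (1, 0.05)],
    )
    def test_thresholds_at_reporting_precision(self, m, rounded):
        assert round_alpha(bonferroni(0.05, m)) == rounded

    def test_raw_threshold_is_alpha_over_m(self):
        assert bonferroni(0.05, 8) == pytest.approx(0.00625)


class TestDistributionChecks:
    def test_identical_groups_give_zero_levene(self):
        out = distribution_checks({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert out["variance_homogeneity"].statistic == 0.0

    def test_unequal_variances_detected(self, rng):
        hits = 0
        for _ in range(30):
            g1 = rng.normal(0, 1, 50)
            g2 = rng.normal(0, math.sqrt(10), 50)
            out = distribution_checks({"g1": g1, "g2": g2})
            hits += out["variance_homogeneity"].p_value < 0.05
        assert hits >= 27  # > 90% power at this separation

    def test_normal_samples_pass_normality_mostly(self, rng):
        ps = []
        for _ in range(40):
            out = distribution_checks(
                {"a": rng.normal(size=80), "b": rng.normal(size=80)}
            )
            ps.extend(t.p_value for t in out["normality"].values())
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = distribution_checks(
                {"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0], "c": [2.0, 3.0, 4.0]}
            )
        assert "a" not in out["normality"]
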