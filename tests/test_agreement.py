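"""Method-comparison statistics, each checked against an independent
oracle: hand-evaluated moment formulas, brute-force double sums, exact
sign-flip and hypergeometric enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, pearsonr

from dgival.agreement import (
    DegenerateInputError,
    PairedScores,
    bland_altman,
    compare_methods,
    fisher_exact,
    lin_ccc,
    paired_location_test,
    percent_agreement,
    quartile_assign,
    subgroup_direction_analysis,
    weighted_kappa,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def ccc_moment_oracle(x, y):
    """Direct evaluation of 2*sxy / (sx^2 + sy^2 + (mx-my)^2), divisor n."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def weighted_kappa_oracle(lx, ly, k, power):
    """Brute-force kappa_w = 1 - sum(w O)/sum(w E) with w = (|i-j|/(K-1))^p."""
    n = len(lx)
    obs = np.zeros((k, k))
    for a, b in zip(lx, ly):
        obs[a - 1, b - 1] += 1
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (abs(i - j) / (k - 1)) ** power
            num += w * obs[i, j]
            den += w * row[i] * col[j] / n
    return 1.0 - num / den


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided p: sum hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed one."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())


def wilcoxon_exact_oracle(d):
    """Exact two-sided p for the signed-rank statistic by enumerating all
    sign assignments of the non-zero differences (no ties assumed)."""
    d = np.asarray([v for v in d if v != 0], float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= stat_obs:
            count += 1
    return count / 2 ** n


# ---------------------------------------------------------------------------
# Lin's CCC
# ---------------------------------------------------------------------------

class TestLinCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        est, lo, hi = lin_ccc(x, x)
        assert est == pytest.approx(1.0)

    def test_location_shift_penalised(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 50.0
        est, _, _ = lin_ccc(x, y)
        r = pearsonr(x, y)[0]
        assert est < r
        assert est < 0.01  # huge shift: near-zero concordance

    def test_five_pair_moment_formula(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        est, lo, hi = lin_ccc(x, y)
        # hand arithmetic: sx2 = sy2 = 2, sxy = 1.6, means equal
        assert est == pytest.approx(0.8)
        assert est == pytest.approx(ccc_moment_oracle(x, y))
        assert lo < est < hi

    def test_constant_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            lin_ccc([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    @given(st.lists(st.tuples(
        st.floats(-50, 50, allow_nan=False),
        st.floats(-50, 50, allow_nan=False),
    ), min_size=4, max_size=30))
    @settings(deadline=None, max_examples=200)
    def test_never_exceeds_pearson(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if x.std() < 1e-6 or y.std() < 1e-6:
            return
        est, _, _ = lin_ccc(x, y)
        r = pearsonr(x, y)[0]
        assert abs(est) <= abs(r) + 1e-9
        assert est == pytest.approx(ccc_moment_oracle(x, y))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

class TestBlandAltman:
    def test_identical_methods(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(x, x)
        assert res.mean_diff == 0.0
        assert res.upper_loa == res.lower_loa == 0.0
        assert res.slope == 0.0

    def test_constant_difference(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x + 2.5, x)
        assert res.mean_diff == pytest.approx(2.5)
        assert res.upper_loa == pytest.approx(2.5)
        assert res.lower_loa == pytest.approx(2.5)
        assert res.slope == 0.0

    def test_reported_loa_consistency(self):
        """Differences with mean 4.78 and SD 15.10 give LOA (−24.82, 34.38)
        at k = 1.96 — internal consistency of mean ± k·SD."""
        d = np.array([4.78 - 15.10, 4.78, 4.78 + 15.10])
        y = np.array([50.0, 60.0, 70.0])
        res = bland_altman(y + d, y)
        assert res.sd_diff == pytest.approx(15.10)
        assert round(res.upper_loa, 2) == 34.38
        assert round(res.lower_loa, 2) == -24.82

    @given(st.lists(st.tuples(
        st.floats(-100, 100, allow_nan=False),
        st.floats(-100, 100, allow_nan=False),
    ), min_size=3, max_size=40), st.floats(-30, 30, allow_nan=False))
    @settings(deadline=None, max_examples=200)
    def test_loa_width_and_translation(self, pairs, shift):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        res = bland_altman(x, y)
        sd = np.std(x - y, ddof=1)
        assert res.upper_loa - res.lower_loa == pytest.approx(2 * 1.96 * sd)
        shifted = bland_altman(x + shift, y + shift)
        assert shifted.mean_diff == pytest.approx(res.mean_diff, abs=1e-8)

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateInputError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# quartiles and kappa
# ---------------------------------------------------------------------------

class TestQuartiles:
    def test_one_to_eight(self):
        labels = quartile_assign(np.arange(1.0, 9.0))
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_balanced_when_divisible(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=20)
        labels = quartile_assign(v)
        assert sorted(np.bincount(labels)[1:].tolist()) == [5, 5, 5, 5]

    def test_tied_block_takes_lower_label(self):
        # ties straddling a cut-point all share the lower quartile
        for values in ([1, 2, 2, 2, 3, 4, 5, 6], [0, 0, 0, 0, 1, 1, 1, 1],
                       [1, 1, 2, 2, 2, 2, 3, 3]):
            v = np.array(values, float)
            labels = quartile_assign(v)
            cuts = np.percentile(v, [25, 50, 75])
            for val, lab in zip(v, labels):
                assert lab == 1 + sum(val > c for c in cuts)
            # equal values always share a label
            for a, b in itertools.combinations(range(len(v)), 2):
                if v[a] == v[b]:
                    assert labels[a] == labels[b]

    def test_too_few(self):
        with pytest.raises(DegenerateInputError):
            quartile_assign([1.0, 2.0, 3.0])


class TestWeightedKappa:
    def test_identity_is_one(self):
        lx = np.array([1, 2, 3, 4, 1, 2, 3, 4])
        k, p = weighted_kappa(lx, lx)
        assert k == pytest.approx(1.0)

    def test_binary_linear_equals_unweighted(self):
        rng = np.random.default_rng(5)
        lx = rng.integers(1, 3, size=60)
        ly = np.where(rng.random(60) < 0.7, lx, 3 - lx)
        kw, _ = weighted_kappa(lx, ly, weights="linear")
        # unweighted Cohen's kappa oracle
        po = np.mean(lx == ly)
        pe = sum(np.mean(lx == c) * np.mean(ly == c) for c in (1, 2))
        assert kw == pytest.approx((po - pe) / (1 - pe))

    @pytest.mark.parametrize("weights,power", [("linear", 1), ("quadratic", 2)])
    def test_four_by_four_against_double_sum(self, weights, power):
        rng = np.random.default_rng(9)
        lx = rng.integers(1, 5, size=120)
        ly = np.clip(lx + rng.integers(-1, 2, size=120), 1, 4)
        k, p = weighted_kappa(lx, ly, weights=weights, n_categories=4)
        assert k == pytest.approx(weighted_kappa_oracle(lx, ly, 4, power))
        assert 0 < p <= 1

    def test_order_reversal_invariance(self):
        rng = np.random.default_rng(2)
        lx = rng.integers(1, 5, size=50)
        ly = rng.integers(1, 5, size=50)
        k1, _ = weighted_kappa(lx, ly, n_categories=4)
        k2, _ = weighted_kappa(5 - lx, 5 - ly, n_categories=4)
        assert k1 == pytest.approx(k2)

    def test_at_most_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            lx = rng.integers(1, 5, size=30)
            ly = rng.integers(1, 5, size=30)
            k, _ = weighted_kappa(lx, ly, n_categories=4)
            assert k <= 1.0 + 1e-12

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            weighted_kappa([1, 2], [1, 2, 3])

    def test_empty(self):
        with pytest.raises(ValueError):
            weighted_kappa([], [])


class TestPercentAgreement:
    def test_breastfeeding_style_table(self):
        # one discordant child of 40: (33+6)/40 = 97.5%
        assert percent_agreement(np.array([[33, 0], [1, 6]])) == pytest.approx(97.5)

    def test_identity_table(self):
        assert percent_agreement(np.array([[7, 0], [0, 13]])) == 100.0

    def test_all_off_diagonal(self):
        assert percent_agreement(np.array([[0, 4], [9, 0]])) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement(np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# paired location tests
# ---------------------------------------------------------------------------

class TestPairedLocation:
    def test_t_identical(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_location_test(x, x, method="t")
        assert res.statistic == 0.0
        assert res.mean_diff == 0.0

    def test_mean_difference_of_group_means(self):
        # paired mean difference equals the difference of the means
        rng = np.random.default_rng(1)
        y = rng.normal(2.95, 1.42, size=40)
        x = y + (6.14 - 2.95) + rng.normal(0, 0.3, size=40)
        x = x - x.mean() + 6.14
        y = y - y.mean() + 2.95
        res = paired_location_test(x, y, method="t")
        assert res.mean_diff == pytest.approx(6.14 - 2.95)
        assert res.ci_low < res.mean_diff < res.ci_high

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_wilcoxon_against_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.4, 1.0, size=9)
        x = np.arange(9, dtype=float)
        res = paired_location_test(x + d, x, method="wilcoxon")
        exact = wilcoxon_exact_oracle(d)
        # normal approximation with continuity correction vs exact law
        assert res.p == pytest.approx(exact, abs=0.04)

    def test_wilcoxon_all_zero_differences(self):
        x = np.ones(6)
        with pytest.warns(UserWarning, match="undefined"):
            res = paired_location_test(x, x, method="wilcoxon")
        assert res.p == 1.0
        assert res.statistic == 0.0

    def test_wilcoxon_too_few_nonzero(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            paired_location_test(x, np.ones(6), method="wilcoxon")


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_extreme_table(self):
        # only the two fully-separated tables are as extreme
        p = fisher_exact(np.array([[10, 0], [0, 10]]))
        assert p == pytest.approx(2.0 / math.comb(20, 10))

    @given(st.tuples(*(st.integers(0, 12),) * 4))
    @settings(deadline=None, max_examples=300)
    def test_matches_enumeration(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p = fisher_exact(np.array([[a, b], [c, d]]))
        assert 0 < p <= 1
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d))

    def test_nonneg_integer_counts_required(self):
        with pytest.raises(ValueError):
            fisher_exact(np.array([[1.5, 2.0], [3.0, 4.0]]))


# ---------------------------------------------------------------------------
# subgroup direction analysis
# ---------------------------------------------------------------------------

class TestSubgroupDirection:
    def test_identical_scores_no_association(self):
        ids = [f"c{i}" for i in range(12)]
        x = np.arange(12, dtype=float)
        pairs = PairedScores(ids, x, x.copy())
        bands = ["<12mo"] * 4 + ["1-2y"] * 5 + [">2y"] * 3
        res = subgroup_direction_analysis(pairs, bands)
        assert all(v["higher"] == 0 for v in res.counts.values())
        assert res.fisher_p == pytest.approx(1.0)

    def test_all_higher_everywhere(self):
        ids = [f"c{i}" for i in range(10)]
        y = np.arange(10, dtype=float)
        pairs = PairedScores(ids, y + 1.0, y)
        bands = ["<12mo"] * 4 + ["1-2y"] * 6
        res = subgroup_direction_analysis(pairs, bands)
        assert res.table.tolist() == [[4, 0], [6, 0]]
        # degenerate margin: a single achievable table, enumeration gives 1
        assert res.fisher_p == pytest.approx(
            fisher_enumeration_oracle(4, 0, 6, 0))

    def test_infant_only_bias_detected_at_scale(self):
        rng = np.random.default_rng(21)
        n = 200
        bands = ["<12mo" if i < n // 2 else "1-2y" for i in range(n)]
        y = rng.normal(60, 10, size=n)
        bias = np.where(np.array(bands) == "<12mo", 5.0, -5.0)
        x = y + bias + rng.normal(0, 1, size=n)
        pairs = PairedScores([f"c{i}" for i in range(n)], x, y)
        res = subgroup_direction_analysis(pairs, bands)
        assert res.fisher_p < 1e-6
        assert res.bland_altman_excluding_infants.mean_diff < 0


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

class TestCompareMethods:
    def test_identical_scores_degenerate_limits(self):
        rng = np.random.default_rng(4)
        x = rng.normal(60, 12, size=24)
        pairs = PairedScores([f"c{i}" for i in range(24)], x, x.copy())
        rep = compare_methods(pairs)
        assert rep.ccc == pytest.approx(1.0)
        assert rep.bland_altman.mean_diff == 0.0
        assert rep.kappa == pytest.approx(1.0)
        assert rep.percent_same_quartile == 100.0

    def test_report_invariants(self):
        rng = np.random.default_rng(8)
        x = rng.normal(60, 12, size=40)
        y = x + rng.normal(3, 8, size=40)
        rep = compare_methods(PairedScores([f"c{i}" for i in range(40)], x, y))
        ba = rep.bland_altman
        assert ba.lower_loa <= ba.mean_diff <= ba.upper_loa
        assert rep.ccc_ci[0] <= rep.ccc <= rep.ccc_ci[1]
        d = rep.to_dict()
        assert set(d) >= {"ccc", "mean_difference", "upper_loa",
                          "weighted_kappa", "percent_same_quartile"}
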