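import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from seizkit.stats import (ContingencyTable, StatResult,
                           circadian_correlation, fisher_freeman_halton,
                           group_tests, holm_adjust, linear_corr,
                           rank_trend)


# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the implementation

def oracle_fisher_r_by_2(counts):
    """Two-sided exact p by literal enumeration of every table with the
    observed margins, using factorial arithmetic."""
    counts = np.asarray(counts)
    rows = counts.sum(axis=1)
    c1 = counts[:, 0].sum()
    n = counts.sum()

    def prob(ks):
        num = math.prod(math.comb(int(r), int(k)) for r, k in zip(rows, ks))
        return num / math.comb(int(n), int(c1))

    p_obs = prob(counts[:, 0])
    total = 0.0
    for ks in itertools.product(*(range(r + 1) for r in rows)):
        if sum(ks) != c1:
            continue
        p = prob(ks)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def oracle_u_two_sided(x, y):
    """Exact permutation p for the Mann-Whitney U by enumerating all group
    assignments of the pooled sample."""
    pooled = list(x) + list(y)
    n = len(x)
    mu = n * len(y) / 2

    def u_of(idx):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(sum(1.0 if a > b else 0.5 if a == b else 0.0
                    for b in rest) for a in grp)
        return u

    u_obs = u_of(tuple(range(n)))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestFisherFreemanHalton:
    def test_two_by_two_diagonal(self):
        res = fisher_freeman_halton(
            ContingencyTable(["a", "b"], np.array([[2, 0], [0, 2]])))
        assert res.p_value == pytest.approx(1 / 3)

    def test_empty_row_dropped_with_flag(self):
        res = fisher_freeman_halton(
            ContingencyTable(["a", "b"], np.array([[3, 2], [0, 0]])))
        assert res.p_value == 1.0
        assert res.extra["dropped_empty_rows"] == 1

    def test_reported_incidence_table_rounds_to_printed_p(self):
        res = fisher_freeman_halton(ContingencyTable(
            ["stim", "nostim", "nochr2"], np.array([[9, 3], [0, 4], [0, 5]])))
        assert round(res.p_value, 3) == 0.001

    @pytest.mark.parametrize("table", [
        [[3, 5], [6, 2]], [[1, 7], [4, 4]], [[5, 0], [2, 6]],
    ])
    def test_two_by_two_matches_scipy(self, table):
        res = fisher_freeman_halton(
            ContingencyTable(["a", "b"], np.array(table)))
        assert res.p_value == pytest.approx(
            sps.fisher_exact(np.array(table)).pvalue, abs=1e-12)

    @pytest.mark.parametrize("table", [
        [[4, 1], [2, 3], [0, 5]], [[2, 2], [3, 1], [1, 4], [0, 3]],
    ])
    def test_r_by_2_matches_enumeration_oracle(self, table):
        res = fisher_freeman_halton(
            ContingencyTable([str(i) for i in range(len(table))],
                             np.array(table)))
        assert res.p_value == pytest.approx(oracle_fisher_r_by_2(table),
                                            abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(["a", "b"], np.array([[1, -1], [2, 2]]))


class TestRankTrend:
    def test_perfect_monotone(self):
        x = np.arange(1, 10)
        assert rank_trend(x, x.astype(float)).statistic == pytest.approx(1.0)
        assert rank_trend(x, -x.astype(float)).statistic == \
            pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle_with_ties(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 2.0, 3.0, 5.0, 4.0]
        res = rank_trend(x, y)
        assert res.method == "exact"
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rho_obs = np.corrcoef(rx, ry)[0, 1]
        count = total = 0
        for perm in itertools.permutations(ry):
            if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_obs) - 1e-12:
                count += 1
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = rank_trend([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert math.isnan(res.statistic)


class TestLinearCorr:
    def test_exact_line(self):
        x = np.arange(10.0)
        assert linear_corr(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_orthogonal_residual_gives_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        xc = x - x.mean()
        yc = y - y.mean()
        y = y - xc * (xc @ yc) / (xc @ xc)
        assert abs(linear_corr(x, y).statistic) < 1e-12

    def test_matches_from_definition_oracle(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = linear_corr(x, y)
        r = (np.sum((x - x.mean()) * (y - y.mean()))
             / np.sqrt(np.sum((x - x.mean()) ** 2)
                       * np.sum((y - y.mean()) ** 2)))
        t = r * math.sqrt(8 / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), 8)
        assert res.statistic == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupTests:
    def test_paired_t_on_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = group_tests((x, x.copy()), "paired_t")
        assert math.isnan(res.statistic) or res.statistic == 0.0

    def test_mann_whitney_extreme_separation(self):
        res = group_tests(([1.0, 2.0], [3.0, 4.0]), "mann_whitney")
        assert res.statistic == 0.0

    def test_mann_whitney_permutation_matches_oracle(self):
        x = [1.2, 3.4, 2.2, 5.0, 0.7]
        y = [4.1, 6.0, 5.5, 2.0]
        res = group_tests((x, y), "mann_whitney", method="permutation")
        assert res.p_value == pytest.approx(oracle_u_two_sided(x, y),
                                            abs=1e-12)

    def test_kruskal_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = group_tests([g, list(g), list(g)], "kruskal")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_kruskal_permutation_matches_scipy_statistic(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=3), rng.normal(size=2),
                  rng.normal(size=2)]
        res = group_tests(groups, "kruskal", method="permutation")
        href, _ = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(href, abs=1e-12)
        assert 0 < res.p_value <= 1

    def test_friedman_matches_scipy(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(10, 4))
        res = group_tests(data, "friedman")
        ref = sps.friedmanchisquare(*[data[:, j] for j in range(4)])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_friedman_permutation_exhaustive(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(3, 3))
        res = group_tests(data, "friedman", method="permutation")
        # oracle: enumerate within-block permutations directly
        chi_obs = res.statistic
        count = total = 0
        for perms in itertools.product(
                itertools.permutations(range(3)), repeat=3):
            arr = np.array([data[i, list(p)] for i, p in enumerate(perms)])
            ranks = np.array([sps.rankdata(row) for row in arr])
            rj = ranks.sum(axis=0)
            chi = 12.0 / (3 * 3 * 4) * np.sum(rj ** 2) - 3 * 3 * 4
            if chi >= chi_obs - 1e-12:
                count += 1
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            group_tests(([1.0], [2.0]), "welch")

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            group_tests(([1.0, 2.0], [1.0, 2.0, 3.0]), "paired_t")


class TestCircadian:
    def test_linear_metric_detected_by_linear_mode(self):
        t = np.linspace(0, 23, 24)
        res = circadian_correlation(t, 2 * t + 1.0)
        assert res.statistic == pytest.approx(1.0)

    def test_sinusoidal_metric_needs_circular_mode(self, rng):
        t = rng.uniform(0, 24, size=60)
        v = np.sin(2 * np.pi * t / 24) + rng.normal(0, 0.1, size=60)
        lin = circadian_correlation(t, v, mode="linear")
        circ = circadian_correlation(t, v, mode="circular")
        assert circ.p_value < 0.001
        assert circ.statistic > abs(lin.statistic)

    def test_null_is_mostly_nonsignificant(self):
        rng = np.random.default_rng(10)
        sig = 0
        for _ in range(100):
            t = rng.uniform(0, 24, size=20)
            v = rng.normal(size=20)
            if circadian_correlation(t, v).p_value < 0.05:
                sig += 1
        assert sig <= 10

    def test_out_of_range_times_rejected(self):
        with pytest.raises(ValueError, match="clock"):
            circadian_correlation([25.0, 1.0, 2.0], [1.0, 2.0, 3.0])


class TestResultContainer:
    def test_pvalue_bounds_enforced(self):
        with pytest.raises(ValueError):
            StatResult("x", 0.0, 1.5, (3,), "exact")

    def test_holm_adjustment_monotone(self):
        adj = holm_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.all(adj >= [0.01, 0.04, 0.03, 0.005])
        assert np.all(adj <= 1.0)
        raw_order = np.argsort([0.01, 0.04, 0.03, 0.005])
        assert np.all(np.diff(adj[raw_order]) >= -1e-12)
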