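"""Gated statistics vs. enumeration/permutation oracles; PCA properties."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mpmri import stats
from mpmri.stats import (FEATURE_COLUMNS, GroupSample, compare_over_time,
                         compare_two_groups, make_feature_table,
                         pc1_threshold_accuracy, pearson_correlation, run_pca,
                         shapiro_gate, zscore_columns)


def _mwu_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    center = n * m / 2.0

    def u_stat(x, y):
        return sum(np.sum(xi > y) for xi in x)  # no ties by construction

    u_obs = u_stat(a, b)
    count = 0
    total = 0
    idx = range(n + m)
    for comb in combinations(idx, n):
        sel = np.zeros(n + m, dtype=bool)
        sel[list(comb)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_separated_triplets_exact_p(self):
        res = compare_two_groups(GroupSample(("a",), [1, 2, 3]),
                                 GroupSample(("b",), [4, 5, 6]),
                                 force="nonparametric")
        assert res.test_name == "mann_whitney_u"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n, m = rng.integers(3, 8, size=2)
            a = rng.normal(0, 1, n)
            b = rng.normal(rng.uniform(-1, 1), 1, m)
            res = compare_two_groups(GroupSample(("a",), a), GroupSample(("b",), b),
                                     force="nonparametric")
            assert res.p_value == pytest.approx(_mwu_enumeration_p(a, b), abs=1e-10)

    def test_identical_groups_full_overlap(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = compare_two_groups(GroupSample(("a",), x), GroupSample(("b",), x),
                                 force="nonparametric")
        assert res.p_value == pytest.approx(1.0)


class TestShapiroGate:
    def test_normal_samples_parametric(self):
        rng = np.random.default_rng(14)
        groups = [GroupSample((g,), rng.normal(0, 1, 30)) for g in "ab"]
        choice, p = shapiro_gate(groups)
        assert choice == "parametric"
        assert all(v > 0.05 for v in p.values())

    def test_exponential_sample_nonparametric(self):
        rng = np.random.default_rng(15)
        groups = [GroupSample(("a",), rng.normal(0, 1, 100)),
                  GroupSample(("b",), rng.exponential(1.0, 100))]
        choice, p = shapiro_gate(groups)
        assert choice == "nonparametric"
        assert p[("b",)] < 0.05

    def test_permutation_invariant_in_group_order(self):
        rng = np.random.default_rng(16)
        g = [GroupSample((i,), rng.normal(0, 1, 20)) for i in range(3)]
        assert shapiro_gate(g)[0] == shapiro_gate(g[::-1])[0]

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            shapiro_gate([GroupSample(("a",), [1.0, 2.0])])


class TestGatedComparisons:
    def test_type_one_error_of_gated_procedure(self):
        """Under equal-mean normal data the gated test keeps its 5% level."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = GroupSample(("a",), rng.normal(0, 1, 10))
            b = GroupSample(("b",), rng.normal(0, 1, 10))
            if compare_two_groups(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_kruskal_wallis_rank_formula(self):
        groups = [GroupSample((d,), v) for d, v in
                  zip((3, 6, 9), ([1.0, 2.0], [3.0, 4.0], [5.0, 6.0]))]
        res = compare_over_time(groups, force="nonparametric")
        # H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 with ranks 1..6
        rank_means = np.array([1.5, 3.5, 5.5])
        h = 12.0 / (6 * 7) * np.sum(2 * (rank_means - 3.5) ** 2)
        assert res.test_name == "kruskal_wallis"
        assert res.statistic == pytest.approx(h, rel=1e-12)

    def test_identical_day_groups_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0]
        groups = [GroupSample((d,), x) for d in (3, 6, 9)]
        res = compare_over_time(groups, force="nonparametric")
        assert res.p_value > 0.99

    def test_anova_f_near_one_under_null(self):
        rng = np.random.default_rng(7)
        fs = []
        for _ in range(1000):
            groups = [GroupSample((d,), rng.normal(0, 1, 8)) for d in (3, 6, 9)]
            fs.append(compare_over_time(groups, force="parametric").statistic)
        # E[F] = dfd/(dfd-2) = 21/19 for 3 groups of 8 under the null
        assert abs(np.mean(fs) - 21.0 / 19.0) < 0.12


class TestPearson:
    def test_perfect_and_zero_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, 2 * x).statistic == pytest.approx(1.0)
        y = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to centered x
        assert pearson_correlation(x, y).statistic == pytest.approx(0.0, abs=1e-12)

    def test_p_value_matches_permutation_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 10)
        y = 0.6 * x + rng.normal(0, 1, 10)
        res = pearson_correlation(x, y)
        n_perm = 100_000
        perm_y = np.array([rng.permutation(y) for _ in range(n_perm)])
        xc = x - x.mean()
        yc = perm_y - perm_y.mean(axis=1, keepdims=True)
        r_perm = (yc @ xc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2, axis=1))
        p_perm = np.mean(np.abs(r_perm) >= abs(res.statistic) - 1e-12)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) < 0.005 + 4 * se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _random_table(n_rows=16, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_rows):
        row = {"tumor_id": f"t{i}", "phenotype": "a" if i % 2 else "b", "day": 3}
        row.update({c: rng.normal(0, 1) for c in FEATURE_COLUMNS})
        rows.append(row)
    return make_feature_table(rows)


class TestZScore:
    def test_column_standardization_and_idempotence(self):
        table = _random_table()
        z = zscore_columns(table)
        for c in FEATURE_COLUMNS:
            assert z[c].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[c].std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        zz = zscore_columns(z)
        pd.testing.assert_frame_equal(z, zz, rtol=1e-10, atol=1e-12)

    def test_simple_column(self):
        table = _random_table(3)
        table.loc[:, "T1"] = [1.0, 2.0, 3.0]
        np.testing.assert_allclose(zscore_columns(table)["T1"], [-1.0, 0.0, 1.0])

    def test_constant_column_rejected(self):
        table = _random_table()
        table.loc[:, "T2"] = 5.0
        with pytest.raises(ValueError):
            zscore_columns(table)


class TestPCA:
    def test_full_rank_explains_everything(self):
        z = zscore_columns(_random_table(16))
        res = run_pca(z, n_components=10)
        assert res.variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.variance_ratio) <= 1e-12)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-10)

    def test_rank_one_table(self):
        table = _random_table(12)
        base = np.arange(12, dtype=float)
        for j, c in enumerate(FEATURE_COLUMNS):
            table.loc[:, c] = (j + 1) * base
        res = run_pca(zscore_columns(table), n_components=10)
        assert res.variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(res.variance_ratio[1:] < 1e-10)

    def test_scores_reconstruct_centered_table(self):
        z = zscore_columns(_random_table(16, seed=5))
        res = run_pca(z, n_components=10)
        x = z[list(FEATURE_COLUMNS)].to_numpy()
        recon = res.scores @ res.loadings.T + x.mean(axis=0)
        np.testing.assert_allclose(recon, x, atol=1e-10)

    def test_row_permutation_permutes_scores(self):
        z = zscore_columns(_random_table(16, seed=6))
        res = run_pca(z, n_components=3)
        perm = np.random.default_rng(0).permutation(len(z))
        res_p = run_pca(z.iloc[perm].reset_index(drop=True), n_components=3)
        np.testing.assert_allclose(res_p.scores, res.scores[perm], atol=1e-8)

    def test_excessive_components_rejected(self):
        z = zscore_columns(_random_table(8))
        with pytest.raises(ValueError):
            run_pca(z, n_components=10)

    def test_pc1_threshold_accuracy_on_separated_groups(self):
        scores = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        labels = np.array(["x", "x", "y", "y"])
        assert pc1_threshold_accuracy(scores, labels) == 1.0
        mixed = np.array([[-2.0], [1.5], [-1.5], [2.0]])
        assert pc1_threshold_accuracy(mixed, labels) == 0.5


def test_missing_feature_column_rejected():
    rows = [{"tumor_id": "t", "phenotype": "a", "day": 3, "T1": 1.0}]
    with pytest.raises(ValueError):
        make_feature_table(rows)
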