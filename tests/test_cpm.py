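import numpy as np
import pytest
from scipy import stats

from traumacpm import cpm


def residualize_then_correlate(edges, y, X):
    """Independent oracle: regress out [1, X] from both sides, then Pearson."""
    n = len(y)
    D = np.column_stack([np.ones(n)] + ([X] if X is not None else []))
    H = D @ np.linalg.pinv(D)
    ry = y - H @ y
    r = np.empty(edges.shape[1])
    for e in range(edges.shape[1]):
        re = edges[:, e] - H @ edges[:, e]
        r[e] = np.corrcoef(re, ry)[0, 1]
    return r


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert cpm.spearman(x, x ** 3) == pytest.approx(1.0)
        assert cpm.spearman(x, -x) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([3.0, 1.0, 2.0, 2.0])
        # explicit average ranks: x -> 1, 2.5, 2.5, 4 ; y -> 4, 1, 2.5, 2.5
        oracle = np.corrcoef([1, 2.5, 2.5, 4], [4, 1, 2.5, 2.5])[0, 1]
        assert cpm.spearman(x, y) == pytest.approx(oracle, abs=1e-12)
        assert cpm.spearman(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cpm.spearman(np.ones(5), np.arange(5.0))


class TestPartialCorr:
    def test_no_covariates_equals_pearson(self, rng):
        edges = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        r, p = cpm.partial_corr_edges(edges, y, None)
        expected = [np.corrcoef(edges[:, e], y)[0, 1] for e in range(10)]
        assert np.allclose(r, expected, atol=1e-12)

    def test_small_printed_fixture_matches_oracle(self):
        # n=6 toy table: two edges, one covariate
        edges = np.array([[1.0, 0.2], [2.1, -0.3], [2.9, 0.8],
                          [4.2, -1.1], [4.8, 0.4], [6.1, -0.2]])
        y = np.array([3.0, 5.0, 4.0, 8.0, 9.0, 11.0])
        X = np.array([[0.5], [1.0], [0.0], [2.0], [1.5], [2.5]])
        r, p = cpm.partial_corr_edges(edges, y, X)
        oracle = residualize_then_correlate(edges, y, X)
        assert np.allclose(r, oracle, atol=1e-10)

    def test_random_instances_match_oracle_and_pingouin(self, rng):
        for _ in range(20):
            n, E, c = 25, 8, 2
            edges = rng.normal(size=(n, E))
            y = rng.normal(size=n)
            X = rng.normal(size=(n, c))
            r, p = cpm.partial_corr_edges(edges, y, X)
            assert np.allclose(r, residualize_then_correlate(edges, y, X),
                               atol=1e-10)
        import pandas as pd
        import pingouin as pg
        df = pd.DataFrame({"e": edges[:, 0], "y": y,
                           "c1": X[:, 0], "c2": X[:, 1]})
        ref = pg.partial_corr(df, x="e", y="y", covar=["c1", "c2"])
        assert r[0] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p[0] == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_duplicated_outcome_as_covariate_errors(self, rng):
        edges = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            cpm.partial_corr_edges(edges, y, y[:, None])

    def test_constant_y_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cpm.partial_corr_edges(rng.normal(size=(10, 3)), np.full(10, 2.0))


class TestSelectEdges:
    def test_nothing_significant(self):
        sel = cpm.select_edges(np.array([0.5, -0.5]), np.array([1.0, 1.0]))
        assert sel.n_pos == sel.n_neg == 0

    def test_alpha_one_partitions_by_sign(self, rng):
        r = rng.normal(size=50)
        p = rng.random(50)
        sel = cpm.select_edges(r, p, alpha=1.0)
        assert np.array_equal(sel.pos_mask, r > 0)
        assert np.array_equal(sel.neg_mask, r < 0)
        assert not np.any(sel.pos_mask & sel.neg_mask)

    def test_matches_elementwise_rule(self, rng):
        r = rng.normal(size=40)
        p = rng.random(40)
        sel = cpm.select_edges(r, p, alpha=0.3)
        for e in range(40):
            assert sel.pos_mask[e] == (p[e] < 0.3 and r[e] > 0)
            assert sel.neg_mask[e] == (p[e] < 0.3 and r[e] < 0)


class TestSummarizeAndFit:
    def test_summarize_matches_masked_sum(self, rng):
        row = rng.normal(size=30)
        sel = cpm.select_edges(rng.normal(size=30), rng.random(30), alpha=0.4)
        pos, neg = cpm.summarize_features(row, sel)
        assert pos == pytest.approx(row[sel.pos_mask].sum())
        assert neg == pytest.approx(row[sel.neg_mask].sum())
        empty = cpm.select_edges(np.ones(30), np.ones(30))
        assert cpm.summarize_features(row, empty) == (0.0, 0.0)

    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(5)
        n = 200
        driver = rng.normal(size=n)
        edges = np.column_stack([driver, rng.normal(size=(n, 9))])
        y = 3.0 + 2.0 * driver
        fit = cpm.fit_cpm(edges, y, alpha=1e-6)
        assert fit.selection.n_pos == 1 and fit.selection.n_neg == 0
        assert fit.coef_pos == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(3.0, abs=1e-8)

    def test_no_selection_predicts_training_mean(self, rng):
        edges = rng.normal(size=(40, 20))
        y = rng.normal(size=40)
        fit = cpm.fit_cpm(edges, y, alpha=1e-15)
        assert fit.selection.n_pos == fit.selection.n_neg == 0
        assert np.allclose(fit.predict(edges), y.mean())


class TestRunCV:
    def test_fold_sizes_for_162_subjects(self):
        fold = cpm._fold_indices(162, 10, seed=0)
        sizes = sorted(np.bincount(fold))
        assert sizes == [16] * 8 + [17] * 2

    def test_partition_covers_everyone_once(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 200))
            k = int(rng.integers(2, 11))
            fold = cpm._fold_indices(n, k, int(rng.integers(0, 2 ** 31)))
            sizes = np.bincount(fold, minlength=k)
            assert sizes.sum() == n
            assert sizes.max() - sizes.min() <= 1

    def test_engine_matches_reference_per_fold_fit(self, rng):
        n, E = 40, 60
        edges = rng.normal(size=(n, E))
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 2))
        run = cpm.run_cv(edges, y, X, k=5, repeats=2, seed=11)
        for rep in range(2):
            fold = run.fold_assignments[rep]
            ref = np.empty(n)
            for f in range(5):
                te = fold == f
                fit = cpm.fit_cpm(edges[~te], y[~te], X[~te])
                ref[te] = fit.predict(edges[te])
            assert np.allclose(ref, run.predictions[rep], atol=1e-8)

    def test_no_leakage_from_held_out_labels(self, rng):
        n, E = 50, 40
        edges = rng.normal(size=(n, E))
        y = rng.normal(size=n)
        run = cpm.run_cv(edges, y, k=5, repeats=1, seed=3)
        test0 = run.fold_assignments[0] == 0
        y2 = y.copy()
        y2[test0] = rng.normal(size=test0.sum())  # relabel held-out subjects
        run2 = cpm.run_cv(edges, y2, k=5, repeats=1, seed=3)
        assert np.allclose(run.predictions[0][test0],
                           run2.predictions[0][test0])

    def test_determinism_bit_identical(self, rng):
        edges = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        a = cpm.run_cv(edges, y, k=5, repeats=3, seed=9)
        b = cpm.run_cv(edges, y, k=5, repeats=3, seed=9)
        assert np.array_equal(a.predictions, b.predictions)
        assert np.array_equal(a.rho_per_repeat, b.rho_per_repeat)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)

    def test_too_few_subjects_errors(self, rng):
        with pytest.raises(ValueError, match="2k"):
            cpm.run_cv(rng.normal(size=(15, 5)), rng.normal(size=15), k=10)

    def test_null_median_rho_centered_at_zero(self):
        medians = []
        for s in range(200):
            rng = np.random.default_rng(10_000 + s)
            edges = rng.normal(size=(100, 500))
            y = rng.normal(size=100)
            medians.append(cpm.score(cpm.run_cv(edges, y, k=10, repeats=5,
                                                seed=s)))
        assert abs(np.mean(medians)) < 0.03


class TestScore:
    def test_small_cases(self):
        run = cpm.CVRun(10, 1, None, None, np.array([0.42]), 0)
        assert cpm.score(run) == pytest.approx(0.42)
        run3 = cpm.CVRun(10, 3, None, None, np.array([0.1, 0.3, 0.2]), 0)
        assert cpm.score(run3) == pytest.approx(0.2)

    def test_matches_sort_based_oracle(self, rng):
        rhos = rng.uniform(-1, 1, size=100)
        srt = np.sort(rhos)
        oracle = 0.5 * (srt[49] + srt[50])
        run = cpm.CVRun(10, 100, None, None, rhos, 0)
        assert cpm.score(run) == pytest.approx(oracle, abs=1e-15)
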