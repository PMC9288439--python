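import numpy as np
import pandas as pd
import pytest
from scipy import stats

from postgwas import (
    ExpressionMatrix,
    ProcessedExpression,
    TimepointEffects,
    gene_property_regression,
    prepost_contrast,
    preprocess_expression,
    timepoint_correlation,
)
from postgwas.simulate import simulate_gene_level
from postgwas.temporal import read_expression, temporal_contrast_pipeline, write_expression


def tiny_expression():
    # 4 genes x 4 samples; samples 2 and 3 share an age
    rpkm = np.array([
        [10.0, 20.0, 40.0, 100.0],
        [0.5, 0.9, 0.8, 0.2],      # never above 1 -> filtered
        [5.0, 3.0, 7.0, 2.0],
        [2.0, 6.0, 4.0, 9.0],
    ])
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3", ""],
        sample_ids=["s1", "s2", "s3", "s4"],
        age_labels=["8pcw", "12pcw", "12pcw", "2yrs"],
        prenatal=np.array([True, True, True, False]),
        rpkm=rpkm,
    )


class TestPreprocess:
    def test_low_expression_and_missing_id_filters(self):
        expr = preprocess_expression(tiny_expression())
        assert expr.gene_ids == ["g1", "g3"]
        rep = expr.filter_report
        assert rep["removed_low_expression"] == 1
        assert rep["removed_missing_id"] == 1
        assert rep["input_genes"] - rep["output_genes"] == (
            rep["removed_low_expression"] + rep["removed_missing_id"]
            + rep["removed_not_brain_gene"]
        )

    def test_winsorization_caps_at_log2_51(self):
        expr = preprocess_expression(tiny_expression())
        # gene g1 sample s4 has RPKM 100 -> winsorized to 50 -> log2(51)
        assert expr.logexpr.max() == pytest.approx(np.log2(51), abs=1e-12)
        assert np.all(expr.logexpr <= np.log2(51) + 1e-12)

    def test_same_age_samples_averaged(self):
        expr = preprocess_expression(tiny_expression())
        assert expr.timepoints == ["8pcw", "12pcw", "2yrs"]
        g1 = expr.logexpr[0]
        expected_mid = (np.log2(21) + np.log2(41)) / 2
        assert g1[1] == pytest.approx(expected_mid, abs=1e-12)

    def test_brain_gene_restriction(self):
        expr = preprocess_expression(tiny_expression(), brain_genes={"g1"})
        assert expr.gene_ids == ["g1"]
        assert expr.filter_report["removed_not_brain_gene"] == 1

    def test_avg_covariate_is_row_mean(self):
        expr = preprocess_expression(tiny_expression())
        assert np.allclose(expr.avg_expr, expr.logexpr.mean(axis=1))

    def test_nothing_survives_errors(self):
        with pytest.raises(ValueError, match="no genes survive"):
            preprocess_expression(tiny_expression(), brain_genes={"nope"})


class TestGenePropertyRegression:
    def make_expr(self, x, avg):
        x = np.asarray(x, float)
        k = 3
        logexpr = np.column_stack([x, np.asarray(avg, float), np.zeros_like(x)])
        # avg_expr set explicitly; logexpr column 0 is the tested timepoint
        return ProcessedExpression(
            gene_ids=[f"g{i}" for i in range(len(x))],
            timepoints=["t0", "t1", "t2"],
            prenatal=np.array([True, False, False]),
            logexpr=logexpr,
            avg_expr=np.asarray(avg, float),
        )

    def test_constant_z_gives_null(self):
        expr = self.make_expr([1, 2, 3, 4], [2, 1, 2, 1])
        assoc = pd.DataFrame({"gene_id": expr.gene_ids, "z": [1.0] * 4})
        beta, se, p = gene_property_regression(assoc, expr, "t0")
        assert beta == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_noise_free_recovery(self):
        x = [1.0, 2.0, 3.0, 4.0]
        avg = [2.0, 1.0, 2.0, 1.0]
        expr = self.make_expr(x, avg)
        z = 0.5 * np.array(x) + 0.2 * np.array(avg)
        assoc = pd.DataFrame({"gene_id": expr.gene_ids, "z": z})
        beta, se, p = gene_property_regression(assoc, expr, "t0")
        assert beta == pytest.approx(0.5, abs=1e-10)

    def test_one_sided_upper_tail(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        avg = rng.standard_normal(200)
        expr = self.make_expr(x, avg)
        z = 0.8 * x + rng.standard_normal(200) * 0.5
        assoc = pd.DataFrame({"gene_id": expr.gene_ids, "z": z})
        _, _, p_pos = gene_property_regression(assoc, expr, "t0")
        assoc_neg = pd.DataFrame({"gene_id": expr.gene_ids, "z": -z})
        _, _, p_neg = gene_property_regression(assoc_neg, expr, "t0")
        assert p_pos < 0.01 and p_neg > 0.99

    def test_constant_column_error(self):
        expr = self.make_expr([1.0, 1.0, 1.0, 1.0], [2, 1, 2, 1])
        assoc = pd.DataFrame({"gene_id": expr.gene_ids, "z": [1, 2, 3, 4.0]})
        with pytest.raises(ValueError, match="timepoint expression"):
            gene_property_regression(assoc, expr, "t0")

    def test_ci_coverage(self):
        # fixed design, 2000 noise replicates: 95% CI covers the true slope
        rng = np.random.default_rng(42)
        n = 200
        x = rng.standard_normal(n)
        avg = 0.5 * x + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, avg])
        XtXi = np.linalg.inv(X.T @ X)
        H = XtXi @ X.T
        true_slope = 0.3
        mean = true_slope * x + 0.1 * avg
        covered = 0
        n_rep = 2000
        noise = rng.standard_normal((n, n_rep)) * 0.7
        Y = mean[:, None] + noise
        coef = H @ Y
        resid = Y - X @ coef
        sigma2 = (resid**2).sum(axis=0) / (n - 3)
        se = np.sqrt(sigma2 * XtXi[1, 1])
        tcrit = stats.t.ppf(0.975, n - 3)
        covered = np.abs(coef[1] - true_slope) <= tcrit * se
        rate = covered.mean()
        assert abs(rate - 0.95) < 3 * np.sqrt(0.95 * 0.05 / n_rep)


class TestTimepointCorrelation:
    def make_processed(self, logexpr):
        logexpr = np.asarray(logexpr, float)
        k = logexpr.shape[1]
        return ProcessedExpression(
            gene_ids=[f"g{i}" for i in range(logexpr.shape[0])],
            timepoints=[f"t{j}" for j in range(k)],
            prenatal=np.array([True] + [False] * (k - 1)),
            logexpr=logexpr,
            avg_expr=logexpr.mean(axis=1),
        )

    def test_duplicated_columns_correlate_fully(self, rng):
        x = rng.standard_normal(50)
        R = timepoint_correlation(self.make_processed(np.column_stack([x, x])))
        assert R[0, 1] == pytest.approx(1.0)

    def test_orthogonalised_columns(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        x = x - x.mean()
        y = y - y.mean()
        y = y - x * (x @ y) / (x @ x)  # exact zero sample correlation
        R = timepoint_correlation(self.make_processed(np.column_stack([x, y])))
        assert abs(R[0, 1]) < 1e-12

    def test_matches_double_loop(self, rng):
        X = rng.standard_normal((40, 5))
        R = timepoint_correlation(self.make_processed(X))
        for j in range(5):
            for k in range(5):
                num = np.mean((X[:, j] - X[:, j].mean()) * (X[:, k] - X[:, k].mean()))
                den = X[:, j].std() * X[:, k].std()
                assert R[j, k] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_errors(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            timepoint_correlation(self.make_processed(X))

    def test_partial_removes_shared_baseline(self, rng):
        base = rng.standard_normal(500)
        X = base[:, None] + 0.1 * rng.standard_normal((500, 4))
        proc = self.make_processed(X)
        raw = timepoint_correlation(proc)
        part = timepoint_correlation(proc, partial=True)
        iu = np.triu_indices(4, 1)
        assert raw[iu].mean() > 0.9
        assert abs(part[iu].mean()) < 0.5


class TestPrepostContrast:
    def test_equal_effects_null_identity(self):
        eff = TimepointEffects(beta_hat=[0.1, 0.1, 0.1, 0.1], se=[0.01] * 4,
                               prenatal=[True, True, False, False], R=np.eye(4))
        res = prepost_contrast(eff)
        assert res.delta == 0.0 and res.z == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        eff = TimepointEffects(beta_hat=[0.02, 0.01, -0.01, -0.02],
                               se=[0.01] * 4,
                               prenatal=[True, True, False, False], R=np.eye(4))
        res = prepost_contrast(eff)
        assert res.delta == pytest.approx(0.03)
        assert res.se_delta == pytest.approx(0.01)
        assert res.z == pytest.approx(3.0)
        assert res.p == pytest.approx(0.0026997, rel=1e-3)
        assert res.mu_pre_hat == pytest.approx(0.015)
        assert res.mu_post_hat == pytest.approx(-0.015)

    def test_delta_equals_coding_vector_product(self):
        eff = TimepointEffects(beta_hat=[0.3, -0.1, 0.2], se=[0.05, 0.04, 0.03],
                               prenatal=[True, False, False], R=np.eye(3))
        res = prepost_contrast(eff)
        assert res.delta == pytest.approx(res.D @ eff.beta_hat)
        assert res.delta == pytest.approx(res.mu_pre_hat - res.mu_post_hat)

    def test_perfectly_correlated_variance_degenerates(self):
        eff = TimepointEffects(beta_hat=[0.1, 0.2, 0.0, 0.1], se=[0.01] * 4,
                               prenatal=[True, True, False, False],
                               R=np.ones((4, 4)))
        with pytest.raises(ValueError, match="degenerate contrast variance"):
            prepost_contrast(eff)

    def test_permutation_invariance_within_group(self, rng):
        beta = np.array([0.05, 0.02, -0.01, -0.03, 0.01])
        se = np.array([0.01, 0.02, 0.015, 0.01, 0.02])
        pre = np.array([True, True, True, False, False])
        R = np.eye(5)
        res1 = prepost_contrast(TimepointEffects(beta, se, pre, R))
        perm = [1, 2, 0, 3, 4]  # shuffle the prenatal block only
        res2 = prepost_contrast(TimepointEffects(
            beta[perm], se[perm], pre[perm], R[np.ix_(perm, perm)]))
        assert res1.z == pytest.approx(res2.z, abs=1e-12)

    def test_reduces_to_two_sample_z(self):
        # R = I and equal se: z = (mean_pre - mean_post)/(s*sqrt(1/K1+1/K2))
        beta = np.array([0.04, 0.01, -0.02, -0.05, 0.00])
        se = np.full(5, 0.02)
        pre = np.array([True, True, False, False, False])
        res = prepost_contrast(TimepointEffects(beta, se, pre, np.eye(5)))
        expected = (beta[:2].mean() - beta[2:].mean()) / (
            0.02 * np.sqrt(1 / 2 + 1 / 3))
        assert res.z == pytest.approx(expected, abs=1e-12)

    def test_calibrated_under_assumed_sampling_model(self, rng):
        # when beta_hat really is MVN(0, SRS), rejection at 0.05 is 5%
        k = 8
        pre = np.array([True] * 3 + [False] * 5)
        se = rng.uniform(0.01, 0.03, k)
        A = rng.standard_normal((k, k))
        cov = A @ A.T + np.eye(k)
        dd = np.sqrt(np.diag(cov))
        R = cov / np.outer(dd, dd)
        S = np.diag(se)
        L = np.linalg.cholesky(S @ R @ S)
        nsim = 20_000
        draws = (L @ rng.standard_normal((k, nsim)))
        rejections = 0
        D = np.where(pre, 1 / 3, -1 / 5)
        var = D @ S @ R @ S @ D
        zstat = (D @ draws) / np.sqrt(var)
        pvals = 2 * stats.norm.sf(np.abs(zstat))
        rate = (pvals < 0.05).mean()
        assert abs(rate - 0.05) < 0.01
        # spot-check one draw through the public function
        res = prepost_contrast(TimepointEffects(draws[:, 0], se, pre, R))
        assert res.z == pytest.approx(zstat[0], abs=1e-12)

    def test_needs_both_groups(self):
        with pytest.raises(ValueError, match="at least one"):
            prepost_contrast(TimepointEffects([0.1, 0.2], [0.1, 0.1],
                                              [True, True], np.eye(2)))


class TestPipelineAndIO:
    def test_pipeline_recovers_prenatal_shift(self):
        # strong opposite pre/post coupling should give delta > 0
        assoc, raw, _ = simulate_gene_level(
            n_genes=1500, effect_pre=0.5, effect_post=-0.5, noise_sd=0.5, seed=7
        )
        table, contrast, expr = temporal_contrast_pipeline(assoc, raw)
        assert contrast.delta > 0
        assert contrast.p < 0.05
        assert len(table) == len(expr.timepoints)

    def test_filter_exercise_genes_are_removed(self):
        assoc, raw, _ = simulate_gene_level(
            n_genes=300, n_low_expression=25, n_missing_id=10, seed=1
        )
        expr = preprocess_expression(raw)
        rep = expr.filter_report
        # the 25 constructed low-expression genes are guaranteed removals;
        # ordinary genes can also fall below the floor (log-normal tail)
        assert rep["removed_low_expression"] >= 25
        low_ids = {f"G{i}" for i in range(300, 325)}
        assert low_ids.isdisjoint(set(expr.gene_ids))
        # no blank ids survive
        assert all(str(g) for g in expr.gene_ids)
        assert rep["removed_missing_id"] <= 10
        assert rep["input_genes"] - rep["output_genes"] == (
            rep["removed_low_expression"] + rep["removed_missing_id"]
            + rep["removed_not_brain_gene"]
        )

    def test_expression_file_roundtrip(self, tmp_path):
        _, raw, _ = simulate_gene_level(n_genes=20, seed=2)
        write_expression(raw, tmp_path / "expr.tsv", tmp_path / "samples.tsv")
        back = read_expression(tmp_path / "expr.tsv", tmp_path / "samples.tsv")
        assert back.gene_ids == raw.gene_ids
        assert back.age_labels == raw.age_labels
        assert np.allclose(back.rpkm, raw.rpkm, rtol=1e-5)
        assert np.array_equal(back.prenatal, raw.prenatal)
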