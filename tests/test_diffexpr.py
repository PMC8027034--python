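import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modevol.diffexpr import (bh_adjust, condition_design,
                              estimate_dispersions, fit_nb_glm, lrt_contrast,
                              standardize_expression, tmm_norm_factors)
from .conftest import make_count_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def tmm_factor_oracle(obs, ref, trim_m=0.3, trim_a=0.05):
    """Direct, unvectorized evaluation of the trimmed-mean-of-M formula."""
    n_obs, n_ref = obs.sum(), ref.sum()
    m, a, w = [], [], []
    for o, r in zip(obs, ref):
        if o == 0 or r == 0:
            continue
        m.append(np.log2((o / n_obs) / (r / n_ref)))
        a.append(0.5 * np.log2((o / n_obs) * (r / n_ref)))
        w.append((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    m, a, w = map(np.array, (m, a, w))
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    return 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def poisson_irls_oracle(y, X, tol=1e-10):
    """Plain textbook Poisson IRLS, independent of the NB implementation."""
    beta = np.zeros(X.shape[1])
    mu = np.maximum(y.astype(float), 0.5)
    eta = np.log(mu)
    beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    for _ in range(200):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        new = np.linalg.solve(X.T @ (mu[:, None] * X), X.T @ (mu * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def bh_oracle(p):
    """Direct evaluation of the step-up formula."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n / rank * p[i])
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        y = np.tile(np.arange(1, 101)[:, None], (1, 2))
        nf = tmm_norm_factors(y)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=200)
        y = np.column_stack([a, 2 * a])
        nf = tmm_norm_factors(y)
        assert np.allclose(nf.factors, 1.0, atol=1e-12)

    def test_asymmetric_upregulation_matches_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(100, size=200) + 1
        b = a.copy()
        b[:10] *= 5  # 10 genes 5-fold up in sample B only
        y = np.column_stack([a, b])
        nf = tmm_norm_factors(y)
        assert nf.factors[1] < 1.0
        raw = tmm_factor_oracle(b.astype(float), a.astype(float))
        # implementation rescales the two factors to geometric mean 1
        expected = np.array([1.0, raw]) / np.sqrt(raw)
        assert np.allclose(nf.factors, expected, rtol=1e-10)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check against edgeR's calcNormFactors via Rscript."""
        import subprocess
        rng = np.random.default_rng(1)
        y = rng.poisson(100, size=(300, 4)) + 1
        y[:15, 1] *= 4
        counts_path = tmp_path / "counts.tsv"
        np.savetxt(counts_path, y, fmt="%d", delimiter="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'y <- as.matrix(read.table("{counts_path}"))\n'
            'cat(calcNormFactors(y, method="TMM"), "\\n")\n')
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        reference = np.array([float(x) for x in proc.stdout.split()])
        ours = tmm_norm_factors(y).factors
        assert np.allclose(ours, reference, rtol=1e-5)

    def test_all_zero_sample_rejected(self):
        y = np.column_stack([np.arange(1, 11), np.zeros(10, dtype=int)])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_norm_factors(y)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(30, size=(300, 6))
        nf = tmm_norm_factors(y)
        assert np.isclose(np.exp(np.mean(np.log(nf.factors))), 1.0)


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------

class TestNBGLM:
    def test_intercept_only_fits_log_mean(self):
        fit = fit_nb_glm(np.array([2, 4, 6]), np.ones((3, 1)), 0.0, 0.1)
        assert np.isclose(fit.coef[0, 0], np.log(4.0), atol=1e-8)

    def test_poisson_limit_matches_independent_irls(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        y = rng.poisson([5, 5, 5, 5, 20, 20, 20, 20])
        fit = fit_nb_glm(y, X, 0.0, 0.0)
        oracle = poisson_irls_oracle(y.astype(float), X)
        assert np.allclose(fit.coef[0], oracle, atol=1e-6)

    def test_two_group_log2fc_consistency(self):
        rng = np.random.default_rng(4)
        n = 200
        X = np.zeros((2 * n, 2))
        X[:n, 0] = 1
        X[n:, 1] = 1
        y = np.concatenate([rng.poisson(10, n), rng.poisson(40, n)])
        fit = fit_nb_glm(y, X, 0.0, 0.0)
        log2fc = (fit.coef[0, 1] - fit.coef[0, 0]) / np.log(2)
        assert abs(log2fc - 2.0) < 0.15

    def test_non_full_rank_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="full rank"):
            fit_nb_glm(np.arange(6), X)


class TestLRT:
    def test_equal_group_means_give_null_result(self):
        X = np.zeros((6, 2))
        X[:3, 0] = 1
        X[3:, 1] = 1
        y = np.array([10, 10, 10, 10, 10, 10])
        fit = fit_nb_glm(y, X, 0.0, 0.05)
        res = lrt_contrast(fit, np.array([1.0, -1.0]))
        assert abs(res["log2FC"].iloc[0]) < 1e-6
        assert res["pvalue"].iloc[0] > 0.99

    def test_zero_contrast_rejected(self):
        fit = fit_nb_glm(np.array([1, 2, 3]), np.ones((3, 1)))
        with pytest.raises(ValueError, match="zeros"):
            lrt_contrast(fit, np.array([0.0]))

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(5)
        G, n = 500, 5
        X = np.zeros((2 * n, 2))
        X[:n, 0] = 1
        X[n:, 1] = 1
        phi = 0.05
        mu = np.hstack([np.full((G, n), 100.0), np.full((G, n), 400.0)])
        y = rng.poisson(rng.gamma(1 / phi, mu * phi))
        fit = fit_nb_glm(y, X, 0.0, phi)
        res = lrt_contrast(fit, np.array([-1.0, 1.0]))
        inside = np.mean((res["log2FC"] > 1.6) & (res["log2FC"] < 2.4))
        assert inside >= 0.90


class TestDispersion:
    def test_poisson_counts_give_tiny_common_dispersion(self):
        rng = np.random.default_rng(6)
        X = np.zeros((10, 2))
        X[:5, 0] = 1
        X[5:, 1] = 1
        y = rng.poisson(100.0, size=(500, 10))
        d = estimate_dispersions(y, X, 0.0)
        assert d.common <= 0.01

    def test_saturated_design_rejected(self):
        X = np.eye(3)
        with pytest.raises(ValueError, match="saturated"):
            estimate_dispersions(np.array([[1, 2, 3]]), X)

    def test_shrinkage_limits(self):
        rng = np.random.default_rng(7)
        X = np.zeros((10, 2))
        X[:5, 0] = 1
        X[5:, 1] = 1
        y = rng.poisson(rng.gamma(10.0, 10.0, size=(50, 10)))
        strong = estimate_dispersions(y, X, prior_df=1e9)
        weak = estimate_dispersions(y, X, prior_df=1e-9)
        assert np.allclose(strong.tagwise, strong.common, rtol=1e-3)
        assert np.allclose(weak.tagwise, weak.per_gene_mle, rtol=1e-3)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_evaluated_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert np.allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_direct_step_up_and_bounds(self, pvals):
        adj = bh_adjust(pvals)
        assert np.allclose(adj, bh_oracle(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)


# ---------------------------------------------------------------------------
# standardized expression
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(8)
        table = make_count_table(rng.poisson(40, size=(50, 15)))
        std = standardize_expression(table)
        assert np.allclose(std.sum(axis=1), 0.0, atol=1e-9)

    def test_flat_gene_is_all_zero(self):
        counts = np.full((20, 15), 7)
        std = standardize_expression(make_count_table(counts))
        assert np.allclose(std.to_numpy(), 0.0, atol=1e-9)

    def test_pine_only_gene_sign_logic(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(40, size=(60, 15))
        conds = (["spruce", "pine", "SCD"] * 5)
        pine_cols = [i for i, c in enumerate(conds) if c == "pine"]
        counts[0] = 0
        counts[0, pine_cols] = 200
        std = standardize_expression(make_count_table(counts, conditions=conds))
        assert std.iloc[0]["pine"] > 0
        assert std.iloc[0]["spruce"] < 0 and std.iloc[0]["SCD"] < 0

    def test_missing_condition_rejected(self):
        counts = np.full((10, 4), 5)
        with pytest.raises(ValueError, match="missing condition"):
            standardize_expression(
                make_count_table(counts, conditions=["spruce"] * 2 + ["pine"] * 2))


def test_condition_design_shape():
    X, levels = condition_design(["spruce", "pine", "SCD", "spruce"])
    assert X.shape == (4, 3)
    assert levels == ["spruce", "pine", "SCD"]
    assert np.all(X.sum(axis=1) == 1)
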