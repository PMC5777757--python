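import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.linear_model import Ridge

from chemoscreen.datatypes import (
    ChemoscreenError,
    DrugResponseTable,
    ExpressionMatrix,
    RunConfig,
)
from chemoscreen.imputation import (
    filter_low_variance,
    fit_ridge,
    homogenize,
    impute_all,
    intersect_genes,
    predict_ic50,
)


def _expr(values, genes=None, samples=None, platform=""):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), platform
    )


# ---------------------------------------------------------------------------
# gene intersection


def test_intersect_genes_shared_subset():
    a = _expr(np.arange(6).reshape(3, 2), genes=["A", "B", "C"])
    b = _expr(np.arange(6).reshape(3, 2), genes=["B", "C", "D"])
    ia, ib = intersect_genes(a, b)
    assert ia.gene_ids == ib.gene_ids == ["B", "C"]


def test_intersect_genes_identity_and_order():
    a = _expr(np.arange(8).reshape(4, 2), genes=["A", "B", "C", "D"])
    ia, ib = intersect_genes(a, a)
    assert ia.gene_ids == a.gene_ids
    # shuffled test gene order: outputs still in identical (train) order
    shuffled = a.subset_genes(["D", "A", "C", "B"])
    ia, ib = intersect_genes(a, shuffled)
    assert ia.gene_ids == ib.gene_ids == ["A", "B", "C", "D"]
    pd.testing.assert_frame_equal(ia.data, ib.data)


def test_intersect_genes_too_few_shared():
    a = _expr([[1.0, 2.0]], genes=["A"])
    b = _expr([[1.0, 2.0]], genes=["B"])
    with pytest.raises(ChemoscreenError, match="shared"):
        intersect_genes(a, b)


# ---------------------------------------------------------------------------
# quantile normalization


def test_homogenize_worked_example():
    train = _expr([[2.0], [4.0], [6.0]], samples=["A"])
    test = _expr([[3.0], [5.0], [7.0]], samples=["B"])
    ht, hs = homogenize(train, test)
    np.testing.assert_allclose(ht.values[:, 0], [2.5, 4.5, 6.5])
    np.testing.assert_allclose(hs.values[:, 0], [2.5, 4.5, 6.5])


def test_homogenize_fixed_point():
    train = _expr([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    test = _expr([[1.0], [2.0], [3.0]], samples=["t0"])
    ht, hs = homogenize(train, test)
    np.testing.assert_allclose(ht.values, train.values)
    np.testing.assert_allclose(hs.values, test.values)
    # idempotence on arbitrary input
    rng = np.random.default_rng(3)
    a, b = _expr(rng.normal(size=(10, 4))), _expr(rng.normal(size=(10, 3)))
    h1a, h1b = homogenize(a, b)
    h2a, h2b = homogenize(h1a, h1b)
    np.testing.assert_allclose(h1a.values, h2a.values)
    np.testing.assert_allclose(h1b.values, h2b.values)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(3, 12), st.integers(1, 5), st.integers(1, 5))
def test_homogenize_defining_property(seed, n_genes, n_train, n_test):
    """Every pooled sample shares one sorted value vector afterwards."""
    rng = np.random.default_rng(seed)
    a = _expr(rng.normal(size=(n_genes, n_train)))
    b = _expr(rng.normal(size=(n_genes, n_test)), samples=[f"t{i}" for i in range(n_test)])
    ha, hb = homogenize(a, b)
    pooled = np.concatenate([ha.values, hb.values], axis=1)
    sorted_cols = np.sort(pooled, axis=0)
    np.testing.assert_allclose(sorted_cols, sorted_cols[:, [0]] * np.ones((1, pooled.shape[1])))


def test_homogenize_zero_variance_sample_named():
    train = _expr([[1.0, 5.0], [1.0, 6.0], [1.0, 7.0]], samples=["flat", "ok"])
    test = _expr([[1.0], [2.0], [3.0]], samples=["t0"])
    with pytest.raises(ChemoscreenError, match="flat"):
        homogenize(train, test)


def test_homogenize_requires_identical_gene_lists():
    a = _expr(np.ones((2, 2)) + np.arange(4).reshape(2, 2), genes=["A", "B"])
    b = _expr(np.ones((2, 2)) + np.arange(4).reshape(2, 2), genes=["B", "A"])
    with pytest.raises(ChemoscreenError, match="gene lists"):
        homogenize(a, b)


# ---------------------------------------------------------------------------
# variance filter


def test_filter_low_variance_identity_top_and_ties():
    base = np.outer([0.0, 1.0, 2.0, 3.0], [1.0, -1.0, 0.5])  # variances 0,v,4v,9v
    expr = _expr(base, genes=["d", "c", "b", "a"])
    assert filter_low_variance(expr, 1.0) is expr
    kept = filter_low_variance(expr, 0.5)
    assert kept.gene_ids == ["b", "a"]  # top-2 variance, original order
    # exact tie: two genes with equal variance, lexicographically smaller wins
    tied = _expr(
        [[0.0, 1.0], [0.0, 1.0], [0.0, 3.0]], genes=["zeta", "alpha", "big"]
    )
    kept = filter_low_variance(tied, 0.5)
    assert kept.gene_ids == ["alpha", "big"]


# ---------------------------------------------------------------------------
# ridge


def _toy():
    expr = _expr([[-1.0, 0.0, 1.0]], genes=["x"], samples=["a", "b", "c"])
    y = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    return expr, y


def test_fit_ridge_closed_form_example():
    """One centered feature, fixed penalty: slope Sxy/(Sxx+lam), unpenalized
    intercept; prediction at the training mean is the response mean."""
    expr, y = _toy()
    cfg = RunConfig(seed=0, cv_folds=3)
    model = fit_ridge(expr, y, cfg, penalty=1.0)
    assert model.coefficients[0] == pytest.approx(2.0 / 3.0, abs=1e-12)
    assert model.intercept == pytest.approx(2.0, abs=1e-12)
    at0 = predict_ic50(model, _expr([[0.0]], genes=["x"], samples=["q"]))
    assert at0.iloc[0] == pytest.approx(2.0, abs=1e-12)
    at2 = predict_ic50(model, _expr([[2.0]], genes=["x"], samples=["q"]))
    assert at2.iloc[0] == pytest.approx(2.0 + 2.0 * 2.0 / 3.0, abs=1e-12)


def test_fit_ridge_lambda_zero_is_ols():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(4, 12))  # 4 genes x 12 samples: n > p, full rank
    y = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
    expr = _expr(X)
    cfg = RunConfig(seed=0, cv_folds=3)
    model = fit_ridge(expr, y, cfg, penalty=0.0)
    Z = (X.T - X.T.mean(0)) / X.T.std(0, ddof=1)
    beta_ols = np.linalg.lstsq(
        np.column_stack([np.ones(12), Z]), y.to_numpy(), rcond=None
    )[0]
    np.testing.assert_allclose(model.coefficients, beta_ols[1:], atol=1e-10)
    # in-sample predictions reproduce OLS fitted values
    fitted = predict_ic50(model, expr)
    np.testing.assert_allclose(
        fitted.to_numpy(), np.column_stack([np.ones(12), Z]) @ beta_ols, atol=1e-10
    )


def test_fit_ridge_constant_response(caplog):
    expr, _ = _toy()
    y = pd.Series([4.0, 4.0, 4.0], index=["a", "b", "c"])
    with caplog.at_level("WARNING"):
        model = fit_ridge(expr, y, RunConfig(seed=0, cv_folds=3))
    assert "constant response" in caplog.text
    pred = predict_ic50(model, _expr([[9.0, -4.0]], genes=["x"]))
    np.testing.assert_allclose(pred.to_numpy(), [4.0, 4.0])


def test_fit_ridge_too_few_samples():
    expr, y = _toy()
    with pytest.raises(ChemoscreenError, match="cv_folds"):
        fit_ridge(expr, y, RunConfig(seed=0, cv_folds=10))


def test_ridge_matches_sklearn_cross_check():
    """Independent route: sklearn Ridge on the standardized design."""
    rng = np.random.default_rng(7)
    for lam in (0.5, 3.0, 50.0):
        X = rng.normal(size=(8, 20))  # 8 genes x 20 samples
        y = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        expr = _expr(X)
        model = fit_ridge(expr, y, RunConfig(seed=0, cv_folds=4), penalty=lam)
        Z = (X.T - X.T.mean(0)) / X.T.std(0, ddof=1)
        sk = Ridge(alpha=lam, fit_intercept=True, solver="cholesky").fit(Z, y)
        np.testing.assert_allclose(model.coefficients, sk.coef_, atol=1e-8)
        assert model.intercept == pytest.approx(sk.intercept_, abs=1e-8)


def test_ridge_shrinkage_monotone_in_penalty():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(15, 12))
    y = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
    expr = _expr(X)
    cfg = RunConfig(seed=0, cv_folds=3)
    norms = [
        np.linalg.norm(fit_ridge(expr, y, cfg, penalty=lam).coefficients)
        for lam in cfg.ridge_penalty_grid
    ]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


def test_cv_selects_from_grid_and_reports_correlation(small_study):
    expr, response, truth, _, _ = small_study
    cfg = RunConfig(seed=0, cv_folds=5)
    model = fit_ridge(expr, response.data[truth.planted_candidates[0]], cfg,
                      drug_id=truth.planted_candidates[0])
    assert model.penalty in cfg.ridge_penalty_grid
    assert -1.0 <= model.training_summary["cv_correlation"] <= 1.0
    # a drug with real expression signal should cross-validate well
    assert model.training_summary["cv_correlation"] > 0.5


def test_predict_missing_model_gene_listed():
    expr, y = _toy()
    model = fit_ridge(expr, y, RunConfig(seed=0, cv_folds=3), penalty=1.0)
    with pytest.raises(ChemoscreenError, match="x"):
        predict_ic50(model, _expr([[1.0]], genes=["other"]))


def test_prediction_invariant_to_sample_permutation(small_study):
    expr, response, truth, cohorts, _ = small_study
    cfg = RunConfig(seed=0, cv_folds=5)
    cohort = cohorts[0]
    perm = cohort.data.sample(frac=1.0, axis=1, random_state=1)
    permuted = ExpressionMatrix(perm, cohort.platform)
    (p1,) = impute_all(expr, response, [cohort], cfg)
    (p2,) = impute_all(expr, response, [permuted], cfg)
    pd.testing.assert_frame_equal(
        p1.data.loc[p2.data.index], p2.data, atol=1e-9, rtol=0
    )


# ---------------------------------------------------------------------------
# panel imputation


def test_impute_all_shapes_and_determinism(small_study):
    expr, response, truth, cohorts, _ = small_study
    cfg = RunConfig(seed=0, cv_folds=5)
    preds1 = impute_all(expr, response, [cohorts[0], cohorts[0]], cfg)
    assert preds1[0].data.shape == (120, 16)
    pd.testing.assert_frame_equal(preds1[0].data, preds1[1].data)


def test_impute_all_requires_log_ic50(small_study):
    expr, response, _, cohorts, _ = small_study
    auc = DrugResponseTable(response.data.copy(), measure="auc")
    with pytest.raises(ChemoscreenError, match="log_ic50"):
        impute_all(expr, auc, [cohorts[0]], RunConfig(seed=0))


def test_impute_recovers_held_out_response():
    """Train on part of a panel, impute the held-out lines, and check the
    predictions track the true log-IC50 of a planted drug."""
    expr, response, truth = __import__("chemoscreen.synthetic", fromlist=["x"]).generate_cell_line_panel(
        n_lines=160, n_genes=300, n_drugs=12, n_candidates=2, seed=21
    )
    train_lines = expr.sample_ids[:120]
    test_lines = expr.sample_ids[120:]
    train = ExpressionMatrix(expr.data[train_lines], "panel")
    test = ExpressionMatrix(expr.data[test_lines], "heldout")
    train_resp = DrugResponseTable(response.data.loc[train_lines], "log_ic50")
    cfg = RunConfig(seed=0, cv_folds=5)
    (pred,) = impute_all(train, train_resp, [test], cfg)
    drug = truth.planted_candidates[0]
    r, p = stats.pearsonr(pred.data[drug], response.data.loc[test_lines, drug])
    assert r > 0
    assert p < 0.01
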