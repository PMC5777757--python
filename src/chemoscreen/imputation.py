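"""Expression-to-IC50 imputation.

Per-drug ridge models are trained on a cell-line panel (log-scale
expression vs log-IC50), after pooling the panel with each target cohort
through quantile normalization so the linear model transfers across
platforms. The ridge problem is solved in closed form on standardized
features with the intercept unpenalized; the penalty is chosen per drug
by k-fold cross-validated mean squared error over a configured grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .datatypes import (
    ChemoscreenError,
    DrugResponseTable,
    ExpressionMatrix,
    PredictionMatrix,
    RunConfig,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RidgeModel",
    "intersect_genes",
    "homogenize",
    "filter_low_variance",
    "fit_ridge",
    "predict_ic50",
    "impute_all",
]


# ---------------------------------------------------------------------------
# preprocessing


def intersect_genes(
    train: ExpressionMatrix, test: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in identical order.

    The shared order follows the training matrix. Fewer than 2 shared
    genes is an error.
    """
    test_genes = set(test.gene_ids)
    shared = [g for g in train.gene_ids if g in test_genes]
    if len(shared) < 2:
        raise ChemoscreenError(
            f"only {len(shared)} gene(s) shared between matrices; need >= 2"
        )
    return train.subset_genes(shared), test.subset_genes(shared)


def homogenize(
    train: ExpressionMatrix, test: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Pooled quantile normalization of train and test onto one distribution.

    All samples of both matrices are pooled; the reference quantile
    vector is the mean of the per-sample sorted value vectors; every
    sample's values are then replaced by the reference values at its
    value ranks (ties resolved by stable within-sample order). After the
    call the sorted value vector of every sample, train or test, equals
    the reference exactly.
    """
    if train.gene_ids != test.gene_ids:
        raise ChemoscreenError(
            "train and test gene lists differ; run intersect_genes first"
        )
    pooled = np.concatenate([train.values, test.values], axis=1)
    stds = pooled.std(axis=0)
    if (stds == 0).any():
        ids = train.sample_ids + test.sample_ids
        bad = [ids[i] for i in np.flatnonzero(stds == 0)]
        raise ChemoscreenError(f"zero-variance sample(s): {bad[:5]}")
    order = np.argsort(pooled, axis=0, kind="stable")
    reference = np.sort(pooled, axis=0).mean(axis=1)
    out = np.empty_like(pooled)
    np.put_along_axis(out, order, reference[:, None], axis=0)
    n_train = train.n_samples
    new_train = ExpressionMatrix(
        pd.DataFrame(out[:, :n_train], index=train.data.index, columns=train.data.columns),
        train.platform,
    )
    new_test = ExpressionMatrix(
        pd.DataFrame(out[:, n_train:], index=test.data.index, columns=test.data.columns),
        test.platform,
    )
    return new_train, new_test


def filter_low_variance(
    expr: ExpressionMatrix, keep_fraction: float
) -> ExpressionMatrix:
    """Keep the ceil(keep_fraction * n_genes) highest-variance genes.

    Variance is computed on ``expr`` (the training portion); the original
    gene order is preserved; exact variance ties are broken in favour of
    lexicographically smaller gene ids.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ChemoscreenError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return expr
    k = int(np.ceil(keep_fraction * expr.n_genes))
    variances = pd.Series(expr.values.var(axis=1, ddof=1), index=expr.data.index)
    ranked = variances.to_frame("var")
    ranked["gene"] = ranked.index
    keep = set(
        ranked.sort_values(["var", "gene"], ascending=[False, True]).head(k).index
    )
    kept_order = [g for g in expr.gene_ids if g in keep]
    return expr.subset_genes(kept_order)


# ---------------------------------------------------------------------------
# ridge


@dataclass
class RidgeModel:
    """A fitted per-drug ridge model on standardized expression features."""

    drug_id: str
    gene_ids: list
    coefficients: np.ndarray  # on the standardized-feature scale
    intercept: float
    penalty: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.gene_ids):
            raise ChemoscreenError("coefficient/gene length mismatch")


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize (mean 0, sample sd 1); zero-sd columns flagged by sd=0."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = np.zeros_like(X)
    ok = sd > 0
    Z[:, ok] = (X[:, ok] - mean[ok]) / sd[ok]
    return Z, mean, sd


def _ridge_solve(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Solve min ||y - b0 - Z beta||^2 + lam ||beta||^2 with b0 unpenalized.

    ``Z`` need not be exactly column-centered (e.g. a CV fold of globally
    standardized data); columns are centered here so the intercept stays
    unpenalized. ``lam == 0`` falls back to a least-squares solve.
    """
    col_mean = Z.mean(axis=0)
    Zc = Z - col_mean
    ybar = y.mean()
    yc = y - ybar
    n, p = Zc.shape
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(Zc, yc, rcond=None)
    elif p > n:
        # dual form: beta = Z' (ZZ' + lam I)^-1 y
        K = Zc @ Zc.T
        K.flat[:: n + 1] += lam
        beta = Zc.T @ np.linalg.solve(K, yc)
    else:
        G = Zc.T @ Zc
        G.flat[:: p + 1] += lam
        beta = np.linalg.solve(G, Zc.T @ yc)
    intercept = ybar - col_mean @ beta
    return beta, intercept


def fit_ridge(
    train_expr: ExpressionMatrix,
    response,
    config: RunConfig,
    drug_id: str = "drug",
    penalty: float | None = None,
) -> RidgeModel:
    """Fit one drug's ridge model.

    ``response`` is a per-sample vector (Series indexed by sample id, or
    array aligned with the matrix columns); missing entries are dropped.
    The penalty is selected from ``config.ridge_penalty_grid`` by k-fold
    CV MSE with seeded fold assignment (ties prefer the smallest
    penalty), unless ``penalty`` fixes it. ``training_summary`` carries
    n_train, the grid, and the held-out Pearson ``cv_correlation`` at
    the chosen penalty.
    """
    y = pd.Series(response, index=train_expr.data.columns if not isinstance(response, pd.Series) else None)
    if isinstance(response, pd.Series):
        y = response.reindex(train_expr.data.columns)
    mask = y.notna().to_numpy()
    n = int(mask.sum())
    if n < config.cv_folds:
        raise ChemoscreenError(
            f"{drug_id}: {n} non-missing responses < cv_folds={config.cv_folds}"
        )
    X = train_expr.values.T[mask]  # n x p
    yv = y.to_numpy(dtype=float)[mask]

    if np.ptp(yv) == 0.0:
        logger.warning("%s: constant response; returning intercept-only model", drug_id)
        return RidgeModel(
            drug_id, [], np.zeros(0), float(yv[0]), 0.0, np.zeros(0), np.zeros(0),
            {"n_train": n, "cv_correlation": float("nan"),
             "penalty_grid": list(config.ridge_penalty_grid), "constant_response": True},
        )

    Z, mean, sd = _standardize_train(X)
    grid = list(config.ridge_penalty_grid)

    if penalty is not None:
        lam = float(penalty)
        cv_corr = float("nan")
    else:
        mse, heldout = _cv_mse(Z, yv[:, None], grid, config.cv_folds, config.seed)
        best = int(np.argmin(mse[:, 0]))  # ascending grid: first min = smallest lam
        lam = grid[best]
        with np.errstate(invalid="ignore"):
            cv_corr = float(stats.pearsonr(heldout[:, best, 0], yv)[0])

    beta, intercept = _ridge_solve(Z, yv, lam)
    return RidgeModel(
        drug_id=drug_id,
        gene_ids=train_expr.gene_ids,
        coefficients=beta,
        intercept=float(intercept),
        penalty=float(lam),
        feature_mean=mean,
        feature_sd=sd,
        training_summary={
            "n_train": n,
            "cv_correlation": cv_corr,
            "penalty_grid": grid,
        },
    )


def _cv_mse(
    Z: np.ndarray, Y: np.ndarray, grid: Sequence[float], folds: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """K-fold held-out MSE for every (penalty, drug) pair, vectorized.

    ``Z``: n x p standardized features; ``Y``: n x d responses (no
    missing). Returns (len(grid) x d MSE matrix, n x len(grid) x d
    held-out prediction array). One eigendecomposition of the fold Gram
    matrix serves every drug and penalty.
    """
    n, p = Z.shape
    d = Y.shape[1]
    heldout = np.empty((n, len(grid), d))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(Z):
        Ztr = Z[tr] - Z[tr].mean(axis=0)
        Zte = Z[te] - Z[tr].mean(axis=0)
        ybar = Y[tr].mean(axis=0)
        Ytr = Y[tr] - ybar
        K = Ztr @ Ztr.T
        evals, U = np.linalg.eigh(K)
        evals = np.maximum(evals, 0.0)
        B = U.T @ Ytr  # ntr x d
        Kx = Zte @ Ztr.T  # nte x ntr
        KxU = Kx @ U
        for j, lam in enumerate(grid):
            denom = evals + lam
            denom[denom < 1e-12] = 1e-12  # lam=0 on singular Gram -> pseudoinverse
            heldout[te, j, :] = KxU @ (B / denom[:, None]) + ybar
    sq = (heldout - Y[:, None, :]) ** 2
    return sq.mean(axis=0), heldout


def predict_ic50(model: RidgeModel, cohort_expr: ExpressionMatrix) -> pd.Series:
    """Predicted log-IC50 per cohort sample (cohort must be homogenized
    with the model's training panel)."""
    if not model.gene_ids:  # intercept-only degenerate model
        return pd.Series(model.intercept, index=cohort_expr.data.columns, name=model.drug_id)
    missing = [g for g in model.gene_ids if g not in cohort_expr.data.index]
    if missing:
        raise ChemoscreenError(
            f"{model.drug_id}: cohort lacks model genes {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    X = cohort_expr.data.loc[model.gene_ids].to_numpy().T  # n x p
    ok = model.feature_sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - model.feature_mean[ok]) / model.feature_sd[ok]
    pred = model.intercept + Z @ model.coefficients
    return pd.Series(pred, index=cohort_expr.data.columns, name=model.drug_id)


# ---------------------------------------------------------------------------
# panel-level imputation


def _fit_panel_and_predict(
    train: ExpressionMatrix,
    response: DrugResponseTable,
    cohort: ExpressionMatrix,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit all drugs against one homogenized (train, cohort) pairing.

    Drugs with complete responses share fold eigendecompositions; drugs
    with missing responses fall back to the per-drug path. Returns
    (predictions samples x drugs, per-drug summary frame).
    """
    Y = response.data.reindex(train.data.columns)
    Xall = train.values.T  # n x p
    Zall, mean, sd = _standardize_train(Xall)

    # cohort on the training standardization
    Xc = cohort.data.loc[train.data.index].to_numpy().T
    ok = sd > 0
    Zc = np.zeros_like(Xc)
    Zc[:, ok] = (Xc[:, ok] - mean[ok]) / sd[ok]

    grid = list(config.ridge_penalty_grid)
    preds: dict[str, np.ndarray] = {}
    summaries = []

    complete = [d for d in Y.columns if Y[d].notna().all() and np.ptp(Y[d].to_numpy()) > 0]
    other = [d for d in Y.columns if d not in complete]

    if complete:
        Yc = Y[complete].to_numpy(dtype=float)
        mse, heldout = _cv_mse(Zall, Yc, grid, config.cv_folds, config.seed)
        best = np.argmin(mse, axis=0)  # per drug; first min = smallest lam
        # final fit: one eigendecomposition, per-penalty groups of drugs
        K = Zall @ Zall.T
        evals, U = np.linalg.eigh(K)
        evals = np.maximum(evals, 0.0)
        ybars = Yc.mean(axis=0)
        B = U.T @ (Yc - ybars)
        ZcU = Zc @ Zall.T @ U  # n_cohort x n_train
        for j in np.unique(best):
            lam = grid[j]
            cols = np.flatnonzero(best == j)
            denom = evals + lam
            denom[denom < 1e-12] = 1e-12
            P = ZcU @ (B[:, cols] / denom[:, None]) + ybars[cols]
            for k, ci in enumerate(cols):
                drug = complete[ci]
                preds[drug] = P[:, k]
                with np.errstate(invalid="ignore"):
                    r = stats.pearsonr(heldout[:, j, ci], Yc[:, ci])[0]
                summaries.append(
                    {"drug_id": drug, "penalty": lam, "cv_correlation": float(r),
                     "n_train": Yc.shape[0]}
                )

    for drug in other:
        try:
            model = fit_ridge(train, Y[drug], config, drug_id=drug)
            preds[drug] = predict_ic50(model, cohort).to_numpy()
            summaries.append(
                {"drug_id": drug, "penalty": model.penalty,
                 "cv_correlation": model.training_summary.get("cv_correlation"),
                 "n_train": model.training_summary.get("n_train")}
            )
        except ChemoscreenError as err:
            logger.warning("skipping drug %s: %s", drug, err)

    pred_df = pd.DataFrame(preds, index=cohort.data.columns)[
        [d for d in Y.columns if d in preds]
    ]
    summary_df = pd.DataFrame(summaries).set_index("drug_id") if summaries else pd.DataFrame()
    return pred_df, summary_df


def impute_all(
    train_expr: ExpressionMatrix,
    train_response: DrugResponseTable,
    cohorts: Sequence[ExpressionMatrix],
    config: RunConfig,
    return_details: bool = False,
):
    """Impute every drug's log-IC50 for every cohort.

    Each cohort is intersected with the training panel, quantile-
    normalized against it independently, the low-variance genes (judged
    on the training portion) dropped, and the full per-drug model panel
    refit for that pairing. Per-drug failures are logged and skipped.

    Returns a list of :class:`PredictionMatrix` (one per cohort), plus a
    list of per-drug summary frames when ``return_details`` is true.
    """
    if train_response.measure != "log_ic50":
        raise ChemoscreenError(
            f"training responses must be log_ic50, got {train_response.measure!r}"
        )
    predictions, details = [], []
    for cohort in cohorts:
        tr, te = intersect_genes(train_expr, cohort)
        tr, te = homogenize(tr, te)
        tr_f = filter_low_variance(tr, config.variance_filter_fraction)
        te_f = te.subset_genes(tr_f.gene_ids)
        pred_df, summary = _fit_panel_and_predict(tr_f, train_response, te_f, config)
        predictions.append(PredictionMatrix(pred_df, platform=cohort.platform))
        details.append(summary)
    if return_details:
        return predictions, details
    return predictions
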