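"""Genotype/expression association with drug sensitivity.

Covers the regression toolkit used to link genomics to IC50: multivariate
OLS on log10 IC50 with effects reported as fold changes, genome-wide
Spearman scans of expression against sensitivity (1/IC50), gene-set shift
tests, regression-based mediation, ElasticNet feature selection with
cross-validated lambda, housekeeping-gene normalization of TPM expression,
and the fold-range summary.

Conventions: expression enters as log2(TPM + 1); regression effects on
log10 IC50 translate to IC50 fold changes as 10^coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

__all__ = [
    "AssociationResult",
    "MediationResult",
    "ElasticNetResult",
    "ols_fit",
    "ic50_fold_effect",
    "expression_sensitivity_scan",
    "gene_set_shift_test",
    "mediation",
    "elasticnet_cv",
    "housekeeping_normalize",
    "fold_range",
]

DEFAULT_HOUSEKEEPING = ("ACTB", "GAPDH")


@dataclass(frozen=True)
class AssociationResult:
    """Per-predictor effects from an OLS model of log10 IC50."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    r_squared: float
    f_pvalue: float
    nobs: int

    def fold_effect(self, predictor: str) -> dict:
        coef = float(self.params[predictor])
        lo, hi = (float(v) for v in self.conf_int.loc[predictor])
        return ic50_fold_effect(coef, (lo, hi))


@dataclass(frozen=True)
class MediationResult:
    marginal_exposure_coef: float
    marginal_exposure_p: float
    conditional_exposure_coef: float
    conditional_exposure_p: float
    conditional_mediator_coef: float
    conditional_mediator_p: float


@dataclass
class ElasticNetResult:
    coefficients: pd.Series  # original scale
    intercept: float
    selected: list[str]
    lambda_: float
    alpha: float
    lambda_grid: np.ndarray
    cv_error: np.ndarray
    coefficients_std: np.ndarray = field(default=None, repr=False)
    dropped: list[str] = field(default_factory=list)


def ols_fit(y, X: pd.DataFrame) -> AssociationResult:
    """Ordinary least squares with intercept; per-coefficient t-tests.

    Raises on rank-deficient designs rather than silently dropping columns.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        raise ValueError("collinear design: X is rank deficient")
    if len(y) <= design.shape[1]:
        raise ValueError("need n > number of parameters")
    model = sm.OLS(y, design).fit()
    ci = model.conf_int()
    ci.columns = ["lower", "upper"]
    return AssociationResult(
        params=model.params,
        bse=model.bse,
        pvalues=model.pvalues,
        conf_int=ci,
        r_squared=float(model.rsquared),
        f_pvalue=float(model.f_pvalue),
        nobs=int(model.nobs),
    )


def ic50_fold_effect(coefficient: float, ci: tuple[float, float] | None = None) -> dict:
    """Translate a log10-IC50 coefficient into a directional fold change.

    A coefficient of +1 is a 10-fold *increase* in IC50 (resistance);
    -1 a 10-fold decrease (sensitization).  The CI transforms monotonically.
    """
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    direction = "increase" if coefficient > 0 else ("decrease" if coefficient < 0 else "none")
    out = {"fold": float(10.0 ** abs(coefficient)), "direction": direction}
    if ci is not None:
        lo, hi = sorted(10.0 ** np.asarray(ci, dtype=float))
        if coefficient < 0:
            # report the CI on the fold-decrease scale (reciprocal ordering)
            lo, hi = 1.0 / hi, 1.0 / lo
        out["fold_ci"] = (float(lo), float(hi))
    return out


def expression_sensitivity_scan(
    expr: pd.DataFrame, sensitivity, min_samples: int = 5
) -> pd.DataFrame:
    """Per-gene Spearman correlation of expression vs a sensitivity vector.

    ``expr`` is genes x samples; ``sensitivity`` is indexed like the
    columns (e.g. 1/IC50).  Constant genes get NaN.  Vectorized: ranks with
    mean-tie handling, then a Pearson correlation of ranks with the
    t-approximation p-value.
    """
    sens = np.asarray(sensitivity, dtype=float)
    n = sens.size
    if expr.shape[1] != n:
        raise ValueError("sensitivity length must match number of samples")
    if n < min_samples:
        raise ValueError(f"need >= {min_samples} paired samples")
    X = expr.to_numpy(dtype=float)
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(sens)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ ry_c) / denom
    rho[denom == 0] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return pd.DataFrame({"spearman_rho": rho, "p_value": p}, index=expr.index)


def gene_set_shift_test(
    per_gene_rhos: pd.Series,
    set_membership,
    mode: str = "unpaired",
    paired_complement: pd.Series | None = None,
) -> tuple[float, float]:
    """Two-sided t-test for a shift of a gene set's correlations.

    ``unpaired`` (default): Welch t-test of in-set vs out-of-set rhos.
    ``paired``: paired t-test against an explicit equal-length pairing
    supplied via ``paired_complement``.
    """
    rhos = pd.Series(per_gene_rhos).dropna()
    members = set(set_membership)
    in_set = rhos[rhos.index.isin(members)]
    if mode == "unpaired":
        out_set = rhos[~rhos.index.isin(members)]
        if in_set.empty or out_set.empty:
            raise ValueError("set and complement must both be non-empty")
        t, p = stats.ttest_ind(in_set, out_set, equal_var=False)
    elif mode == "paired":
        if paired_complement is None or len(paired_complement) != len(in_set):
            raise ValueError("pairing required: supply an equal-length paired vector")
        t, p = stats.ttest_rel(in_set, np.asarray(paired_complement, dtype=float))
    else:
        raise ValueError("mode must be 'unpaired' or 'paired'")
    return float(t), float(p)


def mediation(sensitivity, exposure_expr, mediator_expr) -> MediationResult:
    """Regression-based mediation: marginal y~exposure vs joint y~exposure+mediator.

    Full mediation shows as a significant marginal exposure effect that is
    lost once the mediator enters, while the mediator stays significant.
    """
    y = np.asarray(sensitivity, dtype=float)
    x = np.asarray(exposure_expr, dtype=float)
    m = np.asarray(mediator_expr, dtype=float)
    if not (len(y) == len(x) == len(m)):
        raise ValueError("inputs must be equal length")
    if len(y) < 10:
        raise ValueError("need >= 10 complete triples")
    if abs(np.corrcoef(x, m)[0, 1]) > 0.999:
        raise ValueError("collinear mediator: exposure and mediator are identical")
    marginal = ols_fit(y, pd.DataFrame({"exposure": x}))
    joint = ols_fit(y, pd.DataFrame({"exposure": x, "mediator": m}))
    return MediationResult(
        marginal_exposure_coef=float(marginal.params["exposure"]),
        marginal_exposure_p=float(marginal.pvalues["exposure"]),
        conditional_exposure_coef=float(joint.params["exposure"]),
        conditional_exposure_p=float(joint.pvalues["exposure"]),
        conditional_mediator_coef=float(joint.params["mediator"]),
        conditional_mediator_p=float(joint.pvalues["mediator"]),
    )


def _lambda_grid(Xs, yc, alpha, n_lambda=50, eps=1e-3):
    n = Xs.shape[0]
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def elasticnet_cv(
    X: pd.DataFrame,
    y,
    alpha: float = 0.5,
    k: int = 10,
    lambda_grid=None,
    seed: int | None = None,
    n_lambda: int = 50,
) -> ElasticNetResult:
    """ElasticNet with lambda chosen by k-fold cross-validation.

    Minimizes ``(1/2n)||y - b0 - Xb||^2 + lam*(alpha*||b||_1 +
    (1-alpha)*||b||^2/2)`` on standardized features (intercept
    unpenalized); lambda is the CV-error minimizer; coefficients are
    returned on the original feature scale.  Zero-variance features are
    dropped with a record in ``dropped``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError("too few samples for k folds")
    sd = X.std(axis=0, ddof=0)
    dropped = list(X.columns[sd == 0])
    X = X.loc[:, sd > 0]
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    Xs = ((X - mu) / sd).to_numpy(dtype=float)
    ybar = y.mean()
    yc = y - ybar

    if lambda_grid is None:
        lambda_grid = _lambda_grid(Xs, yc, alpha, n_lambda=n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(Xs))
    order = np.argsort(lambda_grid)[::-1]  # warm-start path from large lambda
    cv_err = np.zeros(lambda_grid.size)
    for train, test in folds:
        est = ElasticNet(alpha=1.0, l1_ratio=alpha, fit_intercept=True,
                         max_iter=50_000, tol=1e-8, warm_start=True)
        for i in order:
            lam = lambda_grid[i]
            if lam == 0:
                model = _enet(Xs[train], yc[train], 0.0, alpha)
            else:
                est.set_params(alpha=lam)
                model = est.fit(Xs[train], yc[train])
            resid = yc[test] - model.predict(Xs[test])
            cv_err[i] += float(np.mean(resid**2))
    cv_err /= len(folds)
    best = int(np.argmin(cv_err))
    lam = float(lambda_grid[best])

    est = _enet(Xs, yc, lam, alpha)
    beta_std = est.coef_
    beta = pd.Series(beta_std / sd.to_numpy(), index=X.columns)
    intercept = float(ybar + est.intercept_ - float(beta @ mu))
    return ElasticNetResult(
        coefficients=beta,
        intercept=intercept,
        selected=list(beta.index[beta_std != 0]),
        lambda_=lam,
        alpha=alpha,
        lambda_grid=lambda_grid,
        cv_error=cv_err,
        coefficients_std=beta_std,
        dropped=dropped,
    )


def _enet(Xs, yc, lam, alpha):
    if lam == 0:
        from sklearn.linear_model import LinearRegression

        return LinearRegression().fit(Xs, yc)
    # sklearn's penalty lam*l1_ratio*||b||_1 + lam*(1-l1_ratio)/2*||b||^2
    # matches the target objective with l1_ratio = alpha
    return ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=True,
        max_iter=50_000, tol=1e-8,
    ).fit(Xs, yc)


def elasticnet_kkt_residual(Xs, yc, beta, intercept, lam, alpha) -> float:
    """Max violation of the ElasticNet subgradient conditions (standardized data)."""
    n = Xs.shape[0]
    grad = Xs.T @ (yc - intercept - Xs @ beta) / n - lam * (1 - alpha) * beta
    active = beta != 0
    viol = np.abs(grad[active] - lam * alpha * np.sign(beta[active]))
    slack = np.maximum(np.abs(grad[~active]) - lam * alpha, 0.0)
    parts = np.concatenate([viol, slack])
    return float(parts.max()) if parts.size else 0.0


def housekeeping_normalize(
    expr: pd.DataFrame, gene: str, housekeeping=DEFAULT_HOUSEKEEPING
) -> pd.Series:
    """log2(TPM+1) of a gene minus the mean over housekeeping genes, per sample."""
    for hk in housekeeping:
        if hk not in expr.index:
            raise ValueError(f"housekeeping gene absent: {hk}")
    if gene not in expr.index:
        raise ValueError(f"gene absent: {gene}")
    log_gene = np.log2(expr.loc[gene].astype(float) + 1.0)
    log_hk = np.log2(expr.loc[list(housekeeping)].astype(float) + 1.0).mean(axis=0)
    return log_gene - log_hk


def fold_range(values) -> float:
    """Max/min ratio of a positive vector (e.g. TPM across tumors)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(v <= 0):
        raise ValueError("non-positive expression")
    return float(v.max() / v.min())
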