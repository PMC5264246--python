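"""Per-balance regression: OLS, linear mixed-effects, and prediction.

Each balance (one ILR coordinate per internal tree node) is regressed
independently against a shared design matrix built from a formula over
the sample covariates.  Because the ILR is an isometry, total and
residual sums of squares pooled over balances do not depend on which
bifurcating tree produced the coordinates, so the global coefficient of
determination

    R^2 = 1 - SSE / SST

(SSE, SST summed over all balances and samples) is a tree-invariant
summary of how much community variation the covariates explain.

Mixed models add a random intercept per grouping level (e.g. patient)
and report Wald p-values for the fixed effects, fitted by REML.
Per-node non-convergence is flagged, not fatal.  Multiple testing across
the D-1 balances is handled by Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .composition import inverse_ilr

__all__ = ["RegressionResult", "fit_ols", "fit_lme", "bonferroni", "predict_proportions"]


def bonferroni(pvalues, alpha: float = 0.05):
    """Bonferroni family-wise correction.

    Returns ``(adjusted, significant)`` with ``adjusted = min(1, p * m)``
    and ``significant = adjusted < alpha``.  NaN p-values (e.g. from
    non-convergent fits) stay NaN and are never significant.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = p[np.isfinite(p)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("bonferroni: p-values must lie in [0, 1]")
    adjusted = np.minimum(p * p.size, 1.0)
    with np.errstate(invalid="ignore"):
        significant = adjusted < alpha
    significant &= np.isfinite(adjusted)
    if isinstance(pvalues, pd.Series):
        return (pd.Series(adjusted, index=pvalues.index),
                pd.Series(significant, index=pvalues.index))
    return adjusted, significant


@dataclass
class RegressionResult:
    """Per-balance fit results.

    Attributes
    ----------
    coefficients : DataFrame indexed by (node, term) with columns
        estimate, stderr, pvalue, pvalue_adj, significant.  Adjusted
        p-values are Bonferroni-corrected across nodes within each term.
    fitted, residual : samples x nodes DataFrames (fitted + residual =
        observed balances for OLS; fixed-effect predictions for LME).
    r_squared : pooled balance-space R^2 (None for mixed models).
    model : human-readable descriptor; formula: the fixed-effect formula.
    grouping : grouping column for mixed models, else None.
    converged : per-node flag (always True for OLS).
    design_info : patsy design info, kept for out-of-sample prediction.
    """

    coefficients: pd.DataFrame
    fitted: pd.DataFrame
    residual: pd.DataFrame
    r_squared: float | None
    model: str
    formula: str
    alpha: float
    grouping: str | None = None
    converged: pd.Series | None = None
    design_info: object = field(default=None, repr=False)
    params: pd.DataFrame = field(default=None, repr=False)  # nodes x terms

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-(node, term) coefficient table for export."""
        out = self.coefficients.reset_index()
        out.insert(0, "model", self.model)
        return out


def _design_matrix(covariates: pd.DataFrame, formula: str) -> pd.DataFrame:
    design = patsy.dmatrix(formula, covariates, return_type="dataframe",
                           NA_action="raise")
    design.index = covariates.index
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # locate columns that add no rank
        bad = []
        kept = np.empty((design.shape[0], 0))
        for name in design.columns:
            cand = np.column_stack([kept, design[name].to_numpy()])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise ValueError(f"rank-deficient design matrix; collinear terms: {bad}")
    return design


def _align(balances: pd.DataFrame, covariates: pd.DataFrame) -> None:
    missing = [str(s) for s in balances.index if s not in covariates.index]
    if missing:
        raise ValueError(f"covariates missing for samples {missing}")


def fit_ols(balances: pd.DataFrame, covariates: pd.DataFrame, formula: str,
            alpha: float = 0.05) -> RegressionResult:
    """Ordinary least squares on every balance against a shared design.

    The same design matrix (from ``formula`` over ``covariates``) is fit
    to each balance column independently.  The pooled R^2 aggregates
    explained variation over all balances; it is invariant to the choice
    of bifurcating tree.
    """
    _align(balances, covariates)
    design = _design_matrix(covariates.loc[balances.index], formula)
    X = design.to_numpy()
    Y = balances.to_numpy(dtype=float)

    rows = []
    params = np.empty((balances.shape[1], X.shape[1]))
    fitted = np.empty_like(Y)
    for j, node in enumerate(balances.columns):
        fit = sm.OLS(Y[:, j], X).fit()
        params[j] = fit.params
        fitted[:, j] = fit.fittedvalues
        for term, est, se, p in zip(design.columns, fit.params, fit.bse, fit.pvalues):
            rows.append((node, term, est, se, p))
    coefficients = pd.DataFrame(
        rows, columns=["node", "term", "estimate", "stderr", "pvalue"]
    ).set_index(["node", "term"])
    _adjust_by_term(coefficients, alpha)

    residual = Y - fitted
    sse = float(np.sum(residual ** 2))
    sst = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst

    return RegressionResult(
        coefficients=coefficients,
        fitted=pd.DataFrame(fitted, index=balances.index, columns=balances.columns),
        residual=pd.DataFrame(residual, index=balances.index, columns=balances.columns),
        r_squared=r2,
        model=f"OLS({formula})",
        formula=formula,
        alpha=alpha,
        converged=pd.Series(True, index=balances.columns),
        design_info=design.design_info,
        params=pd.DataFrame(params, index=balances.columns, columns=design.columns),
    )


def _adjust_by_term(coefficients: pd.DataFrame, alpha: float) -> None:
    """Bonferroni-adjust p-values across nodes, separately per term."""
    adj = pd.Series(np.nan, index=coefficients.index)
    sig = pd.Series(False, index=coefficients.index)
    for term in coefficients.index.get_level_values("term").unique():
        mask = coefficients.index.get_level_values("term") == term
        a, s = bonferroni(coefficients.loc[mask, "pvalue"].to_numpy(), alpha)
        adj.loc[mask] = a
        sig.loc[mask] = s
    coefficients["pvalue_adj"] = adj
    coefficients["significant"] = sig


def fit_lme(balances: pd.DataFrame, covariates: pd.DataFrame, formula: str,
            grouping: str, alpha: float = 0.05) -> RegressionResult:
    """Random-intercept linear mixed model per balance.

    Fits ``balance ~ formula + (1 | grouping)`` by REML for every
    internal node; fixed-effect p-values come from the Wald test.  A
    balance whose optimiser fails to converge is flagged in
    ``result.converged`` and reported with NaN standard errors and
    p-values rather than aborting the whole analysis (tip-adjacent
    balances of sparse features are routinely volatile).
    """
    _align(balances, covariates)
    cov = covariates.loc[balances.index]
    if grouping not in cov.columns:
        raise ValueError(f"grouping column {grouping!r} not in covariates")
    groups = cov[grouping]
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError(
            "grouping column has a single level; use fit_ols for unstructured data"
        )
    design = _design_matrix(cov, formula)
    X = design.to_numpy()
    Y = balances.to_numpy(dtype=float)

    rows = []
    converged = {}
    params = np.full((balances.shape[1], X.shape[1]), np.nan)
    fitted = np.full_like(Y, np.nan)
    for j, node in enumerate(balances.columns):
        ok = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(Y[:, j], X, groups=groups)
                fit = model.fit(reml=True)
            ok = bool(getattr(fit, "converged", True))
        except Exception:
            ok = False
            fit = None
        converged[node] = ok
        if fit is not None:
            fe = np.asarray(fit.fe_params)
            params[j] = fe
            fitted[:, j] = X @ fe
            bse = np.asarray(fit.bse_fe)
            pvals = np.asarray(fit.pvalues)[: X.shape[1]]
        else:
            fe = bse = pvals = [np.nan] * X.shape[1]
        for term, est, se, p in zip(design.columns, fe, bse, pvals):
            if not ok and fit is None:
                est = se = p = np.nan
            elif not ok:
                se = p = np.nan
            rows.append((node, term, est, se, p))
    coefficients = pd.DataFrame(
        rows, columns=["node", "term", "estimate", "stderr", "pvalue"]
    ).set_index(["node", "term"])
    _adjust_by_term(coefficients, alpha)

    fitted_df = pd.DataFrame(fitted, index=balances.index, columns=balances.columns)
    return RegressionResult(
        coefficients=coefficients,
        fitted=fitted_df,
        residual=balances - fitted_df,
        r_squared=None,
        model=f"LME({formula} | random intercept per {grouping})",
        formula=formula,
        alpha=alpha,
        grouping=grouping,
        converged=pd.Series(converged),
        design_info=design.design_info,
        params=pd.DataFrame(params, index=balances.columns, columns=design.columns),
    )


def predict_proportions(result: RegressionResult, new_covariates: pd.DataFrame,
                        basis: pd.DataFrame) -> pd.DataFrame:
    """Predict community proportions for new covariate values.

    Builds the design matrix for ``new_covariates`` with the training
    design information, predicts every balance from the fitted (fixed)
    coefficients, and maps the predicted balance vectors back to the
    simplex through the inverse ILR.  Rows sum to 1.
    """
    if result.design_info is None or result.params is None:
        raise ValueError("result does not carry design information for prediction")
    try:
        (design,) = patsy.build_design_matrices(
            [result.design_info], new_covariates, return_type="dataframe",
            NA_action="raise",
        )
    except patsy.PatsyError as exc:
        raise ValueError(f"missing or invalid covariates for prediction: {exc}") from exc
    design.index = new_covariates.index
    pred = design.to_numpy() @ result.params.to_numpy().T
    balances = pd.DataFrame(pred, index=new_covariates.index,
                            columns=result.params.index)
    if list(balances.columns) != list(basis.index):
        raise ValueError("predict_proportions: balance nodes do not match basis rows")
    return inverse_ilr(balances, basis)
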