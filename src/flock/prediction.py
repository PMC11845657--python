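"""Leave-one-out regression of a group outcome on movement features.

Each fold selects features on the training rows only (pluggable selector;
L1-penalized regression with inner cross-validation by default), fits
ordinary least squares on the selected columns, and predicts the held-out
group. The predictive R^2 pools all held-out predictions; the explanatory
R^2 refits selection + OLS on the full table. Selection stability across
folds is summarized by the mean pairwise Jaccard index, and the explanatory
fit gets the standard residual diagnostics.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV, LinearRegression
from statsmodels.stats.diagnostic import acorr_ljungbox, het_goldfeldquandt


class Selector(Protocol):
    """Feature selector: (X_train, y_train, seed) -> column indices."""

    def __call__(self, X: np.ndarray, y: np.ndarray, seed: int) -> list[int]: ...


def lasso_selector(X: np.ndarray, y: np.ndarray, seed: int = 0,
                   rel_tol: float = 1e-2) -> list[int]:
    """L1-penalized selection; penalty picked by inner cross-validation.

    Coefficients below ``rel_tol`` of the largest magnitude are treated as
    zero: near the interpolating end of the penalty path the solver leaves
    numerically tiny activations on irrelevant columns, which would
    otherwise inflate the support.
    """
    n = X.shape[0]
    # leave-one-out inner CV for small n: less fold noise, and the fold set
    # does not depend on row order, so selection is permutation-invariant
    cv = n if n <= 32 else 5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(cv=cv, random_state=seed, max_iter=50_000).fit(X, y)
    coefs = np.abs(model.coef_)
    if coefs.max() == 0:
        return []
    return sorted(np.nonzero(coefs > rel_tol * coefs.max())[0].tolist())


@dataclass
class LooResult:
    feature_names: list[str]
    fold_selections: list[list[int]]
    held_out_predictions: np.ndarray
    predictive_r2: float
    explanatory_r2: float
    explanatory_selection: list[int]
    explanatory_coef: np.ndarray
    jaccard: float
    diagnostics: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def selected_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.explanatory_selection]


def build_feature_table(group_features: dict[str, dict[str, float]],
                        zscore: bool = True) -> pd.DataFrame:
    """Group x feature matrix from per-group feature dicts.

    Features absent in some groups are imputed by the column median and a
    ``<name>__imputed`` marker column is recorded in ``df.attrs``; features
    present in no group are dropped with a warning. Columns are z-scored
    (constant columns left at zero).
    """
    df = pd.DataFrame.from_dict(group_features, orient="index").sort_index()
    empty = [c for c in df.columns if df[c].isna().all()]
    if empty:
        warnings.warn(f"dropping features absent in every group: {empty}")
        df = df.drop(columns=empty)
    imputed = {c: df[c].isna() for c in df.columns if df[c].isna().any()}
    df = df.fillna(df.median())
    if zscore:
        sd = df.std(ddof=0)
        df = (df - df.mean()) / sd.replace(0.0, 1.0)
    df.attrs["imputed"] = {c: mask[mask].index.tolist() for c, mask in imputed.items()}
    return df


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def _fit_predict(X: np.ndarray, y: np.ndarray, cols: Sequence[int],
                 X_new: np.ndarray) -> np.ndarray:
    if len(cols) == 0:
        return np.full(X_new.shape[0], y.mean())
    ols = LinearRegression().fit(X[:, cols], y)
    return ols.predict(X_new[:, cols])


def loo_evaluate(X: pd.DataFrame | np.ndarray, y: np.ndarray,
                 selector: Selector = lasso_selector, seed: int = 0) -> LooResult:
    """Leave-one-out evaluation with per-fold selection and pooled R^2."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n = Xm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 groups for leave-one-out")

    preds = np.empty(n)
    selections: list[list[int]] = []
    flags: list[str] = []
    for i in range(n):
        train = np.arange(n) != i
        cols = list(selector(Xm[train], y[train], seed))
        if not cols:
            flags.append(f"fold {i}: empty selection, intercept-only model")
        selections.append(cols)
        preds[i] = _fit_predict(Xm[train], y[train], cols, Xm[i:i + 1])[0]

    full_cols = list(selector(Xm, y, seed))
    coef = np.zeros(Xm.shape[1])
    if full_cols:
        ols = LinearRegression().fit(Xm[:, full_cols], y)
        coef[full_cols] = ols.coef_
        fitted = ols.predict(Xm[:, full_cols])
    else:
        flags.append("full-data selection empty, intercept-only model")
        fitted = np.full(n, y.mean())

    residuals = y - fitted
    return LooResult(
        feature_names=names,
        fold_selections=selections,
        held_out_predictions=preds,
        predictive_r2=_r2(y, preds),
        explanatory_r2=_r2(y, fitted),
        explanatory_selection=full_cols,
        explanatory_coef=coef,
        jaccard=jaccard_stability(selections),
        diagnostics=regression_diagnostics(residuals, Xm[:, full_cols]
                                           if full_cols else None),
        flags=flags,
    )


def jaccard_stability(selected_sets: Sequence[Sequence[int]]) -> float:
    """Mean pairwise |A n B| / |A u B| over fold selections (two empty sets = 1)."""
    if len(selected_sets) < 2:
        raise ValueError("need at least 2 folds")
    vals = []
    for a, b in itertools.combinations(selected_sets, 2):
        sa, sb = set(a), set(b)
        union = sa | sb
        vals.append(1.0 if not union else len(sa & sb) / len(union))
    return float(np.mean(vals))


def regression_diagnostics(residuals: np.ndarray,
                           predictors: np.ndarray | None = None) -> dict:
    """Residual checks mirroring the usual linear-model validation list.

    Shapiro-Wilk normality, mean residual, Ljung-Box serial independence and
    Goldfeld-Quandt homoscedasticity. Tests that need more observations than
    available are reported as not applicable.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    out: dict = {"mean_residual": float(residuals.mean())}

    if n >= 3 and np.ptp(residuals) > 0:
        stat, p = stats.shapiro(residuals)
        out["normality"] = {"test": "shapiro-wilk", "stat": float(stat),
                            "pvalue": float(p)}
    else:
        out["normality"] = {"test": "shapiro-wilk", "stat": None, "pvalue": None,
                            "note": "not applicable"}

    min_lb = 4
    if n >= min_lb and np.ptp(residuals) > 0:
        lags = max(1, min(10, n // 5))
        lb = acorr_ljungbox(residuals, lags=[lags], return_df=True)
        out["independence"] = {"test": "ljung-box",
                               "stat": float(lb["lb_stat"].iloc[0]),
                               "pvalue": float(lb["lb_pvalue"].iloc[0])}
    else:
        out["independence"] = {"test": "ljung-box", "stat": None, "pvalue": None,
                               "note": "not applicable"}

    if predictors is not None and n >= 2 * (predictors.shape[1] + 2):
        order = np.argsort(predictors[:, 0])
        exog = np.column_stack([np.ones(n), predictors])
        stat, p, _ = het_goldfeldquandt(residuals[order], exog[order])
        out["homoscedasticity"] = {"test": "goldfeld-quandt", "stat": float(stat),
                                   "pvalue": float(p)}
    else:
        out["homoscedasticity"] = {"test": "goldfeld-quandt", "stat": None,
                                   "pvalue": None, "note": "not applicable"}
    return out
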