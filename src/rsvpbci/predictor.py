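"""Regression predictors of speller AUC from the five RSVP features.

Three model kinds: ``single`` (one feature), ``multiple`` (all five features,
the weighted-sum predictor W1*X1 + ... + W5*X5), and ``stepwise`` (the same
weighted sum with forward/backward p-value feature selection, 0.05/0.10).
Features are z-scored before combination because they carry different units;
within leave-one-subject-out (LOSO) evaluation the z-parameters and the
regression are fit on the training subjects only, so the held-out subject
never leaks into its own prediction.

The outcome stays on its native 0-1 AUC scale during fitting; the reported
MSE multiplies predictions and actuals by 100 first, since squared errors on
the raw scale are too small to compare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spst

from .stepwise import stepwise_select

__all__ = [
    "PredictorModel",
    "RegressionStats",
    "zscore",
    "fit_single",
    "fit_multiple",
    "fit_stepwise",
    "loso_evaluate",
    "predictor_table",
]

MODEL_KINDS = ("single", "multiple", "stepwise")


@dataclass(frozen=True)
class PredictorModel:
    """Linear predictor on z-scored features.

    ``weights`` has one entry per input feature (zero where a feature was not
    selected); z_mean/z_sd are the training-fold standardization parameters.
    """

    kind: str
    weights: np.ndarray
    intercept: float
    z_mean: np.ndarray
    z_sd: np.ndarray
    selected: tuple[int, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xz = (np.asarray(X, dtype=float) - self.z_mean) / self.z_sd
        return self.intercept + Xz @ self.weights


@dataclass(frozen=True)
class RegressionStats:
    """Fit quality: Pearson r, its p-value, F statistic, R^2 and MSE (x100 scale)."""

    r: float
    p: float
    F: float
    R2: float
    MSE: float

    def to_series(self) -> pd.Series:
        return pd.Series({"R": self.r, "p": self.p, "F": self.F,
                          "R2": self.R2, "MSE": self.MSE})


def zscore(X: np.ndarray, fit_rows=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns using mean/SD estimated on ``fit_rows`` only.

    Returns (Xz, mean, sd) with sample SD (n-1). The transform is applied to
    every row, so held-out rows are standardized with training parameters.
    """
    X = np.asarray(X, dtype=float)
    rows = np.arange(X.shape[0]) if fit_rows is None else np.asarray(fit_rows)
    if rows.size < 2:
        raise ValueError("need >= 2 fit rows")
    mean = X[rows].mean(axis=0)
    sd = X[rows].std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature among fit rows")
    return (X - mean) / sd, mean, sd


def _mse_x100(pred: np.ndarray, actual: np.ndarray) -> float:
    return float(np.mean((100.0 * (np.asarray(pred) - np.asarray(actual))) ** 2))


def _corr_stats(pred: np.ndarray, actual: np.ndarray) -> RegressionStats:
    """r/p/F/R2/MSE of predictions against actual outcomes (n-2 df t-transform)."""
    pred, actual = np.asarray(pred, float), np.asarray(actual, float)
    if np.std(actual) == 0:
        raise ValueError("outcome has zero variance; correlation undefined")
    if np.std(pred) == 0:
        return RegressionStats(r=0.0, p=1.0, F=0.0, R2=0.0,
                               MSE=_mse_x100(pred, actual))
    r, p = spst.pearsonr(pred, actual)
    n = pred.size
    t2 = r ** 2 * (n - 2) / max(1.0 - r ** 2, 1e-300)
    return RegressionStats(r=float(r), p=float(p), F=float(t2), R2=float(r ** 2),
                           MSE=_mse_x100(pred, actual))


def _ols_stats(yhat: np.ndarray, y: np.ndarray, res) -> RegressionStats:
    r = float(np.corrcoef(yhat, y)[0, 1]) if np.std(yhat) > 0 else 0.0
    return RegressionStats(r=r, p=float(res.f_pvalue) if res.df_model > 0 else 1.0,
                           F=float(res.fvalue) if res.df_model > 0 else 0.0,
                           R2=float(res.rsquared), MSE=_mse_x100(yhat, y))


def _fit(X: np.ndarray, y: np.ndarray, kind: str, feature: int | None = None,
         p_enter: float = 0.05, p_remove: float = 0.10,
         ) -> tuple[PredictorModel, RegressionStats]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    Xz, mean, sd = zscore(X)
    weights = np.zeros(m)

    if kind == "single":
        if feature is None:
            raise ValueError("single-feature fit needs a feature index")
        cols = [feature]
        design = sm.add_constant(Xz[:, cols])
        res = sm.OLS(y, design).fit()
        weights[feature] = res.params[1]
        intercept = float(res.params[0])
        selected = (feature,)
        yhat = res.fittedvalues
        stats = _ols_stats(yhat, y, res)
    elif kind == "multiple":
        if n <= m + 1:
            raise ValueError(f"need n > {m + 1} subjects for the full model")
        design = sm.add_constant(Xz)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient design")
        res = sm.OLS(y, design).fit()
        weights[:] = res.params[1:]
        intercept = float(res.params[0])
        selected = tuple(range(m))
        stats = _ols_stats(res.fittedvalues, y, res)
    elif kind == "stepwise":
        sw = stepwise_select(Xz, y, p_enter=p_enter, p_remove=p_remove)
        selected = sw.selected
        if selected:
            design = sm.add_constant(Xz[:, list(selected)])
            res = sm.OLS(y, design).fit()
            weights[list(selected)] = res.params[1:]
            intercept = float(res.params[0])
            stats = _ols_stats(res.fittedvalues, y, res)
        else:
            intercept = float(y.mean())
            stats = RegressionStats(r=0.0, p=1.0, F=0.0, R2=0.0,
                                    MSE=_mse_x100(np.full(n, intercept), y))
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    model = PredictorModel(kind=kind, weights=weights, intercept=intercept,
                           z_mean=mean, z_sd=sd, selected=selected)
    return model, stats


def fit_single(x: np.ndarray, y: np.ndarray) -> tuple[PredictorModel, RegressionStats]:
    """Simple linear regression of AUC on one RSVP feature.

    F equals the squared t of the slope and R^2 equals r^2, the standard
    simple-regression identities.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need n >= 3")
    return _fit(x[:, None], y, "single", feature=0)


def fit_multiple(X: np.ndarray, y: np.ndarray) -> tuple[PredictorModel, RegressionStats]:
    """The regular multi-feature model: OLS on all five z-scored features."""
    return _fit(X, y, "multiple")


def fit_stepwise(X: np.ndarray, y: np.ndarray, p_enter: float = 0.05,
                 p_remove: float = 0.10) -> tuple[PredictorModel, RegressionStats]:
    """The stepwise multi-feature model; only surviving features get weight."""
    return _fit(X, y, "stepwise", p_enter=p_enter, p_remove=p_remove)


def loso_evaluate(X: np.ndarray, y: np.ndarray, kind: str = "stepwise",
                  feature: int | None = None,
                  ) -> tuple[np.ndarray, RegressionStats]:
    """Leave-one-subject-out predictions and their agreement with the truth.

    For each subject the standardization and the model (including any
    stepwise selection) are fit on the remaining subjects only. Returns the
    per-subject predictions and RegressionStats of predictions vs. actuals
    (p from the t-transform of r with n-2 df, MSE on the x100 scale).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("LOSO needs n >= 4 subjects")
    preds = np.empty(n)
    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        model, _ = _fit(X[train], y[train], kind, feature=feature)
        preds[i] = model.predict(X[i][None, :])[0]
    return preds, _corr_stats(preds, y)


def predictor_table(features: pd.DataFrame, auc: pd.Series | np.ndarray,
                    ) -> pd.DataFrame:
    """Seven-predictor summary: five single features plus the two multi models.

    ``features`` is a subjects x 5 table (columns ordered X1..X5). For every
    predictor the in-sample regression statistics and the LOSO-evaluated
    statistics are reported, one row per (predictor, evaluation).
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(auc, dtype=float).ravel()
    rows = []
    for j, name in enumerate(features.columns):
        _, ins = fit_single(X[:, j], y)
        _, loso = loso_evaluate(X, y, "single", feature=j)
        rows.append((name, "in_sample", *ins.to_series()))
        rows.append((name, "loso", *loso.to_series()))
    for kind, label in (("multiple", "multi_regular"), ("stepwise", "multi_stepwise")):
        _, ins = _fit(X, y, kind)
        _, loso = loso_evaluate(X, y, kind)
        rows.append((label, "in_sample", *ins.to_series()))
        rows.append((label, "loso", *loso.to_series()))
    return pd.DataFrame(rows, columns=["predictor", "evaluation",
                                       "R", "p", "F", "R2", "MSE"])
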