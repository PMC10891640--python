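"""QSPR regression machinery: descriptor preparation, OLS and principal
component regression, leave-one-out cross-validation, forward variable
selection by RMSECV, and prediction-set validation.

The response throughout this layer is the photodegradation rate k in
units of 1e-3 s^-1.  Estimators follow the scikit-learn protocol
(``fit``/``predict``, ``get_params``), so they compose with sklearn
pipelines and model selection; the module-level functions are thin
wrappers kept for script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import LeaveOneOut
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "drop_constant_columns", "autoscale", "OLSRegressor", "PCRRegressor",
    "fit_ols", "fit_pcr", "loo_cv", "forward_select", "SelectionTrace",
    "ForwardSelector", "predict_named", "validate", "ValidationReport",
]


def _as_matrix(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    x = np.asarray(x, dtype=float)
    return x, [str(j) for j in range(x.shape[1])]


def drop_constant_columns(x):
    """Remove zero-variance descriptor columns, preserving order.

    Returns ``(reduced, removed_names)``.  DataFrames keep their column
    labels; plain arrays use stringified column indices as names.
    """
    mat, names = _as_matrix(x)
    if mat.size == 0:
        raise ValueError("empty descriptor matrix")
    keep = mat.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all descriptor columns are constant")
    removed = [n for n, k in zip(names, keep) if not k]
    if isinstance(x, pd.DataFrame):
        return x.loc[:, keep], removed
    return mat[:, keep], removed


def autoscale(x) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to unit SD (n-1 denominator).

    Returns ``(scaled, means, sds)``.  Zero-variance columns are an
    error; call :func:`drop_constant_columns` first.
    """
    mat, _ = _as_matrix(x)
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("zero-variance column; drop constant columns before autoscaling")
    return (mat - means) / sds, means, sds


class OLSRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares on raw descriptor units.

    Solved through numpy's SVD-based ``lstsq`` (rank-revealing); on a
    rank-deficient problem the minimum-norm solution is returned with a
    warning rather than failing, since near-saturated calibration sets
    (p close to n) are the normal regime for this kind of model.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray (n_features,)
    bw_ : ndarray (n_features,)
        Standardized ("weighted") coefficients coef * column SD, used to
        rank descriptor influence on a common scale.
    """

    def fit(self, X, y):
        x, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if x.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("NaN or infinite values in the regression problem")
        a = np.column_stack([np.ones(x.shape[0]), x])
        beta, _, rank, _ = np.linalg.lstsq(a, y, rcond=None)
        if rank < a.shape[1]:
            import warnings

            warnings.warn(
                "rank-deficient design: returning the minimum-norm OLS solution",
                stacklevel=2,
            )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = x.shape[1]
        sds = x.std(axis=0, ddof=1)
        self.bw_ = self.coef_ * sds
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = self._align(X)
        return self.intercept_ + x @ self.coef_

    def _align(self, X) -> np.ndarray:
        """Accept columns in any order when named; require all model features."""
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.feature_names_in_ if n not in X.columns]
            if missing:
                raise ValueError(f"missing descriptor columns: {missing}")
            return X.loc[:, list(self.feature_names_in_)].to_numpy(dtype=float)
        x = np.asarray(X, dtype=float)
        if x.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return x


class PCRRegressor(RegressorMixin, BaseEstimator):
    """Principal component regression on the autoscaled descriptor matrix.

    The descriptors are autoscaled, decomposed by SVD, and the response
    is regressed on the first ``n_components`` scores.  Coefficients are
    back-transformed to original descriptor units, so ``predict`` is a
    plain affine map; with ``n_components`` equal to the full rank the
    predictions coincide with OLS.
    """

    def __init__(self, n_components: int = 8):
        self.n_components = n_components

    def fit(self, X, y):
        x, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = x.shape
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components must be in [1, {min(n - 1, p)}] for a {n}x{p} problem"
            )
        xs, means, sds = autoscale(x)
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        m = self.n_components
        scores = u[:, :m] * s[:m]
        gamma = np.linalg.lstsq(np.column_stack([np.ones(n), scores]), y, rcond=None)[0]
        w = vt[:m].T @ gamma[1:]  # coefficients on autoscaled descriptors
        self.coef_ = w / sds
        self.intercept_ = float(gamma[0] - means @ self.coef_)
        self.scaling_means_, self.scaling_sds_ = means, sds
        self.loadings_ = vt[:m].T
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.bw_ = w  # already on the standardized scale
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = OLSRegressor._align(self, X)
        return self.intercept_ + x @ self.coef_


def fit_ols(X, y) -> OLSRegressor:
    return OLSRegressor().fit(X, y)


def fit_pcr(X, y, n_components: int = 8) -> PCRRegressor:
    return PCRRegressor(n_components=n_components).fit(X, y)


def loo_cv(X, y, fitter: BaseEstimator | None = None) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validation: refit on n-1 samples, predict the
    held-out one.  Any in-model preprocessing (autoscaling in PCR) is
    re-estimated inside each fold by construction, since the estimator
    is cloned and refit per fold.

    Returns ``(rmsecv, loo_predictions)``.
    """
    xmat, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = xmat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    fitter = OLSRegressor() if fitter is None else fitter
    preds = np.empty(n)
    for train, test in LeaveOneOut().split(xmat):
        try:
            model = clone(fitter).fit(xmat[train], y[train])
            preds[test] = model.predict(xmat[test])
        except Exception as exc:  # pragma: no cover - propagation path
            raise RuntimeError(f"LOO fold {int(test[0])} failed: {exc}") from exc
    rmsecv = float(np.sqrt(np.mean((preds - y) ** 2)))
    return rmsecv, preds


@dataclass
class SelectionTrace:
    """Forward-selection record: variables in entry order + RMSECV path."""

    selected_names: list[str]
    selected_indices: list[int]
    rmsecv_path: list[float]
    stopped_reason: str = ""


def forward_select(X, y, fitter: BaseEstimator | None = None,
                   max_vars: int | None = None,
                   min_improvement: float = 1e-6) -> SelectionTrace:
    """Greedy forward variable selection by leave-one-out RMSECV.

    The first variable is the one most correlated (positively or
    negatively) with the response; each later step adds the candidate
    whose refit model attains the lowest LOO RMSECV.  Selection stops
    when no candidate improves RMSECV by more than ``min_improvement``
    or ``max_vars`` is reached.  Ties break toward the lower column
    index, deterministically.
    """
    xmat, names = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = xmat.shape
    if p == 0:
        raise ValueError("empty descriptor matrix")
    max_vars = p if max_vars is None else min(max_vars, p)
    fitter = OLSRegressor() if fitter is None else fitter

    sds = xmat.std(axis=0, ddof=1)
    ysd = y.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(
            (sds > 0) & (ysd > 0),
            ((xmat - xmat.mean(0)) * (y - y.mean())[:, None]).sum(0)
            / ((n - 1) * sds * ysd),
            0.0,
        )
    selected = [int(np.argmax(np.abs(corr)))]
    rmsecv, _ = loo_cv(xmat[:, selected], y, fitter)
    path = [rmsecv]
    reason = "max_vars"
    while len(selected) < max_vars:
        best_j, best_r = None, None
        for j in range(p):
            if j in selected:
                continue
            r, _ = loo_cv(xmat[:, selected + [j]], y, fitter)
            if best_r is None or r < best_r:  # strict < keeps the lowest index on ties
                best_j, best_r = j, r
        if best_r is None or path[-1] - best_r <= min_improvement:
            reason = "no_improvement"
            break
        selected.append(best_j)
        path.append(best_r)
    return SelectionTrace([names[j] for j in selected], selected, path, reason)


class ForwardSelector(BaseEstimator):
    """Estimator wrapper around :func:`forward_select`.

    After ``fit``, ``support_`` masks the selected columns and
    ``model_`` is the final estimator refit on them.
    """

    def __init__(self, fitter=None, max_vars=None, min_improvement: float = 1e-6):
        self.fitter = fitter
        self.max_vars = max_vars
        self.min_improvement = min_improvement

    def fit(self, X, y):
        trace = forward_select(X, y, self.fitter, self.max_vars, self.min_improvement)
        xmat, _ = _as_matrix(X)
        self.trace_ = trace
        self.support_ = np.zeros(xmat.shape[1], dtype=bool)
        self.support_[trace.selected_indices] = True
        base = OLSRegressor() if self.fitter is None else self.fitter
        self.model_ = clone(base).fit(xmat[:, trace.selected_indices], np.asarray(y, float))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        xmat, _ = _as_matrix(X)
        return self.model_.predict(xmat[:, self.trace_.selected_indices])


def predict_named(model, X: pd.DataFrame) -> np.ndarray:
    """Predict with name-based column alignment (order-insensitive)."""
    return model.predict(X)


@dataclass
class ValidationReport:
    """Experimental vs predicted rates with per-compound relative errors.

    error% = 100 * (predicted - experimental) / experimental.  RMSEP is
    the root-mean-square prediction error in response units; three
    relative-error aggregates are reported because conventions differ
    between groups (mean absolute, mean signed, RMS of relative errors).
    """

    table: pd.DataFrame
    rmsep: float
    mean_abs_error_percent: float
    mean_error_percent: float
    rms_error_percent: float
    r2_pred_vs_exp: float = field(default=float("nan"))


def validate(experimental, predicted, compound_ids=None) -> ValidationReport:
    """Per-compound error report for a prediction (or calibration) set."""
    exp = np.asarray(experimental, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if exp.shape != pred.shape:
        raise ValueError("experimental and predicted vectors differ in length")
    if np.any(exp <= 0):
        raise ValueError("experimental rates must be positive")
    err = 100.0 * (pred - exp) / exp
    ids = list(compound_ids) if compound_ids is not None else list(range(exp.size))
    table = pd.DataFrame({"compound": ids, "experimental": exp,
                          "predicted": pred, "error_percent": err})
    ss_tot = float(np.sum((exp - exp.mean()) ** 2))
    r2 = 1.0 - float(np.sum((pred - exp) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return ValidationReport(
        table=table,
        rmsep=float(np.sqrt(np.mean((pred - exp) ** 2))),
        mean_abs_error_percent=float(np.mean(np.abs(err))),
        mean_error_percent=float(np.mean(err)),
        rms_error_percent=float(np.sqrt(np.mean(err**2))),
        r2_pred_vs_exp=r2,
    )
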