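"""L1-penalized PFI regression: LOOCV tuning over a log-spaced penalty grid,
nested LOOCV evaluation, error-budget penalty relaxation, and cross-cohort
prediction.

The objective is the standard scikit-learn scaling

    (1 / 2n) * ||y - b - X w||^2  +  alpha * ||w||_1

with an unpenalized intercept b.  All error reporting happens in *days*:
predictions made on the transformed-PFI scale are inverted through the
cohort's fitted PFI transform before the RMSE is computed as
sqrt(mean((observed - predicted)^2)).

Leave-one-out cross-validation (LOOCV) is fully deterministic — folds are
the patients in order, and coordinate descent is run to a tight tolerance —
so a fixed input table yields a bit-identical tuning curve across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .panel import AssayPanel
from .preprocess import CohortTable, TransformModel, apply_transform, impute_censored, invert_transform

__all__ = [
    "LassoFit",
    "TuningCurve",
    "CVResult",
    "RelaxedAlpha",
    "fit_lasso",
    "make_alpha_grid",
    "loocv",
    "tune_alpha",
    "nested_loocv_rmse",
    "relax_alpha",
    "cross_predict",
]

_TOL = 1e-7
_MAX_ITER = 100_000


@dataclass
class LassoFit:
    """A fitted L1 model on standardized features."""

    alpha: float
    coefficients: np.ndarray
    intercept: float
    feature_names: list[str]

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    @property
    def support(self) -> list[str]:
        return [f for f, c in zip(self.feature_names, self.coefficients) if c != 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coefficients + self.intercept


@dataclass
class TuningCurve:
    """LOOCV error (days) as a function of the L1 penalty."""

    alphas: np.ndarray
    loocv_rmse_days: np.ndarray
    n_nonzero: np.ndarray
    optimal_alpha: float

    def rmse_at(self, alpha: float) -> float:
        idx = int(np.argmin(np.abs(self.alphas - alpha)))
        if not np.isclose(self.alphas[idx], alpha, rtol=1e-10):
            raise ValueError(f"alpha {alpha} is not a grid point")
        return float(self.loocv_rmse_days[idx])


@dataclass
class CVResult:
    """Held-out predictions from leave-one-out cross-validation."""

    fold_ids: list[str]
    predictions_days: np.ndarray
    observed_days: np.ndarray
    fold_coefficients: np.ndarray  # (n_folds, n_features)
    fold_intercepts: np.ndarray
    feature_names: list[str]

    @property
    def n(self) -> int:
        return len(self.fold_ids)

    @property
    def rmse_days(self) -> float:
        return rmse(self.observed_days, self.predictions_days)


@dataclass
class RelaxedAlpha:
    """Result of error-budget penalty relaxation."""

    alpha: float
    budget_days: float
    feasible: bool


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square error, sqrt(mean((observed - predicted)^2))."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per entry of y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    return X, y


def fit_lasso(X: np.ndarray, y: np.ndarray, alpha: float, feature_names: list[str] | None = None) -> LassoFit:
    """Fit the Lasso at one penalty; coordinate descent to tolerance 1e-7.

    The returned fit satisfies the KKT conditions of the (1/2n)RSS + alpha*L1
    objective: |x_j' r / n| <= alpha for excluded features, = alpha with the
    coefficient's sign for included ones.
    """
    X, y = _check_Xy(X, y)
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    model = Lasso(alpha=alpha, fit_intercept=True, tol=_TOL, max_iter=_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(X.shape[1])]
    return LassoFit(
        alpha=float(alpha),
        coefficients=model.coef_.copy(),
        intercept=float(model.intercept_),
        feature_names=list(names),
    )


def make_alpha_grid(low: float = 1e-5, high: float = 1e5, n: int = 201) -> np.ndarray:
    """Log-uniformly spaced penalty grid, inclusive of both endpoints."""
    if not (low > 0 and high > 0 and low < high):
        raise ValueError("need 0 < low < high")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return np.logspace(np.log10(low), np.log10(high), n)


def _fold_path_predictions(X: np.ndarray, y: np.ndarray, alphas_desc: np.ndarray) -> np.ndarray:
    """Held-out LOOCV predictions (transformed scale) for every alpha.

    Returns an (n, n_alphas) matrix in the order of ``alphas_desc``.  Each
    fold's whole regularization path is computed in one coordinate-descent
    sweep; the intercept is handled by centering the training data.
    """
    n = len(y)
    preds = np.empty((n, len(alphas_desc)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in range(n):
            tr = np.arange(n) != i
            Xtr, ytr = X[tr], y[tr]
            x_mean = Xtr.mean(axis=0)
            y_mean = ytr.mean()
            _, coefs, _ = lasso_path(
                Xtr - x_mean, ytr - y_mean, alphas=alphas_desc, tol=_TOL, max_iter=_MAX_ITER
            )
            # coefs: (n_features, n_alphas), alphas descending
            preds[i] = (X[i] - x_mean) @ coefs + y_mean
    return preds


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    pfi_transform: TransformModel,
    observed_days: np.ndarray,
    fold_ids: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> CVResult:
    """Leave-one-out cross-validation at a fixed penalty.

    Each patient is held out in turn; the model fitted on the other n-1
    predicts the held-out transformed PFI, which is inverted to days.  The
    per-fold coefficient vectors (zeros included) are retained for the
    stability analysis.
    """
    X, y = _check_Xy(X, y)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 patients")
    observed_days = np.asarray(observed_days, float)
    ids = fold_ids if fold_ids is not None else [str(i) for i in range(n)]
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(X.shape[1])]

    coefs = np.empty((n, X.shape[1]))
    intercepts = np.empty(n)
    preds_t = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        fit = fit_lasso(X[tr], y[tr], alpha, feature_names=names)
        coefs[i] = fit.coefficients
        intercepts[i] = fit.intercept
        preds_t[i] = fit.predict(X[i : i + 1])[0]
    preds_days = invert_transform(preds_t, pfi_transform, clip=True)
    return CVResult(
        fold_ids=list(ids),
        predictions_days=preds_days,
        observed_days=observed_days,
        fold_coefficients=coefs,
        fold_intercepts=intercepts,
        feature_names=list(names),
    )


def tune_alpha(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    pfi_transform: TransformModel,
    observed_days: np.ndarray,
    rmse_scale: str = "days",
) -> TuningCurve:
    """LOOCV RMSE (days) at every grid penalty; pick the minimizer.

    Ties are broken toward the *largest* alpha among exact minimizers — the
    sparser model.  ``n_nonzero`` comes from a full-data fit at each alpha.
    With ``rmse_scale="transformed"`` the curve is computed on the
    transformed-PFI scale instead of days (the optimal alpha may differ,
    since the day-scale inversion is nonlinear).
    """
    if rmse_scale not in ("days", "transformed"):
        raise ValueError("rmse_scale must be 'days' or 'transformed'")
    X, y = _check_Xy(X, y)
    grid = np.asarray(grid, float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    observed_days = np.asarray(observed_days, float)

    desc = grid[::-1]
    preds_t = _fold_path_predictions(X, y, desc)  # (n, n_grid) descending order
    rmse_desc = np.empty(len(grid))
    for k in range(len(grid)):
        if rmse_scale == "days":
            rmse_desc[k] = rmse(observed_days, invert_transform(preds_t[:, k], pfi_transform, clip=True))
        else:
            rmse_desc[k] = rmse(apply_transform(observed_days, pfi_transform), preds_t[:, k])
    rmse_days = rmse_desc[::-1].copy()

    n_nonzero = np.empty(len(grid), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        _, coefs, _ = lasso_path(X - x_mean, y - y_mean, alphas=desc, tol=_TOL, max_iter=_MAX_ITER)
    n_nonzero[:] = np.count_nonzero(coefs, axis=0)[::-1]

    best = np.min(rmse_days)
    optimal = float(grid[np.nonzero(rmse_days == best)[0][-1]])
    return TuningCurve(
        alphas=grid.copy(),
        loocv_rmse_days=rmse_days,
        n_nonzero=n_nonzero,
        optimal_alpha=optimal,
    )


def nested_loocv_rmse(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    pfi_transform: TransformModel,
    observed_days: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Nested LOOCV: an honest error estimate when the penalty is tuned.

    The outer loop holds out one patient; the inner loop re-runs the whole
    LOOCV tuning on the remaining n-1 and the inner-chosen penalty is used
    to train on all n-1 and predict the outer case.  Returns the pooled
    RMSE (days) and the per-outer-fold chosen alphas.
    """
    X, y = _check_Xy(X, y)
    n = len(y)
    if n < 4:
        raise ValueError("nested LOOCV needs at least 4 patients")
    observed_days = np.asarray(observed_days, float)

    chosen = np.empty(n)
    outer_preds = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        inner = tune_alpha(X[tr], y[tr], grid, pfi_transform, observed_days[tr])
        chosen[i] = inner.optimal_alpha
        fit = fit_lasso(X[tr], y[tr], inner.optimal_alpha)
        outer_preds[i] = fit.predict(X[i : i + 1])[0]
    preds_days = invert_transform(outer_preds, pfi_transform, clip=True)
    return rmse(observed_days, preds_days), chosen


def relax_alpha(curve: TuningCurve, error_budget_days: float = 20.0) -> RelaxedAlpha:
    """Largest grid penalty whose LOOCV error stays within the budget.

    Trading a bounded increase in error for a sparser, more stable model.
    If no grid point meets the budget the accuracy-optimal alpha is returned
    with ``feasible=False``.
    """
    if not error_budget_days > 0:
        raise ValueError("error budget must be positive (days)")
    ok = np.nonzero(curve.loocv_rmse_days <= error_budget_days)[0]
    if len(ok) == 0:
        return RelaxedAlpha(alpha=curve.optimal_alpha, budget_days=error_budget_days, feasible=False)
    return RelaxedAlpha(
        alpha=float(curve.alphas[ok[-1]]), budget_days=error_budget_days, feasible=True
    )


def project_panel(fit_table: CohortTable, target_panel: AssayPanel) -> np.ndarray:
    """Project a target panel into a source cohort's transformed feature space.

    Each source feature present in the target is imputed, log10-transformed
    and passed through the *source* cohort's fitted column transform; source
    features absent from the target contribute 0 (the source-cohort mean in
    standardized space).
    """
    filled = impute_censored(target_panel)
    if np.any(filled <= 0):
        raise ValueError("non-positive concentration after imputation")
    logged = np.log10(filled)
    col = {a: j for j, a in enumerate(target_panel.analyte_names)}
    X = np.zeros((target_panel.n_patients, len(fit_table.feature_names)))
    overlap = 0
    for k, name in enumerate(fit_table.feature_names):
        if name in col:
            X[:, k] = apply_transform(logged[:, col[name]], fit_table.column_transforms[name])
            overlap += 1
    if overlap == 0:
        raise ValueError("no overlapping analytes between source model and target panel")
    return X


def cross_predict(fit: LassoFit, source_table: CohortTable, target_panel: AssayPanel) -> float:
    """Apply a source-cohort model to another cohort's panel; RMSE in days.

    The target is preprocessed with the source cohort's fitted transforms,
    predictions are inverted through the source PFI transform, and the RMSE
    is computed against the target's observed PFI.
    """
    X = project_panel(source_table, target_panel)
    preds_days = invert_transform(fit.predict(X), source_table.pfi_transform, clip=True)
    return rmse(target_panel.pfi_days, preds_days)
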