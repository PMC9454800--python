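"""Model-stability analysis across cross-validation folds.

For a fitted full-cohort model and its LOOCV fold fits, this module computes
per-feature fold statistics — mean and SD of the coefficient across *all*
folds (zeros included), the percent coefficient of variation
%CV = SD / |mean| x 100, and the number of folds in which the feature
received a nonzero coefficient — plus the cohort-level aggregate %CV over
the features retained by the full model.  A low aggregate %CV and high
inclusion fractions indicate that the penalty has selected a stable,
reproducible feature set rather than an overfit one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lasso import CVResult, LassoFit

__all__ = ["StabilityReport", "ModelComparison", "stability_report", "compare_models", "rank_features"]

#: |fold mean| below this is treated as zero and %CV is undefined.
_MEAN_EPS = 1e-12


@dataclass
class StabilityReport:
    """Per-feature fold statistics and cohort-level aggregates."""

    feature_names: list[str]
    full_model_coefficient: np.ndarray
    fold_mean: np.ndarray
    fold_sd: np.ndarray
    pct_cv: np.ndarray  # NaN where undefined (|fold mean| ~ 0)
    inclusion_count: np.ndarray
    n_folds: int

    @property
    def inclusion_fraction(self) -> np.ndarray:
        return self.inclusion_count / self.n_folds

    @property
    def n_features_full_model(self) -> int:
        return int(np.count_nonzero(self.full_model_coefficient))

    @property
    def n_features_all_folds(self) -> int:
        """Full-model features that received a nonzero coefficient in every fold."""
        full = self.full_model_coefficient != 0
        return int(np.count_nonzero(full & (self.inclusion_count == self.n_folds)))

    @property
    def aggregate_pct_cv(self) -> float:
        """Mean %CV over full-model nonzero features with a defined %CV."""
        mask = (self.full_model_coefficient != 0) & ~np.isnan(self.pct_cv)
        if not mask.any():
            return float("nan")
        return float(np.mean(self.pct_cv[mask]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.full_model_coefficient,
                "fold_mean": self.fold_mean,
                "fold_sd": self.fold_sd,
                "pct_cv": self.pct_cv,
                "inclusion_count": self.inclusion_count,
                "inclusion_fraction": self.inclusion_fraction,
            },
            index=pd.Index(self.feature_names, name="feature"),
        )


@dataclass
class ModelComparison:
    """Structural comparison of two models of the same cohort."""

    shared_features: list[str]
    dropped_features: list[str]
    added_features: list[str]
    sign_agreement_fraction: float  # NaN when no shared features
    delta_rmse_days: float
    delta_aggregate_pct_cv: float


def stability_report(cv: CVResult, full_fit: LassoFit) -> StabilityReport:
    """Fold statistics for every feature of the full-cohort model.

    Fold mean/SD are taken over all folds, including those in which the
    feature was dropped (coefficient 0); the SD is the sample SD (ddof=1).
    %CV is undefined (NaN) when the fold mean is numerically zero.
    """
    if list(cv.feature_names) != list(full_fit.feature_names):
        raise ValueError("CV folds and full fit cover different feature sets")
    coefs = cv.fold_coefficients
    fold_mean = coefs.mean(axis=0)
    fold_sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_cv = np.where(
            np.abs(fold_mean) > _MEAN_EPS, fold_sd / np.abs(fold_mean) * 100.0, np.nan
        )
    inclusion = np.count_nonzero(coefs, axis=0)
    return StabilityReport(
        feature_names=list(full_fit.feature_names),
        full_model_coefficient=full_fit.coefficients.copy(),
        fold_mean=fold_mean,
        fold_sd=fold_sd,
        pct_cv=pct_cv,
        inclusion_count=inclusion,
        n_folds=coefs.shape[0],
    )


def compare_models(
    report_a: StabilityReport,
    report_b: StabilityReport,
    rmse_a: float,
    rmse_b: float,
) -> ModelComparison:
    """Compare supports, coefficient signs, error and stability of two models.

    Features are compared on full-model supports; ``dropped`` are in A but
    not B, ``added`` in B but not A.  Deltas are B minus A, so a negative
    ``delta_aggregate_pct_cv`` means B is the more stable model.
    """
    sup_a = {f for f, c in zip(report_a.feature_names, report_a.full_model_coefficient) if c != 0}
    sup_b = {f for f, c in zip(report_b.feature_names, report_b.full_model_coefficient) if c != 0}
    shared = sorted(sup_a & sup_b)
    ca = dict(zip(report_a.feature_names, report_a.full_model_coefficient))
    cb = dict(zip(report_b.feature_names, report_b.full_model_coefficient))
    if shared:
        agree = np.mean([np.sign(ca[f]) == np.sign(cb[f]) for f in shared])
    else:
        agree = float("nan")
    return ModelComparison(
        shared_features=shared,
        dropped_features=sorted(sup_a - sup_b),
        added_features=sorted(sup_b - sup_a),
        sign_agreement_fraction=float(agree),
        delta_rmse_days=float(rmse_b - rmse_a),
        delta_aggregate_pct_cv=float(report_b.aggregate_pct_cv - report_a.aggregate_pct_cv),
    )


def rank_features(report: StabilityReport) -> list[str]:
    """Features ordered by signed full-model coefficient, descending.

    The most positively weighted feature (longest-PFI association) comes
    first, the most negatively weighted last; ties break alphabetically.
    """
    order = sorted(
        zip(report.feature_names, report.full_model_coefficient),
        key=lambda fc: (-fc[1], fc[0]),
    )
    return [f for f, _ in order]
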