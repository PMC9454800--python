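"""Censored-panel preprocessing: detection filter, limit-based imputation,
and the log10 + Yeo-Johnson + standardization transform chain.

The pipeline mirrors standard practice for multiplex bead-based immunoassay
(Luminex) panels in small clinical cohorts:

1. drop analytes detected in fewer than a minimum fraction of patients
   (default 75%; above-range cells count as detected signal),
2. impute left-censored cells at half the detection limit times the assay
   dilution, and right-censored cells at twice the top standard times the
   dilution,
3. log10-transform concentrations,
4. fit a Yeo-Johnson power transform per analyte column (and to the PFI
   outcome), then standardize to zero mean / unit SD so an L1 penalty acts
   uniformly across analytes.

Everything needed to map model predictions back to days (the fitted PFI
transform) is retained on the resulting :class:`CohortTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import FLAG_ABOVE, FLAG_BELOW, FLAG_NONE, AssayPanel

__all__ = [
    "TransformModel",
    "CohortTable",
    "filter_low_detection",
    "impute_censored",
    "fit_yeo_johnson",
    "apply_transform",
    "invert_transform",
    "yeo_johnson",
    "yeo_johnson_inverse",
    "build_cohort_table",
]

#: Bounded search interval for the Yeo-Johnson power parameter.  +/-5 covers
#: any skew arising from concentration data that is already on a log scale.
LAMBDA_BOUNDS = (-5.0, 5.0)
LAMBDA_TOL = 1e-8


@dataclass(frozen=True)
class TransformModel:
    """A fitted Yeo-Johnson transform plus post-standardization.

    ``apply`` maps raw values v -> (psi(v, lmbda) - post_mean) / post_sd;
    ``invert`` undoes both steps.
    """

    lmbda: float
    post_mean: float
    post_sd: float
    kind: str = "yeo_johnson"

    def __post_init__(self) -> None:
        if not self.post_sd > 0:
            raise ValueError("post_sd must be positive")


def yeo_johnson(v: np.ndarray, lmbda: float) -> np.ndarray:
    """Yeo-Johnson power transform psi(v, lambda), defined for all reals.

    For v >= 0: ((v+1)^lambda - 1)/lambda, or ln(v+1) at lambda = 0.
    For v < 0: -((1-v)^(2-lambda) - 1)/(2-lambda), or -ln(1-v) at lambda = 2.
    Strictly increasing in v for every lambda.
    """
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    pos = v >= 0
    if abs(lmbda) > 1e-12:
        out[pos] = (np.power(v[pos] + 1.0, lmbda) - 1.0) / lmbda
    else:
        out[pos] = np.log1p(v[pos])
    if abs(lmbda - 2.0) > 1e-12:
        out[~pos] = -(np.power(1.0 - v[~pos], 2.0 - lmbda) - 1.0) / (2.0 - lmbda)
    else:
        out[~pos] = -np.log1p(-v[~pos])
    return out


def _psi_range(lmbda: float) -> tuple[float, float]:
    """Open interval of values psi(., lambda) can attain."""
    lo = 1.0 / (2.0 - lmbda) if lmbda > 2.0 + 1e-12 else -np.inf
    hi = -1.0 / lmbda if lmbda < -1e-12 else np.inf
    return lo, hi


def yeo_johnson_inverse(psi: np.ndarray, lmbda: float, clip: bool = False) -> np.ndarray:
    """Inverse of :func:`yeo_johnson`.

    Raises ``ValueError`` when an input lies outside the transform's range
    for the given lambda (e.g. psi*lambda + 1 <= 0 on the positive branch).
    With ``clip=True`` out-of-range inputs are instead clamped just inside
    the boundary, mapping to an extreme but finite original-scale value —
    used when scoring predictions that a model is allowed to get badly wrong.
    """
    psi = np.asarray(psi, dtype=float)
    if clip:
        lo, hi = _psi_range(lmbda)
        if np.isfinite(lo):
            psi = np.maximum(psi, lo + 1e-9 * (abs(lo) + 1.0))
        if np.isfinite(hi):
            psi = np.minimum(psi, hi - 1e-9 * (abs(hi) + 1.0))
    out = np.empty_like(psi)
    pos = psi >= 0  # psi >= 0  <=>  v >= 0 (psi is increasing with psi(0) = 0)
    if abs(lmbda) > 1e-12:
        base = psi[pos] * lmbda + 1.0
        if np.any(base <= 0):
            raise ValueError("value outside the Yeo-Johnson range for this lambda")
        out[pos] = np.power(base, 1.0 / lmbda) - 1.0
    else:
        out[pos] = np.expm1(psi[pos])
    if abs(lmbda - 2.0) > 1e-12:
        base = 1.0 - psi[~pos] * (2.0 - lmbda)
        if np.any(base <= 0):
            raise ValueError("value outside the Yeo-Johnson range for this lambda")
        out[~pos] = 1.0 - np.power(base, 1.0 / (2.0 - lmbda))
    else:
        out[~pos] = -np.expm1(-psi[~pos])
    return out


def fit_yeo_johnson(v: np.ndarray) -> TransformModel:
    """Fit lambda by Gaussian maximum likelihood (profile log-likelihood with
    the Jacobian term), then record the mean/SD of the transformed values.

    lambda is found by bounded scalar optimization on [-5, 5] with absolute
    tolerance 1e-8.  Raises on constant or too-short input (lambda is then
    unidentifiable).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("need a 1-D vector of length >= 3")
    if not np.all(np.isfinite(v)):
        raise ValueError("input contains non-finite values")
    if np.ptp(v) == 0:
        raise ValueError("constant vector: Yeo-Johnson lambda is unidentifiable")

    res = optimize.minimize_scalar(
        lambda lam: -stats.yeojohnson_llf(lam, v),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": LAMBDA_TOL},
    )
    lmbda = float(res.x)
    psi = yeo_johnson(v, lmbda)
    sd = float(np.std(psi))
    if sd == 0:
        raise ValueError("transformed vector is constant; cannot standardize")
    return TransformModel(lmbda=lmbda, post_mean=float(np.mean(psi)), post_sd=sd)


def apply_transform(v: np.ndarray, t: TransformModel) -> np.ndarray:
    """Standardized Yeo-Johnson transform of ``v`` under the fitted model."""
    return (yeo_johnson(np.asarray(v, float), t.lmbda) - t.post_mean) / t.post_sd


def invert_transform(z: np.ndarray, t: TransformModel, clip: bool = False) -> np.ndarray:
    """Map standardized transformed values back to the original scale.

    ``clip=True`` clamps out-of-range inputs just inside the transform's
    boundary instead of raising (see :func:`yeo_johnson_inverse`).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("input contains non-finite values")
    return yeo_johnson_inverse(z * t.post_sd + t.post_mean, t.lmbda, clip=clip)


# ----------------------------------------------------------------------
# Panel-level operations
# ----------------------------------------------------------------------

def filter_low_detection(panel: AssayPanel, min_detected_fraction: float = 0.75) -> AssayPanel:
    """Drop analytes detected in fewer than ``min_detected_fraction`` of patients.

    A cell counts as detected unless it is flagged below the lower detection
    limit; above-range cells are measurable signal and count as detected.
    Raises if no analyte survives, attaching the per-analyte removal table.
    """
    if not 0 < min_detected_fraction <= 1:
        raise ValueError("min_detected_fraction must be in (0, 1]")
    detected = (panel.censor_flags != FLAG_BELOW).mean(axis=0)
    keep = detected >= min_detected_fraction
    removed = [
        (name, float(frac))
        for name, frac, k in zip(panel.analyte_names, detected, keep)
        if not k
    ]
    if not keep.any():
        err = ValueError("all analytes fall below the detection-fraction threshold")
        err.removal_table = removed  # type: ignore[attr-defined]
        raise err
    kept_names = [a for a, k in zip(panel.analyte_names, keep) if k]
    note = (
        f"detection filter ({min_detected_fraction:.0%}): removed "
        f"{len(removed)}/{panel.n_analytes} analytes: "
        + ", ".join(f"{a} ({f:.0%} detected)" for a, f in removed)
    )
    return panel.subset_analytes(kept_names, note=note)


def impute_censored(panel: AssayPanel) -> np.ndarray:
    """Return a complete concentration matrix (pg/mL, sample scale).

    Below-limit cells become 0.5 x lower_limit x dilution_factor; above-range
    cells become 2 x upper_limit x dilution_factor; detected cells pass
    through unchanged.  Idempotent on an already-complete panel.
    """
    if np.any(~np.isfinite(panel.lower_limit)) or np.any(panel.lower_limit <= 0):
        raise ValueError("lower limits must be finite and positive")
    if np.any(~np.isfinite(panel.upper_limit)) or np.any(panel.upper_limit <= 0):
        raise ValueError("upper limits must be finite and positive")
    if np.any(~np.isfinite(panel.dilution_factor)) or np.any(panel.dilution_factor <= 0):
        raise ValueError("dilution factors must be finite and positive")

    filled = panel.concentrations.copy()
    below_fill = 0.5 * panel.lower_limit * panel.dilution_factor
    above_fill = 2.0 * panel.upper_limit * panel.dilution_factor
    for j in range(panel.n_analytes):
        col_flags = panel.censor_flags[:, j]
        filled[col_flags == FLAG_BELOW, j] = below_fill[j]
        filled[col_flags == FLAG_ABOVE, j] = above_fill[j]
    return filled


@dataclass
class CohortTable:
    """Model-ready design matrix and outcome for one cohort.

    ``X`` holds fully transformed analyte columns (log10 -> Yeo-Johnson ->
    standardized), ``y`` the transformed PFI.  ``column_transforms`` and
    ``pfi_transform`` allow new panels to be projected into this space and
    predictions to be inverted back to days.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    column_transforms: dict[str, TransformModel]
    pfi_transform: TransformModel
    pfi_days: np.ndarray
    patient_ids: list[str]
    provenance: list[str] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.patient_ids, columns=self.feature_names)


def build_cohort_table(panel: AssayPanel) -> CohortTable:
    """Run the full preprocessing chain on a detection-filtered panel.

    impute -> log10 -> per-column Yeo-Johnson (fitted on the whole cohort)
    -> standardize, and the same Yeo-Johnson + standardization for PFI days.
    A literal 0 concentration with no flag is treated as below-limit and
    imputed (an instrument artifact, not a measurable zero).
    """
    flags = panel.censor_flags.copy()
    zero_unflagged = (flags == FLAG_NONE) & (panel.concentrations == 0)
    notes = list(panel.provenance)
    if zero_unflagged.any():
        flags[zero_unflagged] = FLAG_BELOW
        notes.append(
            f"re-flagged {int(zero_unflagged.sum())} literal-zero cells as below-limit"
        )
    work = AssayPanel(
        patient_ids=panel.patient_ids,
        cohort_labels=panel.cohort_labels,
        pfi_days=panel.pfi_days,
        analyte_names=panel.analyte_names,
        concentrations=np.where(zero_unflagged, np.nan, panel.concentrations),
        censor_flags=flags,
        lower_limit=panel.lower_limit,
        upper_limit=panel.upper_limit,
        dilution_factor=panel.dilution_factor,
        provenance=notes,
    )
    filled = impute_censored(work)
    if np.any(filled <= 0):
        raise ValueError("non-positive concentration after imputation")
    logged = np.log10(filled)

    transforms: dict[str, TransformModel] = {}
    X = np.empty_like(logged)
    for j, name in enumerate(panel.analyte_names):
        t = fit_yeo_johnson(logged[:, j])
        transforms[name] = t
        X[:, j] = apply_transform(logged[:, j], t)

    pfi_t = fit_yeo_johnson(panel.pfi_days)
    y = apply_transform(panel.pfi_days, pfi_t)

    return CohortTable(
        X=X,
        y=y,
        feature_names=list(panel.analyte_names),
        column_transforms=transforms,
        pfi_transform=pfi_t,
        pfi_days=panel.pfi_days.copy(),
        patient_ids=list(panel.patient_ids),
        provenance=notes + ["imputed, log10, Yeo-Johnson + standardization per column and for PFI"],
    )
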