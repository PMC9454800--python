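"""Descriptive cohort-level analysis: PFI distribution comparison,
per-analyte dispersion and between-cohort tests, and the patient
similarity matrix.

These summaries motivate modeling the two treatment cohorts (NACT, PDS)
separately: their PFI distributions differ while few individual analytes
do, and patients do not cluster by treatment in the similarity matrix.
No multiple-testing correction is applied to the per-analyte tests — they
are descriptive, and the number of tests is reported alongside the
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AssayPanel
from .preprocess import impute_censored

__all__ = ["CohortSummary", "SimilarityMatrix", "summarize_cohorts", "patient_similarity"]


@dataclass
class CohortSummary:
    """Between-cohort comparison of PFI and per-analyte concentrations."""

    n_nact: int
    n_pds: int
    pfi_mean_days: dict[str, float]
    pfi_median_days: dict[str, float]
    mannwhitney_U: float
    mannwhitney_p: float
    analyte_tests: pd.DataFrame  # t statistic + p per shared analyte
    pct_cv_raw: pd.DataFrame  # per-analyte raw-scale %CV within each cohort
    n_tests: int
    excluded_analytes: list[str]


@dataclass
class SimilarityMatrix:
    """Patient-by-patient Pearson correlation of normalized analyte profiles."""

    patient_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.patient_ids)


def _raw_pct_cv(filled: np.ndarray) -> np.ndarray:
    """Raw-scale coefficient of variation per analyte, SD/mean x 100 (ddof=1)."""
    mean = filled.mean(axis=0)
    sd = filled.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean != 0, sd / np.abs(mean) * 100.0, np.nan)


def summarize_cohorts(panel_nact: AssayPanel, panel_pds: AssayPanel) -> CohortSummary:
    """Compare the two treatment cohorts.

    PFI days are compared with a two-sided Mann-Whitney U test (tie-corrected
    normal approximation).  Each analyte present in both panels is compared
    with an equal-variance two-tailed t-test on log10 imputed concentrations,
    uncorrected for multiple testing.  Raw-scale %CV (SD/mean of imputed
    concentrations) is reported per analyte within each cohort.
    """
    filled_n = impute_censored(panel_nact)
    filled_p = impute_censored(panel_pds)
    log_n = np.log10(filled_n)
    log_p = np.log10(filled_p)

    mw = stats.mannwhitneyu(
        panel_nact.pfi_days, panel_pds.pfi_days, alternative="two-sided", method="asymptotic"
    )

    shared = [a for a in panel_nact.analyte_names if a in panel_pds.analyte_names]
    excluded = sorted(
        (set(panel_nact.analyte_names) ^ set(panel_pds.analyte_names))
    )
    rows = []
    for a in shared:
        jn = panel_nact.analyte_names.index(a)
        jp = panel_pds.analyte_names.index(a)
        t = stats.ttest_ind(log_n[:, jn], log_p[:, jp], equal_var=True)
        rows.append((a, float(t.statistic), float(t.pvalue)))
    tests = pd.DataFrame(rows, columns=["analyte", "t_statistic", "p_value"]).set_index("analyte")

    cv_n = pd.Series(_raw_pct_cv(filled_n), index=panel_nact.analyte_names)
    cv_p = pd.Series(_raw_pct_cv(filled_p), index=panel_pds.analyte_names)
    pct_cv = pd.DataFrame({"NACT": cv_n, "PDS": cv_p})

    return CohortSummary(
        n_nact=panel_nact.n_patients,
        n_pds=panel_pds.n_patients,
        pfi_mean_days={
            "NACT": float(panel_nact.pfi_days.mean()),
            "PDS": float(panel_pds.pfi_days.mean()),
        },
        pfi_median_days={
            "NACT": float(np.median(panel_nact.pfi_days)),
            "PDS": float(np.median(panel_pds.pfi_days)),
        },
        mannwhitney_U=float(mw.statistic),
        mannwhitney_p=float(mw.pvalue),
        analyte_tests=tests,
        pct_cv_raw=pct_cv,
        n_tests=len(shared),
        excluded_analytes=excluded,
    )


def patient_similarity(X_combined: pd.DataFrame) -> SimilarityMatrix:
    """Pearson correlation between patients' normalized analyte profiles.

    ``X_combined`` is a patient x analyte DataFrame of power-transform
    normalized concentrations over the analyte intersection of the cohorts.
    Raises when a patient has zero variance across analytes (correlation
    undefined for that profile).
    """
    X = X_combined.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 analytes to correlate profiles")
    sds = X.std(axis=1)
    flat = np.nonzero(sds == 0)[0]
    if len(flat):
        ids = [X_combined.index[i] for i in flat]
        raise ValueError(f"zero-variance analyte profile for patients {ids}")
    values = np.corrcoef(X)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(patient_ids=list(X_combined.index), values=values)
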