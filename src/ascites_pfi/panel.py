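"""Raw assay-panel container and its plain-text serialization.

An :class:`AssayPanel` holds one cohort's multiplex bead-based immunoassay
export: a patient x analyte concentration matrix (pg/mL) with per-cell
censoring flags, per-analyte assay limits and dilution factors, plus the
clinical outcome (platinum-free interval, PFI, in days) and the treatment
cohort label (NACT = neoadjuvant chemotherapy, PDS = primary debulking
surgery).

Concentrations are stored on the *sample* scale (already multiplied by the
assay dilution); the detection limits are stored on the *assay* scale, so a
sample-scale limit is ``limit * dilution_factor``.  Cells outside the assay
range carry a flag (``below`` the lower detection limit or ``above`` the top
standard) and an undefined (NaN) concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Censoring-flag codes used throughout the package.
FLAG_NONE = "none"
FLAG_BELOW = "below"
FLAG_ABOVE = "above"

#: Literal cell markers used in the CSV dialect.
_BELOW_TOKEN = "<LOD"
_ABOVE_TOKEN = ">ULOQ"

COHORT_LABELS = ("NACT", "PDS")


@dataclass
class AssayPanel:
    """One cohort's censored immunoassay export.

    Attributes
    ----------
    patient_ids : list of str
    cohort_labels : list of str
        One of ``"NACT"`` / ``"PDS"`` per patient.
    pfi_days : ndarray, shape (n_patients,)
        Platinum-free interval in days; strictly positive.
    analyte_names : list of str
    concentrations : ndarray, shape (n_patients, n_analytes)
        Sample-scale concentrations in pg/mL; NaN where flagged.
    censor_flags : ndarray of str, same shape
        ``"none"`` / ``"below"`` / ``"above"`` per cell.
    lower_limit : ndarray, shape (n_analytes,)
        Assay-scale lower detection limit (pg/mL).
    upper_limit : ndarray, shape (n_analytes,)
        Assay-scale top standard (pg/mL).
    dilution_factor : ndarray, shape (n_analytes,)
        Dilution applied to the sample for that analyte's assay.
    provenance : list of str
        Human-readable record of filtering/imputation actions applied.
    """

    patient_ids: list[str]
    cohort_labels: list[str]
    pfi_days: np.ndarray
    analyte_names: list[str]
    concentrations: np.ndarray
    censor_flags: np.ndarray
    lower_limit: np.ndarray
    upper_limit: np.ndarray
    dilution_factor: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pfi_days = np.asarray(self.pfi_days, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.censor_flags = np.asarray(self.censor_flags, dtype=object)
        self.lower_limit = np.asarray(self.lower_limit, dtype=float)
        self.upper_limit = np.asarray(self.upper_limit, dtype=float)
        self.dilution_factor = np.asarray(self.dilution_factor, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n, p = len(self.patient_ids), len(self.analyte_names)
        if self.concentrations.shape != (n, p):
            raise ValueError(
                f"concentration matrix shape {self.concentrations.shape} "
                f"inconsistent with {n} patients x {p} analytes"
            )
        if self.censor_flags.shape != (n, p):
            raise ValueError("censor flag matrix shape mismatch")
        if len(self.cohort_labels) != n:
            raise ValueError("cohort label list length mismatch")
        for lab in self.cohort_labels:
            if lab not in COHORT_LABELS:
                raise ValueError(f"unknown cohort label {lab!r}")
        for vec, name in (
            (self.lower_limit, "lower_limit"),
            (self.upper_limit, "upper_limit"),
            (self.dilution_factor, "dilution_factor"),
        ):
            if vec.shape != (p,):
                raise ValueError(f"{name} must have one entry per analyte")
        if self.pfi_days.shape != (n,):
            raise ValueError("pfi_days must have one entry per patient")
        if np.any(self.pfi_days <= 0):
            raise ValueError("PFI must be positive (days)")
        bad = {f for f in self.censor_flags.ravel()} - {FLAG_NONE, FLAG_BELOW, FLAG_ABOVE}
        if bad:
            raise ValueError(f"unknown censor flags {bad}")
        detected = self.censor_flags == FLAG_NONE
        vals = self.concentrations[detected]
        if vals.size and (np.any(~np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("detected cells must hold finite, non-negative concentrations")

    # ------------------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_names)

    def subset_patients(self, indices: list[int] | np.ndarray, note: str | None = None) -> "AssayPanel":
        """Return a panel restricted to the given patient rows."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            patient_ids=[self.patient_ids[i] for i in idx],
            cohort_labels=[self.cohort_labels[i] for i in idx],
            pfi_days=self.pfi_days[idx].copy(),
            concentrations=self.concentrations[idx].copy(),
            censor_flags=self.censor_flags[idx].copy(),
            provenance=self.provenance + ([note] if note else []),
        )

    def subset_analytes(self, names: list[str], note: str | None = None) -> "AssayPanel":
        """Return a panel restricted to ``names`` (order preserved)."""
        idx = [self.analyte_names.index(a) for a in names]
        return replace(
            self,
            analyte_names=list(names),
            concentrations=self.concentrations[:, idx].copy(),
            censor_flags=self.censor_flags[:, idx].copy(),
            lower_limit=self.lower_limit[idx].copy(),
            upper_limit=self.upper_limit[idx].copy(),
            dilution_factor=self.dilution_factor[idx].copy(),
            provenance=self.provenance + ([note] if note else []),
        )


# ----------------------------------------------------------------------
# CSV dialect
# ----------------------------------------------------------------------

def write_panel_csv(panel: AssayPanel, data_path: str | Path, meta_path: str | Path) -> None:
    """Write a panel as a wide patient table plus an analyte-metadata table.

    The data table has columns ``patient_id, cohort, pfi_days`` followed by
    one column per analyte; censored cells are encoded as the literal strings
    ``<LOD`` and ``>ULOQ``.  The metadata table has one row per analyte with
    columns ``analyte, lower_limit_pg_ml, upper_limit_pg_ml, dilution_factor``.
    """
    cells = np.empty(panel.concentrations.shape, dtype=object)
    for i in range(panel.n_patients):
        for j in range(panel.n_analytes):
            flag = panel.censor_flags[i, j]
            if flag == FLAG_BELOW:
                cells[i, j] = _BELOW_TOKEN
            elif flag == FLAG_ABOVE:
                cells[i, j] = _ABOVE_TOKEN
            else:
                cells[i, j] = format(panel.concentrations[i, j], ".17g")
    df = pd.DataFrame(cells, columns=panel.analyte_names)
    df.insert(0, "pfi_days", panel.pfi_days)
    df.insert(0, "cohort", panel.cohort_labels)
    df.insert(0, "patient_id", panel.patient_ids)
    df.to_csv(data_path, index=False)

    meta = pd.DataFrame(
        {
            "analyte": panel.analyte_names,
            "lower_limit_pg_ml": panel.lower_limit,
            "upper_limit_pg_ml": panel.upper_limit,
            "dilution_factor": panel.dilution_factor,
        }
    )
    meta.to_csv(meta_path, index=False)


def read_panel_csv(data_path: str | Path, meta_path: str | Path) -> AssayPanel:
    """Read a panel written by :func:`write_panel_csv`."""
    df = pd.read_csv(data_path, dtype={"patient_id": str, "cohort": str})
    meta = pd.read_csv(meta_path)
    analytes = list(meta["analyte"].astype(str))
    missing = [a for a in analytes if a not in df.columns]
    if missing:
        raise ValueError(f"analytes in metadata but not in data table: {missing}")

    n = len(df)
    conc = np.full((n, len(analytes)), np.nan)
    flags = np.full((n, len(analytes)), FLAG_NONE, dtype=object)
    for j, a in enumerate(analytes):
        col = df[a].astype(str).str.strip()
        below = col == _BELOW_TOKEN
        above = col == _ABOVE_TOKEN
        flags[below, j] = FLAG_BELOW
        flags[above, j] = FLAG_ABOVE
        ok = ~(below | above)
        conc[ok, j] = pd.to_numeric(col[ok]).to_numpy()

    return AssayPanel(
        patient_ids=list(df["patient_id"]),
        cohort_labels=list(df["cohort"]),
        pfi_days=df["pfi_days"].to_numpy(float),
        analyte_names=analytes,
        concentrations=conc,
        censor_flags=flags,
        lower_limit=meta["lower_limit_pg_ml"].to_numpy(float),
        upper_limit=meta["upper_limit_pg_ml"].to_numpy(float),
        dilution_factor=meta["dilution_factor"].to_numpy(float),
    )
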