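"""Subject-level data container and long-format dataset parsing.

The CSV dialect is the de-facto long format: one row per observation with
required columns ID, TIME (hours), DV (concentration, mg/L); the dose comes
from an AMT column (first non-missing value per subject, mg) or an explicit
override; every remaining numeric column is treated as a subject-level
covariate.  Missing values may be empty or NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InputFormatError, InvalidInputError
from .pk_models import DoseRegimen

__all__ = ["SubjectRecord", "subjects_from_dataframe"]


@dataclass
class SubjectRecord:
    """One subject's dose regimen, sampling times, observed concentrations,
    covariates and BLQ flags.

    Times are hours since dosing, concentrations mg/L.  Rows are kept in the
    order supplied by the caller; routines that need time ordering sort
    internally.
    """

    subject_id: str
    dose: DoseRegimen
    times: np.ndarray
    concentrations: np.ndarray
    blq_flags: np.ndarray | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise InvalidInputError(
                f"subject {self.subject_id}: times and concentrations differ in length"
            )
        if np.any(self.times < 0):
            raise InvalidInputError(
                f"subject {self.subject_id}: negative sampling times"
            )
        if self.blq_flags is None:
            self.blq_flags = np.zeros(self.times.shape, dtype=bool)
        else:
            self.blq_flags = np.asarray(self.blq_flags, dtype=bool)
            if self.blq_flags.shape != self.times.shape:
                raise InvalidInputError(
                    f"subject {self.subject_id}: blq_flags length mismatch"
                )

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    def with_observations(self, times, concentrations, blq_flags=None) -> "SubjectRecord":
        return replace(
            self,
            times=np.asarray(times, float),
            concentrations=np.asarray(concentrations, float),
            blq_flags=None if blq_flags is None else np.asarray(blq_flags, bool),
        )


def _numeric_column(df: pd.DataFrame, col: str) -> pd.Series:
    raw = df[col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    bad &= ~raw.astype(str).str.strip().str.upper().isin(["NA", "NAN", "."])
    if bad.any():
        # +2: header line plus 1-based indexing
        line = int(bad.idxmax()) + 2
        raise InputFormatError(
            f"non-numeric value {raw[bad.idxmax()]!r} in column {col!r} (line {line})"
        )
    return values


def subjects_from_dataframe(
    df: pd.DataFrame,
    route: str = "iv_bolus",
    dose: float | None = None,
) -> list[SubjectRecord]:
    """Build :class:`SubjectRecord` objects from a long-format table.

    Columns ID, TIME, DV are required; the dose comes from the first
    non-missing AMT per subject unless ``dose`` overrides it; remaining
    numeric columns become subject covariates (first value per subject).
    Rows with missing DV are dropped; non-numeric TIME/DV raise a row-level
    :class:`InputFormatError`.
    """
    for col in ("ID", "TIME", "DV"):
        if col not in df.columns:
            raise InputFormatError(f"required column {col!r} missing from dataset")
    df = df.reset_index(drop=True)
    time = _numeric_column(df, "TIME")
    dv = _numeric_column(df, "DV")
    amt = _numeric_column(df, "AMT") if "AMT" in df.columns else None
    cov_cols = [c for c in df.columns if c not in ("ID", "TIME", "DV", "AMT")]
    subjects = []
    for sid, idx in df.groupby("ID", sort=False).groups.items():
        idx = list(idx)
        sub_amt = None
        if amt is not None:
            vals = amt[idx].dropna()
            sub_amt = float(vals.iloc[0]) if len(vals) else None
        amount = dose if dose is not None else sub_amt
        if amount is None:
            raise InputFormatError(
                f"subject {sid!r}: no AMT value and no dose override supplied"
            )
        keep = [i for i in idx if pd.notna(dv[i]) and pd.notna(time[i])]
        covariates = {}
        for c in cov_cols:
            vals = pd.to_numeric(df[c][idx], errors="coerce").dropna()
            if len(vals):
                covariates[c] = float(vals.iloc[0])
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                dose=DoseRegimen(amount, route),
                times=time[keep].to_numpy(float),
                concentrations=dv[keep].to_numpy(float),
                covariates=covariates,
            )
        )
    return subjects
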