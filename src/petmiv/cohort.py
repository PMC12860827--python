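"""Cohort table: the per-patient join of scores, PET metrics and clinical data.

One row per patient.  Score cells hold extent grades in {0, 1, 2}; PET
metrics are nonnegative; spirometry is percent-predicted (> 0).  Missing
cells are preserved as missing and flagged — they propagate into the
statistics stage via pairwise deletion, never by silently dropping rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scores import DEFAULT_FEATURES, MODALITIES, REGIONS, EichingerSheet, score_column

__all__ = [
    "CohortError",
    "CohortTable",
    "read_cohort_table",
    "write_cohort_table",
    "METRIC_COLUMNS",
    "SPIROMETRY_COLUMNS",
    "CLINICAL_COLUMNS",
    "cohort_columns",
]

METRIC_COLUMNS: tuple[str, ...] = ("miv_cm3", "miv_pct", "suv_max", "suv_mean", "tlg")
SPIROMETRY_COLUMNS: tuple[str, ...] = ("fvc_pct_pred", "fev1_pct_pred", "fef2575_pct_pred")
CLINICAL_COLUMNS: tuple[str, ...] = ("exacerbations_last_year", "sputum_positive")


class CohortError(ValueError):
    """Invalid cohort table content."""


def cohort_columns(features: tuple[str, ...] = DEFAULT_FEATURES) -> list[str]:
    """Full wide-format column schema, in canonical order."""
    cols = ["patient_id"]
    for modality in MODALITIES:
        for region in REGIONS:
            for feat in features:
                cols.append(score_column(modality, region, feat))
    cols += list(METRIC_COLUMNS) + list(SPIROMETRY_COLUMNS) + list(CLINICAL_COLUMNS)
    return cols


def _score_cols(features) -> list[str]:
    return [
        score_column(m, r, f) for m in MODALITIES for r in REGIONS for f in features
    ]


@dataclass
class CohortTable:
    """Validated per-patient cohort table.

    Attributes
    ----------
    data
        One row per patient, columns per :func:`cohort_columns`.
    features
        Radiological feature list behind the score columns.
    params
        Optional record of the generating parameters (present when the
        table was produced by the synthetic cohort generator; used by
        parameter-recovery tests).
    """

    data: pd.DataFrame
    features: tuple[str, ...] = DEFAULT_FEATURES
    params: dict | None = None

    def __post_init__(self):
        self.data = _validate(self.data, self.features)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list[str]:
        return self.data["patient_id"].tolist()

    def sheet(self, patient_id: str, modality: str) -> EichingerSheet:
        """Reconstruct one patient's score sheet for one modality.

        Raises :class:`CohortError` if the patient is unknown or any of the
        sheet's cells is missing.
        """
        rows = self.data.loc[self.data["patient_id"] == patient_id]
        if rows.empty:
            raise CohortError(f"unknown patient_id {patient_id!r}")
        row = rows.iloc[0]
        cols = [score_column(modality, r, f) for r in REGIONS for f in self.features]
        missing = [c for c in cols if pd.isna(row[c])]
        if missing:
            raise CohortError(
                f"patient {patient_id} ({modality}): missing score cells {missing[:4]}"
            )
        return EichingerSheet.from_columns(
            patient_id, modality, {c: int(row[c]) for c in cols}, self.features
        )

    def total_scores(self, modality: str) -> pd.Series:
        """Per-patient total score for one modality (NaN when any cell missing)."""
        cols = [score_column(modality, r, f) for r in REGIONS for f in self.features]
        return self.data[cols].sum(axis=1, min_count=len(cols)).rename(
            f"{modality.lower()}_total"
        )

    def feature_scores(self, modality: str, feature: str) -> pd.Series:
        cols = [score_column(modality, r, feature) for r in REGIONS]
        return self.data[cols].sum(axis=1, min_count=len(cols))

    def region_scores(self, modality: str, region: str) -> pd.Series:
        cols = [score_column(modality, region, f) for f in self.features]
        return self.data[cols].sum(axis=1, min_count=len(cols))

    def missing_report(self) -> pd.DataFrame:
        """All missing cells, one row per (patient, column)."""
        rows = []
        for _, row in self.data.iterrows():
            for col in self.data.columns:
                if col != "patient_id" and pd.isna(row[col]):
                    rows.append({"patient_id": row["patient_id"], "column": col})
        return pd.DataFrame(rows, columns=["patient_id", "column"])


def _validate(df: pd.DataFrame, features) -> pd.DataFrame:
    expected = cohort_columns(features)
    if "patient_id" not in df.columns:
        raise CohortError("cohort table must have a patient_id column")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise CohortError(f"unknown column(s): {unknown}")
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise CohortError(f"missing column(s): {missing_cols[:6]}")
    df = df[expected].copy()
    df["patient_id"] = df["patient_id"].astype(str)

    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise CohortError(f"duplicated patient id(s): {sorted(set(dup))}")

    for col in _score_cols(features):
        vals = df[col]
        bad = vals.dropna()[~vals.dropna().isin([0, 1, 2])]
        if not bad.empty:
            i = bad.index[0]
            raise CohortError(
                f"score out of range: patient {df.loc[i, 'patient_id']!r}, "
                f"column {col!r}, value {bad.iloc[0]!r} (allowed: 0, 1, 2)"
            )
    for col in METRIC_COLUMNS:
        bad = df[col].dropna()
        if (bad < 0).any():
            i = bad[bad < 0].index[0]
            raise CohortError(
                f"negative metric: patient {df.loc[i, 'patient_id']!r}, column {col!r}"
            )
    for col in SPIROMETRY_COLUMNS:
        bad = df[col].dropna()
        if (bad <= 0).any():
            i = bad[bad <= 0].index[0]
            raise CohortError(
                f"nonpositive %predicted: patient {df.loc[i, 'patient_id']!r}, "
                f"column {col!r}"
            )
    ex = df["exacerbations_last_year"].dropna()
    if ((ex < 0) | (ex != ex.round())).any():
        raise CohortError("exacerbations_last_year must be a nonnegative integer")
    sp = df["sputum_positive"].dropna()
    if not sp.isin([0, 1, True, False]).all():
        raise CohortError("sputum_positive must be 0/1 or missing")
    return df.reset_index(drop=True)


def read_cohort_table(path, features: tuple[str, ...] = DEFAULT_FEATURES) -> CohortTable:
    """Read and validate a cohort CSV (UTF-8, header row, wide score layout)."""
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    df = pd.read_csv(path)
    return CohortTable(df, features=features)


def write_cohort_table(table: CohortTable, path) -> None:
    table.data.to_csv(path, index=False)
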