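"""Cohort selection and comorbidity-indicator construction.

A wave's high-risk cohort is defined from weekly hospitalization-risk
scores: a patient is eligible for a calendar year if at least one weekly
score in that year carries the top-decile flag and the patient has a
primary-care panel assignment overlapping the year.  The entry date is
the first top-decile week.  Chronic-condition indicators are then built
with a 2-year lookback: condition j is present for patient i when at
least one coded encounter mapping to j falls within the closed window
[entry - 730 days, entry].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CONDITIONS",
    "CONDITION_FAMILIES",
    "default_condition_map",
    "IndicatorMatrix",
    "select_cohort",
    "build_indicator_matrix",
    "condition_prevalence",
]

logger = logging.getLogger(__name__)

LOOKBACK_DAYS = 730

# The 26 chronic conditions used as latent-class indicators, grouped for
# readability by the families used when labeling segments.  Names are
# configurable; these defaults follow the multiple-chronic-conditions
# framework common in high-risk primary-care segmentation work.
DEFAULT_CONDITIONS: tuple[str, ...] = (
    # cardiometabolic
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "coronary_artery_disease",
    "congestive_heart_failure",
    "arrhythmia",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "chronic_renal_failure",
    # mental health
    "depression",
    "anxiety",
    "ptsd",
    "bipolar_disorder",
    "psychotic_disorder",
    # substance use
    "alcohol_use_disorder",
    "substance_use_disorder",
    "nicotine_use_disorder",
    # other chronic disease
    "chronic_pulmonary_disease",
    "chronic_liver_disease",
    "thyroid_disorder",
    "arthritis",
    "osteoporosis",
    "dementia",
    "malignant_tumor",
    "gastrointestinal_disorder",
    "obesity",
)

# Condition families used by the deterministic group-labeling rule.
# Conditions outside every family never pull a group toward a family label.
CONDITION_FAMILIES: dict[str, tuple[str, ...]] = {
    "Cardiometabolic": DEFAULT_CONDITIONS[0:9],
    "Mental Health": DEFAULT_CONDITIONS[9:14],
    "Substance Use Disorders": DEFAULT_CONDITIONS[14:17],
}


def default_condition_map(conditions: tuple[str, ...] = DEFAULT_CONDITIONS) -> pd.DataFrame:
    """Two-column (code, condition) map with opaque codes C01..C26.

    Real registries key encounters by diagnosis codes; here each condition
    owns exactly one token.  Many-to-one maps (several codes per
    condition) are equally valid inputs to :func:`build_indicator_matrix`.
    """
    codes = [f"C{i + 1:02d}" for i in range(len(conditions))]
    return pd.DataFrame({"code": codes, "condition": list(conditions)})


@dataclass
class IndicatorMatrix:
    """Patients x conditions binary matrix for one wave."""

    patient_ids: np.ndarray
    conditions: list[str]
    values: np.ndarray  # (n, J) uint8, entries exactly 0/1
    wave: int | str | None = None

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.patient_ids), len(self.conditions)):
            raise ValueError("shape mismatch between ids, conditions and values")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("indicator entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.conditions)
        df.insert(0, "patient_id", self.patient_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, wave=None) -> "IndicatorMatrix":
        df = pd.read_csv(path)
        conditions = [c for c in df.columns if c != "patient_id"]
        return cls(
            patient_ids=df["patient_id"].to_numpy(),
            conditions=conditions,
            values=df[conditions].to_numpy(),
            wave=wave,
        )


def _checked_dates(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        rows = list(series.index[bad][:10])
        raise ValueError(f"malformed {what} dates at rows {rows}")
    return parsed


def select_cohort(risk: pd.DataFrame, panel: pd.DataFrame, year: int) -> pd.DataFrame:
    """High-risk cohort for one calendar year.

    Includes exactly the patients with >= 1 top-decile week starting in
    ``year`` and >= 1 panel interval overlapping the year (any nonzero
    day-level overlap).  Returns columns patient_id, entry_date (the
    earliest top-decile week_start) and wave.
    """
    if len(risk) == 0:
        warnings.warn(f"empty risk table: cohort for {year} is empty")
        return pd.DataFrame({"patient_id": [], "entry_date": pd.to_datetime([]), "wave": []})

    week = _checked_dates(risk["week_start"], "risk week_start")
    top = risk["top_decile"].astype(bool)
    in_year = week.dt.year == year
    hits = risk.loc[top & in_year, ["patient_id"]].copy()
    hits["entry_date"] = week[top & in_year]
    entries = hits.groupby("patient_id", as_index=False)["entry_date"].min()

    year_start = pd.Timestamp(year=year, month=1, day=1)
    year_end = pd.Timestamp(year=year, month=12, day=31)
    pstart = _checked_dates(panel["start"], "panel start")
    pend = _checked_dates(panel["end"], "panel end")
    active = panel.loc[(pstart <= year_end) & (pend >= year_start), "patient_id"].unique()

    cohort = entries[entries["patient_id"].isin(active)].reset_index(drop=True)
    cohort["wave"] = year
    return cohort


def build_indicator_matrix(
    encounters: pd.DataFrame,
    condition_map: pd.DataFrame,
    cohort: pd.DataFrame,
    conditions: list[str] | None = None,
) -> IndicatorMatrix:
    """Binary indicators from coded encounters under the 2-year lookback.

    y_ij = 1 iff patient i has >= 1 encounter whose code maps to
    condition j dated within [entry_date - 730 days, entry_date]
    (closed on both ends).  Cohort patients without any qualifying
    encounter keep an all-zero row.  Codes absent from the map are
    ignored with a logged count; duplicated encounter rows are idempotent.
    """
    if conditions is None:
        # column order fixed by first occurrence in the map
        conditions = list(dict.fromkeys(condition_map["condition"]))
    J = len(conditions)
    cond_index = {c: j for j, c in enumerate(conditions)}

    pids = cohort["patient_id"].to_numpy()
    if len(np.unique(pids)) != len(pids):
        raise ValueError("cohort has duplicate patients")
    pid_index = {p: i for i, p in enumerate(pids)}
    Y = np.zeros((len(pids), J), dtype=np.uint8)

    if len(encounters):
        enc = encounters.merge(condition_map, on="code", how="left")
        unmapped = enc["condition"].isna()
        if unmapped.any():
            logger.info("ignoring %d encounters with unmapped codes", int(unmapped.sum()))
            enc = enc[~unmapped]
        enc = enc.merge(cohort[["patient_id", "entry_date"]], on="patient_id", how="inner")
        if len(enc):
            date = _checked_dates(enc["date"], "encounter")
            entry = pd.to_datetime(enc["entry_date"])
            in_window = (date <= entry) & (date >= entry - pd.Timedelta(days=LOOKBACK_DAYS))
            enc = enc[in_window & enc["condition"].isin(cond_index)]
            if len(enc):
                rows = enc["patient_id"].map(pid_index).to_numpy()
                cols = enc["condition"].map(cond_index).to_numpy()
                Y[rows.astype(int), cols.astype(int)] = 1

    wave = cohort["wave"].iloc[0] if "wave" in cohort.columns and len(cohort) else None
    return IndicatorMatrix(patient_ids=pids, conditions=list(conditions), values=Y, wave=wave)


def condition_prevalence(matrix: IndicatorMatrix) -> pd.Series:
    """Per-condition marginal prevalence (column means)."""
    if matrix.n == 0:
        raise ValueError("empty indicator matrix")
    return pd.Series(matrix.values.mean(axis=0), index=matrix.conditions, name="prevalence")
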