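"""Two-wave stability: class alignment, prevalence drift, status transitions.

The repeated cross-sectional design fits each wave's latent class model
independently, so class indices carry no meaning across waves.  Classes
are matched by an optimal bijection minimizing total L1 distance between
item-probability profiles (Hungarian assignment).  Population stability
is summarized as signed percentage-point prevalence drift; individual
stability as a four-way wave-2 status (retained high risk / improved /
died / out of care) plus a row-percent transition matrix over aligned
group assignments, with UNASSIGNED kept as a category in both waves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .lca_core import LCAParams
from .segmentation import UNASSIGNED, AssignmentResult, GroupProfile, RateReport, overall_prevalence
from .synthetic_cohort import (
    STATUS_DIED,
    STATUS_IMPROVED,
    STATUS_NO_CARE,
    STATUS_RETAINED,
    STATUSES,
)

__all__ = [
    "ClassAlignment",
    "TransitionSummary",
    "align_classes",
    "prevalence_drift",
    "classify_status",
    "status_summary",
    "transition_matrix",
    "switch_rate",
]


@dataclass
class ClassAlignment:
    """Bijection from wave-1 class indices to wave-2 class indices.

    ``mapping[a]`` is the wave-2 class matched to wave-1 class ``a``
    (-1 when K1 > K2 leaves a class unmatched).  UNASSIGNED always maps
    to UNASSIGNED.
    """

    mapping: np.ndarray
    pair_distance: np.ndarray
    total_distance: float

    def wave2_to_wave1(self, g2: np.ndarray) -> np.ndarray:
        """Translate wave-2 class indices into wave-1 index space.

        Wave-2 classes without a wave-1 partner keep their own index
        offset beyond the wave-1 range; UNASSIGNED passes through.
        """
        g2 = np.asarray(g2)
        K1 = len(self.mapping)
        inverse = {int(v): a for a, v in enumerate(self.mapping) if v >= 0}
        out = np.empty(len(g2), dtype=int)
        for i, g in enumerate(g2):
            if g == UNASSIGNED:
                out[i] = UNASSIGNED
            else:
                out[i] = inverse.get(int(g), K1 + int(g))
        return out


def align_classes(params1: LCAParams, params2: LCAParams) -> ClassAlignment:
    """Optimal class matching across waves by L1 profile distance.

    Solves the assignment problem over the K1 x K2 cost matrix
    C[a, b] = sum_j |rho1[a, j] - rho2[b, j]|, guaranteeing the
    global minimum-total-distance bijection on min(K1, K2) classes.
    """
    if params1.J != params2.J:
        raise ValueError("models disagree on the number of indicators")
    cost = np.abs(params1.rho[:, None, :] - params2.rho[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.full(params1.K, -1)
    mapping[rows] = cols
    pair = np.full(params1.K, np.nan)
    pair[rows] = cost[rows, cols]
    return ClassAlignment(
        mapping=mapping,
        pair_distance=pair,
        total_distance=float(cost[rows, cols].sum()),
    )


@dataclass
class DriftTable:
    """Signed percentage-point prevalence differences, wave 2 minus wave 1."""

    overall: pd.Series            # per-condition drift, percentage points
    by_group: pd.DataFrame        # group x condition drift (aligned groups)
    max_abs_overall: float
    max_abs_by_group: float
    unmatched_groups: list[int]


def prevalence_drift(
    profiles1: list[GroupProfile],
    profiles2: list[GroupProfile],
    alignment: ClassAlignment,
) -> DriftTable:
    """Population-level drift between waves, overall and within aligned groups."""
    conds = profiles1[0].conditions
    p1 = {p.group: p for p in profiles1}
    p2 = {p.group: p for p in profiles2}
    overall1 = overall_prevalence(profiles1)
    overall2 = overall_prevalence(profiles2)
    overall = pd.Series(100.0 * (overall2 - overall1), index=conds, name="drift_pp")

    rows, index, unmatched = [], [], []
    for a, b in enumerate(alignment.mapping):
        if b < 0 or a not in p1 or int(b) not in p2 or p1[a].size == 0 or p2[int(b)].size == 0:
            unmatched.append(a)
            continue
        rows.append(100.0 * (p2[int(b)].prevalence - p1[a].prevalence))
        index.append(a)
    if UNASSIGNED in p1 and UNASSIGNED in p2 and p1[UNASSIGNED].size and p2[UNASSIGNED].size:
        rows.append(100.0 * (p2[UNASSIGNED].prevalence - p1[UNASSIGNED].prevalence))
        index.append(UNASSIGNED)
    by_group = pd.DataFrame(rows, index=index, columns=conds)
    return DriftTable(
        overall=overall,
        by_group=by_group,
        max_abs_overall=float(overall.abs().max()),
        max_abs_by_group=float(by_group.abs().to_numpy().max()) if len(by_group) else float("nan"),
        unmatched_groups=unmatched,
    )


def classify_status(
    cohort1: pd.DataFrame,
    risk2: pd.DataFrame,
    deaths: pd.DataFrame,
    panel2: pd.DataFrame | None,
    year2: int,
) -> pd.DataFrame:
    """Wave-2 status for every wave-1 cohort patient.

    Precedence: DIED (death date on or before the end of ``year2``)
    > NO_CARE (no risk score recorded in ``year2``) > HIGH_RISK_RETAINED
    (>= 1 top-decile week) > IMPROVED (scores present, none top-decile).
    Returns columns patient_id, status.
    """
    pids = cohort1["patient_id"].to_numpy()
    year_end = pd.Timestamp(year=year2, month=12, day=31)

    dead: set = set()
    if deaths is not None and len(deaths):
        dd = pd.to_datetime(deaths["death_date"])
        dead = set(deaths.loc[dd <= year_end, "patient_id"])

    top_in_year: set = set()
    scored_in_year: set = set()
    if risk2 is not None and len(risk2):
        week = pd.to_datetime(risk2["week_start"])
        in_year = week.dt.year == year2
        scored_in_year = set(risk2.loc[in_year, "patient_id"])
        top_in_year = set(risk2.loc[in_year & risk2["top_decile"].astype(bool), "patient_id"])

    status = np.empty(len(pids), dtype=object)
    for i, p in enumerate(pids):
        if p in dead:
            status[i] = STATUS_DIED
        elif p not in scored_in_year:
            status[i] = STATUS_NO_CARE
        elif p in top_in_year:
            status[i] = STATUS_RETAINED
        else:
            status[i] = STATUS_IMPROVED
    return pd.DataFrame({"patient_id": pids, "status": status})


def status_summary(statuses: pd.DataFrame) -> pd.DataFrame:
    """Counts and 1-decimal percentages per wave-2 status (of the wave-1 cohort)."""
    if len(statuses) == 0:
        raise ValueError("empty status table")
    n = len(statuses)
    counts = statuses["status"].value_counts()
    rows = []
    for s in STATUSES:
        c = int(counts.get(s, 0))
        rows.append({"status": s, "count": c, "percent": round(100.0 * c / n, 1)})
    return pd.DataFrame(rows)


@dataclass
class TransitionSummary:
    """Wave-1 group x wave-2 outcome transition table plus headline rates."""

    counts: pd.DataFrame    # raw cell counts; rows sum to the wave-1 group sizes
    row_percent: pd.DataFrame
    status: pd.DataFrame    # output of status_summary
    switch: RateReport      # group switching among dual-high-risk patients


def _group_row_labels(K1: int) -> list[str]:
    return [f"class_{a}" for a in range(K1)] + ["unassigned"]


def _join_waves(
    assign1: AssignmentResult,
    assign2: AssignmentResult,
    statuses: pd.DataFrame,
    alignment: ClassAlignment,
) -> pd.DataFrame:
    """Per-wave-1-patient frame: wave-1 group, status, aligned wave-2 group."""
    if assign1.patient_ids is None or assign2.patient_ids is None:
        raise ValueError("assignments must carry patient ids for two-wave joins")
    df = pd.DataFrame({"patient_id": assign1.patient_ids, "g1": assign1.group})
    df = df.merge(statuses, on="patient_id", how="left", validate="one_to_one")
    if df["status"].isna().any():
        raise ValueError("every wave-1 patient needs a wave-2 status")
    w2 = pd.DataFrame({
        "patient_id": assign2.patient_ids,
        "g2": alignment.wave2_to_wave1(assign2.group),
    })
    df = df.merge(w2, on="patient_id", how="left")
    retained = df["status"] == STATUS_RETAINED
    if df.loc[retained, "g2"].isna().any():
        raise ValueError("retained patients missing from the wave-2 assignment")
    return df


def transition_matrix(
    assign1: AssignmentResult,
    assign2: AssignmentResult,
    statuses: pd.DataFrame,
    alignment: ClassAlignment,
) -> TransitionSummary:
    """Row-percent transition table: wave-1 group (incl. unassigned) by
    wave-2 outcome (aligned wave-2 groups, unassigned, improved, died,
    out of care).  Cell counts sum to the wave-1 cohort size."""
    df = _join_waves(assign1, assign2, statuses, alignment)
    K1 = assign1.n_classes
    extra = sorted({int(g) for g in df["g2"].dropna() if g >= K1})
    col_labels = (
        [f"class_{a}" for a in range(K1)]
        + [f"w2_class_{g - K1}" for g in extra]
        + ["unassigned", STATUS_IMPROVED, STATUS_DIED, STATUS_NO_CARE]
    )
    row_labels = _group_row_labels(K1)
    counts = pd.DataFrame(0, index=row_labels, columns=col_labels, dtype=int)

    def row_of(g1: int) -> str:
        return "unassigned" if g1 == UNASSIGNED else f"class_{g1}"

    retained = df["status"] == STATUS_RETAINED
    for status, label in ((STATUS_IMPROVED,) * 2, (STATUS_DIED,) * 2,
                          (STATUS_NO_CARE,) * 2):
        sub = df[df["status"] == status]
        for g1, c in sub.groupby("g1").size().items():
            counts.loc[row_of(int(g1)), label] += int(c)
    for (g1, g2), c in df[retained].groupby(["g1", "g2"]).size().items():
        g2 = int(g2)
        if g2 == UNASSIGNED:
            col = "unassigned"
        elif g2 >= K1:
            col = f"w2_class_{g2 - K1}"
        else:
            col = f"class_{g2}"
        counts.loc[row_of(int(g1)), col] += int(c)

    totals = counts.sum(axis=1)
    row_percent = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    return TransitionSummary(
        counts=counts,
        row_percent=row_percent.round(1),
        status=status_summary(statuses),
        switch=switch_rate(assign1, assign2, statuses, alignment),
    )


def switch_rate(
    assign1: AssignmentResult,
    assign2: AssignmentResult,
    statuses: pd.DataFrame,
    alignment: ClassAlignment,
) -> RateReport:
    """Fraction of dual-high-risk patients whose (aligned) group changed.

    UNASSIGNED counts as a category in both waves, so unassigned-to-
    assigned moves (and the reverse) are switches.
    """
    df = _join_waves(assign1, assign2, statuses, alignment)
    dual = df[df["status"] == STATUS_RETAINED]
    if len(dual) == 0:
        raise ValueError("no dual-high-risk patients")
    switched = int((dual["g1"].to_numpy() != dual["g2"].to_numpy().astype(int)).sum())
    return RateReport(count=switched, total=len(dual))
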