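"""Posterior-threshold group assignment, group profiles and labeling.

A patient joins the modal latent group only when the maximum posterior
reaches the threshold (default 0.5, inclusive); otherwise the patient is
held out as UNASSIGNED, so classification uncertainty is surfaced rather
than hidden.  Profiles report per-group condition prevalence and mean
condition counts, and a deterministic lift rule attaches clinical labels
(family-dominant, "High Complexity", "Low Diagnosis").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_indicators import CONDITION_FAMILIES, IndicatorMatrix

__all__ = [
    "UNASSIGNED",
    "AssignmentResult",
    "RateReport",
    "GroupProfile",
    "assign_patients",
    "assignment_rate",
    "group_profiles",
    "label_groups",
]

logger = logging.getLogger(__name__)

UNASSIGNED = -1
UNASSIGNED_LABEL = "Unassigned"

DEFAULT_LIFT_THRESHOLD = 0.15   # absolute prevalence lift marking a condition "elevated"
DEFAULT_BREADTH_THRESHOLD = 0.6  # fraction of conditions elevated => High Complexity


@dataclass
class AssignmentResult:
    """Hard group assignments with abstention."""

    group: np.ndarray          # assigned class index or UNASSIGNED
    max_posterior: np.ndarray
    threshold: float
    n_classes: int
    patient_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.group)

    @property
    def n_assigned(self) -> int:
        return int((self.group != UNASSIGNED).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"group": self.group, "max_posterior": self.max_posterior})
        if self.patient_ids is not None:
            df.insert(0, "patient_id", self.patient_ids)
        return df


@dataclass(frozen=True)
class RateReport:
    """A count/total pair with its percentage at reporting precision."""

    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total

    @property
    def percent(self) -> float:
        """Percentage at the 1-decimal reporting precision."""
        return round(100.0 * self.count / self.total, 1)

    @property
    def percent_whole(self) -> int:
        return round(100.0 * self.count / self.total)

    def __str__(self) -> str:
        return f"{self.count:,}/{self.total:,} ({self.percent}%)"


def assign_patients(
    posteriors: np.ndarray,
    threshold: float = 0.5,
    patient_ids: np.ndarray | None = None,
) -> AssignmentResult:
    """Modal assignment with abstention below ``threshold``.

    The comparison is inclusive (max >= threshold assigns), and a tie at
    the maximum resolves to the lowest class index — only reachable at
    exactly threshold 0.5 with two equal posteriors.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    tau = np.asarray(posteriors, dtype=float)
    if tau.ndim != 2:
        raise ValueError("posteriors must be an n x K matrix")
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    max_post = tau.max(axis=1)
    group = np.where(max_post >= threshold, tau.argmax(axis=1), UNASSIGNED)
    return AssignmentResult(
        group=group,
        max_posterior=max_post,
        threshold=threshold,
        n_classes=tau.shape[1],
        patient_ids=None if patient_ids is None else np.asarray(patient_ids),
    )


def assignment_rate(result: AssignmentResult) -> RateReport:
    """Fraction of the cohort assigned to any group, with counts."""
    if result.n == 0:
        raise ValueError("empty assignment result")
    return RateReport(count=result.n_assigned, total=result.n)


@dataclass
class GroupProfile:
    """Membership size, condition prevalence and burden for one group."""

    group: int                     # class index or UNASSIGNED
    size: int
    prevalence: np.ndarray         # (J,), NaN row when the group is empty
    mean_conditions: float
    sd_conditions: float
    conditions: list[str] = field(default_factory=list)
    label: str | None = None
    label_ambiguous: bool = False


def group_profiles(
    assignments: AssignmentResult, matrix: IndicatorMatrix
) -> list[GroupProfile]:
    """Per-group condition prevalence and mean +- SD condition counts.

    One profile per model class (0..K-1) plus the UNASSIGNED pool; sizes
    partition the cohort exactly.
    """
    if assignments.n != matrix.n:
        raise ValueError("assignments and indicator matrix are misaligned")
    if assignments.patient_ids is not None and not np.array_equal(
        assignments.patient_ids, matrix.patient_ids
    ):
        raise ValueError("assignments and indicator matrix list different patients")
    counts = matrix.values.sum(axis=1)
    profiles = []
    for g in list(range(assignments.n_classes)) + [UNASSIGNED]:
        mask = assignments.group == g
        size = int(mask.sum())
        if size:
            prev = matrix.values[mask].mean(axis=0)
            mean_c = float(counts[mask].mean())
            sd_c = float(counts[mask].std(ddof=1)) if size > 1 else 0.0
        else:
            prev = np.full(matrix.J, np.nan)
            mean_c, sd_c = float("nan"), float("nan")
        profiles.append(GroupProfile(
            group=g, size=size, prevalence=prev,
            mean_conditions=mean_c, sd_conditions=sd_c,
            conditions=list(matrix.conditions),
            label=UNASSIGNED_LABEL if g == UNASSIGNED else None,
        ))
    return profiles


def profiles_frame(profiles: list[GroupProfile], wave=None) -> pd.DataFrame:
    """Long-format (group, condition, prevalence) table for reporting."""
    rows = []
    for p in profiles:
        for cond, prev in zip(p.conditions, p.prevalence):
            rows.append({
                "group": p.group,
                "label": p.label,
                "condition": cond,
                "prevalence": prev,
                "size": p.size,
                "wave": wave,
            })
    return pd.DataFrame(rows)


def overall_prevalence(profiles: list[GroupProfile]) -> np.ndarray:
    """Cohort-wide prevalence recovered as the size-weighted profile mean."""
    sizes = np.array([p.size for p in profiles], dtype=float)
    prev = np.vstack([np.where(np.isnan(p.prevalence), 0.0, p.prevalence)
                      for p in profiles])
    return (sizes @ prev) / sizes.sum()


def label_groups(
    profiles: list[GroupProfile],
    overall_prev: np.ndarray | None = None,
    families: dict[str, tuple[str, ...]] = CONDITION_FAMILIES,
    lift_threshold: float = DEFAULT_LIFT_THRESHOLD,
    breadth_threshold: float = DEFAULT_BREADTH_THRESHOLD,
    complex_label: str = "High Complexity",
    low_label: str = "Low Diagnosis",
) -> list[GroupProfile]:
    """Deterministic labeling by prevalence lift over the cohort average.

    A condition is "elevated" in a group when its prevalence exceeds the
    overall prevalence by at least ``lift_threshold``.  A group elevated
    across >= ``breadth_threshold`` of all conditions is High Complexity;
    a group with no elevated conditions and below-average burden is Low
    Diagnosis; otherwise the configured family holding the most elevated
    conditions gives its label, with ties flagged as a compound label for
    manual renaming.
    """
    if overall_prev is None:
        overall_prev = overall_prevalence(profiles)
    out = []
    for p in profiles:
        if p.group == UNASSIGNED or p.size == 0:
            out.append(replace(p))
            continue
        lift = p.prevalence - overall_prev
        elevated = {c for c, l in zip(p.conditions, lift) if l >= lift_threshold}
        if len(elevated) / len(p.conditions) >= breadth_threshold:
            label, ambiguous = complex_label, False
        elif not elevated:
            label, ambiguous = low_label, False
        else:
            hits = {fam: len(elevated & set(members)) for fam, members in families.items()}
            best = max(hits.values())
            winners = sorted(fam for fam, h in hits.items() if h == best and best > 0)
            if len(winners) == 1:
                label, ambiguous = winners[0], False
            elif winners:
                label, ambiguous = " / ".join(winners), True
                logger.warning("group %d labeled ambiguously as %r", p.group, label)
            else:
                label, ambiguous = low_label, False
        out.append(replace(p, label=label, label_ambiguous=ambiguous))
    return out
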