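"""Synthetic multi-wave registry generator with known latent-class truth.

Emulates the registry extracts consumed by the pipeline — coded
encounters, weekly hospitalization-risk scores with a top-decile flag,
primary-care panel intervals and vital-status records — for a population
drawn from a 5-class Bernoulli mixture over 26 chronic-condition
indicators.  Because the latent truth (class labels, indicator vectors,
wave-2 statuses) is returned alongside the tables, every downstream
stage — cohort selection, indicator construction, EM estimation, class
assignment, two-wave stability — can be validated by parameter and
label recovery rather than against an inaccessible registry.

A configurable fraction of "boundary" patients is drawn from the 50/50
blend of two classes' item probabilities, conditioned (by rejection
sampling) on the realized vector being posterior-ambiguous under the
generating model — no class reaches the 0.5 assignment threshold.
These low-confidence patients populate the unassigned category
downstream; unconditioned blend draws are almost always decisive over
26 indicators and would leave that category nearly empty.

Wave-2 dynamics: each wave-1 patient dies, drops below the top risk
decile, leaves primary care, or is retained as high risk; retained
patients redraw their class through a row-stochastic transition kernel
and their indicators with per-condition persistence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_indicators import DEFAULT_CONDITIONS, default_condition_map

__all__ = [
    "CLASS_NAMES",
    "STATUS_RETAINED",
    "STATUS_IMPROVED",
    "STATUS_DIED",
    "STATUS_NO_CARE",
    "STATUSES",
    "Wave2Dynamics",
    "TruthConfig",
    "SyntheticTruth",
    "default_truth",
    "generate_wave1",
    "generate_wave2",
    "write_wave",
    "load_config",
]

# Wave-2 status vocabulary (shared with the stability module).
STATUS_RETAINED = "high_risk_retained"
STATUS_IMPROVED = "improved"
STATUS_DIED = "died"
STATUS_NO_CARE = "no_care"
STATUSES = (STATUS_RETAINED, STATUS_IMPROVED, STATUS_DIED, STATUS_NO_CARE)

CLASS_NAMES = (
    "cardiometabolic",
    "mental_health",
    "substance_use",
    "low_diagnosis",
    "high_complexity",
)

# Per-class condition probabilities for the default 5-class truth, columns
# ordered as DEFAULT_CONDITIONS.  One cardiometabolic-elevated class, one
# mental-health-elevated, one substance-use-elevated (with secondary mental
# health burden), one low-prevalence class, and one elevated-everywhere
# class whose expected condition count dominates every other class.
_DEFAULT_ITEM_PROBS = np.array([
    # cardiometabolic class
    [0.90, 0.82, 0.65, 0.60, 0.50, 0.45, 0.32, 0.30, 0.38,
     0.15, 0.10, 0.08, 0.03, 0.02,
     0.06, 0.04, 0.22,
     0.28, 0.06, 0.12, 0.32, 0.08, 0.08, 0.16, 0.22, 0.32],
    # mental health class
    [0.42, 0.36, 0.22, 0.08, 0.05, 0.08, 0.04, 0.06, 0.08,
     0.88, 0.72, 0.68, 0.28, 0.12,
     0.14, 0.12, 0.38,
     0.18, 0.06, 0.14, 0.28, 0.05, 0.04, 0.07, 0.26, 0.28],
    # substance use class
    [0.35, 0.26, 0.16, 0.08, 0.06, 0.06, 0.05, 0.07, 0.07,
     0.52, 0.40, 0.32, 0.18, 0.14,
     0.88, 0.78, 0.82,
     0.22, 0.24, 0.05, 0.16, 0.03, 0.03, 0.06, 0.22, 0.12],
    # low diagnosis class
    [0.42, 0.34, 0.18, 0.06, 0.04, 0.06, 0.03, 0.04, 0.05,
     0.12, 0.07, 0.05, 0.015, 0.012,
     0.04, 0.025, 0.16,
     0.08, 0.025, 0.07, 0.22, 0.03, 0.025, 0.07, 0.14, 0.22],
    # high complexity class
    [0.94, 0.88, 0.75, 0.72, 0.68, 0.58, 0.52, 0.46, 0.62,
     0.66, 0.55, 0.45, 0.22, 0.13,
     0.45, 0.38, 0.58,
     0.55, 0.32, 0.22, 0.45, 0.16, 0.20, 0.32, 0.50, 0.48],
])

_DEFAULT_MIXING = np.array([0.25, 0.20, 0.17, 0.27, 0.11])


@dataclass(frozen=True)
class Wave2Dynamics:
    """Per-class wave-2 fate probabilities and the class-transition kernel.

    For each class: p_death + p_improve + p_leave <= 1; the remainder is
    the probability of staying high risk into wave 2.  Retained patients
    redraw their class from the row-stochastic ``class_transition``
    kernel.  A wave-1-present condition is re-coded in the wave-2
    lookback with probability max(condition_persistence, class rate).
    """

    p_death: np.ndarray
    p_improve: np.ndarray
    p_leave: np.ndarray
    class_transition: np.ndarray
    condition_persistence: float = 0.85

    def __post_init__(self) -> None:
        for name in ("p_death", "p_improve", "p_leave"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        kernel = np.asarray(self.class_transition, dtype=float)
        object.__setattr__(self, "class_transition", kernel)
        K = self.p_death.shape[0]
        if self.p_improve.shape != (K,) or self.p_leave.shape != (K,):
            raise ValueError("per-class fate vectors must share one length")
        total = self.p_death + self.p_improve + self.p_leave
        if np.any(total > 1 + 1e-12) or np.any(self.p_death < 0) or np.any(
            self.p_improve < 0
        ) or np.any(self.p_leave < 0):
            raise ValueError("per-class fate probabilities must be >= 0 and sum to <= 1")
        if kernel.shape != (K, K):
            raise ValueError("class_transition must be K x K")
        if np.any(kernel < 0) or not np.allclose(kernel.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("class_transition rows must be nonnegative and sum to 1")
        if not 0.0 <= self.condition_persistence <= 1.0:
            raise ValueError("condition_persistence must lie in [0, 1]")

    @property
    def p_retain(self) -> np.ndarray:
        return 1.0 - self.p_death - self.p_improve - self.p_leave


@dataclass(frozen=True)
class TruthConfig:
    """Generative truth for the synthetic registries."""

    n_patients: int
    n_conditions: int = 26
    K_true: int = 5
    mixing: np.ndarray = field(default_factory=lambda: _DEFAULT_MIXING.copy())
    item_probs: np.ndarray = field(default_factory=lambda: _DEFAULT_ITEM_PROBS.copy())
    boundary_fraction: float = 0.0
    dynamics: Wave2Dynamics | None = None
    seed: int = 0
    wave1_year: int = 2018
    wave2_year: int = 2020
    condition_names: tuple[str, ...] = DEFAULT_CONDITIONS
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        mixing = np.asarray(self.mixing, dtype=float)
        probs = np.asarray(self.item_probs, dtype=float)
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if mixing.shape != (self.K_true,):
            raise ValueError("mixing must have K_true entries")
        if abs(mixing.sum() - 1.0) > 1e-12:
            raise ValueError("mixing must sum to 1 within 1e-12")
        if probs.shape != (self.K_true, self.n_conditions):
            raise ValueError("item_probs must be K_true x n_conditions")
        if np.any(probs <= 0) or np.any(probs >= 1):
            raise ValueError("item_probs must lie strictly inside (0, 1)")
        if not 0.0 <= self.boundary_fraction < 0.5:
            raise ValueError("boundary_fraction must lie in [0, 0.5)")
        if len(self.condition_names) != self.n_conditions:
            raise ValueError("condition_names length must equal n_conditions")
        object.__setattr__(self, "mixing", mixing / mixing.sum())
        object.__setattr__(self, "item_probs", probs)
        if self.dynamics is not None and self.dynamics.p_death.shape[0] != self.K_true:
            raise ValueError("dynamics are sized for a different K_true")

    def to_dict(self) -> dict:
        d = {
            "n_patients": int(self.n_patients),
            "n_conditions": int(self.n_conditions),
            "K_true": int(self.K_true),
            "mixing": self.mixing.tolist(),
            "item_probs": self.item_probs.tolist(),
            "boundary_fraction": float(self.boundary_fraction),
            "seed": int(self.seed),
            "wave1_year": int(self.wave1_year),
            "wave2_year": int(self.wave2_year),
            "condition_names": list(self.condition_names),
            "class_names": list(self.class_names),
        }
        if self.dynamics is not None:
            d["dynamics"] = {
                "p_death": self.dynamics.p_death.tolist(),
                "p_improve": self.dynamics.p_improve.tolist(),
                "p_leave": self.dynamics.p_leave.tolist(),
                "class_transition": self.dynamics.class_transition.tolist(),
                "condition_persistence": float(self.dynamics.condition_persistence),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthConfig":
        d = dict(d)
        dyn = d.pop("dynamics", None)
        if dyn is not None:
            dyn = Wave2Dynamics(**dyn)
        if "condition_names" in d:
            d["condition_names"] = tuple(d["condition_names"])
        if "class_names" in d:
            d["class_names"] = tuple(d["class_names"])
        return cls(dynamics=dyn, **d)


def load_config(path) -> TruthConfig:
    """Read a TruthConfig from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        return TruthConfig.from_dict(yaml.safe_load(fh))


def default_dynamics() -> Wave2Dynamics:
    """Wave-2 fates calibrated so the class-weighted aggregates land near
    14.2% death, 25.3% improved risk, 1.3% out of care and 59.2% retained,
    with the high-complexity class the least likely to improve and the
    most likely to die."""
    return Wave2Dynamics(
        p_death=np.array([0.18, 0.10, 0.12, 0.10, 0.28]),
        p_improve=np.array([0.17, 0.32, 0.32, 0.29, 0.128]),
        p_leave=np.full(5, 0.013),
        class_transition=np.array([
            [0.76, 0.05, 0.03, 0.06, 0.10],
            [0.08, 0.62, 0.12, 0.08, 0.10],
            [0.06, 0.12, 0.60, 0.06, 0.16],
            [0.12, 0.08, 0.06, 0.64, 0.10],
            [0.12, 0.05, 0.05, 0.03, 0.75],
        ]),
        condition_persistence=0.85,
    )


def default_truth(n_patients: int = 20_000, boundary_fraction: float = 0.08,
                  seed: int = 0) -> TruthConfig:
    """The default 5-class, 26-condition truth.

    Class mixing (0.25, 0.20, 0.17, 0.27, 0.11) with a boundary fraction
    chosen so that, after fitting and thresholded assignment, the
    expected assigned shares approximate 23/18/16/25/10% of the cohort
    with roughly 8% unassigned.
    """
    return TruthConfig(
        n_patients=n_patients,
        boundary_fraction=boundary_fraction,
        dynamics=default_dynamics(),
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Oracle labels for one wave of a synthetic cohort.

    ``primary_class`` is the latent class driving dynamics; boundary
    patients additionally carry a ``secondary_class`` (else -1) and draw
    indicators from the ambiguity-conditioned 50/50 blend of the two
    classes' item probabilities.  For wave 2, ``status`` records each
    wave-1 patient's fate; class and indicators are populated only for
    retained patients (class -1, all-zero row otherwise).
    """

    wave: int
    patient_ids: np.ndarray
    primary_class: np.ndarray
    secondary_class: np.ndarray
    indicators: np.ndarray
    entry_date: np.ndarray
    status: np.ndarray | None = None  # wave-2 only

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        if self.status is not None:
            if not set(np.unique(self.status)) <= set(STATUSES):
                raise ValueError("unknown status labels")
            dead = self.status == STATUS_DIED
            if np.any(self.primary_class[dead] >= 0):
                raise ValueError("dead patients must carry no wave-2 class")
        for arr in (self.primary_class, self.secondary_class, self.entry_date):
            if len(arr) != n:
                raise ValueError("truth arrays must share one length")

    @property
    def is_boundary(self) -> np.ndarray:
        return self.secondary_class >= 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "patient_id": self.patient_ids,
            "primary_class": self.primary_class,
            "secondary_class": self.secondary_class,
            "entry_date": self.entry_date,
        })
        if self.status is not None:
            df["status"] = self.status
        for j in range(self.indicators.shape[1]):
            df[f"y{j:02d}"] = self.indicators[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# calendar helpers

def _mondays(year: int) -> np.ndarray:
    """All Mondays of a calendar year as datetime64[D]."""
    days = np.arange(np.datetime64(f"{year}-01-01"), np.datetime64(f"{year + 1}-01-01"))
    # 1970-01-01 was a Thursday; Monday satisfies (epoch_day + 3) % 7 == 0
    return days[(days.astype(int) + 3) % 7 == 0]


def _draw_indicator_probs(config: TruthConfig, primary: np.ndarray,
                          secondary: np.ndarray) -> np.ndarray:
    """Per-patient item probabilities: the class row, or the 50/50 blend of
    the two classes for boundary patients."""
    probs = config.item_probs[primary]
    boundary = secondary >= 0
    if boundary.any():
        probs = probs.copy()
        probs[boundary] = 0.5 * (
            config.item_probs[primary[boundary]] + config.item_probs[secondary[boundary]]
        )
    return probs


def _true_params(config: TruthConfig):
    from .lca_core import LCAParams

    return LCAParams(pi=config.mixing, rho=config.item_probs)


def _draw_ambiguous(
    rng: np.random.Generator,
    probs: np.ndarray,
    config: TruthConfig,
    threshold: float = 0.5,
    max_rounds: int = 500,
) -> np.ndarray:
    """Indicator draws from ``probs`` conditioned on posterior ambiguity.

    Rejection-samples each row until no class posterior (under the
    generating model) reaches ``threshold``.  Acceptance is ~10% per
    round for between-class blends, so a handful of rounds suffices;
    rows still undecided after ``max_rounds`` keep their last draw.
    """
    from .lca_core import e_step

    params = _true_params(config)
    Y = (rng.random(probs.shape) < probs).astype(np.uint8)
    pending = np.arange(Y.shape[0])
    for _ in range(max_rounds):
        if len(pending) == 0:
            break
        tau = e_step(params, Y[pending].astype(float))
        pending = pending[tau.max(axis=1) >= threshold]
        if len(pending):
            Y[pending] = rng.random((len(pending), probs.shape[1])) < probs[pending]
    return Y


def _risk_table(
    rng: np.random.Generator,
    patient_ids: np.ndarray,
    year: int,
    entry_week_idx: np.ndarray | None,
    n_extra_weeks: int = 6,
    p_top_after_entry: float = 0.6,
) -> pd.DataFrame:
    """Weekly risk-score rows for one wave.

    Scores are percentile-style values in [0, 1]; the top-decile flag is
    score >= 0.9.  When ``entry_week_idx`` is given, that week is the
    patient's first top-decile week (earlier sampled weeks stay below the
    decile, later ones re-enter it with probability ``p_top_after_entry``).
    When it is None the patient never reaches the top decile ("improved").
    """
    weeks = _mondays(year)
    W = len(weeks)
    n = len(patient_ids)
    if n == 0:
        return pd.DataFrame({"patient_id": [], "week_start": [], "score": [], "top_decile": []})

    # distinct extra observation weeks per patient
    extra_idx = np.argsort(rng.random((n, W)), axis=1)[:, :n_extra_weeks]

    rows_pid, rows_week, rows_score, rows_top = [], [], [], []
    if entry_week_idx is not None:
        rows_pid.append(patient_ids)
        rows_week.append(weeks[entry_week_idx])
        rows_score.append(rng.uniform(0.90, 0.995, size=n))
        rows_top.append(np.ones(n, dtype=bool))

    for c in range(n_extra_weeks):
        idx = extra_idx[:, c]
        if entry_week_idx is not None:
            keep = idx != entry_week_idx
            after = idx > entry_week_idx
            top = after & (rng.random(n) < p_top_after_entry)
        else:
            keep = np.ones(n, dtype=bool)
            top = np.zeros(n, dtype=bool)
        score = np.where(top, rng.uniform(0.90, 0.995, n), rng.uniform(0.30, 0.90, n))
        rows_pid.append(patient_ids[keep])
        rows_week.append(weeks[idx[keep]])
        rows_score.append(score[keep])
        rows_top.append(top[keep])

    df = pd.DataFrame({
        "patient_id": np.concatenate(rows_pid),
        "week_start": np.concatenate(rows_week),
        "score": np.round(np.concatenate(rows_score), 6),
        "top_decile": np.concatenate(rows_top),
    })
    # one record per patient-week
    df = df.drop_duplicates(["patient_id", "week_start"], keep="first")
    return df.sort_values(["patient_id", "week_start"], kind="stable").reset_index(drop=True)


def _encounter_table(rng: np.random.Generator, patient_ids: np.ndarray,
                     Y: np.ndarray, entry: np.ndarray,
                     codes: np.ndarray) -> pd.DataFrame:
    """One encounter per present condition, dated uniformly in the lookback window."""
    pi_idx, cond_idx = np.nonzero(Y)
    offsets = rng.integers(0, 731, size=len(pi_idx))
    dates = entry[pi_idx] - offsets.astype("timedelta64[D]")
    df = pd.DataFrame({
        "patient_id": patient_ids[pi_idx],
        "date": dates,
        "code": codes[cond_idx],
    })
    return df.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def _panel_table(rng: np.random.Generator, patient_ids: np.ndarray,
                 year: int) -> pd.DataFrame:
    n = len(patient_ids)
    start = np.datetime64(f"{year}-01-01") - rng.integers(30, 400, n).astype("timedelta64[D]")
    end = np.datetime64(f"{year}-12-31") + rng.integers(30, 400, n).astype("timedelta64[D]")
    return pd.DataFrame({"patient_id": patient_ids, "start": start, "end": end})


# ---------------------------------------------------------------------------
# wave generators

def _patient_ids(n: int) -> np.ndarray:
    return np.array([f"P{i:07d}" for i in range(n)])


def generate_wave1(
    config: TruthConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """First-wave registries (encounters, risk scores, panel) plus truth labels."""
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    n, J, K = config.n_patients, config.n_conditions, config.K_true
    pids = _patient_ids(n)

    primary = rng.choice(K, size=n, p=config.mixing)
    secondary = np.full(n, -1)
    boundary = rng.random(n) < config.boundary_fraction
    if boundary.any():
        # second class uniform over the remaining K-1
        shift = rng.integers(1, K, size=int(boundary.sum()))
        secondary[boundary] = (primary[boundary] + shift) % K

    probs = _draw_indicator_probs(config, primary, secondary)
    Y = (rng.random((n, J)) < probs).astype(np.uint8)
    if boundary.any():
        Y[boundary] = _draw_ambiguous(rng, probs[boundary], config)

    weeks = _mondays(config.wave1_year)
    entry_idx = rng.integers(0, len(weeks), size=n)
    entry = weeks[entry_idx]

    codes = default_condition_map(config.condition_names)["code"].to_numpy()
    encounters = _encounter_table(rng, pids, Y, entry, codes)
    risk = _risk_table(rng, pids, config.wave1_year, entry_idx)
    panel = _panel_table(rng, pids, config.wave1_year)

    truth = SyntheticTruth(
        wave=config.wave1_year,
        patient_ids=pids,
        primary_class=primary,
        secondary_class=secondary,
        indicators=Y,
        entry_date=entry,
    )
    return encounters, risk, panel, truth


def generate_wave2(
    config: TruthConfig, truth1: SyntheticTruth, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Second-wave registries for the wave-1 population, plus deaths and truth.

    Every wave-1 patient draws exactly one status.  Retained high-risk
    patients transition class, redraw indicators with condition
    persistence, and receive top-decile risk scores; improved patients
    keep sub-decile scores; leavers lose panel coverage and risk scores;
    the dead get a death date between the waves.
    """
    if truth1 is None or truth1.wave != config.wave1_year:
        raise ValueError("truth1 must come from generate_wave1 with the same config")
    if len(truth1.patient_ids) != config.n_patients:
        raise ValueError("truth1 size does not match config.n_patients")
    dyn = config.dynamics
    if dyn is None:
        raise ValueError("config.dynamics is required for wave-2 generation")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    n, J, K = config.n_patients, config.n_conditions, config.K_true
    pids = truth1.patient_ids
    c1 = truth1.primary_class

    # status draw from per-class cumulative thresholds
    u = rng.random(n)
    t_death = dyn.p_death[c1]
    t_improve = t_death + dyn.p_improve[c1]
    t_leave = t_improve + dyn.p_leave[c1]
    status = np.where(
        u < t_death, STATUS_DIED,
        np.where(u < t_improve, STATUS_IMPROVED,
                 np.where(u < t_leave, STATUS_NO_CARE, STATUS_RETAINED)),
    ).astype(object)
    retained = status == STATUS_RETAINED
    improved = status == STATUS_IMPROVED
    died = status == STATUS_DIED

    # class transition for retained patients; boundary patients stay boundary
    c2 = np.full(n, -1)
    s2 = np.full(n, -1)
    if retained.any():
        r_idx = np.flatnonzero(retained)
        cum = np.cumsum(dyn.class_transition[c1[r_idx]], axis=1)
        c2[r_idx] = (rng.random(len(r_idx))[:, None] < cum).argmax(axis=1)
        was_boundary = truth1.secondary_class[r_idx] >= 0
        if was_boundary.any():
            b_idx = r_idx[was_boundary]
            shift = rng.integers(1, K, size=len(b_idx))
            s2[b_idx] = (c2[b_idx] + shift) % K

    # indicators: fresh class draw with persistence applied to wave-1 positives
    Y2 = np.zeros((n, J), dtype=np.uint8)
    if retained.any():
        r_idx = np.flatnonzero(retained)
        probs = _draw_indicator_probs(config, c2[r_idx], s2[r_idx])
        probs = np.where(truth1.indicators[r_idx] == 1,
                         np.maximum(dyn.condition_persistence, probs), probs)
        Y2[r_idx] = rng.random((len(r_idx), J)) < probs
        is_boundary2 = s2[r_idx] >= 0
        if is_boundary2.any():
            b_idx = r_idx[is_boundary2]
            Y2[b_idx] = _draw_ambiguous(rng, probs[is_boundary2], config)

    weeks = _mondays(config.wave2_year)
    entry_idx = np.full(n, -1)
    entry2 = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    if retained.any():
        r_idx = np.flatnonzero(retained)
        entry_idx[r_idx] = rng.integers(0, len(weeks), size=len(r_idx))
        entry2[r_idx] = weeks[entry_idx[r_idx]]

    codes = default_condition_map(config.condition_names)["code"].to_numpy()
    r_idx = np.flatnonzero(retained)
    encounters = _encounter_table(rng, pids[r_idx], Y2[r_idx], entry2[r_idx], codes)
    risk_parts = [
        _risk_table(rng, pids[r_idx], config.wave2_year, entry_idx[r_idx]),
        _risk_table(rng, pids[improved], config.wave2_year, None),
    ]
    nonempty = [r for r in risk_parts if len(r)]
    risk = pd.concat(nonempty, ignore_index=True) if nonempty else risk_parts[0]
    risk = risk.sort_values(["patient_id", "week_start"], kind="stable").reset_index(drop=True)

    in_care = retained | improved
    panel = _panel_table(rng, pids[in_care], config.wave2_year)
    # leavers keep a stale interval that ends before the wave-2 year
    leavers = status == STATUS_NO_CARE
    if leavers.any():
        lp = pids[leavers]
        l_start = np.datetime64(f"{config.wave1_year}-01-01") - rng.integers(
            30, 400, len(lp)).astype("timedelta64[D]")
        l_end = np.datetime64(f"{config.wave1_year}-12-31") + rng.integers(
            0, 300, len(lp)).astype("timedelta64[D]")
        stale = pd.DataFrame({"patient_id": lp, "start": l_start, "end": l_end})
        panel = pd.concat([p for p in (panel, stale) if len(p)], ignore_index=True)
    panel = panel.sort_values("patient_id", kind="stable").reset_index(drop=True)

    # deaths strictly between the waves
    gap_start = np.datetime64(f"{config.wave1_year + 1}-01-01")
    gap_days = int(
        (np.datetime64(f"{config.wave2_year}-01-01") - gap_start)
        / np.timedelta64(1, "D")
    )
    d_idx = np.flatnonzero(died)
    deaths = pd.DataFrame({
        "patient_id": pids[d_idx],
        "death_date": gap_start + rng.integers(0, max(gap_days, 1), len(d_idx)).astype(
            "timedelta64[D]"),
    })

    truth2 = SyntheticTruth(
        wave=config.wave2_year,
        patient_ids=pids,
        primary_class=c2,
        secondary_class=s2,
        indicators=Y2,
        entry_date=entry2,
        status=status,
    )
    return encounters, risk, panel, deaths, truth2


# ---------------------------------------------------------------------------
# persistence

def write_wave(
    outdir,
    encounters: pd.DataFrame,
    risk: pd.DataFrame,
    panel: pd.DataFrame,
    truth: SyntheticTruth,
    deaths: pd.DataFrame | None = None,
) -> None:
    """Write one wave's tables as CSV (ISO-8601 dates) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    encounters.to_csv(outdir / "encounters.csv", index=False)
    risk.to_csv(outdir / "risk.csv", index=False)
    panel.to_csv(outdir / "panel.csv", index=False)
    truth.to_csv(outdir / "truth.csv")
    if deaths is not None:
        deaths.to_csv(outdir / "deaths.csv", index=False)


def simulate_to_dir(config: TruthConfig, seed: int, outdir) -> None:
    """Generate both waves and persist everything a downstream run needs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enc1, risk1, panel1, truth1 = generate_wave1(config, seed)
    enc2, risk2, panel2, deaths, truth2 = generate_wave2(config, truth1, seed)
    write_wave(outdir / "wave1", enc1, risk1, panel1, truth1)
    write_wave(outdir / "wave2", enc2, risk2, panel2, truth2, deaths=deaths)
    default_condition_map(config.condition_names).to_csv(
        outdir / "condition_map.csv", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump({"config": config.to_dict(), "seed": int(seed)}, fh, indent=2)
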