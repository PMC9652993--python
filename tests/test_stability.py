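"""Tests for cross-wave alignment, drift, status classification and transitions."""

import itertools

import numpy as np
import pandas as pd
import pytest

import riskseg as rs
from riskseg.lca_core import LCAParams
from riskseg.segmentation import UNASSIGNED, AssignmentResult, GroupProfile
from riskseg.stability import (
    align_classes,
    classify_status,
    prevalence_drift,
    status_summary,
    switch_rate,
    transition_matrix,
)
from riskseg.synthetic_cohort import (
    STATUS_DIED,
    STATUS_IMPROVED,
    STATUS_NO_CARE,
    STATUS_RETAINED,
)

# ---------------------------------------------------------------------------
# class alignment


def _params(rho, pi=None):
    K = rho.shape[0]
    return LCAParams(pi=np.full(K, 1 / K) if pi is None else pi, rho=rho)


def test_align_recovers_permutation_with_zero_distance():
    rng = np.random.default_rng(0)
    rho = rng.uniform(0.1, 0.9, (5, 8))
    perm = np.array([3, 0, 4, 1, 2])
    alignment = align_classes(_params(rho), _params(rho[perm]))
    # mapping[a] = position of class a inside the permuted model
    assert np.array_equal(perm[alignment.mapping], np.arange(5))
    assert alignment.total_distance == pytest.approx(0.0, abs=1e-12)


def test_align_obvious_two_class_case():
    rho1 = np.array([[0.1], [0.9]])
    rho2 = np.array([[0.15], [0.85]])
    alignment = align_classes(_params(rho1), _params(rho2))
    assert alignment.mapping.tolist() == [0, 1]


@pytest.mark.parametrize("K", [3, 5, 6])
def test_align_matches_bruteforce_minimum(K):
    rng = np.random.default_rng(K)
    for _ in range(4):
        rho1 = rng.uniform(0.05, 0.95, (K, 7))
        rho2 = rng.uniform(0.05, 0.95, (K, 7))
        alignment = align_classes(_params(rho1), _params(rho2))
        cost = np.abs(rho1[:, None, :] - rho2[None, :, :]).sum(axis=2)
        best = min(
            sum(cost[a, p[a]] for a in range(K))
            for p in itertools.permutations(range(K))
        )
        assert alignment.total_distance == pytest.approx(best, abs=1e-10)


def test_align_dimension_mismatch():
    with pytest.raises(ValueError):
        align_classes(_params(np.full((2, 3), 0.5)), _params(np.full((2, 4), 0.5)))


# ---------------------------------------------------------------------------
# prevalence drift


def _profile(group, prevalence, size=100, conds=None):
    prevalence = np.asarray(prevalence, dtype=float)
    return GroupProfile(
        group=group, size=size, prevalence=prevalence,
        mean_conditions=float(prevalence.sum()), sd_conditions=1.0,
        conditions=conds or [f"c{j}" for j in range(len(prevalence))],
    )


def _identity_alignment(K):
    from riskseg.stability import ClassAlignment

    return ClassAlignment(mapping=np.arange(K), pair_distance=np.zeros(K),
                          total_distance=0.0)


def test_drift_zero_for_identical_profiles():
    profiles = [_profile(0, [0.2, 0.4]), _profile(1, [0.6, 0.1]),
                _profile(UNASSIGNED, [0.3, 0.3], size=10)]
    drift = prevalence_drift(profiles, profiles, _identity_alignment(2))
    assert drift.max_abs_overall == 0.0
    assert drift.max_abs_by_group == 0.0


def test_drift_single_cell_percentage_points():
    p1 = [_profile(0, [0.28, 0.5]), _profile(UNASSIGNED, [0.28, 0.5], size=0)]
    p2 = [_profile(0, [0.42, 0.5]), _profile(UNASSIGNED, [0.42, 0.5], size=0)]
    drift = prevalence_drift(p1, p2, _identity_alignment(1))
    assert drift.by_group.loc[0, "c0"] == pytest.approx(14.0)
    assert drift.by_group.loc[0, "c1"] == pytest.approx(0.0)


def test_drift_antisymmetry():
    rng = np.random.default_rng(1)
    p1 = [_profile(0, rng.uniform(0.1, 0.9, 5)), _profile(1, rng.uniform(0.1, 0.9, 5))]
    p2 = [_profile(0, rng.uniform(0.1, 0.9, 5)), _profile(1, rng.uniform(0.1, 0.9, 5))]
    fwd = prevalence_drift(p1, p2, _identity_alignment(2))
    rev = prevalence_drift(p2, p1, _identity_alignment(2))
    assert np.allclose(fwd.overall.to_numpy(), -rev.overall.to_numpy())
    assert np.allclose(fwd.by_group.to_numpy(), -rev.by_group.to_numpy())


def test_drift_between_independent_same_truth_waves_is_sampling_noise():
    """Two independent draws from one truth differ by binomial noise only."""
    cfg = rs.default_truth(n_patients=50_000)
    _, _, _, t1 = rs.generate_wave1(cfg, seed=31)
    _, _, _, t2 = rs.generate_wave1(cfg, seed=32)
    drift_pp = 100 * np.abs(t1.indicators.mean(0) - t2.indicators.mean(0))
    assert drift_pp.max() < 1.5


# ---------------------------------------------------------------------------
# status classification and summary


def test_classify_status_precedence():
    cohort1 = pd.DataFrame({"patient_id": ["dead", "improved", "retained", "gone"]})
    risk2 = pd.DataFrame({
        "patient_id": ["improved", "improved", "retained", "dead"],
        "week_start": ["2020-02-03", "2020-06-01", "2020-06-01", "2020-06-01"],
        "score": [0.5, 0.6, 0.95, 0.95],
        "top_decile": [False, False, True, True],
    })
    deaths = pd.DataFrame({"patient_id": ["dead"], "death_date": ["2019-06-01"]})
    statuses = classify_status(cohort1, risk2, deaths, None, 2020)
    expect = {
        "dead": STATUS_DIED,        # death outranks the top-decile score
        "improved": STATUS_IMPROVED,
        "retained": STATUS_RETAINED,
        "gone": STATUS_NO_CARE,     # absent from every wave-2 table
    }
    assert dict(zip(statuses["patient_id"], statuses["status"])) == expect


def test_status_summary_worked_example_and_partition():
    statuses = pd.DataFrame({
        "patient_id": np.arange(951_771).astype(str),
        "status": np.repeat(
            [STATUS_RETAINED, STATUS_DIED, STATUS_IMPROVED, STATUS_NO_CARE],
            [563_725, 135_151, 240_524, 12_371],
        ),
    })
    summary = status_summary(statuses).set_index("status")
    assert summary.loc[STATUS_RETAINED, "percent"] == 59.2
    assert summary["count"].sum() == 951_771
    assert summary["percent"].sum() == pytest.approx(100.0, abs=0.2)


def test_status_summary_equal_counts():
    statuses = pd.DataFrame({
        "patient_id": np.arange(40).astype(str),
        "status": np.repeat(
            [STATUS_RETAINED, STATUS_DIED, STATUS_IMPROVED, STATUS_NO_CARE], 10),
    })
    assert (status_summary(statuses)["percent"] == 25.0).all()


# ---------------------------------------------------------------------------
# transitions and switch rate


def _assignment(groups, ids, K):
    groups = np.asarray(groups)
    return AssignmentResult(
        group=groups,
        max_posterior=np.where(groups == UNASSIGNED, 0.4, 0.9),
        threshold=0.5,
        n_classes=K,
        patient_ids=np.asarray(ids),
    )


def test_transition_identity_scenario_is_diagonal():
    ids = [f"p{i}" for i in range(6)]
    a1 = _assignment([0, 0, 1, 1, 2, UNASSIGNED], ids, 3)
    a2 = _assignment([0, 0, 1, 1, 2, UNASSIGNED], ids, 3)
    statuses = pd.DataFrame({"patient_id": ids, "status": [STATUS_RETAINED] * 6})
    summary = transition_matrix(a1, a2, statuses, _identity_alignment(3))
    counts = summary.counts
    assert counts.to_numpy().sum() == 6
    for g in range(3):
        assert counts.loc[f"class_{g}", f"class_{g}"] == [2, 2, 1][g]
    assert counts.loc["unassigned", "unassigned"] == 1
    assert summary.switch.percent == 0.0
    row_sums = summary.row_percent.sum(axis=1)
    assert np.allclose(row_sums, 100.0, atol=0.2)


def test_transition_rows_sum_to_100_and_conserve_counts():
    rng = np.random.default_rng(2)
    n = 500
    ids = [f"p{i}" for i in range(n)]
    g1 = rng.choice([0, 1, 2, UNASSIGNED], size=n)
    status = rng.choice(
        [STATUS_RETAINED, STATUS_IMPROVED, STATUS_DIED, STATUS_NO_CARE],
        size=n, p=[0.6, 0.25, 0.13, 0.02],
    )
    statuses = pd.DataFrame({"patient_id": ids, "status": status})
    retained_ids = [i for i, s in zip(ids, status) if s == STATUS_RETAINED]
    g2 = rng.choice([0, 1, 2, UNASSIGNED], size=len(retained_ids))
    a1 = _assignment(g1, ids, 3)
    a2 = _assignment(g2, retained_ids, 3)
    summary = transition_matrix(a1, a2, statuses, _identity_alignment(3))
    assert summary.counts.to_numpy().sum() == n
    sums = summary.row_percent.dropna(how="all").sum(axis=1)
    assert np.allclose(sums, 100.0, atol=0.3)


def test_switch_rate_examples():
    ids = ["a", "b", "c"]
    statuses = pd.DataFrame({"patient_id": ids, "status": [STATUS_RETAINED] * 3})
    same = switch_rate(_assignment([0, 1, UNASSIGNED], ids, 2),
                       _assignment([0, 1, UNASSIGNED], ids, 2),
                       statuses, _identity_alignment(2))
    assert same.percent == 0.0
    moved = switch_rate(_assignment([UNASSIGNED] * 3, ids, 2),
                        _assignment([0, 1, 0], ids, 2),
                        statuses, _identity_alignment(2))
    assert moved.percent == 100.0
    assert rs.RateReport(230_185, 563_725).percent == 40.8


def test_switch_rate_uses_alignment():
    from riskseg.stability import ClassAlignment

    ids = ["a", "b"]
    statuses = pd.DataFrame({"patient_id": ids, "status": [STATUS_RETAINED] * 2})
    swap = ClassAlignment(mapping=np.array([1, 0]), pair_distance=np.zeros(2),
                          total_distance=0.0)
    # wave-2 labels are swapped relative to wave 1; alignment undoes the swap
    rate = switch_rate(_assignment([0, 1], ids, 2), _assignment([1, 0], ids, 2),
                       statuses, swap)
    assert rate.percent == 0.0


def test_transition_on_stable_synthetic_cohort_is_diagonal_dominant():
    """Identity dynamics, fresh same-class redraws: classification noise is
    the only leak off the diagonal.  Two independent modal classifications
    at per-wave accuracy a agree at rate ~a^2, so the diagonal dominates
    every row without approaching 100%."""
    from dataclasses import replace

    from riskseg.lca_core import e_step
    from riskseg.segmentation import assign_patients
    from riskseg.synthetic_cohort import Wave2Dynamics

    base = rs.default_truth(n_patients=6000, boundary_fraction=0.0)
    dyn = Wave2Dynamics(
        p_death=np.zeros(5), p_improve=np.zeros(5), p_leave=np.zeros(5),
        class_transition=np.eye(5), condition_persistence=0.0,
    )
    cfg = replace(base, dynamics=dyn)
    _, _, _, t1 = rs.generate_wave1(cfg, seed=33)
    _, _, _, _, t2 = rs.generate_wave2(cfg, t1, seed=33)
    params = LCAParams(pi=cfg.mixing, rho=cfg.item_probs)
    a1 = assign_patients(e_step(params, t1.indicators.astype(float)),
                         patient_ids=t1.patient_ids)
    a2 = assign_patients(e_step(params, t2.indicators.astype(float)),
                         patient_ids=t2.patient_ids)
    statuses = pd.DataFrame({"patient_id": t1.patient_ids,
                             "status": [STATUS_RETAINED] * cfg.n_patients})
    summary = transition_matrix(a1, a2, statuses, _identity_alignment(5))
    group_cols = [f"class_{g}" for g in range(5)] + ["unassigned"]
    for g in range(5):
        row = summary.row_percent.loc[f"class_{g}", group_cols]
        assert row[f"class_{g}"] > 70.0
        assert row.idxmax() == f"class_{g}"
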