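"""Class-number grid fitting, canonical ordering and model selection.

Fits the 2-7 class grid, resolves label switching by ordering classes by
descending class weight, and selects a class number from AIC/BIC/
adjusted-BIC/entropy — with an explicit manual override, since the final
choice in applied segmentation work typically folds in clinical
interpretability that no criterion automates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lca_core import EmptyClassError, LCAFit, LCAParams, fit_em

__all__ = [
    "SelectionReport",
    "fit_grid",
    "canonicalize",
    "select_model",
    "save_fit",
    "load_fit",
]

DEFAULT_ENTROPY_FLOOR = 0.8
DEFAULT_BIC_IMPROVE_FRAC = 0.01


def canonicalize(fit: LCAFit) -> LCAFit:
    """Reorder classes by descending class weight (ties by first item
    probability, ascending); posterior columns are permuted consistently
    and every fit statistic is unchanged.  Idempotent."""
    pi, rho = fit.params.pi, fit.params.rho
    order = np.lexsort((rho[:, 0], -pi))
    if np.array_equal(order, np.arange(fit.K)):
        return fit
    return replace(
        fit,
        params=fit.params.permuted(order),
        posteriors=fit.posteriors[:, order],
    )


def fit_grid(
    data,
    k_min: int = 2,
    k_max: int = 7,
    seed: int = 0,
    n_starts: int | None = None,
    **em_kwargs,
) -> list[LCAFit]:
    """One best-of-starts, canonicalized fit per K in [k_min, k_max].

    Deterministic given the seed (per-K randomness is derived inside
    :func:`riskseg.lca_core.fit_em` from (seed, K, start), so results do
    not depend on execution order).  A K whose every start degenerates is
    skipped; downstream selection then never sees it.
    """
    if not 2 <= k_min <= k_max:
        raise ValueError("need k_max >= k_min >= 2")
    fits = []
    for K in range(k_min, k_max + 1):
        try:
            fit = fit_em(data, K, seed=seed, n_starts=n_starts, **em_kwargs)
        except EmptyClassError:
            continue
        fits.append(canonicalize(fit))
    return fits


@dataclass
class SelectionReport:
    """Fit statistics per class number, plus the applied rule and choice."""

    table: pd.DataFrame
    chosen_K: int
    rule_applied: str

    def to_json(self) -> str:
        return json.dumps({
            "chosen_K": int(self.chosen_K),
            "rule_applied": self.rule_applied,
            "grid": self.table.to_dict(orient="records"),
        }, indent=2)


def _report_table(fits: list[LCAFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "K": f.K,
            "loglik": f.loglik,
            "n_params": f.n_params,
            "aic": f.aic,
            "bic": f.bic,
            "abic": f.abic,
            "entropy": f.entropy,
            "converged": f.converged,
            "n_iter": f.n_iter,
            "best_of_starts": f.best_of_starts,
            "seed": f.seed,
        }
        for f in fits
    ])


def select_model(
    fits: list[LCAFit],
    rule: str = "default",
    entropy_floor: float = DEFAULT_ENTROPY_FLOOR,
    bic_improve_frac: float = DEFAULT_BIC_IMPROVE_FRAC,
) -> tuple[LCAFit, SelectionReport]:
    """Choose a class number from the fitted grid.

    Rules:

    - ``"min_bic"`` / ``"min_abic"``: the criterion minimizer.
    - ``"default"``: walk K upward and stop at the last K before either
      the BIC improvement over K-1 falls under ``bic_improve_frac`` of
      |BIC(K-1)| or entropy drops below ``entropy_floor``; if neither
      triggers, fall back to min-BIC.
    - ``"manual:K"``: the stated K regardless of criteria — the
      interpretability override; it must be in the fitted grid.

    Only converged fits participate.  The report always carries the full
    grid, so selection can be re-run from the saved table alone.
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to select from")
    usable = sorted(usable, key=lambda f: f.K)
    table = _report_table(sorted(fits, key=lambda f: f.K))
    by_k = {f.K: f for f in usable}

    if rule.startswith("manual:"):
        K = int(rule.split(":", 1)[1])
        if K not in by_k:
            raise ValueError(f"manual K={K} is not in the fitted grid")
        chosen = K
        applied = "manual"
    elif rule == "min_bic":
        chosen = min(usable, key=lambda f: f.bic).K
        applied = "min_bic"
    elif rule == "min_abic":
        chosen = min(usable, key=lambda f: f.abic).K
        applied = "min_abic"
    elif rule == "default":
        chosen, applied = None, "min_bic"
        for prev, cur in zip(usable, usable[1:]):
            improvement = prev.bic - cur.bic
            if improvement < bic_improve_frac * abs(prev.bic):
                chosen, applied = prev.K, "bic_plateau"
                break
            if np.isfinite(cur.entropy) and cur.entropy < entropy_floor:
                chosen, applied = prev.K, "entropy_floor"
                break
        if chosen is None:
            chosen = min(usable, key=lambda f: f.bic).K
    else:
        raise ValueError(f"unknown selection rule {rule!r}")

    return by_k[chosen], SelectionReport(table=table, chosen_K=chosen, rule_applied=applied)


# ---------------------------------------------------------------------------
# fit persistence (JSON params/criteria + CSV posteriors)

def save_fit(fit: LCAFit, outdir, patient_ids=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "K": fit.K,
        "J": fit.params.J,
        "pi": fit.params.pi.tolist(),
        "rho": fit.params.rho.tolist(),
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "bic": fit.bic,
        "abic": fit.abic,
        "entropy": None if np.isnan(fit.entropy) else fit.entropy,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "best_of_starts": fit.best_of_starts,
        "seed": fit.seed,
    }
    with open(outdir / "params.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    tau = pd.DataFrame(fit.posteriors, columns=[f"tau_{k}" for k in range(fit.K)])
    if patient_ids is not None:
        tau.insert(0, "patient_id", np.asarray(patient_ids))
    tau.to_csv(outdir / "posteriors.csv", index=False)


def load_fit(outdir) -> tuple[LCAFit, np.ndarray | None]:
    """Inverse of :func:`save_fit`; returns the fit and patient ids (if saved)."""
    outdir = Path(outdir)
    with open(outdir / "params.json") as fh:
        d = json.load(fh)
    tau_df = pd.read_csv(outdir / "posteriors.csv")
    pids = tau_df["patient_id"].to_numpy() if "patient_id" in tau_df.columns else None
    tau = tau_df[[f"tau_{k}" for k in range(d["K"])]].to_numpy()
    fit = LCAFit(
        params=LCAParams(pi=np.array(d["pi"]), rho=np.array(d["rho"])),
        posteriors=tau,
        loglik=d["loglik"],
        n_obs=d["n_obs"],
        n_params=d["n_params"],
        aic=d["aic"],
        bic=d["bic"],
        abic=d["abic"],
        entropy=float("nan") if d["entropy"] is None else d["entropy"],
        converged=d["converged"],
        n_iter=d["n_iter"],
        best_of_starts=d["best_of_starts"],
        seed=d["seed"],
    )
    return fit, pids
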