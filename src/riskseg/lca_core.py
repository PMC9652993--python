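"""Latent class analysis for binary comorbidity indicators.

The model is a finite mixture of products of Bernoullis.  Patient ``i``
carries ``J`` binary indicators ``y_ij``; latent class ``k`` has weight
``pi_k`` and item probabilities ``rho_kj``, and indicators are
conditionally independent given class:

    P(y_i) = sum_k pi_k * prod_j rho_kj**y_ij * (1 - rho_kj)**(1 - y_ij)

Estimation is by expectation-maximization with multiple random starts.
All likelihood arithmetic runs in log space with log-sum-exp
stabilization, and item probabilities are clamped away from {0, 1} to
keep the log-likelihood finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "LCAParams",
    "LCAFit",
    "log_likelihood",
    "e_step",
    "m_step",
    "fit_em",
    "information_criteria",
    "relative_entropy",
    "default_n_starts",
]

# Convergence / numerical defaults; overridable per call.
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_CLAMP = 1e-4

# Weight below which a class is treated as emptied-out (degenerate start).
_EMPTY_CLASS_WEIGHT = 1e-10


@dataclass(frozen=True)
class LCAParams:
    """Mixture parameters: class weights ``pi`` (K,) and item probabilities ``rho`` (K, J)."""

    pi: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 2:
            raise ValueError("rho must be a K x J matrix")
        if pi.ndim != 1 or pi.shape[0] != rho.shape[0]:
            raise ValueError("pi must be a length-K vector matching rho's rows")
        if not math.isclose(float(pi.sum()), 1.0, abs_tol=1e-8):
            raise ValueError(f"class weights must sum to 1, got {pi.sum()!r}")
        if np.any(pi <= 0):
            raise ValueError("class weights must be strictly positive")
        if np.any(rho <= 0) or np.any(rho >= 1):
            raise ValueError("item probabilities must lie strictly inside (0, 1)")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "rho", rho)

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def J(self) -> int:
        return self.rho.shape[1]

    def permuted(self, order: np.ndarray) -> "LCAParams":
        """Return a copy with classes reordered by ``order`` (a permutation of 0..K-1)."""
        order = np.asarray(order)
        return LCAParams(pi=self.pi[order], rho=self.rho[order])


@dataclass
class LCAFit:
    """One fitted latent class model: parameters, posteriors and fit statistics."""

    params: LCAParams
    posteriors: np.ndarray  # (n, K), rows sum to 1
    loglik: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    abic: float
    entropy: float  # relative entropy in [0, 1]; NaN for K = 1
    converged: bool
    n_iter: int
    best_of_starts: int
    seed: int

    @property
    def K(self) -> int:
        return self.params.K


def _as_data(data) -> np.ndarray:
    """Accept an ndarray or anything exposing ``.values`` (IndicatorMatrix, DataFrame)."""
    values = getattr(data, "values", data)
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2:
        raise ValueError("indicator data must be a 2-D patients x conditions array")
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("indicator data must be binary (0/1)")
    return Y


def _log_joint(params: LCAParams, Y: np.ndarray) -> np.ndarray:
    """log(pi_k) + log P(y_i | class k), an (n, K) matrix.

    Uses the identity sum_j [y log rho + (1-y) log(1-rho)]
    = y . logit(rho) + sum_j log(1-rho), so the n x K work is one matmul.
    """
    if Y.shape[1] != params.J:
        raise ValueError(
            f"data has {Y.shape[1]} indicators but params expect {params.J}"
        )
    log_rho = np.log(params.rho)
    log_1m = np.log1p(-params.rho)
    return Y @ (log_rho - log_1m).T + log_1m.sum(axis=1) + np.log(params.pi)


def log_likelihood(params: LCAParams, data) -> float:
    """Total log-likelihood of binary data under the mixture, log-sum-exp stabilized."""
    Y = _as_data(data)
    return float(logsumexp(_log_joint(params, Y), axis=1).sum())


def e_step(params: LCAParams, data) -> np.ndarray:
    """Posterior class membership probabilities tau_ik, row-normalized."""
    tau, _ = _e_step_with_ll(params, _as_data(data))
    return tau


def _e_step_with_ll(params: LCAParams, Y: np.ndarray) -> tuple[np.ndarray, float]:
    lj = _log_joint(params, Y)
    norm = logsumexp(lj, axis=1, keepdims=True)
    return np.exp(lj - norm), float(norm.sum())


def m_step(posteriors: np.ndarray, data, clamp: float = DEFAULT_CLAMP) -> LCAParams:
    """Maximize the expected complete-data log-likelihood.

    pi_k = mean_i tau_ik; rho_kj = weighted item mean, clamped to
    [clamp, 1 - clamp].  A class whose total responsibility vanishes has
    no maximizer; the caller is expected to restart.
    """
    Y = _as_data(data)
    tau = np.asarray(posteriors, dtype=float)
    if tau.shape[0] != Y.shape[0]:
        raise ValueError("posteriors and data disagree on the number of patients")
    n = Y.shape[0]
    weight = tau.sum(axis=0)
    if np.any(weight / n < _EMPTY_CLASS_WEIGHT):
        raise EmptyClassError("a class received (near-)zero total responsibility")
    pi = weight / n
    pi = pi / pi.sum()
    rho = (tau.T @ Y) / weight[:, None]
    rho = np.clip(rho, clamp, 1.0 - clamp)
    return LCAParams(pi=pi, rho=rho)


class EmptyClassError(RuntimeError):
    """Raised when an EM iteration empties a class; the start should be re-drawn."""


def information_criteria(loglik: float, K: int, J: int, n: int) -> tuple[float, float, float]:
    """AIC, BIC and sample-size-adjusted BIC for a K-class model on J binary items.

    The free-parameter count is p = (K - 1) + K * J.  The adjusted BIC
    replaces log(n) with log((n + 2) / 24), the usual sample-size
    adjustment reported by mainstream LCA software.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p = (K - 1) + K * J
    aic = -2.0 * loglik + 2.0 * p
    bic = -2.0 * loglik + p * math.log(n)
    abic = -2.0 * loglik + p * math.log((n + 2) / 24.0)
    return aic, bic, abic


def relative_entropy(posteriors: np.ndarray, K: int | None = None) -> float:
    """Relative entropy E = 1 - sum_ik(-tau log tau) / (n log K).

    1 for perfectly separated (one-hot) posteriors, 0 for uniform ones.
    Undefined for K = 1; returned as NaN.
    """
    tau = np.asarray(posteriors, dtype=float)
    if K is None:
        K = tau.shape[1]
    if K != tau.shape[1]:
        raise ValueError("K does not match the posterior matrix width")
    if K < 2:
        return float("nan")
    n = tau.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(tau > 0, tau * np.log(tau), 0.0)
    return float(1.0 + plogp.sum() / (n * math.log(K)))


def default_n_starts(K: int) -> int:
    """Multistart budget: 20 random starts for K <= 5, 40 above."""
    return 20 if K <= 5 else 40


def _random_start(Y: np.ndarray, K: int, rng: np.random.Generator,
                  clamp: float) -> LCAParams:
    """Initialize from random responsibilities (Dirichlet rows), then one M-step."""
    tau0 = rng.dirichlet(np.ones(K), size=Y.shape[0])
    return m_step(tau0, Y, clamp=clamp)


def fit_em(
    data,
    K: int,
    seed: int,
    *,
    n_starts: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    clamp: float = DEFAULT_CLAMP,
) -> LCAFit:
    """Fit a K-class model by EM with multiple seeded random starts, keeping the best.

    Per-start seeds are derived from ``seed`` via ``np.random.SeedSequence``
    spawn keys, so a given (data, K, seed, n_starts) is fully reproducible.
    A start that empties a class is abandoned and recorded as non-converged.
    """
    Y = _as_data(data)
    n = Y.shape[0]
    if K < 1:
        raise ValueError("K must be at least 1")
    if n <= K:
        raise ValueError("need more patients than classes")
    if n_starts is None:
        n_starts = default_n_starts(K)

    best: tuple[float, LCAParams, np.ndarray, bool, int] | None = None
    for start in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(K, start)))
        try:
            params = _random_start(Y, K, rng, clamp)
            ll_prev = -np.inf
            converged = False
            n_iter = 0
            for n_iter in range(1, max_iter + 1):
                tau, ll = _e_step_with_ll(params, Y)
                if ll - ll_prev < tol and n_iter > 1:
                    converged = True
                    break
                ll_prev = ll
                params = m_step(tau, Y, clamp=clamp)
            tau, ll = _e_step_with_ll(params, Y)
        except EmptyClassError:
            continue
        if best is None or ll > best[0]:
            best = (ll, params, tau, converged, n_iter)

    if best is None:
        raise EmptyClassError(
            f"all {n_starts} starts degenerated for K={K}; data may be too sparse"
        )
    ll, params, tau, converged, n_iter = best
    aic, bic, abic = information_criteria(ll, K, params.J, n)
    return LCAFit(
        params=params,
        posteriors=tau,
        loglik=ll,
        n_obs=n,
        n_params=(K - 1) + K * params.J,
        aic=aic,
        bic=bic,
        abic=abic,
        entropy=relative_entropy(tau, K),
        converged=converged,
        n_iter=n_iter,
        best_of_starts=n_starts,
        seed=seed,
    )
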