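"""Supervised NMF: the Flda family (multiplicative) and Flog (ADADELTA).

Supervision couples the factorization to binary labels ``u`` through the
feature map ``F = Y X^T``:

* Flda / FRlda / FROlda add a least-squares penalty
  ``gamma/2 ||u - Y X^T beta||^2`` with ``beta >= 0`` (the labels are
  modeled as a non-negative superposition of correlation images), solved
  by the same multiplicative MM sweeps as the unsupervised models with
  one extra rule for ``beta``.
* Flog adds the logistic-regression negative log-likelihood
  ``gamma/n (sum_i log(1 + exp(z_i)) - u^T z)`` with
  ``z = [1 | Y X^T] beta``; ``beta`` (length p+1, intercept first) may go
  negative, so ``X`` and ``beta`` are driven by ADADELTA gradient steps,
  with a positivity projection on ``X`` after every step.  ``K`` keeps its
  multiplicative rule.

Gradients are full-batch, so every fit is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nmf_unsupervised import (
    FitTrace,
    NMFConfig,
    NMFFactors,
    SUPERVISED_MODELS,
    _update_k,
    cost_fr,
    cost_fro,
    init_factors,
    rescale,
)

__all__ = [
    "AdadeltaState",
    "cost_flda",
    "update_flda",
    "flog_cost",
    "flog_gradients",
    "adadelta_step",
    "project_positive",
    "fit_supervised",
]


@dataclass
class AdadeltaState:
    """Decaying accumulators of squared gradients and squared updates."""

    accum_grad_sq: np.ndarray
    accum_update_sq: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "AdadeltaState":
        return cls(np.zeros(shape), np.zeros(shape))


def _check_labels(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float).ravel()
    if not np.isin(u, (0.0, 1.0)).all():
        raise ValueError("labels u must be binary (0/1)")
    return u


def cost_flda(Y: np.ndarray, u: np.ndarray, factors: NMFFactors,
              config: NMFConfig) -> float:
    """Flda-family cost: base FR/FRO cost + gamma/2 ||u - Y X^T beta||^2."""
    if factors.beta is None:
        raise ValueError("supervised cost requires beta")
    if (factors.beta < 0).any():
        raise ValueError("Flda-family beta must be entrywise non-negative")
    u = _check_labels(u)
    base = cost_fro(Y, factors, config) if config.uses_w \
        else cost_fr(Y, factors, config)
    resid = u - Y @ factors.X.T @ factors.beta
    return float(base + 0.5 * config.gamma * np.sum(resid * resid))


def update_flda(Y: np.ndarray, u: np.ndarray, factors: NMFFactors,
                config: NMFConfig) -> NMFFactors:
    """One multiplicative sweep (K, X, W when present, beta) of Flda/FRlda/FROlda.

    The X rule gains supervision terms ``gamma beta u^T Y`` (numerator) and
    ``gamma beta beta^T X Y^T Y`` (denominator); beta follows the
    non-negative least-squares rule
    ``beta <- beta o X Y^T u / (X Y^T Y X^T beta)``.
    """
    if factors.beta is None:
        raise ValueError("update_flda requires beta in the factors")
    u = _check_labels(u)
    if not u.any():
        raise ValueError("labels are all zero: supervision is degenerate "
                         "(the beta numerator vanishes)")
    eps = config.eps_div
    s1, s2 = config.sigma1, config.sigma2
    g = config.gamma
    beta = factors.beta
    K = _update_k(Y, factors.K, factors.X, config.mu, eps)
    X, W = factors.X, factors.W
    num = K.T @ Y + g * np.outer(beta, u @ Y)
    # beta beta^T X Y^T Y evaluated left-to-right in O(pnm)
    den = K.T @ K @ X \
        + g * np.outer(beta, ((beta @ X) @ Y.T) @ Y) \
        + config.nu * X + config.lambda_l1 + eps
    if config.uses_w:
        if W is None:
            raise ValueError("FROlda requires the auxiliary factor W")
        num = num + (s1 + s2) * W
        den = den + s1 * (X @ W.T @ W) + s2 * X
    X = X * num / den
    if config.uses_w:
        W = W * ((s1 + s2) * X) / (
            W @ (s1 * (X.T @ X) + s2 * np.eye(X.shape[1])) + eps
        )
    F = Y @ X.T
    beta = beta * (F.T @ u) / (F.T @ (F @ beta) + eps)
    return NMFFactors(K=K, X=X, W=W, beta=beta)


def _logistic_z(Y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """z = [1 | Y X^T] beta with the intercept as beta[0]."""
    return beta[0] + Y @ X.T @ beta[1:]


def flog_cost(Y: np.ndarray, u: np.ndarray, X: np.ndarray, K: np.ndarray,
              beta: np.ndarray, config: NMFConfig) -> float:
    """Flog cost: 1/2||Y-KX||_F^2 + gamma/n (sum softplus(z) - u^T z).

    The logistic term is the negative log-likelihood of ``u`` under class-1
    probabilities ``sigmoid(z)``; computed via ``log1p(exp(-|z|))`` so it
    stays finite for |z| up to ~1e3 and beyond.
    """
    u = _check_labels(u)
    n = Y.shape[0]
    z = _logistic_z(Y, X, np.asarray(beta, dtype=float).ravel())
    resid = Y - K @ X
    softplus = np.logaddexp(0.0, z)
    return float(0.5 * np.sum(resid * resid)
                 + config.gamma / n * (softplus.sum() - u @ z))


def flog_gradients(Y: np.ndarray, u: np.ndarray, X: np.ndarray,
                   K: np.ndarray, beta: np.ndarray,
                   config: NMFConfig) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`flog_cost` w.r.t. X and beta.

    With ``Z = [1 | Y X^T]`` and ``s = sigmoid(Z beta)``:
    ``grad_beta = gamma/n Z^T (s - u)`` and
    ``grad_X = -K^T (Y - KX) + gamma/n beta_{1:p} (s - u)^T Y``.
    """
    u = _check_labels(u)
    beta = np.asarray(beta, dtype=float).ravel()
    n = Y.shape[0]
    z = _logistic_z(Y, X, beta)
    from scipy.special import expit

    r = expit(z) - u  # s - u
    grad_beta = np.empty_like(beta)
    grad_beta[0] = config.gamma / n * r.sum()
    grad_beta[1:] = config.gamma / n * (Y @ X.T).T @ r
    grad_X = -K.T @ (Y - K @ X) \
        + config.gamma / n * np.outer(beta[1:], r @ Y)
    return grad_X, grad_beta


def adadelta_step(grad: np.ndarray, state: AdadeltaState, rho: float,
                  eps: float) -> tuple[np.ndarray, AdadeltaState]:
    """One ADADELTA update: adaptively scaled negative-gradient step.

    Accumulates squared gradients with decay ``rho``, scales the step by
    the ratio of root-mean-square past updates to root-mean-square past
    gradients (``eps`` stabilizes both), and accumulates the squared step:

    ``E[g^2] <- rho E[g^2] + (1-rho) g^2``;
    ``delta = -sqrt(E[dx^2]+eps)/sqrt(E[g^2]+eps) o g``;
    ``E[dx^2] <- rho E[dx^2] + (1-rho) delta^2``.
    """
    accum_grad = rho * state.accum_grad_sq + (1 - rho) * grad * grad
    delta = -np.sqrt(state.accum_update_sq + eps) / np.sqrt(accum_grad + eps) * grad
    accum_update = rho * state.accum_update_sq + (1 - rho) * delta * delta
    return delta, AdadeltaState(accum_grad, accum_update)


def project_positive(X: np.ndarray, floor: float) -> np.ndarray:
    """Replace every non-positive entry of X with the constant ``floor``."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.where(X <= 0, floor, X)


def _fit_flda(Y, u, factors, config):
    from .nmf_unsupervised import _run_alternating

    def sweep(Y_, f, cfg):
        return update_flda(Y_, u, f, cfg)

    def cost(Y_, f, cfg):
        return cost_flda(Y_, u, f, cfg)

    return _run_alternating(Y, factors, config, sweep, cost)


def _fit_flog(Y, u, factors, config):
    from scipy.special import expit

    X = factors.X
    K = factors.K
    n = Y.shape[0]
    g_n = config.gamma / n
    beta = np.zeros(config.p + 1)
    state_x = AdadeltaState.zeros(X.shape)
    state_b = AdadeltaState.zeros(beta.shape)
    rho, a_eps = config.adadelta_rho, config.adadelta_eps
    costs = [flog_cost(Y, u, X, K, beta, config)]
    converged = False
    it = 0
    # inline equivalent of flog_gradients / flog_cost, sharing the large
    # matrix products (Y X^T, K X) between the sequential sub-steps
    for it in range(1, config.max_iter + 1):
        F = Y @ X.T
        K = K * F / (K @ (X @ X.T) + config.eps_div)
        r = expit(beta[0] + F @ beta[1:]) - u
        grad_X = -K.T @ (Y - K @ X) + g_n * np.outer(beta[1:], r @ Y)
        delta_X, state_x = adadelta_step(grad_X, state_x, rho, a_eps)
        X = project_positive(X + delta_X, config.proj_floor)
        F = Y @ X.T
        r = expit(beta[0] + F @ beta[1:]) - u
        grad_b = g_n * np.concatenate([[r.sum()], F.T @ r])
        delta_b, state_b = adadelta_step(grad_b, state_b, rho, a_eps)
        beta = beta + delta_b
        z = beta[0] + F @ beta[1:]
        resid = Y - K @ X
        c = float(0.5 * np.sum(resid * resid)
                  + g_n * (np.logaddexp(0.0, z).sum() - u @ z))
        if not np.isfinite(c):
            raise FloatingPointError(f"Flog cost diverged at iteration {it}")
        costs.append(c)
        if abs(costs[-2] - c) / max(abs(costs[-2]), config.eps_div) < config.rel_tol:
            converged = True
            break
    factors = NMFFactors(K=K, X=X, beta=beta)
    return factors, FitTrace(np.array(costs), iterations_run=it,
                             converged=converged)


def fit_supervised(Y: np.ndarray, u: np.ndarray,
                   config: NMFConfig) -> tuple[NMFFactors, FitTrace]:
    """Fit a supervised model (Flda, FRlda, FROlda or Flog) to labeled data.

    The Flda family alternates the multiplicative sweeps of
    :func:`update_flda` under the stopping rule of ``fit_nmf`` (optionally
    rescaling with beta compensation).  Flog initializes beta to zero and
    alternates the multiplicative K rule with sequential ADADELTA steps on
    X (positively projected) and beta.
    """
    if config.model not in SUPERVISED_MODELS:
        raise ValueError(
            f"fit_supervised handles {SUPERVISED_MODELS}; got {config.model!r}"
        )
    Y = np.asarray(Y, dtype=float)
    u = _check_labels(u)
    if u.shape[0] != Y.shape[0]:
        raise ValueError("labels length must match the number of spectra")
    n, m = Y.shape
    factors = init_factors(n, m, config.p, config.seed,
                           with_w=config.uses_w, y_mean=float(Y.mean()))
    if config.model == "Flog":
        return _fit_flog(Y, u, factors, config)
    if not u.any():
        raise ValueError("labels are all zero: supervision is degenerate")
    beta_rng = np.random.default_rng([config.seed, 0x5eed])
    factors = replace(factors, beta=1.0 - beta_rng.random(config.p))
    return _fit_flda(Y, u, factors, config)
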