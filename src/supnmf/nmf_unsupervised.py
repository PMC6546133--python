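"""Unsupervised NMF models FR, FO and FRO with multiplicative MM updates.

The data matrix ``Y`` (n spectra x m channels, non-negative) is factorized
as ``Y ~ K X`` with ``K`` (n x p) holding pseudo-channel loadings and ``X``
(p x m) holding pseudo spectra.  Three cost functionals are provided:

* ``FR``  — Frobenius discrepancy + l1 sparsity on X + l2 (Tikhonov)
  penalties on K and X:
  ``1/2 ||Y - KX||_F^2 + lambda ||X||_1 + mu/2 ||K||_F^2 + nu/2 ||X||_F^2``
* ``FRO`` — FR plus a split orthogonality penalty on the pseudo spectra
  through an auxiliary non-negative matrix ``W``:
  ``+ sigma1/2 ||I - X W^T||_F^2 + sigma2/2 ||W - X||_F^2``
* ``FO``  — FRO with ``lambda = mu = nu = 0`` (orthogonality only).

All updates are multiplicative majorize-minimization steps: each variable
is multiplied entrywise by the ratio of the negative to the positive part
of its partial gradient, which keeps the factors non-negative and makes the
cost non-increasing.  A small constant is added to every denominator to
guard against division by zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

__all__ = [
    "NMFFactors",
    "NMFConfig",
    "FitTrace",
    "init_factors",
    "cost_fr",
    "cost_fro",
    "update_fr",
    "update_fro",
    "rescale",
    "fit_nmf",
    "save_factors",
    "load_factors",
]

UNSUPERVISED_MODELS = ("FR", "FO", "FRO")
SUPERVISED_MODELS = ("Flda", "FRlda", "FROlda", "Flog")
MODELS = UNSUPERVISED_MODELS + SUPERVISED_MODELS

#: models whose cost includes the split orthogonality penalty (use W)
ORTHOGONAL_MODELS = ("FO", "FRO", "FROlda")


@dataclass
class NMFFactors:
    """Factorization state ``Y ~ K X`` (plus optional ``W`` and ``beta``).

    ``K`` and ``X`` are entrywise non-negative at all times.  ``W`` mirrors
    the shape of ``X`` and exists only for orthogonality-penalized models.
    ``beta`` holds regression weights for supervised models: length p and
    non-negative for the least-squares (Flda) family, length p+1 with a
    leading intercept and free sign for the logistic (Flog) model.
    """

    K: np.ndarray
    X: np.ndarray
    W: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.K.ndim != 2 or self.X.ndim != 2:
            raise ValueError("K and X must be matrices")
        if self.K.shape[1] != self.X.shape[0]:
            raise ValueError(
                f"inner dimensions differ: K is {self.K.shape}, X is {self.X.shape}"
            )
        if (self.K < 0).any() or (self.X < 0).any():
            raise ValueError("K and X must be entrywise non-negative")
        if self.W is not None:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.shape != self.X.shape:
                raise ValueError("W must have the same shape as X")
            if (self.W < 0).any():
                raise ValueError("W must be entrywise non-negative")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float).ravel()

    @property
    def p(self) -> int:
        return self.X.shape[0]

    def copy(self) -> "NMFFactors":
        return NMFFactors(
            self.K.copy(),
            self.X.copy(),
            None if self.W is None else self.W.copy(),
            None if self.beta is None else self.beta.copy(),
        )


@dataclass
class NMFConfig:
    """Model selector plus every regularization and optimizer knob.

    Parameters
    ----------
    model
        One of ``FR``, ``FO``, ``FRO`` (unsupervised) or ``Flda``,
        ``FRlda``, ``FROlda``, ``Flog`` (supervised).
    p
        Number of pseudo spectra (rows of X).
    lambda_l1, mu, nu
        l1 weight on X and l2 weights on K and X.
    sigma1, sigma2
        Weights of the split orthogonality penalty (FO/FRO/FROlda).
    gamma
        Supervision weight coupling the factorization to the labels.
    max_iter, rel_tol
        Stop after ``max_iter`` sweeps or when the relative cost change
        drops below ``rel_tol``.
    rescale
        Rescale rows of X to unit l2 norm after each sweep, compensating
        in K (and beta for the Flda family) so the data fit is unchanged.
    eps_div
        Additive guard on every multiplicative-update denominator.
    adadelta_rho, adadelta_eps
        Decay rate and stability constant of the ADADELTA steps used for
        the Flog model's X and beta updates.
    proj_floor
        Positive constant replacing non-positive X entries after each
        ADADELTA step (positivity projection, Flog only).
    """

    model: str = "FR"
    p: int = 10
    lambda_l1: float = 0.0
    mu: float = 0.0
    nu: float = 0.0
    sigma1: float = 0.0
    sigma2: float = 0.0
    gamma: float = 0.0
    max_iter: int = 500
    rel_tol: float = 1e-6
    seed: int = 0
    rescale: bool = False
    eps_div: float = 1e-12
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6
    proj_floor: float = 1e-9

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.p < 1:
            raise ValueError("p must be a positive integer")
        for name in ("lambda_l1", "mu", "nu", "sigma1", "sigma2", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.model == "FO" and (self.lambda_l1 or self.mu or self.nu):
            raise ValueError("FO is the orthogonal model without l1/l2 terms; "
                             "set lambda_l1 = mu = nu = 0")
        if not 0 < self.adadelta_rho < 1:
            raise ValueError("adadelta_rho must lie in (0, 1)")
        if self.rel_tol <= 0 or self.eps_div <= 0 or self.proj_floor <= 0:
            raise ValueError("rel_tol, eps_div and proj_floor must be positive")

    @property
    def uses_w(self) -> bool:
        return self.model in ORTHOGONAL_MODELS


@dataclass
class FitTrace:
    """Cost trajectory of a fit (element 0 is the cost at initialization)."""

    cost_per_iteration: np.ndarray
    iterations_run: int
    converged: bool


def init_factors(
    n: int,
    m: int,
    p: int,
    seed: int,
    *,
    with_w: bool = False,
    y_mean: float = 1.0,
) -> NMFFactors:
    """Strictly positive random initialization, deterministic per seed.

    Entries are uniform on (0, 1], scaled so the product ``K X`` has mean
    comparable to ``y_mean`` (the mean of the data being factorized).
    """
    if min(n, m, p) < 1:
        raise ValueError("n, m, p must all be >= 1")
    if p > min(n, m):
        warnings.warn(
            f"p={p} exceeds min(n, m)={min(n, m)}; factorization rank "
            "exceeds the data rank", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    # 1 - random() lies in (0, 1]; mean(KX) for unit-uniform factors is p/4
    scale = np.sqrt(max(y_mean, np.finfo(float).tiny) / (p / 4.0))
    K = (1.0 - rng.random((n, p))) * scale
    X = (1.0 - rng.random((p, m))) * scale
    W = (1.0 - rng.random((p, m))) if with_w else None
    return NMFFactors(K=K, X=X, W=W)


def cost_fr(Y: np.ndarray, factors: NMFFactors, config: NMFConfig) -> float:
    """FR cost: 1/2||Y-KX||_F^2 + lambda||X||_1 + mu/2||K||_F^2 + nu/2||X||_F^2."""
    K, X = factors.K, factors.X
    if Y.shape != (K.shape[0], X.shape[1]):
        raise ValueError(
            f"Y has shape {Y.shape}, factors imply {(K.shape[0], X.shape[1])}"
        )
    resid = Y - K @ X
    return float(
        0.5 * np.sum(resid * resid)
        + config.lambda_l1 * np.abs(X).sum()
        + 0.5 * config.mu * np.sum(K * K)
        + 0.5 * config.nu * np.sum(X * X)
    )


def cost_fro(Y: np.ndarray, factors: NMFFactors, config: NMFConfig) -> float:
    """FRO cost: FR plus sigma1/2||I-XW^T||_F^2 + sigma2/2||W-X||_F^2."""
    if factors.W is None:
        raise ValueError("FRO cost requires the auxiliary factor W")
    X, W = factors.X, factors.W
    ortho = np.eye(X.shape[0]) - X @ W.T
    return float(
        cost_fr(Y, factors, config)
        + 0.5 * config.sigma1 * np.sum(ortho * ortho)
        + 0.5 * config.sigma2 * np.sum((W - X) ** 2)
    )


def _update_k(Y: np.ndarray, K: np.ndarray, X: np.ndarray,
              mu: float, eps: float) -> np.ndarray:
    """K <- K o YX^T / (KXX^T + mu K)."""
    XXt = X @ X.T
    return K * (Y @ X.T) / (K @ XXt + mu * K + eps)


def update_fr(Y: np.ndarray, factors: NMFFactors, config: NMFConfig) -> NMFFactors:
    """One alternating multiplicative sweep (K then X) of the FR model.

    ``K <- K o YX^T / (KXX^T + mu K)``;
    ``X <- X o K^T Y / (K^T K X + nu X + lambda)``.
    """
    eps = config.eps_div
    K = _update_k(Y, factors.K, factors.X, config.mu, eps)
    X = factors.X
    X = X * (K.T @ Y) / (K.T @ K @ X + config.nu * X + config.lambda_l1 + eps)
    return replace(factors, K=K, X=X)


def update_fro(Y: np.ndarray, factors: NMFFactors, config: NMFConfig) -> NMFFactors:
    """One multiplicative sweep (K, X, W) of the FRO/FO model.

    The X rule gains the orthogonality terms
    ``(sigma1+sigma2) W`` (numerator) and ``sigma1 X W^T W + sigma2 X``
    (denominator); W follows
    ``W <- W o (sigma1+sigma2) X / (W (sigma1 X^T X + sigma2 I))``.
    """
    if factors.W is None:
        raise ValueError("FRO update requires the auxiliary factor W")
    eps = config.eps_div
    s1, s2 = config.sigma1, config.sigma2
    K = _update_k(Y, factors.K, factors.X, config.mu, eps)
    X, W = factors.X, factors.W
    num = K.T @ Y + (s1 + s2) * W
    den = K.T @ K @ X + s1 * (X @ W.T @ W) + s2 * X \
        + config.nu * X + config.lambda_l1 + eps
    X = X * num / den
    W = W * ((s1 + s2) * X) / (W @ (s1 * (X.T @ X) + s2 * np.eye(X.shape[1])) + eps)
    return replace(factors, K=K, X=X, W=W)


def rescale(factors: NMFFactors) -> NMFFactors:
    """Normalize rows of X to unit l2 norm, moving the scale into K.

    With ``D = diag(||X_k||_2)``, returns ``X <- D^-1 X`` and ``K <- K D``,
    leaving the product ``K X`` unchanged.  For the Flda family the
    regression weights are compensated as ``beta <- D beta`` so the
    supervision residual ``u - Y X^T beta`` is invariant too.
    """
    norms = np.linalg.norm(factors.X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"cannot rescale: row {zero[0]} of X has zero norm")
    beta = factors.beta
    if beta is not None and beta.size == factors.p:
        beta = beta * norms
    return replace(
        factors,
        X=factors.X / norms[:, None],
        K=factors.K * norms[None, :],
        beta=beta,
    )


def _run_alternating(Y, factors, config, sweep, cost):
    """Shared driver: sweep until the relative cost change is < rel_tol."""
    costs = [cost(Y, factors, config)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        factors = sweep(Y, factors, config)
        if config.rescale:
            factors = rescale(factors)
        c = cost(Y, factors, config)
        if not np.isfinite(c):
            raise FloatingPointError(f"cost diverged at iteration {it}")
        costs.append(c)
        if abs(costs[-2] - c) / max(abs(costs[-2]), config.eps_div) < config.rel_tol:
            converged = True
            break
    trace = FitTrace(np.array(costs), iterations_run=it, converged=converged)
    return factors, trace


def fit_nmf(Y: np.ndarray, config: NMFConfig) -> tuple[NMFFactors, FitTrace]:
    """Fit an unsupervised model (FR, FO or FRO) to ``Y``.

    Initializes from ``config.seed``, alternates multiplicative sweeps
    (with per-sweep rescaling when ``config.rescale``) and stops when the
    relative cost change falls below ``config.rel_tol`` or after
    ``config.max_iter`` sweeps.
    """
    if config.model not in UNSUPERVISED_MODELS:
        raise ValueError(
            f"fit_nmf handles {UNSUPERVISED_MODELS}; got {config.model!r}"
        )
    Y = np.asarray(Y, dtype=float)
    factors = init_factors(
        Y.shape[0], Y.shape[1], config.p, config.seed,
        with_w=config.uses_w, y_mean=float(Y.mean()),
    )
    if config.model == "FR":
        return _run_alternating(Y, factors, config, update_fr, cost_fr)
    return _run_alternating(Y, factors, config, update_fro, cost_fro)


def save_factors(factors: NMFFactors, config: NMFConfig, path: str | Path) -> None:
    """Serialize factors (and the config as attributes) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("K", data=factors.K)
        f.create_dataset("X", data=factors.X)
        if factors.W is not None:
            f.create_dataset("W", data=factors.W)
        if factors.beta is not None:
            f.create_dataset("beta", data=factors.beta)
        for key, value in vars(config).items():
            f.attrs[key] = value


def load_factors(path: str | Path) -> tuple[NMFFactors, NMFConfig]:
    """Inverse of :func:`save_factors`."""
    with h5py.File(path, "r") as f:
        factors = NMFFactors(
            K=f["K"][()],
            X=f["X"][()],
            W=f["W"][()] if "W" in f else None,
            beta=f["beta"][()] if "beta" in f else None,
        )
        attrs = {k: v for k, v in f.attrs.items()}
    attrs["model"] = str(attrs["model"])
    for key in ("p", "max_iter", "seed"):
        attrs[key] = int(attrs[key])
    attrs["rescale"] = bool(attrs["rescale"])
    return factors, NMFConfig(**attrs)
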