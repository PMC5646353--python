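"""Multivariate autoregressive (MVAR) modeling of source signals.

The directed-connectivity stage models m source time courses jointly as

    x(t) = sum_{k=1..p} A_k x(t-k) + e(t),   e ~ N(0, Sigma)

with the order p chosen by minimizing AIC(p) = ln det(Sigma_p) + 2 p m^2 / n.
The least-squares fit also retains the inverse regressor Gram matrix, which
the renormalized partial directed coherence needs for its estimator
covariance.  Simulation is vectorized over replicates so the bootstrap can
drive hundreds of null realizations cheaply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import config


@dataclass
class SourceSignals:
    """Source-space time courses: ``data`` is sources x samples."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    @property
    def n_sources(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class MVARModel:
    """Fitted MVAR model at the AIC-selected order.

    ``A`` has shape (p, m, m) with ``A[k-1, i, j]`` the effect of source j at
    lag k on source i.  ``gram_inv`` is the inverse of the regressor Gram
    matrix Z'Z (lag-major stacking: index k*m + j), which already carries the
    1/n scaling of the coefficient covariance.
    """

    order: int
    A: np.ndarray
    Sigma: np.ndarray
    n_samples: int
    aic_curve: np.ndarray
    gram_inv: np.ndarray
    stable: bool = True

    @property
    def n_sources(self) -> int:
        return self.A.shape[1]


def companion_matrix(A: np.ndarray) -> np.ndarray:
    """Companion form of the coefficient stack (p, m, m) -> (pm, pm)."""
    p, m, _ = A.shape
    comp = np.zeros((p * m, p * m))
    comp[:m] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[m:, : (p - 1) * m] = np.eye((p - 1) * m)
    return comp


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))))


def is_stable(A: np.ndarray, tol: float = 1.0) -> bool:
    return spectral_radius(A) < tol


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Regression target Y (..., n-p, m) and design Z (..., n-p, m*p).

    ``x`` is (..., m, n); the design stacks lags 1..p, lag-major.
    """
    m, n = x.shape[-2], x.shape[-1]
    Y = np.swapaxes(x[..., :, p:], -1, -2)
    blocks = [np.swapaxes(x[..., :, p - k : n - k], -1, -2) for k in range(1, p + 1)]
    Z = np.concatenate(blocks, axis=-1)
    return Y, Z


def _fit_fixed_order(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit at fixed order; batched over leading axes.

    Returns (A, Sigma, gram_inv) with A (..., p, m, m); Sigma is the ML
    (1/n_eff) residual covariance.
    """
    m = x.shape[-2]
    Y, Z = _lagged_design(x, p)
    n_eff = Y.shape[-2]
    G = np.swapaxes(Z, -1, -2) @ Z
    H = np.swapaxes(Z, -1, -2) @ Y
    gram_inv = np.linalg.inv(G)
    B = gram_inv @ H  # (..., m*p, m); column i predicts source i
    resid = Y - Z @ B
    Sigma = np.swapaxes(resid, -1, -2) @ resid / n_eff
    # B rows are lag-major regressors; reshape to (..., p, m, m) with
    # A[k, i, j] = coefficient of source j, lag k+1, in the equation of i
    A = np.swapaxes(B, -1, -2)  # (..., m, m*p)
    A = A.reshape(*A.shape[:-1], p, m)  # (..., m, p, m)
    A = np.moveaxis(A, -2, -3)  # (..., p, m, m)
    return A, Sigma, gram_inv


def fit_mvar(
    sig: SourceSignals | np.ndarray,
    max_order: int = config.MVAR_MAX_ORDER,
    order: int | None = None,
) -> MVARModel:
    """Fit an MVAR model, selecting the order by AIC unless ``order`` fixes it.

    Ties in the AIC curve break toward the smaller order.  A selected model
    whose companion spectral radius reaches 1 is returned with
    ``stable=False`` and a warning rather than rejected: the caller decides.
    """
    x = sig.data if isinstance(sig, SourceSignals) else np.atleast_2d(np.asarray(sig, float))
    m, n = x.shape
    if order is not None:
        candidates = [order]
    else:
        candidates = list(range(1, max_order + 1))
    if n <= 10 * candidates[-1] * m:
        raise ValueError(
            f"n={n} too short for order {candidates[-1]} with m={m} sources "
            "(need n > 10 * p * m)"
        )
    x = x - x.mean(axis=1, keepdims=True)
    aic = np.full(candidates[-1] + 1, np.nan)
    best = None
    for p in candidates:
        A, Sigma, gram_inv = _fit_fixed_order(x, p)
        sign, logdet = np.linalg.slogdet(Sigma)
        a = (logdet if sign > 0 else -np.inf) + 2.0 * p * m * m / n
        aic[p] = a
        if best is None or a < best[0] - 1e-12:
            best = (a, p, A, Sigma, gram_inv)
    _, p, A, Sigma, gram_inv = best
    stable = is_stable(A)
    if not stable:
        warnings.warn(
            f"selected MVAR order {p} is unstable (spectral radius "
            f"{spectral_radius(A):.3f})",
            stacklevel=2,
        )
    return MVARModel(
        order=p,
        A=A,
        Sigma=Sigma,
        n_samples=n,
        aic_curve=aic,
        gram_inv=gram_inv,
        stable=stable,
    )


def simulate_mvar(
    A: np.ndarray,
    innovations: np.ndarray,
    burn_in: int = 200,
) -> np.ndarray:
    """Drive the MVAR recursion with given innovations.

    ``innovations`` is (..., n + burn_in, m); leading axes are independent
    replicates.  Returns (..., m, n).
    """
    A = np.asarray(A, dtype=float)
    p, m, _ = A.shape
    e = np.asarray(innovations, dtype=float)
    total = e.shape[-2]
    n = total - burn_in
    if n <= 0:
        raise ValueError("innovation array shorter than the burn-in")
    x = np.zeros(e.shape)
    for t in range(total):
        acc = e[..., t, :].copy()
        for k in range(1, min(p, t) + 1):
            acc += x[..., t - k, :] @ A[k - 1].T
        x[..., t, :] = acc
    return np.swapaxes(x[..., burn_in:, :], -1, -2)


def gaussian_innovations(
    rng: np.random.Generator, Sigma: np.ndarray, n: int, shape: tuple[int, ...] = ()
) -> np.ndarray:
    """Draw (..., n, m) Gaussian innovations with covariance Sigma."""
    m = Sigma.shape[0]
    L = np.linalg.cholesky(Sigma)
    z = rng.standard_normal(shape + (n, m))
    return z @ L.T
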