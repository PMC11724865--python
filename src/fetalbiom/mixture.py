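"""Offline maximum-likelihood fit of the Gaussian + uniform mixture.

Pooling demeaned measurements across many scans (each scan's final
estimate subtracted from all its measurements) gives a residual sample
whose distribution the streaming estimator assumes to be

    f(x) = P_t * N(x; mu, sigma^2) + (1 - P_t) / (b - a)   on [a, b].

Fitting (P_t, mu, sigma) to a residual pool by expectation-maximization
validates that model: the fitted CDF overlaid on the empirical CDF should
track it closely when the Gaussian-plus-uniform decomposition is adequate.
The uniform bounds (a, b) are fixed from the plausibility window rather
than fitted, mirroring the streaming estimator's fixed nuisance component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .estimator import MixtureModel

__all__ = ["ResidualPool", "MixtureFitResult", "FitError", "fit_mixture", "ecdf_overlay"]


class FitError(RuntimeError):
    """EM failed to converge from every restart."""


@dataclass(frozen=True)
class ResidualPool:
    """Demeaned measurements pooled across scans, with nuisance bounds."""

    residuals: np.ndarray
    a: float
    b: float

    def __post_init__(self) -> None:
        r = np.asarray(self.residuals, dtype=float)
        if not np.all(np.isfinite(r)):
            raise ValueError("residuals must be finite")
        if not self.a < self.b:
            raise ValueError("require a < b")
        object.__setattr__(self, "residuals", r)


@dataclass(frozen=True)
class MixtureFitResult:
    P_t: float
    mu: float
    sigma: float
    loglik: float
    n_iter: int
    ecdf_max_gap: float

    def as_model(self, a: float, b: float) -> MixtureModel:
        return MixtureModel(P_t=self.P_t, mu=self.mu, sigma2=self.sigma**2, a=a, b=b)


_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _em_once(
    x: np.ndarray,
    a: float,
    b: float,
    p0: float,
    mu0: float,
    sigma0: float,
    max_iter: int,
    tol: float,
    sigma_floor: float,
) -> tuple[float, float, float, float, int]:
    u = 1.0 / (b - a)
    p_t, mu, sigma = p0, mu0, max(sigma0, sigma_floor)
    prev_ll = -np.inf
    n = x.size
    for it in range(1, max_iter + 1):
        gauss = np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * _SQRT_2PI)
        num = p_t * gauss
        den = num + (1.0 - p_t) * u
        ll = float(np.log(den).sum())
        resp = num / den
        w = resp.sum()
        if w <= 0:
            return 0.0, mu, sigma, ll, it
        p_t = float(w / n)
        mu = float((resp * x).sum() / w)
        var = float((resp * (x - mu) ** 2).sum() / w)
        sigma = max(np.sqrt(var), sigma_floor)
        p_t = min(max(p_t, 1e-12), 1.0 - 1e-12)
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return p_t, mu, sigma, prev_ll, it


def fit_mixture(
    pool: ResidualPool,
    init: Optional[tuple[float, float, float]] = None,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    sigma_floor: float = 1e-3,
    seed: int = 0,
) -> MixtureFitResult:
    """EM fit of (P_t, mu, sigma) with multi-start.

    ``init`` optionally supplies one (P_t, mu, sigma) starting point; the
    remaining restarts are randomized over P_t in (0.1, 0.9), mu within the
    central data range and sigma between a tenth and the full sample
    spread.  The sigma floor keeps EM away from the degenerate
    single-point-spike likelihood singularity.  Requires >= 50 residuals.
    """
    x = pool.residuals
    if x.size < 50:
        raise ValueError(f"need at least 50 residuals, got {x.size}")
    rng = np.random.default_rng(seed)
    spread = max(float(np.std(x)), sigma_floor)
    starts: list[tuple[float, float, float]] = []
    if init is not None:
        starts.append(init)
    starts.append((0.75, float(np.median(x)), spread / 2.0))
    while len(starts) < n_restarts:
        starts.append(
            (
                float(rng.uniform(0.1, 0.9)),
                float(rng.uniform(np.quantile(x, 0.25), np.quantile(x, 0.75))),
                float(rng.uniform(0.1, 1.0) * spread),
            )
        )
    best = None
    for p0, mu0, s0 in starts:
        p_t, mu, sigma, ll, it = _em_once(
            x, pool.a, pool.b, p0, mu0, s0, max_iter, tol, sigma_floor
        )
        if np.isfinite(ll) and (best is None or ll > best[3]):
            best = (p_t, mu, sigma, ll, it)
    if best is None:
        raise FitError("EM failed to produce a finite log-likelihood from any start")
    p_t, mu, sigma, ll, it = best
    model = MixtureModel(P_t=p_t, mu=mu, sigma2=sigma**2, a=pool.a, b=pool.b)
    gap = _ecdf_sup_gap(x, model)
    return MixtureFitResult(
        P_t=p_t, mu=mu, sigma=sigma, loglik=ll, n_iter=it, ecdf_max_gap=gap
    )


def _ecdf_sup_gap(x: np.ndarray, model: MixtureModel) -> float:
    xs = np.sort(x)
    n = xs.size
    model_cdf = model.cdf(xs)
    upper = np.arange(1, n + 1) / n
    lower = np.arange(0, n) / n
    return float(max(np.max(np.abs(upper - model_cdf)), np.max(np.abs(lower - model_cdf))))


def ecdf_overlay(
    pool: ResidualPool, fit: MixtureFitResult, n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired empirical and fitted-model CDF curves on a shared grid.

    Returns (x_grid, empirical_cdf, model_cdf), ready for a validation
    overlay plot of observed against modelled measurement distributions.
    """
    x = np.sort(pool.residuals)
    grid = np.linspace(min(pool.a, x[0]), max(pool.b, x[-1]), n_grid)
    empirical = np.searchsorted(x, grid, side="right") / x.size
    model = fit.as_model(pool.a, pool.b).cdf(grid)
    return grid, empirical, model
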