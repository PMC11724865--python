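"""Streaming Bayesian aggregation of per-frame biometric measurements.

A whole ultrasound scan yields hundreds of automatic measurements of each
biometric.  Correctly classified frames produce values scattered around the
true biometric (modelled as Gaussian), while misclassified planes and
failed extractions produce effectively arbitrary values (modelled as
uniform over the biological limits).  The observed measurement stream is
therefore a two-component contamination mixture

    D_o = P_t * N(mu, sigma^2) + (1 - P_t) * U(a, b),

where ``P_t`` is the proportion of valid measurements.  Each incoming
measurement x_i is scored with the normalized Bayes posterior probability
p_i = P(T | x_i) that it came from the Gaussian (true) component, and the
running estimates of P_t, mu and sigma^2 are updated by weighted cumulative
averages in which x_i contributes with weight p_i.  Outliers thus pull the
estimate only in proportion to their (tiny) posterior probability of being
genuine.  The reported 95% credible interval is mu ± 2*sigma_hat with
standard error sigma_hat = sigma / sqrt(W_sigma2), which shrinks as
evidence accumulates.

The update is purely streaming: state is O(1) and each measurement is
folded in once, in frame order.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import BiometricSpec, CentileReference

__all__ = [
    "MixtureModel",
    "EstimatorState",
    "CredibleInterval",
    "PriorConfig",
    "init_state",
    "posterior_true_prob",
    "update",
    "credible_interval",
    "run_stream",
    "trajectory_to_csv",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _normal_pdf(x: float, mu: float, sigma2: float) -> float:
    sigma = math.sqrt(sigma2)
    z = (x - mu) / sigma
    return math.exp(-0.5 * z * z) / (sigma * _SQRT_2PI)


@dataclass(frozen=True)
class MixtureModel:
    """Gaussian + uniform contamination mixture over observed measurements."""

    P_t: float
    mu: float
    sigma2: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.P_t <= 1.0:
            raise ValueError(f"P_t {self.P_t} not in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not self.a < self.b:
            raise ValueError(f"require a < b, got a={self.a}, b={self.b}")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sigma = math.sqrt(self.sigma2)
        gauss = np.exp(-0.5 * ((x - self.mu) / sigma) ** 2) / (sigma * _SQRT_2PI)
        unif = np.where((x >= self.a) & (x <= self.b), 1.0 / (self.b - self.a), 0.0)
        return self.P_t * gauss + (1.0 - self.P_t) * unif

    def cdf(self, x) -> np.ndarray:
        from scipy.stats import norm

        x = np.asarray(x, dtype=float)
        gauss = norm.cdf(x, loc=self.mu, scale=math.sqrt(self.sigma2))
        unif = np.clip((x - self.a) / (self.b - self.a), 0.0, 1.0)
        return self.P_t * gauss + (1.0 - self.P_t) * unif


@dataclass(frozen=True)
class EstimatorState:
    """Running mixture-parameter estimates and their cumulative weights.

    ``W`` counts all measurements seen plus the prior weight; ``W_mu`` and
    ``W_sigma2`` accumulate posterior probabilities (effective number of
    genuine measurements).  The nuisance bounds ``a``, ``b`` stay fixed for
    the scan: the uniform component has no parameters worth tracking.
    """

    P_t: float
    mu: float
    sigma2: float
    W: float
    W_mu: float
    W_sigma2: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 < self.P_t < 1.0:
            raise ValueError(
                f"P_t must lie strictly in (0, 1); got {self.P_t} "
                "(the estimator cannot move off the boundary)"
            )
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.W < 0 or self.W_mu <= 0 or self.W_sigma2 <= 0:
            raise ValueError("weights must satisfy W >= 0, W_mu > 0, W_sigma2 > 0")
        if not self.a < self.b:
            raise ValueError(f"degenerate nuisance bounds a={self.a}, b={self.b}")


@dataclass(frozen=True)
class CredibleInterval:
    """95% credible interval mu ± 2*sigma_hat."""

    mu: float
    sigma_hat: float
    low: float
    high: float


@dataclass(frozen=True)
class PriorConfig:
    """Prior initialisation for one scan.

    ``P_t0`` must be strictly inside (0, 1): the update converges on the
    true valid-measurement proportion from any interior starting point but
    is stuck at the boundaries.  ``W_0`` trades convergence speed against
    early oscillation of P_t.  ``W_mu0``/``W_sigma2_0`` control how fast
    data overwhelms the centile-chart prior for mu and sigma^2.
    """

    P_t0: float = 0.75
    W_0: float = 10.0
    W_mu0: float = 1.0
    W_sigma2_0: float = 1.0
    plausibility_window_weeks: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.P_t0 < 1.0:
            raise ValueError(
                "P_t0 must be strictly between 0 and 1: the estimator "
                "cannot converge from a boundary prior"
            )
        if self.W_0 < 0 or self.W_mu0 <= 0 or self.W_sigma2_0 <= 0:
            raise ValueError("prior weights must be positive (W_0 may be 0)")


def init_state(
    ref: CentileReference,
    biometric: Union[BiometricSpec, str],
    ga_weeks: float,
    config: Optional[PriorConfig] = None,
) -> EstimatorState:
    """Initialise the estimator from the centile chart at the scan GA.

    The prior mean is the 50th centile at the gestational age; the prior
    standard deviation spans the p3–p97 band (sigma_0 = (p97 - p3) / 4, so
    ±2 sigma_0 covers the chart's normal range).  The fixed nuisance bounds
    are the plausibility window: p3 at GA−3 weeks to p97 at GA+3 weeks.
    """
    config = config or PriorConfig()
    code = biometric.code if isinstance(biometric, BiometricSpec) else biometric
    p3, p50, p97 = ref.centiles(code, ga_weeks)
    w = config.plausibility_window_weeks
    a = ref.p3(code, ga_weeks - w)
    b = ref.p97(code, ga_weeks + w)
    if not a < b:
        raise ValueError(f"degenerate plausibility window for {code}: a={a}, b={b}")
    sigma0 = (p97 - p3) / 4.0
    return EstimatorState(
        P_t=config.P_t0,
        mu=p50,
        sigma2=sigma0 * sigma0,
        W=config.W_0,
        W_mu=config.W_mu0,
        W_sigma2=config.W_sigma2_0,
        a=a,
        b=b,
    )


def posterior_true_prob(state: EstimatorState, x: float) -> float:
    """P(T | x): posterior probability that x is a genuine measurement.

    Normalized Bayes rule over the two mixture branches, with the Gaussian
    likelihood N(x; mu, sigma^2) against the uniform density 1/(b-a).
    Callers guarantee a <= x <= b (out-of-window values are rejected by the
    plausibility gate before reaching the estimator).
    """
    g = _normal_pdf(x, state.mu, state.sigma2)
    u = 1.0 / (state.b - state.a)
    num = g * state.P_t
    den = num + u * (1.0 - state.P_t)
    return num / den


def update(state: EstimatorState, x: float) -> EstimatorState:
    """Fold one measurement into the running state.

    Weighted cumulative averages: P_t moves with unit weight per frame;
    mu and sigma^2 move with weight p = P(T | x).  The squared deviation
    in the variance update uses the PREVIOUS mean, and the three parameter
    updates all read the pre-update weights.
    """
    p = posterior_true_prob(state, x)
    P_t = (p + state.W * state.P_t) / (state.W + 1.0)
    mu = (x * p + state.W_mu * state.mu) / (p + state.W_mu)
    sigma2 = ((x - state.mu) ** 2 * p + state.W_sigma2 * state.sigma2) / (
        p + state.W_sigma2
    )
    return replace(
        state,
        P_t=P_t,
        mu=mu,
        sigma2=sigma2,
        W=state.W + 1.0,
        W_mu=state.W_mu + p,
        W_sigma2=state.W_sigma2 + p,
    )


def credible_interval(state: EstimatorState) -> CredibleInterval:
    """95% credible interval from the current state.

    The standard error of the running mean is sigma / sqrt(W_sigma2), the
    Gaussian spread divided by the effective number of genuine measurements
    absorbed so far.
    """
    if state.sigma2 <= 0:
        raise ValueError("corrupted state: sigma2 must be positive")
    sigma_hat = math.sqrt(state.sigma2 / state.W_sigma2)
    return CredibleInterval(
        mu=state.mu,
        sigma_hat=sigma_hat,
        low=state.mu - 2.0 * sigma_hat,
        high=state.mu + 2.0 * sigma_hat,
    )


def run_stream(
    measurements: Iterable[float],
    state0: EstimatorState,
    record_trajectory: bool = True,
) -> tuple[EstimatorState, pd.DataFrame]:
    """Fold accepted measurements (in frame order) into the estimator.

    Returns the final state and a trajectory table with one row per
    measurement (columns ``i, x, p_true, P_t, mu, sigma2, sigma_hat``) for
    plotting the estimate's evolution; the table is empty when
    ``record_trajectory`` is false or the stream is empty.
    """
    state = state0
    rows: list[tuple] = []
    for i, x in enumerate(measurements):
        p = posterior_true_prob(state, x)
        state = update(state, x)
        if record_trajectory:
            rows.append(
                (i, x, p, state.P_t, state.mu, state.sigma2,
                 math.sqrt(state.sigma2 / state.W_sigma2))
            )
    traj = pd.DataFrame(
        rows, columns=["i", "x", "p_true", "P_t", "mu", "sigma2", "sigma_hat"]
    )
    return state, traj


def trajectory_to_csv(traj: pd.DataFrame, path: Union[str, Path, io.IOBase]) -> None:
    traj.to_csv(path, index=False)
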