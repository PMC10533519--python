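"""Ex-Gaussian response-time distribution and the saturating tau trajectory.

The ex-Gaussian is the distribution of ``X = N(mu, sigma^2) + Exp(tau)``:
a Gaussian "non-decision" component plus an exponentially distributed
decision component with mean ``tau``.  In the time-evolving model only the
exponential mean changes over trials, following a three-parameter
saturating exponential (start level, rate time constant, asymptote).

All parameters are in milliseconds except the rate, which is a time
constant measured in trials: the number of trials after the first at which
exactly half of the start-to-asymptote change has been completed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx, log_ndtr

from .errors import ParameterError

__all__ = [
    "ExGaussParams",
    "TrajectoryParams",
    "exgauss_logpdf",
    "exgauss_sample",
    "exgauss_mean",
    "exgauss_var",
    "tau_trajectory",
]

_LOG2 = np.log(2.0)
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters of an ex-Gaussian distribution (all in ms).

    Attributes
    ----------
    mu_ms : float
        Mean of the Gaussian component.
    sigma_ms : float
        Standard deviation of the Gaussian component; strictly positive.
    tau_ms : float
        Mean of the exponential component; strictly positive.
    """

    mu_ms: float
    sigma_ms: float
    tau_ms: float

    def __post_init__(self) -> None:
        if not (self.sigma_ms > 0):
            raise ParameterError(f"sigma_ms must be > 0, got {self.sigma_ms}")
        if not (self.tau_ms > 0):
            raise ParameterError(f"tau_ms must be > 0, got {self.tau_ms}")


@dataclass(frozen=True)
class TrajectoryParams:
    """Saturating-exponential trajectory of the exponential mean tau.

    Attributes
    ----------
    start_ms : float
        tau at the first trial (t = 1).
    rate_trials : float
        Time constant: trials past the first at which 50% of the
        start-to-asymptote change is complete.
    asym_ms : float
        Limiting tau as the trial index grows.
    """

    start_ms: float
    rate_trials: float
    asym_ms: float

    def __post_init__(self) -> None:
        for name in ("start_ms", "rate_trials", "asym_ms"):
            v = getattr(self, name)
            if not (v > 0):
                raise ParameterError(f"{name} must be > 0, got {v}")


def _logpdf(x, mu, sigma, tau):
    """Vectorized ex-Gaussian log-density, stable over the whole real line.

    Two algebraically identical forms are switched at z = 0, where
    ``z = (x - mu)/sigma - sigma/tau``:

    * ``z <= 0`` (including the entire left tail and the small-tau /
      Gaussian-dominated regime): a scaled-complementary-erf form,
      ``log f = -log(2 tau) + log erfcx(-z/sqrt 2) - (x-mu)^2/(2 sigma^2)``,
      which never forms the catastrophically large ``sigma^2/(2 tau^2)``
      term explicitly.
    * ``z > 0`` (exponential-dominated right tail): the direct form with
      ``log_ndtr``, which is accurate there and avoids erfcx overflow for
      negative arguments.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, tau = (np.asarray(v, dtype=float) for v in (mu, sigma, tau))
    z = (x - mu) / sigma - sigma / tau
    # Branch 1: erfcx route (z <= 0).
    with np.errstate(over="ignore", invalid="ignore"):
        left = -np.log(2.0 * tau) + np.log(erfcx(-z / np.sqrt(2.0))) \
            - (x - mu) ** 2 / (2.0 * sigma ** 2)
        right = -np.log(tau) + sigma ** 2 / (2.0 * tau ** 2) \
            - (x - mu) / tau + log_ndtr(z)
    return np.where(z <= 0, left, right)


def _logpdf_grad(x, mu, sigma, tau):
    """Gradient of the ex-Gaussian log-density w.r.t. (mu, sigma, tau).

    Returns three arrays broadcast to the shape of the inputs.  Uses the
    inverse Mills ratio ``r = phi(z)/Phi(z)`` computed fully in log space.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, tau = (np.asarray(v, dtype=float) for v in (mu, sigma, tau))
    z = (x - mu) / sigma - sigma / tau
    log_phi = -0.5 * z ** 2 - _HALF_LOG_2PI
    r = np.exp(log_phi - log_ndtr(z))
    d_mu = 1.0 / tau - r / sigma
    d_sigma = sigma / tau ** 2 + r * (-(x - mu) / sigma ** 2 - 1.0 / tau)
    d_tau = (-1.0 / tau - sigma ** 2 / tau ** 3 + (x - mu) / tau ** 2
             + r * sigma / tau ** 2)
    return d_mu, d_sigma, d_tau


def exgauss_logpdf(x, params: ExGaussParams):
    """Log-density of the ex-Gaussian distribution.

    Parameters
    ----------
    x : float or array_like
        Evaluation point(s) in ms.
    params : ExGaussParams

    Returns
    -------
    float or ndarray
        Finite log-density for every finite ``x``.
    """
    out = _logpdf(x, params.mu_ms, params.sigma_ms, params.tau_ms)
    return float(out) if np.isscalar(x) else out


def exgauss_sample(n: int, params: ExGaussParams, seed) -> np.ndarray:
    """Draw ``n`` ex-Gaussian variates (ms), reproducible given ``seed``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return (rng.normal(params.mu_ms, params.sigma_ms, size=n)
            + rng.exponential(params.tau_ms, size=n))


def exgauss_mean(params: ExGaussParams) -> float:
    """Analytic mean: mu + tau."""
    return params.mu_ms + params.tau_ms


def exgauss_var(params: ExGaussParams) -> float:
    """Analytic variance: sigma^2 + tau^2."""
    return params.sigma_ms ** 2 + params.tau_ms ** 2


def _tau_trajectory(t, start, rate, asym):
    """Vectorized trajectory: asym + (start - asym) * 2**(-(t-1)/rate)."""
    t = np.asarray(t, dtype=float)
    return asym + (start - asym) * np.exp2(-(t - 1.0) / rate)


def tau_trajectory(t, traj: TrajectoryParams):
    """Exponential mean at trial ``t`` under a saturating trajectory.

    ``tau(t) = asym + (start - asym) * 2**(-(t - 1)/rate)``, so that
    ``tau(1) = start`` and at ``t = 1 + rate`` exactly half of the
    start-to-asymptote change has occurred (the rate parameter is a time
    constant in trials).

    Parameters
    ----------
    t : int, float or array_like
        Trial index, >= 1.
    traj : TrajectoryParams

    Returns
    -------
    float or ndarray
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 1):
        raise ParameterError("trial index t must be >= 1")
    out = _tau_trajectory(t_arr, traj.start_ms, traj.rate_trials, traj.asym_ms)
    return float(out) if np.isscalar(t) else out
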