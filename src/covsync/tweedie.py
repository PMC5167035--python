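"""Tweedie distribution Tw(mu, phi, p) for index p in (1, 2).

For this index range the Tweedie exponential-dispersion family is the
distribution of a compound Poisson sum of gamma variates: continuous on
(0, inf) with an atom at exactly zero, and with the power mean-variance
relationship Var(Y) = phi * mu**p.  This matches panel data of annual mean
counts, which are non-negative, effectively continuous, and contain exact
zeros.

Parameterization used throughout:

* Poisson rate      lambda = mu**(2-p) / (phi * (2-p))
* gamma shape       alpha  = (2-p) / (p-1) per Poisson event
* gamma scale       tau    = phi * (p-1) * mu**(p-1)

so that E[Y] = lambda * alpha * tau = mu and Var(Y) = phi * mu**p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import tweedie_logpdf_array

__all__ = ["TweedieParams", "zero_probability", "log_density", "sample"]


@dataclass(frozen=True)
class TweedieParams:
    """Parameters of a Tweedie distribution with index in the open (1, 2).

    Attributes
    ----------
    mu : float
        Mean, on the count scale; strictly positive.
    phi : float
        Dispersion; strictly positive.  The implied variance is
        ``phi * mu**p``.
    p : float
        Index parameter, strictly inside (1, 2).  The endpoints (Poisson
        and gamma limits) are excluded because the series density
        degenerates there.
    """

    mu: float
    phi: float
    p: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not (self.phi > 0 and math.isfinite(self.phi)):
            raise ValueError(f"phi must be positive and finite, got {self.phi}")
        if not (1.0 < self.p < 2.0):
            raise ValueError(f"p must lie strictly in (1, 2), got {self.p}")

    @property
    def poisson_rate(self) -> float:
        return self.mu ** (2.0 - self.p) / (self.phi * (2.0 - self.p))

    @property
    def gamma_shape(self) -> float:
        return (2.0 - self.p) / (self.p - 1.0)

    @property
    def gamma_scale(self) -> float:
        return self.phi * (self.p - 1.0) * self.mu ** (self.p - 1.0)

    @property
    def variance(self) -> float:
        return self.phi * self.mu**self.p


def zero_probability(params: TweedieParams) -> float:
    """Probability of an exact zero, ``exp(-lambda)``.

    The zero event is "no Poisson arrivals" in the compound
    Poisson-gamma construction, so P(Y = 0) = exp(-mu**(2-p)/(phi*(2-p))).
    """
    return math.exp(-params.poisson_rate)


def log_density(y, params: TweedieParams):
    """Log density of Tw(mu, phi, p), with a point-mass convention at 0.

    Parameters
    ----------
    y : float or array_like
        Non-negative evaluation point(s).  ``y == 0`` (exact) returns the
        log of the discrete mass; ``y > 0`` the log of the continuous
        density, evaluated by summing the compound Poisson-gamma series
        outward from its dominant term.

    Returns
    -------
    float or ndarray matching the shape of ``y``.

    Raises
    ------
    ValueError
        If any ``y < 0``.
    FloatingPointError
        If the series fails to converge within the term cap.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("y must be non-negative")
    out = np.empty(y_arr.size)
    tweedie_logpdf_array(
        y_arr.ravel(), np.full(y_arr.size, params.mu), params.phi, params.p, out
    )
    if np.any(np.isnan(out)):
        bad = y_arr.ravel()[np.isnan(out)][0]
        raise FloatingPointError(
            f"Tweedie series did not converge at y={bad} for {params}"
        )
    if np.isscalar(y) or y_arr.ndim == 0:
        return float(out[0])
    return out.reshape(y_arr.shape)


def sample(params: TweedieParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` variates via the compound Poisson-gamma construction.

    N ~ Poisson(lambda); conditional on N = m > 0 the draw is
    Gamma(m * alpha, tau) (a sum of m iid gamma variates), and exactly 0
    when m = 0.  Reproducible under a fixed ``rng`` state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = rng.poisson(params.poisson_rate, size=n)
    out = np.zeros(n)
    pos = counts > 0
    if np.any(pos):
        out[pos] = rng.gamma(
            shape=counts[pos] * params.gamma_shape, scale=params.gamma_scale
        )
    return out
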