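"""Prior configuration.

Defaults follow the weakly-informative prior set used for this model
class: N(0, sigma^2 = 1e-2) on intercepts and regression coefficients (sd
0.1, an order of magnitude above typical log-scale growth effects), a
negative half-normal with the same scale on density dependence, U[0, 200]
on augmented initial means, U[0, 5] and U[1, 2] on the Tweedie dispersion
and index, and InvGamma(1e-3, 1e-3) on the two random-effect variances.
The coefficient scale is also what makes the reversible-jump innovation sd
of 1e-3 a workable proposal for split moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PriorConfig"]


@dataclass
class PriorConfig:
    coef_variance: float = 1e-2  # alpha, beta, gamma, interspecific nu
    dd_variance: float = 1e-2  # negative half-normal on nu[s, s]
    mu0_bounds: tuple[float, float] = (0.0, 200.0)
    phi_bounds: tuple[float, float] = (0.0, 5.0)
    p_bounds: tuple[float, float] = (1.0, 2.0)
    invgamma_a: float = 1e-3
    invgamma_b: float = 1e-3
    # Optional discrete prior for selected coefficient families: the family
    # value is uniform on a finite grid instead of normal.  Used for exact
    # brute-force model-probability oracles.
    grid: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.coef_variance <= 0 or self.dd_variance <= 0:
            raise ValueError("prior variances must be positive")
        for name in ("mu0_bounds", "phi_bounds", "p_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered")
        if self.invgamma_a <= 0 or self.invgamma_b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")
        self.grid = {k: np.asarray(v, dtype=float) for k, v in self.grid.items()}

    @property
    def coef_sd(self) -> float:
        return math.sqrt(self.coef_variance)

    def to_dict(self) -> dict:
        return {
            "coef_variance": self.coef_variance,
            "dd_variance": self.dd_variance,
            "mu0_bounds": list(self.mu0_bounds),
            "phi_bounds": list(self.phi_bounds),
            "p_bounds": list(self.p_bounds),
            "invgamma_a": self.invgamma_a,
            "invgamma_b": self.invgamma_b,
            "grid": {k: list(map(float, v)) for k, v in self.grid.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        d = dict(d)
        for name in ("mu0_bounds", "phi_bounds", "p_bounds"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)
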