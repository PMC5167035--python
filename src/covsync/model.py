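"""Hierarchically-centered multispecies dynamic model for panel counts.

The observation ``y[s,i,t]`` (annual mean count of species ``s`` at site
``i`` in year ``t``) follows ``Tw(mu[s,i,t], phi{s}, p{s})`` where the mean
evolves on the log scale:

    log mu[s,i,t] = log mu[s,i,t-1]
                    + v[i,t]' gamma{s}
                    + sum_l nu[l,s] * ylag[l,i,t-1]
                    + eps(i) + delta_s(i)

seeded at the augmented pre-survey mean ``mu0[s,i]`` (which also serves as
the lagged-abundance regressor for the first observed year).  Under
hierarchical centering the intercept and the site covariates enter through
the prior mean of the asynchronous random effect,

    delta_s(i) ~ N(alpha_s + x_i' beta{s}, sigma2_s),
    eps(i)     ~ N(0, sigma2_eps),

which is equivalent to the uncentered form where the linear predictor sits
in the growth rate and ``delta'_s(i) = delta_s(i) - alpha_s - x_i' beta{s}``
has a zero-mean prior.

Regression coefficients (each beta_j, each gamma_j) and the two Tweedie
parameters can be *shared* across species: a ``SharingStructure`` assigns a
set partition of the species to each such family, and block members read a
common value.  Intercepts and interaction terms are always species-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from ._kernels import panel_loglik

__all__ = [
    "Partition",
    "PanelData",
    "SharingStructure",
    "ModelState",
    "mean_trajectory",
    "log_likelihood",
    "loglik_matrix",
    "log_prior",
    "log_joint",
    "intraclass_correlation",
    "beta_family",
    "gamma_family",
    "PHI_FAMILY",
    "P_FAMILY",
]

PHI_FAMILY = "phi"
P_FAMILY = "p"


def beta_family(j: int) -> str:
    """Family key for the j-th site-covariate coefficient."""
    return f"beta_{j}"


def gamma_family(j: int) -> str:
    """Family key for the j-th time-varying-covariate coefficient."""
    return f"gamma_{j}"


def family_kind(key: str) -> str:
    return key.split("_", 1)[0]


def family_cov_index(key: str) -> int:
    return int(key.split("_", 1)[1])


class Partition:
    """A set partition of species indices ``{0, ..., n_species-1}``.

    Blocks are canonicalized (members sorted, blocks ordered by smallest
    member) so that equality and hashing are well defined.
    """

    __slots__ = ("blocks", "_bidx")

    def __init__(self, blocks: Iterable[Iterable[int]]):
        cleaned = [tuple(sorted(set(b))) for b in blocks]
        if not cleaned or any(len(b) == 0 for b in cleaned):
            raise ValueError("blocks must be non-empty")
        canon = tuple(sorted(cleaned, key=lambda b: b[0]))
        flat = [s for b in canon for s in b]
        n = max(flat) + 1
        if sorted(flat) != list(range(n)):
            raise ValueError(
                f"blocks must partition 0..{n - 1} disjointly, got {canon}"
            )
        self.blocks = canon

    @property
    def n_species(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, species: int) -> int:
        for b, members in enumerate(self.blocks):
            if species in members:
                return b
        raise KeyError(species)

    def block_index(self) -> np.ndarray:
        """Array mapping species index -> block index (cached; immutable)."""
        try:
            return self._bidx
        except AttributeError:
            pass
        idx = np.empty(self.n_species, dtype=np.int64)
        for b, members in enumerate(self.blocks):
            for s in members:
                idx[s] = b
        object.__setattr__(self, "_bidx", idx)
        return idx

    def expand(self, values: np.ndarray) -> np.ndarray:
        """Per-species values from per-block values."""
        return np.asarray(values)[self.block_index()]

    def label(self, names: list[str] | None = None) -> str:
        def nm(s):
            return names[s] if names is not None else str(s + 1)

        return ", ".join("{" + ", ".join(nm(s) for s in b) + "}" for b in self.blocks)

    @classmethod
    def singletons(cls, n: int) -> "Partition":
        return cls([[s] for s in range(n)])

    @classmethod
    def pooled(cls, n: int) -> "Partition":
        return cls([list(range(n))])

    def __eq__(self, other):
        return isinstance(other, Partition) and self.blocks == other.blocks

    def __hash__(self):
        return hash(self.blocks)

    def __repr__(self):
        return f"Partition({self.label()})"


@dataclass
class PanelData:
    """Unbalanced species x site x year panel with covariates.

    Observations are stored with sites concatenated along a flat time axis:
    site ``i`` occupies the slice ``offsets[i]:offsets[i+1]`` covering the
    inclusive calendar-year window ``window_start[i] .. window_start[i] +
    window_len[i] - 1``.  Every species is observed in every site-year of
    the window; gaps inside a window are rejected at load time.
    """

    species: list[str]
    sites: list[str]
    window_start: np.ndarray  # (n_sites,) int calendar years
    window_len: np.ndarray  # (n_sites,) int
    y: np.ndarray  # (n_species, N)
    v: np.ndarray  # (N, d_v) time-varying covariates
    x: np.ndarray  # (n_sites, d_x) site covariates
    x_names: list[str] = field(default_factory=list)
    v_names: list[str] = field(default_factory=list)
    standardization: dict | None = None

    def __post_init__(self):
        self.window_start = np.asarray(self.window_start, dtype=np.int64)
        self.window_len = np.asarray(self.window_len, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if len(self.species) < 2:
            raise ValueError("at least 2 species are required")
        if np.any(self.window_len < 1):
            raise ValueError("every site needs a non-empty observation window")
        if self.y.shape != (len(self.species), int(self.window_len.sum())):
            raise ValueError("y shape inconsistent with windows")
        if not np.all(np.isfinite(self.y)) or np.any(self.y < 0):
            raise ValueError("observations must be finite and non-negative")
        if self.v.shape[0] != self.y.shape[1]:
            raise ValueError("time-varying covariates must cover every site-year")
        if self.x.shape[0] != len(self.sites):
            raise ValueError("site covariates must cover every site")
        if not np.all(np.isfinite(self.v)) or not np.all(np.isfinite(self.x)):
            raise ValueError("covariates must be finite (no missing values)")
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.d_x)]
        if not self.v_names:
            self.v_names = [f"v{j}" for j in range(self.d_v)]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def d_x(self) -> int:
        return self.x.shape[1]

    @property
    def d_v(self) -> int:
        return self.v.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        if not hasattr(self, "_offsets"):
            self._offsets = np.concatenate([[0], np.cumsum(self.window_len)])
        return self._offsets

    @property
    def n_obs(self) -> int:
        return self.n_species * self.y.shape[1]

    def site_years(self, i: int) -> np.ndarray:
        return self.window_start[i] + np.arange(self.window_len[i])

    def site_slice(self, i: int) -> slice:
        off = self.offsets
        return slice(int(off[i]), int(off[i + 1]))

    def shareable_families(self) -> list[str]:
        return (
            [beta_family(j) for j in range(self.d_x)]
            + [gamma_family(j) for j in range(self.d_v)]
            + [PHI_FAMILY, P_FAMILY]
        )


@dataclass
class SharingStructure:
    """Model indicator: one species partition per shareable family plus
    inclusion flags for the interaction matrix nu (nu[l, s] = effect of
    species l's lagged abundance on species s; the diagonal is density
    dependence).  Intercepts and nu values themselves are never shared."""

    partitions: dict[str, Partition]
    nu_included: np.ndarray  # (n_s, n_s) bool

    def __post_init__(self):
        self.nu_included = np.asarray(self.nu_included, dtype=bool)

    def validate(self, data: PanelData) -> None:
        n_s = data.n_species
        expected = set(data.shareable_families())
        if set(self.partitions) != expected:
            raise ValueError(
                f"sharing families {set(self.partitions)} != expected {expected}"
            )
        for key, part in self.partitions.items():
            if part.n_species != n_s:
                raise ValueError(f"partition for {key} covers {part.n_species} species")
        if self.nu_included.shape != (n_s, n_s):
            raise ValueError("nu_included must be (n_species, n_species)")

    def copy(self) -> "SharingStructure":
        return SharingStructure(dict(self.partitions), self.nu_included.copy())

    @classmethod
    def saturated(cls, data: PanelData, include_nu: str = "all") -> "SharingStructure":
        """Finest model: singleton partitions everywhere; nu inclusion per
        ``include_nu`` in {"all", "diag", "none"}."""
        n_s = data.n_species
        parts = {k: Partition.singletons(n_s) for k in data.shareable_families()}
        if include_nu == "all":
            inc = np.ones((n_s, n_s), dtype=bool)
        elif include_nu == "diag":
            inc = np.eye(n_s, dtype=bool)
        elif include_nu == "none":
            inc = np.zeros((n_s, n_s), dtype=bool)
        else:
            raise ValueError(include_nu)
        return cls(parts, inc)

    @classmethod
    def pooled(cls, data: PanelData, include_nu: str = "none") -> "SharingStructure":
        base = cls.saturated(data, include_nu)
        base.partitions = {
            k: Partition.pooled(data.n_species) for k in base.partitions
        }
        return base


class ExpandedParams(NamedTuple):
    """Per-species views of the block-shared parameters."""

    beta_sp: np.ndarray  # (n_s, d_x)
    gamma_sp: np.ndarray  # (n_s, d_v)
    phi_sp: np.ndarray  # (n_s,)
    p_sp: np.ndarray  # (n_s,)
    nu_mat: np.ndarray  # (n_s, n_s), zeros where excluded


@dataclass
class ModelState:
    """All continuous unknowns of the model at one sharing structure.

    ``values[family]`` stores one value per block of that family's current
    partition, aligned with ``Partition.blocks``.  ``nu`` stores only the
    interactions currently included in the model.
    """

    alpha: np.ndarray  # (n_s,)
    values: dict[str, np.ndarray]  # family key -> (n_blocks,)
    nu: dict[tuple[int, int], float]  # (l, s) -> value; diag constrained <= 0
    eps: np.ndarray  # (n_sites,)
    delta: np.ndarray  # (n_s, n_sites)
    mu0: np.ndarray  # (n_s, n_sites), supported on [0, 200]
    sigma2_eps: float
    sigma2_s: np.ndarray  # (n_s,)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.sigma2_s = np.asarray(self.sigma2_s, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}

    @property
    def n_species(self) -> int:
        return self.alpha.shape[0]

    def copy(self) -> "ModelState":
        return ModelState(
            alpha=self.alpha.copy(),
            values={k: v.copy() for k, v in self.values.items()},
            nu=dict(self.nu),
            eps=self.eps.copy(),
            delta=self.delta.copy(),
            mu0=self.mu0.copy(),
            sigma2_eps=float(self.sigma2_eps),
            sigma2_s=self.sigma2_s.copy(),
        )

    def nu_matrix(self) -> np.ndarray:
        n_s = self.n_species
        mat = np.zeros((n_s, n_s))
        for (l, s), val in self.nu.items():
            mat[l, s] = val
        return mat

    def expanded(self, sharing: SharingStructure, data: PanelData) -> ExpandedParams:
        n_s = self.n_species
        beta_sp = np.empty((n_s, data.d_x))
        for j in range(data.d_x):
            key = beta_family(j)
            beta_sp[:, j] = sharing.partitions[key].expand(self.values[key])
        gamma_sp = np.empty((n_s, data.d_v))
        for j in range(data.d_v):
            key = gamma_family(j)
            gamma_sp[:, j] = sharing.partitions[key].expand(self.values[key])
        phi_sp = sharing.partitions[PHI_FAMILY].expand(self.values[PHI_FAMILY])
        p_sp = sharing.partitions[P_FAMILY].expand(self.values[P_FAMILY])
        return ExpandedParams(beta_sp, gamma_sp, phi_sp, p_sp, self.nu_matrix())

    def check_consistent(self, sharing: SharingStructure) -> None:
        for key, part in sharing.partitions.items():
            if self.values[key].shape != (part.n_blocks,):
                raise ValueError(
                    f"{key}: {self.values[key].shape[0]} values for "
                    f"{part.n_blocks} blocks"
                )
        inc = {tuple(p) for p in np.argwhere(sharing.nu_included)}
        if set(self.nu) != inc:
            raise ValueError("stored nu entries do not match inclusion flags")


def mean_trajectory(
    state: ModelState,
    sharing: SharingStructure,
    data: PanelData,
    species: int,
    site: int,
    uncentered: bool = False,
) -> np.ndarray:
    """Reference (pure Python) evaluation of mu[s, i, t] over the window.

    The recursion is seeded at the augmented ``mu0[s, i]``; the lagged
    abundance regressor is ``mu0[l, i]`` for the first observed year and
    the observed count thereafter.  Under centering (default) alpha and
    beta do not appear here; with ``uncentered=True`` they are added to
    every increment (and ``state.delta`` is read as the zero-mean
    effect delta').
    """
    if data.window_len[site] < 1:
        raise ValueError("empty observation window")
    exp_par = state.expanded(sharing, data)
    s, i = species, site
    o0 = int(data.offsets[i])
    out = np.empty(int(data.window_len[i]))
    logmu = math.log(state.mu0[s, i])
    for k in range(out.shape[0]):
        inc = state.eps[i] + state.delta[s, i]
        if uncentered:
            inc += state.alpha[s] + float(data.x[i] @ exp_par.beta_sp[s])
        inc += float(data.v[o0 + k] @ exp_par.gamma_sp[s])
        for l in range(data.n_species):
            nls = exp_par.nu_mat[l, s]
            if nls != 0.0:
                ylag = state.mu0[l, i] if k == 0 else data.y[l, o0 + k - 1]
                inc += nls * ylag
        logmu += inc
        out[k] = math.exp(logmu)
    return out


# lgamma lookup tables for the series kernel: lgamma(j + 1) is universal;
# lgamma(j * alpha) depends only on the index parameter p, so rows are cached
# per p value (bounded cache; p values recur between acceptances)
_LGFACT = np.array([0.0])
_LGALPHA: dict[float, np.ndarray] = {}
_TABLE_GROWTH = 1.5


def _series_tables(data: PanelData, phi_sp, p_sp):
    global _LGFACT
    n_s = data.n_species
    if not hasattr(data, "_ymax"):
        data._ymax = data.y.max(axis=1)
    n_tab = np.empty(n_s, dtype=np.int64)
    for s in range(n_s):
        ymax, phi, p = data._ymax[s], phi_sp[s], p_sp[s]
        jpeak = ymax ** (2.0 - p) / (phi * (2.0 - p)) if ymax > 0 else 1.0
        n_tab[s] = min(int(3.0 * jpeak) + 64, 20_000)
    need = int(n_tab.max())
    if _LGFACT.shape[0] < need:
        from scipy.special import gammaln

        grown = int(need * _TABLE_GROWTH)
        _LGFACT = gammaln(np.arange(grown) + 1.0)
    rows = []
    for s in range(n_s):
        p = float(p_sp[s])
        alpha = (2.0 - p) / (p - 1.0)
        row = _LGALPHA.get(p)
        if row is None or row.shape[0] < n_tab[s]:
            from scipy.special import gammaln

            grown = int(n_tab[s] * _TABLE_GROWTH)
            j = np.arange(grown, dtype=float)
            row = np.empty(grown)
            row[0] = 0.0
            row[1:] = gammaln(j[1:] * alpha)
            if len(_LGALPHA) > 256:
                _LGALPHA.clear()
            _LGALPHA[p] = row
        rows.append(row)
    width = max(r.shape[0] for r in rows)
    lgalpha = np.zeros((n_s, width))
    for s, r in enumerate(rows):
        lgalpha[s, : r.shape[0]] = r
    return _LGFACT, lgalpha, n_tab


def loglik_matrix(
    state: ModelState,
    sharing: SharingStructure,
    data: PanelData,
    species_mask: np.ndarray | None = None,
    uncentered: bool = False,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Per-(species, site) log-likelihood contributions via the fast kernel."""
    exp_par = state.expanded(sharing, data)
    if species_mask is None:
        species_mask = np.ones(data.n_species, dtype=bool)
    if out is None:
        out = np.zeros((data.n_species, data.n_sites))
    delta = state.delta
    if uncentered:
        delta = delta + state.alpha[:, None] + (exp_par.beta_sp @ data.x.T)
    lgfact, lgalpha, n_tab = _series_tables(data, exp_par.phi_sp, exp_par.p_sp)
    panel_loglik(
        data.y,
        data.v,
        data.offsets,
        state.mu0,
        state.eps,
        np.ascontiguousarray(delta),
        exp_par.gamma_sp,
        exp_par.nu_mat,
        exp_par.phi_sp,
        exp_par.p_sp,
        np.ascontiguousarray(species_mask),
        lgfact,
        lgalpha,
        n_tab,
        out,
    )
    return out


def log_likelihood(
    state: ModelState,
    sharing: SharingStructure,
    data: PanelData,
    uncentered: bool = False,
) -> float:
    """Total Tweedie log-likelihood of the panel."""
    return float(loglik_matrix(state, sharing, data, uncentered=uncentered).sum())


def _norm_logpdf(x, var):
    return -0.5 * (math.log(2.0 * math.pi * var)) - np.square(x) / (2.0 * var)


def _invgamma_logpdf(x, a, b):
    if x <= 0:
        return -math.inf
    return a * math.log(b) - math.lgamma(a) - (a + 1.0) * math.log(x) - b / x


def log_prior(
    state: ModelState,
    sharing: SharingStructure,
    data: PanelData,
    priors,
    uncentered: bool = False,
) -> float:
    """Joint log prior density of a model state given the sharing structure.

    Shared parameters contribute one prior term per block.  Values outside
    their support return -inf (never raise), so Metropolis-Hastings can
    reject uniformly.  The random-effect "priors" N(0, sigma2_eps) for eps
    and N(alpha + x'beta, sigma2_s) for delta are part of this sum; with
    ``uncentered=True`` the delta prior is centered at zero instead (and
    the linear predictor moves into the likelihood).
    """
    lp = 0.0
    var_coef = priors.coef_variance
    var_dd = priors.dd_variance
    lp += float(_norm_logpdf(state.alpha, var_coef).sum())
    for key, part in sharing.partitions.items():
        vals = state.values[key]
        kind = family_kind(key)
        if kind in ("beta", "gamma"):
            grid = priors.grid.get(key)
            if grid is not None:
                if all(np.any(np.isclose(v, grid, atol=1e-12)) for v in vals):
                    lp += -len(vals) * math.log(len(grid))
                else:
                    return -math.inf
            else:
                lp += float(_norm_logpdf(vals, var_coef).sum())
        elif kind == PHI_FAMILY:
            lo, hi = priors.phi_bounds
            if np.any(vals <= lo) or np.any(vals >= hi):
                return -math.inf
            lp += -len(vals) * math.log(hi - lo)
        elif kind == P_FAMILY:
            lo, hi = priors.p_bounds
            if np.any(vals <= lo) or np.any(vals >= hi):
                return -math.inf
            lp += -len(vals) * math.log(hi - lo)
        else:  # pragma: no cover
            raise ValueError(key)
    for (l, s), val in state.nu.items():
        if l == s:  # density dependence: negative half-normal
            if val > 0:
                return -math.inf
            lp += math.log(2.0) + float(_norm_logpdf(val, var_dd))
        else:
            lp += float(_norm_logpdf(val, var_coef))
    lo, hi = priors.mu0_bounds
    if np.any(state.mu0 < lo) or np.any(state.mu0 > hi):
        return -math.inf
    lp += -state.mu0.size * math.log(hi - lo)
    if state.sigma2_eps <= 0 or np.any(state.sigma2_s <= 0):
        return -math.inf
    a, b = priors.invgamma_a, priors.invgamma_b
    lp += _invgamma_logpdf(state.sigma2_eps, a, b)
    lp += sum(_invgamma_logpdf(s2, a, b) for s2 in state.sigma2_s)
    lp += float(_norm_logpdf(state.eps, state.sigma2_eps).sum())
    exp_par = state.expanded(sharing, data)
    mean = np.zeros((state.n_species, data.n_sites))
    if not uncentered:
        mean = state.alpha[:, None] + exp_par.beta_sp @ data.x.T
    z = state.delta - mean
    s2 = state.sigma2_s[:, None]
    lp += float(
        (-0.5 * np.log(2.0 * np.pi * s2) - np.square(z) / (2.0 * s2)).sum()
    )
    return lp


def log_joint(
    state: ModelState,
    sharing: SharingStructure,
    data: PanelData,
    priors,
    uncentered: bool = False,
) -> float:
    """Unnormalized log posterior density: likelihood plus prior.

    The centered (default) and uncentered parameterizations describe the
    same joint density; ``log_joint(state) ==
    log_joint(uncentered_state, uncentered=True)`` whenever
    ``uncentered_state.delta = state.delta - alpha - x'beta`` (the Jacobian
    of that shift is 1).
    """
    lp = log_prior(state, sharing, data, priors, uncentered=uncentered)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(state, sharing, data, uncentered=uncentered)


def intraclass_correlation(sigma2_eps, sigma2_s):
    """ICC = sigma2_eps / (sigma2_eps + sigma2_s): the synchronous fraction
    of residual variance for a species."""
    sigma2_eps = np.asarray(sigma2_eps, dtype=float)
    sigma2_s = np.asarray(sigma2_s, dtype=float)
    if np.any(sigma2_eps <= 0) or np.any(sigma2_s <= 0):
        raise ValueError("variance components must be positive")
    out = sigma2_eps / (sigma2_eps + sigma2_s)
    return float(out) if out.ndim == 0 else out
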