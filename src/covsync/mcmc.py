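"""Within-model posterior sampling.

Single-update adaptive Metropolis-Hastings for the continuous parameters,
conjugate Gibbs draws for the two random-effect variances, and MH updates
for the augmented initial means.  Site-level scalars (eps, delta rows, mu0
rows) are proposed as per-site independent batches: because the likelihood
factorizes over sites given everything else, accepting or rejecting each
site separately is distributionally identical to sequential single-site
updates and vectorizes the hot path.

Proposal standard deviations adapt toward a 0.44 acceptance rate during
burn-in only (sd *= exp(kappa * (rate - 0.44)), clamped to [1e-6, 10]) and
are frozen afterwards so the chain is ergodic for its stationary
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    PanelData,
    SharingStructure,
    ModelState,
    loglik_matrix,
    beta_family,
    gamma_family,
    family_kind,
    PHI_FAMILY,
    P_FAMILY,
)
from .priors import PriorConfig

__all__ = [
    "ProposalTable",
    "Sampler",
    "mh_update_scalar",
    "gibbs_update_variances",
    "adapt_proposals",
    "run_pilot",
    "initial_state",
    "state_from_pilot",
]

TARGET_RATE = 0.44
SD_CLAMP = (1e-6, 10.0)

#: component groups a sweep may update; used by ``update_mask``
COMPONENTS = (
    "alpha",
    "beta",
    "gamma",
    "nu",
    "phi",
    "p",
    "mu0",
    "eps",
    "delta",
    "variances",
)


@dataclass
class ProposalTable:
    """Random-walk proposal sds, acceptance counters, and the pilot-run
    statistics used as birth proposals for interaction terms."""

    sd: dict
    accept: dict = field(default_factory=dict)
    attempt: dict = field(default_factory=dict)
    nu_birth_mean: np.ndarray | None = None
    nu_birth_sd: np.ndarray | None = None
    # posterior means from the pilot run (per-species for shared families);
    # used to start the main chain near the saturated-model mode
    pilot_state: dict | None = None

    def __post_init__(self):
        for key, val in self.sd.items():
            if np.any(np.asarray(val) <= 0):
                raise ValueError(f"proposal sd for {key} must be positive")
            if key not in self.accept:
                self.accept[key] = np.zeros_like(np.asarray(val, dtype=float))
                self.attempt[key] = np.zeros_like(np.asarray(val, dtype=float))

    @classmethod
    def default(cls, data: PanelData) -> "ProposalTable":
        n_s, n_i = data.n_species, data.n_sites
        sd = {"alpha": np.full(n_s, 0.01)}
        for j in range(data.d_x):
            sd[beta_family(j)] = np.array(0.01)
        for j in range(data.d_v):
            sd[gamma_family(j)] = np.array(0.01)
        sd[PHI_FAMILY] = np.array(0.02)
        sd[P_FAMILY] = np.array(0.02)
        sd["nu"] = np.full((n_s, n_s), 0.005)
        sd["eps"] = np.full(n_i, 0.05)
        sd["delta"] = np.full((n_s, n_i), 0.05)
        sd["mu0"] = np.full((n_s, n_i), 0.5)
        return cls(sd={k: np.asarray(v, dtype=float) for k, v in sd.items()})

    def has_birth_stats(self) -> bool:
        return self.nu_birth_mean is not None and self.nu_birth_sd is not None

    def to_dict(self) -> dict:
        out = {"sd": {k: np.asarray(v).tolist() for k, v in self.sd.items()}}
        if self.has_birth_stats():
            out["nu_birth_mean"] = self.nu_birth_mean.tolist()
            out["nu_birth_sd"] = self.nu_birth_sd.tolist()
        if self.pilot_state is not None:
            out["pilot_state"] = {
                k: (
                    {kk: np.asarray(vv).tolist() for kk, vv in v.items()}
                    if isinstance(v, dict)
                    else np.asarray(v).tolist()
                )
                for k, v in self.pilot_state.items()
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ProposalTable":
        tab = cls(sd={k: np.asarray(v, dtype=float) for k, v in d["sd"].items()})
        if "nu_birth_mean" in d:
            tab.nu_birth_mean = np.asarray(d["nu_birth_mean"], dtype=float)
            tab.nu_birth_sd = np.asarray(d["nu_birth_sd"], dtype=float)
        if "pilot_state" in d:
            tab.pilot_state = {
                k: (
                    {kk: np.asarray(vv, dtype=float) for kk, vv in v.items()}
                    if isinstance(v, dict)
                    else np.asarray(v, dtype=float)
                )
                for k, v in d["pilot_state"].items()
            }
        return tab


def adapt_proposals(
    proposals: ProposalTable, kappa: float = 1.0, reset: bool = True
) -> ProposalTable:
    """Scale each proposal sd by exp(kappa * (rate - 0.44)) in place.

    Parameters with no attempts in the window are left untouched.  Rates
    are computed from the table's own counters, which are reset afterwards
    (one adaptation window).
    """
    for key, sd in proposals.sd.items():
        att = proposals.attempt[key]
        acc = proposals.accept[key]
        rate = np.divide(acc, att, out=np.full_like(att, TARGET_RATE), where=att > 0)
        new = np.asarray(sd * np.exp(kappa * (rate - TARGET_RATE)))
        sd[...] = np.clip(new, SD_CLAMP[0], SD_CLAMP[1])
        if reset:
            att[...] = 0.0
            acc[...] = 0.0
    return proposals


def _invgamma_draw(rng: np.random.Generator, a: float, b: float) -> float:
    return float(b / rng.gamma(shape=a))


def gibbs_update_variances(
    state: ModelState,
    sharing: SharingStructure,
    data: PanelData,
    priors: PriorConfig,
    rng: np.random.Generator,
) -> ModelState:
    """Conjugate full-conditional draws for sigma2_eps and each sigma2_s.

    With the InvGamma(a, b) prior, sigma2_eps | eps ~ InvGamma(a + n/2,
    b + sum(eps^2)/2) and sigma2_s | delta ~ InvGamma(a + n/2,
    b + sum((delta - alpha - x'beta)^2)/2); the update is exact so the
    stationary distribution is unchanged relative to MH.
    """
    n = data.n_sites
    a, b = priors.invgamma_a, priors.invgamma_b
    state.sigma2_eps = _invgamma_draw(
        rng, a + 0.5 * n, b + 0.5 * float(np.square(state.eps).sum())
    )
    exp_par = state.expanded(sharing, data)
    mean = state.alpha[:, None] + exp_par.beta_sp @ data.x.T
    resid2 = np.square(state.delta - mean).sum(axis=1)
    for s in range(data.n_species):
        state.sigma2_s[s] = _invgamma_draw(rng, a + 0.5 * n, b + 0.5 * resid2[s])
    return state


def initial_state(
    data: PanelData,
    sharing: SharingStructure,
    priors: PriorConfig,
    rng: np.random.Generator | None = None,
) -> ModelState:
    """Deterministic, data-driven starting point for the samplers.

    Initial means come from the first observed year; the asynchronous
    effects start at the site's crude mean log growth rate (corrected for
    the small initial density-dependence value), which puts the hierarchy
    near its mode and shortens burn-in considerably.
    """
    n_s, n_i = data.n_species, data.n_sites
    off = data.offsets
    mu0 = np.empty((n_s, n_i))
    growth = np.zeros((n_s, n_i))
    ybar = np.zeros((n_s, n_i))
    for i in range(n_i):
        block = data.y[:, off[i] : off[i + 1]]
        mu0[:, i] = np.clip(block[:, 0], 0.5, priors.mu0_bounds[1] * 0.75)
        ybar[:, i] = block.mean(axis=1)
        if block.shape[1] > 1:
            lg = np.log(block + 0.5)
            growth[:, i] = (lg[:, -1] - lg[:, 0]) / (block.shape[1] - 1)
    values = {}
    for key in data.shareable_families():
        nb = sharing.partitions[key].n_blocks
        kind = family_kind(key)
        if kind == "phi":
            values[key] = np.full(nb, 0.3)
        elif kind == "p":
            values[key] = np.full(nb, 1.5)
        elif key in priors.grid:
            values[key] = np.full(nb, float(priors.grid[key][0]))
        else:
            values[key] = np.zeros(nb)
    nu = {}
    dd0 = -0.005
    for l, s in np.argwhere(sharing.nu_included):
        nu[(int(l), int(s))] = dd0 if l == s else 0.0
    delta = growth.copy()
    for s in range(n_s):
        if (s, s) in nu:
            delta[s] -= dd0 * ybar[s]
    alpha = delta.mean(axis=1)
    sigma2_s = np.maximum(delta.var(axis=1), 1e-4)
    return ModelState(
        alpha=alpha,
        values=values,
        nu=nu,
        eps=np.zeros(n_i),
        delta=delta,
        mu0=mu0,
        sigma2_eps=1e-3,
        sigma2_s=sigma2_s,
    )


def state_from_pilot(
    data: PanelData,
    sharing: SharingStructure,
    priors: PriorConfig,
    pilot_state: dict,
    nu_mean: np.ndarray | None = None,
) -> ModelState:
    """Build a starting state from pilot-run posterior means.

    Shared-family block values average the pilot's per-species means over
    each block; interaction terms included in ``sharing`` start at the
    pilot mean (density dependence clipped to the negative support).
    """
    n_s = data.n_species
    ps = pilot_state
    values = {}
    for key in data.shareable_families():
        part = sharing.partitions[key]
        per_sp = np.asarray(ps["values"][key], dtype=float)
        values[key] = np.array([per_sp[list(b)].mean() for b in part.blocks])
    lo, hi = priors.p_bounds
    values[P_FAMILY] = np.clip(values[P_FAMILY], lo + 1e-6, hi - 1e-6)
    lo, hi = priors.phi_bounds
    values[PHI_FAMILY] = np.clip(values[PHI_FAMILY], lo + 1e-6, hi - 1e-6)
    nu = {}
    mean_mat = nu_mean
    for l, s in np.argwhere(sharing.nu_included):
        l, s = int(l), int(s)
        val = float(mean_mat[l, s]) if mean_mat is not None else 0.0
        if l == s:
            val = min(val, -1e-6)
        nu[(l, s)] = val
    lo, hi = priors.mu0_bounds
    return ModelState(
        alpha=np.asarray(ps["alpha"], dtype=float).copy(),
        values=values,
        nu=nu,
        eps=np.asarray(ps["eps"], dtype=float).copy(),
        delta=np.asarray(ps["delta"], dtype=float).copy(),
        mu0=np.clip(np.asarray(ps["mu0"], dtype=float), lo + 1e-6, hi - 1e-6),
        sigma2_eps=float(ps["sigma2_eps"]),
        sigma2_s=np.asarray(ps["sigma2_s"], dtype=float).copy(),
    )


class Sampler:
    """Fixed-sharing MCMC engine with a cached per-(species, site)
    log-likelihood matrix.

    ``likelihood_on=False`` replaces the likelihood with a constant, which
    turns the sampler into a prior sampler (the standard validity check for
    the trans-model moves layered on top).  ``update_mask`` restricts the
    sweep to a subset of the component groups in ``COMPONENTS``.
    """

    def __init__(
        self,
        data: PanelData,
        priors: PriorConfig,
        sharing: SharingStructure,
        state: ModelState,
        proposals: ProposalTable,
        rng: np.random.Generator,
        likelihood_on: bool = True,
        update_mask: set[str] | None = None,
    ):
        sharing.validate(data)
        state.check_consistent(sharing)
        unknown = (update_mask or set()) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown update components: {unknown}")
        self.data = data
        self.priors = priors
        self.sharing = sharing
        self.state = state
        self.proposals = proposals
        self.rng = rng
        self.likelihood_on = likelihood_on
        self.update = set(update_mask) if update_mask is not None else set(COMPONENTS)
        self._scratch = np.zeros((data.n_species, data.n_sites))
        self.L = self._ll(state).copy()

    # -- likelihood plumbing -------------------------------------------------

    def _ll(self, state: ModelState, mask: np.ndarray | None = None) -> np.ndarray:
        """Masked log-likelihood rows, written into a reused scratch buffer
        (valid until the next call)."""
        if not self.likelihood_on:
            self._scratch[:] = 0.0
            return self._scratch
        return loglik_matrix(
            state, self.sharing, self.data, species_mask=mask, out=self._scratch
        )

    def total_loglik(self) -> float:
        return float(self.L.sum())

    def refresh_likelihood(self) -> None:
        self.L = self._ll(self.state).copy()

    # -- scalar MH -----------------------------------------------------------

    def _count(self, key, idx, accepted: bool) -> None:
        self.proposals.attempt[key][idx] += 1.0
        if accepted:
            self.proposals.accept[key][idx] += 1.0

    def _accept(self, log_ratio: float) -> bool:
        # log(u) < 0 <= log_ratio covers the always-accept case
        return math.log(self.rng.uniform()) < log_ratio

    def mh_update_scalar(self, target: tuple) -> bool:
        """One symmetric random-walk update of the addressed scalar.

        Addresses: ("alpha", s), (family_key, block), ("nu", l, s),
        ("eps", i), ("delta", s, i), ("mu0", s, i).  Returns the accept
        flag; the state and likelihood cache are updated in place.
        """
        kind = target[0]
        if kind == "alpha":
            return self._update_alpha(target[1])
        if kind == "nu":
            return self._update_nu(target[1], target[2])
        if kind in ("eps", "delta", "mu0"):
            return self._update_site_scalar(target)
        if kind in self.sharing.partitions:
            return self._update_family_block(kind, target[1])
        raise ValueError(f"unknown target {target}")

    def _update_alpha(self, s: int) -> bool:
        st, pri = self.state, self.priors
        cur = st.alpha[s]
        prop = cur + self.rng.normal() * self.proposals.sd["alpha"][s]
        xb = self.data.x @ self._beta_row(s)
        m = cur + xb
        m_new = prop + xb
        s2 = st.sigma2_s[s]
        d = st.delta[s]
        dlp = float(
            (np.square(d - m) - np.square(d - m_new)).sum() / (2.0 * s2)
        ) + (cur * cur - prop * prop) / (2.0 * pri.coef_variance)
        ok = self._accept(dlp)
        if ok:
            st.alpha[s] = prop
        self._count("alpha", s, ok)
        return ok

    def _update_family_block(self, key: str, b: int) -> bool:
        st, pri = self.state, self.priors
        part = self.sharing.partitions[key]
        kind = family_kind(key)
        cur = st.values[key][b]
        grid = pri.grid.get(key)
        if grid is not None:
            prop = float(grid[self.rng.integers(len(grid))])  # symmetric
            dprior = 0.0
        else:
            prop = cur + self.rng.normal() * float(self.proposals.sd[key])
            if kind in ("beta", "gamma"):
                dprior = (cur * cur - prop * prop) / (2.0 * pri.coef_variance)
            elif kind == "phi":
                lo, hi = pri.phi_bounds
                if not lo < prop < hi:
                    self._count(key, (), False)
                    return False
                dprior = 0.0
            elif kind == "p":
                lo, hi = pri.p_bounds
                if not lo < prop < hi:
                    self._count(key, (), False)
                    return False
                dprior = 0.0
            else:  # pragma: no cover
                raise ValueError(key)
        members = list(part.blocks[b])
        if kind == "beta":
            # likelihood-free under centering: only the delta prior moves
            j = int(key.split("_", 1)[1])
            dlp = dprior
            for s in members:
                beta_s = self._beta_row(s)
                m = st.alpha[s] + self.data.x @ beta_s
                m_new = m + self.data.x[:, j] * (prop - beta_s[j])
                d = st.delta[s]
                dlp += float(
                    (np.square(d - m) - np.square(d - m_new)).sum()
                    / (2.0 * st.sigma2_s[s])
                )
            ok = self._accept(dlp)
            if ok:
                st.values[key][b] = prop
            self._count(key, (), ok)
            return ok
        # gamma / phi / p change the likelihood of the block's species
        mask = np.zeros(self.data.n_species, dtype=bool)
        mask[members] = True
        st.values[key][b] = prop
        L2 = self._ll(st, mask)
        st.values[key][b] = cur
        dll = float((L2[mask] - self.L[mask]).sum())
        ok = self._accept(dll + dprior)
        if ok:
            st.values[key][b] = prop
            self.L[mask] = L2[mask]
        self._count(key, (), ok)
        return ok

    def _beta_row(self, s: int) -> np.ndarray:
        """Per-species site-covariate coefficient vector."""
        st = self.state
        out = np.empty(self.data.d_x)
        for j in range(self.data.d_x):
            key = beta_family(j)
            part = self.sharing.partitions[key]
            out[j] = st.values[key][part.block_index()[s]]
        return out

    def _update_nu(self, l: int, s: int) -> bool:
        st, pri = self.state, self.priors
        if (l, s) not in st.nu:
            raise ValueError(f"nu[{l},{s}] is not in the current model")
        cur = st.nu[(l, s)]
        prop = cur + self.rng.normal() * self.proposals.sd["nu"][l, s]
        if l == s:
            if prop > 0:
                self._count("nu", (l, s), False)
                return False
            dprior = (cur * cur - prop * prop) / (2.0 * pri.dd_variance)
        else:
            dprior = (cur * cur - prop * prop) / (2.0 * pri.coef_variance)
        mask = np.zeros(self.data.n_species, dtype=bool)
        mask[s] = True
        st.nu[(l, s)] = prop
        L2 = self._ll(st, mask)
        st.nu[(l, s)] = cur
        dll = float((L2[s] - self.L[s]).sum())
        ok = self._accept(dll + dprior)
        if ok:
            st.nu[(l, s)] = prop
            self.L[s] = L2[s]
        self._count("nu", (l, s), ok)
        return ok

    def _update_site_scalar(self, target: tuple) -> bool:
        """Scalar-address path for eps/delta/mu0 (the sweep uses the batched
        equivalents below)."""
        st, pri = self.state, self.priors
        kind = target[0]
        cand = st.copy()
        if kind == "eps":
            i = target[1]
            cur = st.eps[i]
            prop = cur + self.rng.normal() * self.proposals.sd["eps"][i]
            cand.eps[i] = prop
            dprior = (cur * cur - prop * prop) / (2.0 * st.sigma2_eps)
            mask = np.ones(self.data.n_species, dtype=bool)
            idx = i
        elif kind == "delta":
            s, i = target[1], target[2]
            cur = st.delta[s, i]
            prop = cur + self.rng.normal() * self.proposals.sd["delta"][s, i]
            cand.delta[s, i] = prop
            exp_par = st.expanded(self.sharing, self.data)
            m = st.alpha[s] + float(self.data.x[i] @ exp_par.beta_sp[s])
            dprior = ((cur - m) ** 2 - (prop - m) ** 2) / (2.0 * st.sigma2_s[s])
            mask = np.zeros(self.data.n_species, dtype=bool)
            mask[s] = True
            idx = (s, i)
        else:  # mu0
            s, i = target[1], target[2]
            cur = st.mu0[s, i]
            prop = cur + self.rng.normal() * self.proposals.sd["mu0"][s, i]
            lo, hi = pri.mu0_bounds
            if not lo < prop < hi:
                self._count("mu0", (s, i), False)
                return False
            cand.mu0[s, i] = prop
            dprior = 0.0
            mask = np.zeros(self.data.n_species, dtype=bool)
            mask[s] = True
            mask |= st.nu_matrix()[s] != 0.0  # initial-year lag feeds others
            idx = (s, i)
        i_site = target[-1]
        L2 = self._ll(cand, mask)
        dll = float((L2[mask, i_site] - self.L[mask, i_site]).sum())
        ok = self._accept(dll + dprior)
        if ok:
            if kind == "eps":
                st.eps[i_site] = prop
            elif kind == "delta":
                st.delta[target[1], i_site] = prop
            else:
                st.mu0[target[1], i_site] = prop
            self.L[mask, i_site] = L2[mask, i_site]
        self._count(kind, idx, ok)
        return ok

    # -- batched independent-block updates ------------------------------------
    #
    # Blocks of one shareable family cover disjoint species, and the
    # likelihood factorizes over species rows given everything else, so all
    # blocks can be proposed in one kernel evaluation and accepted
    # independently -- distributionally identical to sequential
    # single-block updates.  The same argument batches interaction updates
    # that target distinct species.

    def update_family_batch(self, key: str) -> None:
        st, pri = self.state, self.priors
        part = self.sharing.partitions[key]
        kind = family_kind(key)
        if kind == "beta":
            for b in range(part.n_blocks):
                # cheap (likelihood-free); reuse the scalar machinery per block
                self.mh_update_scalar((key, b))
            return
        nb = part.n_blocks
        cur = st.values[key].copy()
        grid = pri.grid.get(key)
        if grid is not None:
            prop = grid[self.rng.integers(len(grid), size=nb)].astype(float)
            dprior = np.zeros(nb)
            ok_support = np.ones(nb, dtype=bool)
        else:
            prop = cur + self.rng.normal(size=nb) * float(self.proposals.sd[key])
            if kind in ("beta", "gamma"):
                dprior = (cur * cur - prop * prop) / (2.0 * pri.coef_variance)
                ok_support = np.ones(nb, dtype=bool)
            else:
                lo, hi = pri.phi_bounds if kind == "phi" else pri.p_bounds
                ok_support = (prop > lo) & (prop < hi)
                dprior = np.zeros(nb)
        bidx = part.block_index()
        trial = np.where(ok_support, prop, cur)
        st.values[key] = trial
        L2 = self._ll(st)
        st.values[key] = cur
        row_delta = (L2 - self.L).sum(axis=1)
        dll = np.zeros(nb)
        np.add.at(dll, bidx, row_delta)
        dpost = np.where(ok_support, dll + dprior, -np.inf)
        acc = self._batch_accept(dpost)
        if np.any(acc):
            newvals = np.where(acc, trial, cur)
            st.values[key] = newvals
            row_acc = acc[bidx]
            self.L[row_acc] = L2[row_acc]
        self.proposals.attempt[key][...] += 1.0
        self.proposals.accept[key][...] += float(acc.mean())

    def update_nu_batch(self) -> None:
        """Update every included interaction, batching pairs that target
        distinct species into shared kernel evaluations."""
        st, pri = self.state, self.priors
        n_s = self.data.n_species
        by_target: dict[int, list[tuple[int, int]]] = {}
        for (l, s) in sorted(st.nu):
            by_target.setdefault(s, []).append((l, s))
        n_rounds = max((len(v) for v in by_target.values()), default=0)
        for r in range(n_rounds):
            pairs = [v[r] for v in by_target.values() if len(v) > r]
            cur = {pr: st.nu[pr] for pr in pairs}
            prop = {}
            dprior = {}
            ok = {}
            for (l, s) in pairs:
                pv = cur[(l, s)] + self.rng.normal() * self.proposals.sd["nu"][l, s]
                prop[(l, s)] = pv
                if l == s:
                    ok[(l, s)] = pv <= 0
                    dprior[(l, s)] = (
                        cur[(l, s)] ** 2 - pv * pv
                    ) / (2.0 * pri.dd_variance)
                else:
                    ok[(l, s)] = True
                    dprior[(l, s)] = (
                        cur[(l, s)] ** 2 - pv * pv
                    ) / (2.0 * pri.coef_variance)
            mask = np.zeros(n_s, dtype=bool)
            for (l, s) in pairs:
                if ok[(l, s)]:
                    st.nu[(l, s)] = prop[(l, s)]
                    mask[s] = True
            if not mask.any():
                for (l, s) in pairs:
                    self._count("nu", (l, s), False)
                continue
            L2 = self._ll(st, mask)
            for (l, s) in pairs:
                st.nu[(l, s)] = cur[(l, s)]
            for (l, s) in pairs:
                if not ok[(l, s)]:
                    self._count("nu", (l, s), False)
                    continue
                dll = float((L2[s] - self.L[s]).sum())
                accepted = self._accept(dll + dprior[(l, s)])
                if accepted:
                    st.nu[(l, s)] = prop[(l, s)]
                    self.L[s] = L2[s]
                self._count("nu", (l, s), accepted)

    def update_delta_all(self) -> None:
        st = self.state
        cur = st.delta.copy()
        prop = cur + self.rng.normal(size=cur.shape) * self.proposals.sd["delta"]
        st.delta = prop
        L2 = self._ll(st)
        st.delta = cur
        mean = st.alpha[:, None] + np.stack(
            [self.data.x @ self._beta_row(s) for s in range(self.data.n_species)]
        )
        s2 = st.sigma2_s[:, None]
        dprior = (np.square(cur - mean) - np.square(prop - mean)) / (2.0 * s2)
        dpost = L2 - self.L + dprior
        acc = self._batch_accept(dpost)
        st.delta[acc] = prop[acc]
        self.L[acc] = L2[acc]
        self.proposals.attempt["delta"] += 1.0
        self.proposals.accept["delta"] += acc

    def update_mu0_all(self) -> None:
        """Elementwise-independent mu0 update; only valid with no
        interspecific interactions in the model (the sweep falls back to
        per-species batches otherwise)."""
        st, pri = self.state, self.priors
        cur = st.mu0.copy()
        prop = cur + self.rng.normal(size=cur.shape) * self.proposals.sd["mu0"]
        lo, hi = pri.mu0_bounds
        in_support = (prop > lo) & (prop < hi)
        st.mu0 = np.where(in_support, prop, cur)
        L2 = self._ll(st)
        st.mu0 = cur
        dpost = np.where(in_support, L2 - self.L, -np.inf)
        acc = self._batch_accept(dpost) & in_support
        st.mu0[acc] = prop[acc]
        self.L[acc] = L2[acc]
        self.proposals.attempt["mu0"] += 1.0
        self.proposals.accept["mu0"] += acc

    # -- batched site-level updates -------------------------------------------

    def _batch_accept(self, dpost: np.ndarray) -> np.ndarray:
        return np.log(self.rng.uniform(size=dpost.shape)) < dpost

    def update_eps_batch(self) -> None:
        st = self.state
        sd = self.proposals.sd["eps"]
        cur = st.eps
        prop = cur + self.rng.normal(size=cur.shape) * sd
        st.eps = prop
        L2 = self._ll(st)
        st.eps = cur
        dprior = (np.square(cur) - np.square(prop)) / (2.0 * st.sigma2_eps)
        dpost = (L2 - self.L).sum(axis=0) + dprior
        acc = self._batch_accept(dpost)
        st.eps[acc] = prop[acc]
        self.L[:, acc] = L2[:, acc]
        self.proposals.attempt["eps"] += 1.0
        self.proposals.accept["eps"] += acc

    def update_delta_batch(self, s: int) -> None:
        st = self.state
        sd = self.proposals.sd["delta"][s]
        cur = st.delta[s].copy()
        prop = cur + self.rng.normal(size=cur.shape) * sd
        mask = np.zeros(self.data.n_species, dtype=bool)
        mask[s] = True
        st.delta[s] = prop
        L2 = self._ll(st, mask)
        st.delta[s] = cur
        m = st.alpha[s] + self.data.x @ self._beta_row(s)
        dprior = (np.square(cur - m) - np.square(prop - m)) / (2.0 * st.sigma2_s[s])
        dpost = L2[s] - self.L[s] + dprior
        acc = self._batch_accept(dpost)
        st.delta[s, acc] = prop[acc]
        self.L[s, acc] = L2[s, acc]
        self.proposals.attempt["delta"][s] += 1.0
        self.proposals.accept["delta"][s] += acc

    def update_mu0_batch(self, s: int) -> None:
        st, pri = self.state, self.priors
        sd = self.proposals.sd["mu0"][s]
        cur = st.mu0[s].copy()
        prop = cur + self.rng.normal(size=cur.shape) * sd
        lo, hi = pri.mu0_bounds
        in_support = (prop > lo) & (prop < hi)
        mask = np.zeros(self.data.n_species, dtype=bool)
        mask[s] = True
        mask |= st.nu_matrix()[s] != 0.0
        st.mu0[s] = np.where(in_support, prop, cur)
        L2 = self._ll(st, mask)
        st.mu0[s] = cur
        dpost = np.where(
            in_support, (L2[mask] - self.L[mask]).sum(axis=0), -np.inf
        )
        acc = self._batch_accept(dpost) & in_support
        st.mu0[s, acc] = prop[acc]
        self.L[np.ix_(mask, acc)] = L2[np.ix_(mask, acc)]
        self.proposals.attempt["mu0"][s] += 1.0
        self.proposals.accept["mu0"][s] += acc

    # -- full sweep ------------------------------------------------------------

    def sweep(self) -> None:
        """One fixed-sharing iteration in the documented update order:
        alpha, beta blocks, gamma blocks, nu, phi and p blocks, mu0, eps,
        delta, then the Gibbs variance draws."""
        data, sharing = self.data, self.sharing
        if "alpha" in self.update:
            for s in range(data.n_species):
                self.mh_update_scalar(("alpha", s))
        if "beta" in self.update:
            for j in range(data.d_x):
                self.update_family_batch(beta_family(j))
        if "gamma" in self.update:
            for j in range(data.d_v):
                self.update_family_batch(gamma_family(j))
        if "nu" in self.update:
            self.update_nu_batch()
        if "phi" in self.update:
            self.update_family_batch(PHI_FAMILY)
        if "p" in self.update:
            self.update_family_batch(P_FAMILY)
        if "mu0" in self.update:
            if any(l != s for (l, s) in self.state.nu):
                for s in range(data.n_species):
                    self.update_mu0_batch(s)
            else:
                self.update_mu0_all()
        if "eps" in self.update:
            self.update_eps_batch()
        if "delta" in self.update:
            self.update_delta_all()
        if "variances" in self.update:
            gibbs_update_variances(self.state, sharing, data, self.priors, self.rng)


def mh_update_scalar(
    target: tuple,
    state: ModelState,
    sharing: SharingStructure,
    data: PanelData,
    priors: PriorConfig,
    proposals: ProposalTable,
    rng: np.random.Generator,
    likelihood_on: bool = True,
) -> tuple[ModelState, bool]:
    """Standalone single-scalar MH update (convenience wrapper around
    :class:`Sampler`); returns the updated state and the accept flag."""
    sampler = Sampler(
        data, priors, sharing, state, proposals, rng, likelihood_on=likelihood_on
    )
    ok = sampler.mh_update_scalar(target)
    return sampler.state, ok


def run_pilot(
    data: PanelData,
    priors: PriorConfig,
    iterations: int = 50_000,
    burn_in: int = 30_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    proposals: ProposalTable | None = None,
    adapt_window: int = 100,
) -> ProposalTable:
    """Pilot run of the saturated model (finest partitions, all interaction
    terms included) without trans-model moves.

    The post-burn-in posterior mean and sd of every nu (including density
    dependence) are recorded in the returned :class:`ProposalTable` as the
    birth-proposal statistics for the reversible-jump inclusion moves; the
    adapted random-walk sds are returned as well.
    """
    if burn_in >= iterations:
        raise ValueError("pilot needs post-burn-in iterations (burn_in < iterations)")
    if rng is None:
        rng = np.random.default_rng(seed)
    sharing = SharingStructure.saturated(data, include_nu="all")
    state = initial_state(data, sharing, priors, rng)
    if proposals is None:
        proposals = ProposalTable.default(data)
    sampler = Sampler(data, priors, sharing, state, proposals, rng)
    n_s = data.n_species
    nu_sum = np.zeros((n_s, n_s))
    nu_sq = np.zeros((n_s, n_s))
    acc = {
        "alpha": np.zeros(n_s),
        "eps": np.zeros(data.n_sites),
        "delta": np.zeros((n_s, data.n_sites)),
        "mu0": np.zeros((n_s, data.n_sites)),
        "sigma2_eps": 0.0,
        "sigma2_s": np.zeros(n_s),
        "values": {k: np.zeros(n_s) for k in data.shareable_families()},
    }
    kept = 0
    for it in range(iterations):
        sampler.sweep()
        if it < burn_in:
            if (it + 1) % adapt_window == 0:
                adapt_proposals(proposals)
        else:
            st = sampler.state
            mat = st.nu_matrix()
            nu_sum += mat
            nu_sq += mat * mat
            acc["alpha"] += st.alpha
            acc["eps"] += st.eps
            acc["delta"] += st.delta
            acc["mu0"] += st.mu0
            acc["sigma2_eps"] += st.sigma2_eps
            acc["sigma2_s"] += st.sigma2_s
            exp_par = st.expanded(sharing, data)
            for j in range(data.d_x):
                acc["values"][f"beta_{j}"] += exp_par.beta_sp[:, j]
            for j in range(data.d_v):
                acc["values"][f"gamma_{j}"] += exp_par.gamma_sp[:, j]
            acc["values"][PHI_FAMILY] += exp_par.phi_sp
            acc["values"][P_FAMILY] += exp_par.p_sp
            kept += 1
    mean = nu_sum / kept
    var = np.maximum(nu_sq / kept - mean * mean, 0.0)
    proposals.nu_birth_mean = mean
    proposals.nu_birth_sd = np.maximum(np.sqrt(var), 1e-4)
    for key, val in acc.items():
        if key == "values":
            acc[key] = {k: v / kept for k, v in val.items()}
        else:
            acc[key] = val / kept
    proposals.pilot_state = acc
    return proposals
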