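"""Trans-model moves and the top-level sampler driver.

Model uncertainty has two parts:

* which species share a value of each shareable family (a set partition
  per family), explored by split/merge reversible-jump moves; and
* which interaction terms nu[l, s] are in the model at all, explored by
  birth/death toggles whose birth proposals come from a pilot run.

The continuous split uses the dimension-matching map (theta, u) ->
(theta + u, theta - u) with u ~ N(0, rj_proposal_sd^2) and |Jacobian| = 2;
the matching merge takes the midpoint and has |Jacobian| = 1/2.  Families
with a finite grid prior use a discrete scheme instead (the new block value
is drawn uniformly from the grid; merging keeps the value of the sub-block
containing the smallest species index), which needs no Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from .model import (
    PanelData,
    SharingStructure,
    ModelState,
    Partition,
    log_joint,
    family_kind,
    PHI_FAMILY,
    P_FAMILY,
)
from .mcmc import (
    ProposalTable,
    Sampler,
    adapt_proposals,
    initial_state,
)
from .priors import PriorConfig

__all__ = [
    "RJConfig",
    "MoveProposal",
    "ChainOutput",
    "enumerate_partitions",
    "propose_split",
    "propose_merge",
    "rj_accept",
    "toggle_nu",
    "run_sampler",
]

MAX_ENUM_SPECIES = 8


@dataclass
class RJConfig:
    """Run configuration for the reversible-jump sampler."""

    iterations: int = 100_000
    burn_in: int = 50_000
    thin: int = 1
    seed: int | None = None
    rj_proposal_sd: float = 1e-3
    nu_prior_inclusion: float = 0.5
    model_prior: str = "uniform"  # uniform over partitions; "nblocks" alternative
    enable_rj: bool = True
    enable_nu_moves: bool = True
    rj_families: list[str] | None = None  # default: every shareable family
    nu_pairs: list[tuple[int, int]] | None = None  # default: all ordered pairs
    likelihood_on: bool = True
    update_mask: set[str] | None = None
    adapt_window: int = 100
    store_latent: bool = True
    # trans-model move attempts per iteration (each picks a family / pair
    # uniformly at random); more attempts speed model-space mixing on short
    # desk-scale chains at negligible cost
    rj_moves_per_iter: int = 1
    nu_toggles_per_iter: int = 1

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.rj_proposal_sd <= 0:
            raise ValueError("rj_proposal_sd must be positive")
        if not 0.0 < self.nu_prior_inclusion < 1.0:
            raise ValueError("nu inclusion prior must be in (0, 1)")
        if self.model_prior not in ("uniform", "nblocks"):
            raise ValueError(self.model_prior)
        if self.rj_moves_per_iter < 0 or self.nu_toggles_per_iter < 0:
            raise ValueError("move counts must be non-negative")


def enumerate_partitions(n_species: int) -> list[Partition]:
    """All set partitions of {0..n_species-1} in canonical order
    (Bell(n_species) of them); refuses n_species > 8."""
    if n_species < 1:
        raise ValueError("need at least one species")
    if n_species > MAX_ENUM_SPECIES:
        raise ValueError(
            f"refusing to enumerate partitions of {n_species} > "
            f"{MAX_ENUM_SPECIES} species"
        )

    def rec(s: int, blocks: list[list[int]]):
        if s == n_species:
            yield Partition([list(b) for b in blocks])
            return
        for b in blocks:
            b.append(s)
            yield from rec(s + 1, blocks)
            b.pop()
        blocks.append([s])
        yield from rec(s + 1, blocks)
        blocks.pop()

    parts = list(rec(0, []))
    return sorted(parts, key=lambda p: p.blocks)


class MoveProposal(NamedTuple):
    """Outcome of a split or merge proposal."""

    kind: str  # "split" or "merge"
    partition: Partition
    values: np.ndarray
    log_proposal_ratio: float  # log q(reverse) - log q(forward)
    log_jacobian: float
    changed_species: tuple[int, ...]  # species whose value changed
    u: float  # dimension-matching innovation (0 for grid moves)


def _split_available(partition: Partition) -> bool:
    return any(len(b) >= 2 for b in partition.blocks)


def _merge_available(partition: Partition) -> bool:
    return partition.n_blocks >= 2


def _p_move(partition: Partition, kind: str) -> float:
    """Probability of attempting a split (or merge) at this partition; the
    unavailable move hands its probability to the other one."""
    s_av, m_av = _split_available(partition), _merge_available(partition)
    if kind == "split":
        return 0.5 if (s_av and m_av) else (1.0 if s_av else 0.0)
    return 0.5 if (s_av and m_av) else (1.0 if m_av else 0.0)


def _bipartitions(block: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """The 2^(m-1) - 1 unordered bipartitions of a block, each listed once
    with the part containing the block's smallest member first."""
    m = len(block)
    out = []
    # block[0] always sits in part A; the remaining m-1 members choose a
    # side, excluding the all-A assignment (part B must be non-empty)
    for mask in range(2 ** (m - 1) - 1):
        a = [block[0]]
        b = []
        for k in range(1, m):
            (a if (mask >> (k - 1)) & 1 else b).append(block[k])
        out.append((tuple(a), tuple(b)))
    return out


def _rebuild(pairs: list[tuple[tuple[int, ...], float]]) -> tuple[Partition, np.ndarray]:
    pairs = sorted(pairs, key=lambda kv: kv[0][0])
    part = Partition([list(b) for b, _ in pairs])
    return part, np.array([v for _, v in pairs], dtype=float)


def propose_split(
    partition: Partition,
    values: np.ndarray,
    rng: np.random.Generator,
    cfg: RJConfig,
    grid: np.ndarray | None = None,
) -> MoveProposal | None:
    """Propose splitting one shared block into two.

    Chooses a block of size >= 2 uniformly, then one of its unordered
    bipartitions uniformly.  Continuous families perturb the parent value
    to theta +/- u (the '+' goes to the part holding the block's smallest
    member); grid families keep the parent value for that part and draw the
    other uniformly from the grid.  Returns None when nothing can split.
    """
    if not _split_available(partition):
        return None
    values = np.asarray(values, dtype=float)
    splittable = [b for b, blk in enumerate(partition.blocks) if len(blk) >= 2]
    b = splittable[rng.integers(len(splittable))]
    block = partition.blocks[b]
    bips = _bipartitions(block)
    part_a, part_b = bips[rng.integers(len(bips))]
    theta = values[b]
    if grid is None:
        u = rng.normal() * cfg.rj_proposal_sd
        val_a, val_b = theta + u, theta - u
        log_q_fwd = (
            math.log(_p_move(partition, "split"))
            - math.log(len(splittable))
            - math.log(len(bips))
            + norm.logpdf(u, 0.0, cfg.rj_proposal_sd)
        )
        log_jac = math.log(2.0)
    else:
        u = 0.0
        val_a = theta
        val_b = float(grid[rng.integers(len(grid))])
        log_q_fwd = (
            math.log(_p_move(partition, "split"))
            - math.log(len(splittable))
            - math.log(len(bips))
            - math.log(len(grid))
        )
        log_jac = 0.0
    pairs = [
        (blk, values[k]) for k, blk in enumerate(partition.blocks) if k != b
    ]
    pairs += [(part_a, val_a), (part_b, val_b)]
    new_part, new_vals = _rebuild(pairs)
    n_pairs = new_part.n_blocks * (new_part.n_blocks - 1) // 2
    log_q_rev = math.log(_p_move(new_part, "merge")) - math.log(n_pairs)
    return MoveProposal(
        "split", new_part, new_vals, log_q_rev - log_q_fwd, log_jac, block, u
    )


def propose_merge(
    partition: Partition,
    values: np.ndarray,
    rng: np.random.Generator,
    cfg: RJConfig,
    grid: np.ndarray | None = None,
) -> MoveProposal | None:
    """Propose merging a uniformly chosen unordered pair of blocks.

    The continuous merge takes the midpoint (implied innovation
    u = (theta_A - theta_B) / 2, A the block containing the pair's smallest
    member); the grid merge keeps A's value.  Returns None with one block.
    """
    if not _merge_available(partition):
        return None
    values = np.asarray(values, dtype=float)
    nb = partition.n_blocks
    pair_idx = rng.integers(nb * (nb - 1) // 2)
    pairs_list = [(i, j) for i in range(nb) for j in range(i + 1, nb)]
    i, j = pairs_list[pair_idx]
    blk_i, blk_j = partition.blocks[i], partition.blocks[j]
    # A = the block containing the union's smallest member (canonical order
    # guarantees that is blk_i)
    theta_a, theta_b = values[i], values[j]
    merged_block = tuple(sorted(blk_i + blk_j))
    if grid is None:
        u = 0.5 * (theta_a - theta_b)
        merged_val = 0.5 * (theta_a + theta_b)
        log_jac = -math.log(2.0)
    else:
        u = 0.0
        merged_val = theta_a
        log_jac = 0.0
    log_q_fwd = math.log(_p_move(partition, "merge")) - math.log(len(pairs_list))
    pairs = [
        (blk, values[k])
        for k, blk in enumerate(partition.blocks)
        if k not in (i, j)
    ] + [(merged_block, merged_val)]
    new_part, new_vals = _rebuild(pairs)
    splittable = sum(1 for b in new_part.blocks if len(b) >= 2)
    n_bips = 2 ** (len(merged_block) - 1) - 1
    log_q_rev = (
        math.log(_p_move(new_part, "split"))
        - math.log(splittable)
        - math.log(n_bips)
    )
    if grid is None:
        log_q_rev += norm.logpdf(u, 0.0, cfg.rj_proposal_sd)
    else:
        log_q_rev -= math.log(len(grid))
    changed = tuple(sorted(blk_i + blk_j))
    return MoveProposal(
        "merge", new_part, new_vals, log_q_rev - log_q_fwd, log_jac, changed, u
    )


def _stirling2(n: int, k: int) -> int:
    if k in (0, n):
        return int(k == n) if n > 0 or k == 0 else 0
    if k < 0 or k > n:
        return 0
    row = [1]
    for nn in range(1, n + 1):
        new = [0] * (nn + 1)
        for kk in range(1, nn + 1):
            new[kk] = (row[kk] if kk < len(row) else 0) * kk + row[kk - 1]
        row = new
    return row[k]


def log_partition_prior(partition: Partition, model_prior: str) -> float:
    """Log model-prior weight of a partition (up to a family constant).

    "uniform": every set partition is equally likely (contributes 0).
    "nblocks": uniform over the number of blocks, then uniform over
    partitions with that block count.
    """
    if model_prior == "uniform":
        return 0.0
    n, k = partition.n_species, partition.n_blocks
    return -math.log(_stirling2(n, k))


def rj_accept(
    move: MoveProposal,
    state_before: ModelState,
    state_after: ModelState,
    sharing_before: SharingStructure,
    sharing_after: SharingStructure,
    data: PanelData,
    priors: PriorConfig,
    cfg: RJConfig,
    likelihood_on: bool = True,
) -> float:
    """Acceptance probability of a split/merge move, computed from the full
    joint density (reference path; the driver uses an algebraically
    identical incremental version)."""
    if likelihood_on:
        lj_after = log_joint(state_after, sharing_after, data, priors)
        lj_before = log_joint(state_before, sharing_before, data, priors)
    else:
        from .model import log_prior

        lj_after = log_prior(state_after, sharing_after, data, priors)
        lj_before = log_prior(state_before, sharing_before, data, priors)
    if not math.isfinite(lj_after):
        return 0.0
    family = None
    for key, part in sharing_after.partitions.items():
        if sharing_before.partitions[key] != part:
            family = key
    dmodel = 0.0
    if family is not None:
        dmodel = log_partition_prior(
            sharing_after.partitions[family], cfg.model_prior
        ) - log_partition_prior(sharing_before.partitions[family], cfg.model_prior)
    log_a = (
        lj_after
        - lj_before
        + dmodel
        + move.log_proposal_ratio
        + move.log_jacobian
    )
    return min(1.0, math.exp(min(log_a, 0.0)))


# ---------------------------------------------------------------------------
# driver internals


def _family_block_log_prior(vals: np.ndarray, key: str, priors: PriorConfig) -> float:
    """Sum of per-block prior terms for one family (the only prior terms a
    split/merge changes)."""
    kind = family_kind(key)
    if kind in ("beta", "gamma"):
        grid = priors.grid.get(key)
        if grid is not None:
            ok = all(np.any(np.isclose(v, grid, atol=1e-12)) for v in vals)
            return -len(vals) * math.log(len(grid)) if ok else -math.inf
        var = priors.coef_variance
        return float(
            (-0.5 * math.log(2 * math.pi * var) - np.square(vals) / (2 * var)).sum()
        )
    lo, hi = priors.phi_bounds if kind == "phi" else priors.p_bounds
    if np.any(vals <= lo) or np.any(vals >= hi):
        return -math.inf
    return -len(vals) * math.log(hi - lo)


def _attempt_rj_move(sampler: Sampler, cfg: RJConfig, family: str) -> bool:
    """One split-or-merge attempt on ``family``, using the sampler's cached
    likelihood; mirrors :func:`rj_accept` exactly."""
    rng = sampler.rng
    data, priors, st = sampler.data, sampler.priors, sampler.state
    part = sampler.sharing.partitions[family]
    vals = st.values[family]
    grid = priors.grid.get(family)
    s_av, m_av = _split_available(part), _merge_available(part)
    if not s_av and not m_av:  # single species family; nothing to do
        return False
    do_split = s_av if not m_av else (False if not s_av else rng.uniform() < 0.5)
    move = (
        propose_split(part, vals, rng, cfg, grid)
        if do_split
        else propose_merge(part, vals, rng, cfg, grid)
    )
    if move is None:  # pragma: no cover - availability already checked
        return False
    dprior = _family_block_log_prior(move.values, family, priors) - (
        _family_block_log_prior(vals, family, priors)
    )
    if not math.isfinite(dprior):
        return False
    dmodel = log_partition_prior(move.partition, cfg.model_prior) - (
        log_partition_prior(part, cfg.model_prior)
    )
    kind = family_kind(family)
    mask = np.zeros(data.n_species, dtype=bool)
    mask[list(move.changed_species)] = True
    if kind == "beta":
        # delta-prior terms only (centering keeps beta out of the likelihood)
        j = int(family.split("_", 1)[1])
        exp_old = st.expanded(sampler.sharing, data)
        dll = 0.0
        new_sp = move.partition.expand(move.values)
        old_sp = part.expand(vals)
        for s in np.where(mask)[0]:
            beta_s = exp_old.beta_sp[s].copy()
            m_old = st.alpha[s] + data.x @ beta_s
            beta_s[j] = new_sp[s]
            m_new = st.alpha[s] + data.x @ beta_s
            d = st.delta[s]
            dll += float(
                (np.square(d - m_old) - np.square(d - m_new)).sum()
                / (2.0 * st.sigma2_s[s])
            )
            beta_s[j] = old_sp[s]
        L2 = None
    else:
        old_vals = st.values[family]
        st.values[family] = move.values
        sampler.sharing.partitions[family] = move.partition
        try:
            L2 = sampler._ll(st, mask)
        finally:
            st.values[family] = old_vals
            sampler.sharing.partitions[family] = part
        dll = float((L2[mask] - sampler.L[mask]).sum())
    log_a = dll + dprior + dmodel + move.log_proposal_ratio + move.log_jacobian
    if math.log(rng.uniform()) < log_a:
        sampler.sharing.partitions[family] = move.partition
        st.values[family] = move.values
        if L2 is not None:
            sampler.L[mask] = L2[mask]
        return True
    return False


def _truncnorm_neg_draw(rng, m: float, sd: float) -> float:
    """Draw from N(m, sd^2) truncated to (-inf, 0] by inverse CDF."""
    cap = norm.cdf(0.0, m, sd)
    u = rng.uniform() * cap
    return float(norm.ppf(max(u, 1e-300), m, sd))


def _nu_birth_logq(v: float, l: int, s: int, m: float, sd: float) -> float:
    lq = norm.logpdf(v, m, sd)
    if l == s:  # truncated to <= 0
        lq -= math.log(max(norm.cdf(0.0, m, sd), 1e-300))
    return lq


def _attempt_nu_toggle(sampler: Sampler, cfg: RJConfig, pair: tuple[int, int]) -> bool:
    rng = sampler.rng
    st, priors, data = sampler.state, sampler.priors, sampler.data
    tab = sampler.proposals
    if not tab.has_birth_stats():
        raise ValueError(
            "nu birth proposal statistics missing: run the pilot first "
            "(run_pilot) or disable nu moves"
        )
    l, s = pair
    m, sd = float(tab.nu_birth_mean[l, s]), float(tab.nu_birth_sd[l, s])
    included = bool(sampler.sharing.nu_included[l, s])
    prior_odds = math.log(cfg.nu_prior_inclusion) - math.log(
        1.0 - cfg.nu_prior_inclusion
    )
    var = priors.dd_variance if l == s else priors.coef_variance
    mask = np.zeros(data.n_species, dtype=bool)
    mask[s] = True
    if not included:
        v = _truncnorm_neg_draw(rng, m, sd) if l == s else m + sd * rng.normal()
        lp_v = -0.5 * math.log(2 * math.pi * var) - v * v / (2 * var)
        if l == s:
            lp_v += math.log(2.0)
        st.nu[(l, s)] = v
        try:
            L2 = sampler._ll(st, mask)
        finally:
            del st.nu[(l, s)]
        dll = float((L2[s] - sampler.L[s]).sum())
        log_a = dll + lp_v + prior_odds - _nu_birth_logq(v, l, s, m, sd)
        if math.log(rng.uniform()) < log_a:
            sampler.sharing.nu_included[l, s] = True
            st.nu[(l, s)] = v
            sampler.L[s] = L2[s]
            return True
        return False
    v = st.nu[(l, s)]
    lp_v = -0.5 * math.log(2 * math.pi * var) - v * v / (2 * var)
    if l == s:
        lp_v += math.log(2.0)
    del st.nu[(l, s)]
    try:
        L2 = sampler._ll(st, mask)
    finally:
        st.nu[(l, s)] = v
    dll = float((L2[s] - sampler.L[s]).sum())
    log_a = dll - lp_v - prior_odds + _nu_birth_logq(v, l, s, m, sd)
    if math.log(rng.uniform()) < log_a:
        sampler.sharing.nu_included[l, s] = False
        del st.nu[(l, s)]
        sampler.L[s] = L2[s]
        return True
    return False


def toggle_nu(
    pair: tuple[int, int],
    state: ModelState,
    sharing: SharingStructure,
    data: PanelData,
    priors: PriorConfig,
    proposals: ProposalTable,
    cfg: RJConfig,
    rng: np.random.Generator,
    likelihood_on: bool = True,
) -> tuple[ModelState, SharingStructure, bool]:
    """Birth/death toggle of one interaction term (standalone wrapper)."""
    sampler = Sampler(
        data, priors, sharing, state, proposals, rng, likelihood_on=likelihood_on
    )
    ok = _attempt_nu_toggle(sampler, cfg, pair)
    return sampler.state, sampler.sharing, ok


# ---------------------------------------------------------------------------
# chain container and driver


@dataclass
class ChainOutput:
    """Thinned post-burn-in posterior draws plus model indicators."""

    species: list[str]
    families: list[str]
    draws: dict[str, np.ndarray]
    partitions: dict[str, list[Partition]]
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.draws["sigma2_eps"].shape[0]


def run_sampler(
    data: PanelData,
    priors: PriorConfig,
    cfg: RJConfig,
    proposals: ProposalTable | None = None,
    init_sharing: SharingStructure | None = None,
    init_state: ModelState | None = None,
) -> ChainOutput:
    """Full posterior sampler: per iteration one fixed-sharing sweep, one
    split/merge attempt on a uniformly chosen shareable family, and one
    birth/death toggle on a uniformly chosen interaction pair.

    Fully reproducible under ``cfg.seed``.  Requires pilot birth statistics
    in ``proposals`` when nu moves are enabled.
    """
    rng = np.random.default_rng(cfg.seed)
    if proposals is None:
        proposals = ProposalTable.default(data)
    if cfg.enable_nu_moves and not proposals.has_birth_stats():
        raise ValueError(
            "nu moves enabled but proposal table has no pilot birth "
            "statistics; run run_pilot first or set enable_nu_moves=False"
        )
    if init_sharing is not None:
        sharing = init_sharing.copy()
    else:
        # start with density dependence in the model when toggles are on:
        # its inclusion is strongly coupled to the intercepts, so starting
        # from the pilot's mode mixes far better than birthing it cold
        include = "diag" if cfg.enable_nu_moves else "none"
        sharing = SharingStructure.saturated(data, include_nu=include)
    if init_state is not None:
        state = init_state.copy()
    elif proposals.pilot_state is not None:
        from .mcmc import state_from_pilot

        state = state_from_pilot(
            data, sharing, priors, proposals.pilot_state, proposals.nu_birth_mean
        )
    else:
        state = initial_state(data, sharing, priors, rng)
    sampler = Sampler(
        data,
        priors,
        sharing,
        state,
        proposals,
        rng,
        likelihood_on=cfg.likelihood_on,
        update_mask=cfg.update_mask,
    )
    families = (
        list(cfg.rj_families)
        if cfg.rj_families is not None
        else data.shareable_families()
    )
    n_s = data.n_species
    pairs = (
        [tuple(p) for p in cfg.nu_pairs]
        if cfg.nu_pairs is not None
        else [(l, s) for l in range(n_s) for s in range(n_s)]
    )
    n_keep = (cfg.iterations - cfg.burn_in + cfg.thin - 1) // cfg.thin
    rec = {
        "alpha": np.empty((n_keep, n_s)),
        "nu": np.zeros((n_keep, n_s, n_s)),
        "nu_included": np.zeros((n_keep, n_s, n_s), dtype=bool),
        "sigma2_eps": np.empty(n_keep),
        "sigma2_s": np.empty((n_keep, n_s)),
    }
    for key in data.shareable_families():
        rec[key] = np.empty((n_keep, n_s))
    if cfg.store_latent:
        rec["eps"] = np.empty((n_keep, data.n_sites))
        rec["delta"] = np.empty((n_keep, n_s, data.n_sites))
        rec["mu0"] = np.empty((n_keep, n_s, data.n_sites))
    part_rec: dict[str, list[Partition]] = {k: [] for k in data.shareable_families()}
    rj_attempt = rj_acc = nu_attempt = nu_acc = 0
    kept = 0
    for it in range(cfg.iterations):
        sampler.sweep()
        if cfg.enable_rj and families:
            for _ in range(cfg.rj_moves_per_iter):
                fam = families[int(rng.integers(len(families)))]
                rj_attempt += 1
                rj_acc += _attempt_rj_move(sampler, cfg, fam)
        if cfg.enable_nu_moves and pairs:
            for _ in range(cfg.nu_toggles_per_iter):
                pair = pairs[int(rng.integers(len(pairs)))]
                nu_attempt += 1
                nu_acc += _attempt_nu_toggle(sampler, cfg, pair)
        if it < cfg.burn_in:
            if (it + 1) % cfg.adapt_window == 0:
                adapt_proposals(proposals)
            continue
        if (it - cfg.burn_in) % cfg.thin != 0:
            continue
        st = sampler.state
        exp_par = st.expanded(sampler.sharing, data)
        rec["alpha"][kept] = st.alpha
        rec["nu"][kept] = exp_par.nu_mat
        rec["nu_included"][kept] = sampler.sharing.nu_included
        rec["sigma2_eps"][kept] = st.sigma2_eps
        rec["sigma2_s"][kept] = st.sigma2_s
        for j in range(data.d_x):
            rec[f"beta_{j}"][kept] = exp_par.beta_sp[:, j]
        for j in range(data.d_v):
            rec[f"gamma_{j}"][kept] = exp_par.gamma_sp[:, j]
        rec[PHI_FAMILY][kept] = exp_par.phi_sp
        rec[P_FAMILY][kept] = exp_par.p_sp
        if cfg.store_latent:
            rec["eps"][kept] = st.eps
            rec["delta"][kept] = st.delta
            rec["mu0"][kept] = st.mu0
        for key in part_rec:
            part_rec[key].append(sampler.sharing.partitions[key])
        kept += 1
    for key in rec:
        rec[key] = rec[key][:kept]
    meta = {
        "config": {
            "iterations": cfg.iterations,
            "burn_in": cfg.burn_in,
            "thin": cfg.thin,
            "seed": cfg.seed,
            "rj_proposal_sd": cfg.rj_proposal_sd,
            "nu_prior_inclusion": cfg.nu_prior_inclusion,
            "model_prior": cfg.model_prior,
        },
        "rj_acceptance": rj_acc / rj_attempt if rj_attempt else None,
        "nu_toggle_acceptance": nu_acc / nu_attempt if nu_attempt else None,
    }
    return ChainOutput(
        species=list(data.species),
        families=data.shareable_families(),
        draws=rec,
        partitions=part_rec,
        meta=meta,
    )
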