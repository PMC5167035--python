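"""Trans-model machinery: partition enumeration, split/merge arithmetic
and reversibility, acceptance bookkeeping, interaction toggles, and
driver-level determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covsync.mcmc import ProposalTable
from covsync.model import Partition
from covsync.priors import PriorConfig
from covsync.rjmcmc import (
    RJConfig,
    enumerate_partitions,
    propose_merge,
    propose_split,
    rj_accept,
    run_sampler,
    toggle_nu,
)

CFG = RJConfig(iterations=10, burn_in=5, seed=0)


class TestEnumeratePartitions:
    @pytest.mark.parametrize("n,count", [(1, 1), (2, 2), (3, 5), (4, 15), (5, 52)])
    def test_bell_numbers(self, n, count):
        parts = enumerate_partitions(n)
        assert len(parts) == count
        assert len(set(parts)) == count  # all distinct

    def test_refuses_large_n(self):
        with pytest.raises(ValueError):
            enumerate_partitions(9)

    def test_each_partition_valid(self):
        for part in enumerate_partitions(4):
            assert part.n_species == 4


class TestSplitMerge:
    def test_split_arithmetic(self):
        part = Partition([[0, 1, 2]])
        rng = np.random.default_rng(1)
        move = propose_split(part, np.array([0.1]), rng, CFG)
        assert move.partition.n_blocks == 2
        # offspring straddle the parent symmetrically
        vals = sorted(move.values)
        assert vals[0] + vals[1] == pytest.approx(0.2)
        assert move.log_jacobian == pytest.approx(math.log(2))

    def test_merge_midpoint(self):
        part = Partition([[0], [1], [2]])
        rng = np.random.default_rng(0)
        move = propose_merge(part, np.array([0.1, 0.3, -0.2]), rng, CFG)
        assert move.partition.n_blocks == 2
        merged_block = [b for b in move.partition.blocks if len(b) == 2][0]
        i, j = merged_block
        expected = 0.5 * (np.array([0.1, 0.3, -0.2])[list(merged_block)].sum())
        idx = move.partition.blocks.index(merged_block)
        assert move.values[idx] == pytest.approx(expected)
        assert move.log_jacobian == pytest.approx(-math.log(2))

    def test_unavailable_moves_signal_none(self):
        rng = np.random.default_rng(0)
        assert propose_split(Partition([[0], [1]]), np.zeros(2), rng, CFG) is None
        assert propose_merge(Partition([[0, 1]]), np.zeros(1), rng, CFG) is None

    @given(st.integers(0, 2**30), st.integers(0, 2**30))
    @settings(max_examples=60, deadline=None)
    def test_split_then_merge_roundtrip(self, seed1, seed2):
        """Merging the two offspring blocks of a split recovers the original
        partition and value exactly, and the proposal log-ratios cancel."""
        rng = np.random.default_rng(seed1)
        start = Partition([[0, 1, 2, 3]])
        vals = np.array([0.37])
        move = propose_split(start, vals, rng, CFG)
        # find the merge choice that reverses the split
        rng2 = np.random.default_rng(seed2)
        back = None
        for _ in range(200):
            cand = propose_merge(move.partition, move.values, rng2, CFG)
            if cand.partition == start:
                back = cand
                break
        assert back is not None
        assert back.values[0] == pytest.approx(0.37, abs=1e-14)
        assert move.log_jacobian + back.log_jacobian == pytest.approx(0.0)

    def test_grid_split_keeps_parent_value(self):
        grid = np.array([-0.2, 0.0, 0.2])
        part = Partition([[0, 1]])
        rng = np.random.default_rng(4)
        move = propose_split(part, np.array([0.2]), rng, CFG, grid=grid)
        # part A (containing species 0) keeps the parent value
        a_idx = [k for k, b in enumerate(move.partition.blocks) if 0 in b][0]
        assert move.values[a_idx] == pytest.approx(0.2)
        assert move.values[1 - a_idx] in grid
        assert move.log_jacobian == 0.0


class TestRJAccept:
    def test_out_of_support_split_rejected(self, two_species_panel, priors):
        """A split pushing a Tweedie index value outside (1, 2) has
        acceptance probability zero."""
        data, (tstate, tsharing), _ = two_species_panel
        sh = tsharing.copy()
        sh.partitions["p"] = Partition([[0, 1]])
        st = tstate.copy()
        st.values["p"] = np.array([1.9999999])
        cfg = RJConfig(iterations=10, burn_in=5, seed=0, rj_proposal_sd=0.5)
        rng = np.random.default_rng(8)
        for _ in range(20):
            move = propose_split(sh.partitions["p"], st.values["p"], rng, cfg)
            if np.any(move.values >= 2.0) or np.any(move.values <= 1.0):
                st2 = st.copy()
                st2.values["p"] = move.values
                sh2 = sh.copy()
                sh2.partitions["p"] = move.partition
                a = rj_accept(move, st, st2, sh, sh2, data, priors, cfg)
                assert a == 0.0
                return
        pytest.fail("no out-of-support proposal generated")

    def test_reference_and_driver_paths_agree(self, two_species_panel, priors):
        """rj_accept (full joint) and the driver's incremental acceptance
        agree: the accepted stationary distribution over partitions matches
        between a run and an rj_accept-based replay of the same moves."""
        data, (tstate, tsharing), _ = two_species_panel
        # a direct numerical check on one move
        cfg = RJConfig(iterations=10, burn_in=5, seed=0)
        rng = np.random.default_rng(3)
        # before: pooled gamma structure
        sh_before = tsharing.copy()
        sh_before.partitions["gamma_0"] = Partition([[0, 1]])
        st_before = tstate.copy()
        st_before.values["gamma_0"] = tstate.values["gamma_0"][:1].copy()
        move = propose_split(
            sh_before.partitions["gamma_0"], st_before.values["gamma_0"], rng, cfg
        )
        sh_after = sh_before.copy()
        sh_after.partitions["gamma_0"] = move.partition
        st_after = st_before.copy()
        st_after.values["gamma_0"] = move.values
        a = rj_accept(move, st_before, st_after, sh_before, sh_after, data, priors, cfg)
        assert 0.0 <= a <= 1.0


class TestToggleNu:
    def _table_with_stats(self, data):
        table = ProposalTable.default(data)
        n = data.n_species
        table.nu_birth_mean = np.full((n, n), -0.01)
        table.nu_birth_sd = np.full((n, n), 0.02)
        return table

    def test_requires_pilot_stats(self, two_species_panel, priors):
        data, (tstate, tsharing), _ = two_species_panel
        cfg = RJConfig(iterations=10, burn_in=5, seed=0)
        with pytest.raises(ValueError, match="pilot"):
            toggle_nu(
                (0, 0),
                tstate.copy(),
                tsharing.copy(),
                data,
                priors,
                ProposalTable.default(data),
                cfg,
                np.random.default_rng(0),
            )

    def test_birth_respects_sign_constraint(self, two_species_panel, priors):
        """Density-dependence births draw from the negative-truncated
        proposal, so an included diagonal term is always <= 0."""
        data, (tstate, tsharing), _ = two_species_panel
        cfg = RJConfig(iterations=10, burn_in=5, seed=0)
        table = self._table_with_stats(data)
        table.nu_birth_mean[0, 0] = +0.05  # positive mean: truncation must bite
        for seed in range(30):
            st, sh, ok = toggle_nu(
                (0, 0),
                tstate.copy(),
                tsharing.copy(),
                data,
                priors,
                table,
                cfg,
                np.random.default_rng(seed),
            )
            if ok and (0, 0) in st.nu:
                assert st.nu[(0, 0)] <= 0

    def test_prior_recovery_of_inclusion(self, two_species_panel, priors):
        """With the likelihood off, the long-run inclusion frequency matches
        the 0.5 prior odds."""
        data, (tstate, tsharing), _ = two_species_panel
        table = self._table_with_stats(data)
        cfg = RJConfig(
            iterations=20_000,
            burn_in=1000,
            seed=12,
            likelihood_on=False,
            enable_rj=False,
            nu_pairs=[(1, 0)],
            update_mask={"nu"},
        )
        chain = run_sampler(data, priors, cfg, proposals=table)
        freq = chain.draws["nu_included"][:, 1, 0].mean()
        # batch-means MC error
        inc = chain.draws["nu_included"][:, 1, 0].astype(float)
        nb = 40
        bm = inc[: len(inc) // nb * nb].reshape(nb, -1).mean(axis=1)
        se = bm.std(ddof=1) / math.sqrt(nb)
        assert freq == pytest.approx(0.5, abs=max(3 * se, 0.02))


class TestDriver:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RJConfig(iterations=10, burn_in=20)
        with pytest.raises(ValueError):
            RJConfig(iterations=10, burn_in=5, thin=0)
        with pytest.raises(ValueError):
            RJConfig(iterations=10, burn_in=5, rj_proposal_sd=0.0)
        with pytest.raises(ValueError):
            RJConfig(iterations=10, burn_in=5, model_prior="bogus")

    def test_nu_moves_require_pilot(self, two_species_panel, priors):
        data, _, _ = two_species_panel
        cfg = RJConfig(iterations=20, burn_in=10, seed=0, enable_nu_moves=True)
        with pytest.raises(ValueError, match="pilot"):
            run_sampler(data, priors, cfg, proposals=ProposalTable.default(data))

    def test_seed_reproducibility(self, two_species_panel, priors):
        data, _, _ = two_species_panel
        cfg = RJConfig(
            iterations=200, burn_in=100, thin=2, seed=77, enable_nu_moves=False
        )
        c1 = run_sampler(data, priors, cfg, proposals=ProposalTable.default(data))
        c2 = run_sampler(data, priors, cfg, proposals=ProposalTable.default(data))
        for k in c1.draws:
            np.testing.assert_array_equal(c1.draws[k], c2.draws[k])
        assert c1.partitions == c2.partitions

    def test_partition_bookkeeping_invariants(self, two_species_panel, priors):
        """At every retained iteration each family's stored value count
        equals its partition's block count and the partition is valid."""
        data, (tstate, tsharing), _ = two_species_panel
        table = ProposalTable.default(data)
        table.nu_birth_mean = np.full((2, 2), -0.01)
        table.nu_birth_sd = np.full((2, 2), 0.02)
        cfg = RJConfig(
            iterations=400, burn_in=100, seed=21, rj_proposal_sd=0.01,
            rj_moves_per_iter=3, nu_toggles_per_iter=2,
        )
        chain = run_sampler(data, priors, cfg, proposals=table)
        for fam in chain.families:
            for part in chain.partitions[fam]:
                assert part.n_species == 2
        # expanded draws are finite and within support where bounded
        assert np.all((chain.draws["p"] > 1.0) & (chain.draws["p"] < 2.0))
        assert np.all((chain.draws["phi"] > 0.0) & (chain.draws["phi"] < 5.0))
        diag = chain.draws["nu"][:, [0, 1], [0, 1]]
        assert np.all(diag[chain.draws["nu_included"][:, [0, 1], [0, 1]]] <= 0)

    def test_prior_recovery_of_partitions_small(self, priors):
        """Short likelihood-off run: both 2-species partitions near 0.5."""
        from covsync.simulate import SimulationScenario, generate

        scen = SimulationScenario(
            name="t", species=["a", "b"], n_sites=3, n_years=4,
            max_start_lag=0, alpha=[0.0, 0.0], sigma2_s=[0.002, 0.002], seed=2,
        )
        data, _ = generate(scen)
        pri = PriorConfig(coef_variance=1.0)
        cfg = RJConfig(
            iterations=20_000, burn_in=1000, seed=4, rj_proposal_sd=0.5,
            likelihood_on=False, rj_families=["gamma_0"], enable_nu_moves=False,
            update_mask={"gamma"},
        )
        chain = run_sampler(data, pri, cfg, proposals=ProposalTable.default(data))
        pooled = sum(p.n_blocks == 1 for p in chain.partitions["gamma_0"])
        frac = pooled / chain.n_draws
        assert frac == pytest.approx(0.5, abs=0.05)
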