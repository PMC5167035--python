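"""Core model structures: partitions, the mean recursion, likelihood
additivity, priors, parameterization equivalence, and the ICC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covsync.model import (
    ModelState,
    PanelData,
    Partition,
    SharingStructure,
    intraclass_correlation,
    log_joint,
    log_likelihood,
    log_prior,
    loglik_matrix,
    mean_trajectory,
)
from covsync.tweedie import TweedieParams, log_density


def make_single_site_panel(y_rows, v=None, x=None, n_species=None):
    """Panel with one site whose window length equals the y row length."""
    y = np.asarray(y_rows, dtype=float)
    n_s, L = y.shape
    v = np.zeros((L, 1)) if v is None else np.asarray(v, dtype=float).reshape(L, -1)
    x = np.zeros((1, 1)) if x is None else np.asarray(x, dtype=float).reshape(1, -1)
    return PanelData(
        species=[f"s{i + 1}" for i in range(n_s)],
        sites=["site1"],
        window_start=np.array([1970]),
        window_len=np.array([L]),
        y=y,
        v=v,
        x=x,
    )


def make_state(data, sharing, **overrides):
    n_s, n_i = data.n_species, data.n_sites
    values = {}
    for key, part in sharing.partitions.items():
        if key == "phi":
            values[key] = np.full(part.n_blocks, 1.0)
        elif key == "p":
            values[key] = np.full(part.n_blocks, 1.5)
        else:
            values[key] = np.zeros(part.n_blocks)
    state = ModelState(
        alpha=np.zeros(n_s),
        values=values,
        nu={tuple(map(int, p)): 0.0 for p in np.argwhere(sharing.nu_included)},
        eps=np.zeros(n_i),
        delta=np.zeros((n_s, n_i)),
        mu0=np.full((n_s, n_i), 3.0),
        sigma2_eps=0.01,
        sigma2_s=np.full(n_s, 0.01),
    )
    for k, v in overrides.items():
        setattr(state, k, v)
    return state


class TestPartition:
    def test_canonical_ordering(self):
        assert Partition([[2], [1, 0]]) == Partition([[0, 1], [2]])
        assert Partition([[2], [0, 1]]).blocks == ((0, 1), (2,))

    @pytest.mark.parametrize("blocks", [[[0, 1], [1, 2]], [[0], [2]], [[]], []])
    def test_invalid_blocks_rejected(self, blocks):
        with pytest.raises(ValueError):
            Partition(blocks)

    def test_expand_and_label(self):
        part = Partition([[0, 1], [2]])
        np.testing.assert_array_equal(part.expand([5.0, 7.0]), [5.0, 5.0, 7.0])
        assert part.label(["bt", "gt", "ct"]) == "{bt, gt}, {ct}"
        assert part.label() == "{1, 2}, {3}"

    @given(st.lists(st.integers(0, 3), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_block_index_roundtrip(self, assignment):
        # any labelling of 4 species into groups induces a valid partition
        groups = {}
        for s, g in enumerate(assignment):
            groups.setdefault(g, []).append(s)
        part = Partition(groups.values())
        idx = part.block_index()
        for s in range(4):
            assert s in part.blocks[idx[s]]


class TestPanelData:
    def test_rejects_single_species(self):
        with pytest.raises(ValueError, match="2 species"):
            make_single_site_panel([[1.0, 2.0]])

    def test_rejects_negative_observations(self):
        with pytest.raises(ValueError):
            make_single_site_panel([[1.0, -2.0], [0.0, 1.0]])

    def test_site_years_are_inclusive_window(self):
        data = make_single_site_panel([[1, 2, 3], [1, 1, 1]])
        np.testing.assert_array_equal(data.site_years(0), [1970, 1971, 1972])


class TestMeanTrajectory:
    def test_zero_growth_is_constant(self, small_panel):
        data, _, _ = small_panel
        sharing = SharingStructure.saturated(data, include_nu="none")
        state = make_state(data, sharing)
        mu = mean_trajectory(state, sharing, data, species=1, site=0)
        np.testing.assert_allclose(mu, 3.0)

    def test_constant_growth_is_exponential(self, small_panel):
        data, _, _ = small_panel
        sharing = SharingStructure.saturated(data, include_nu="none")
        state = make_state(data, sharing)
        state.eps[2] = 0.07
        state.delta[0, 2] = 0.03
        mu = mean_trajectory(state, sharing, data, 0, 2)
        L = data.window_len[2]
        np.testing.assert_allclose(mu, 3.0 * np.exp(0.1 * np.arange(1, L + 1)))

    def test_hand_recursion_with_time_covariate(self):
        # exponent accumulates 0.1 + 0.2 * v_t per year from mu0 = 2
        data = make_single_site_panel([[1, 1, 1], [1, 1, 1]], v=[0.5, -0.5, 1.0])
        sharing = SharingStructure.saturated(data, include_nu="none")
        state = make_state(data, sharing)
        state.values["gamma_0"] = np.array([0.2, 0.0])
        state.eps[0] = 0.1
        state.mu0[:, 0] = 2.0
        mu = mean_trajectory(state, sharing, data, 0, 0)
        np.testing.assert_allclose(
            mu, [2 * math.exp(0.2), 2 * math.exp(0.2), 2 * math.exp(0.5)]
        )

    def test_lagged_abundance_uses_mu0_then_observations(self):
        data = make_single_site_panel([[4.0, 2.0, 1.0], [1.0, 1.0, 1.0]])
        sharing = SharingStructure.saturated(data, include_nu="diag")
        state = make_state(data, sharing)
        state.nu[(0, 0)] = -0.1
        state.mu0[0, 0] = 5.0
        mu = mean_trajectory(state, sharing, data, 0, 0)
        # increments: -0.1*5 (augmented lag), then -0.1*4, -0.1*2 (observed)
        expected = 5.0 * np.exp(np.cumsum([-0.5, -0.4, -0.2]))
        np.testing.assert_allclose(mu, expected)

    def test_strictly_positive(self, small_panel):
        data, (tstate, tsharing), _ = small_panel
        for s in range(data.n_species):
            for i in range(data.n_sites):
                assert np.all(mean_trajectory(tstate, tsharing, data, s, i) > 0)


class TestLogLikelihood:
    def test_single_zero_observation_equals_zero_mass(self):
        data = make_single_site_panel([[0.0], [0.0]])
        sharing = SharingStructure.saturated(data, include_nu="none")
        state = make_state(data, sharing)
        # each species contributes the Tweedie zero mass at mu=3, phi=1, p=1.5
        lam = 3.0 ** (2 - 1.5) / (1 * (2 - 1.5))
        assert log_likelihood(state, sharing, data) == pytest.approx(-2 * lam)

    def test_site_additivity(self, small_panel):
        data, (tstate, tsharing), _ = small_panel
        L = loglik_matrix(tstate, tsharing, data)
        assert log_likelihood(tstate, tsharing, data) == pytest.approx(L.sum())
        # each (species, site) cell matches a scalar-API evaluation
        s, i = 1, 3
        mu = mean_trajectory(tstate, tsharing, data, s, i)
        exp_par = tstate.expanded(tsharing, data)
        off = int(data.offsets[i])
        ref = sum(
            log_density(
                float(data.y[s, off + k]),
                TweedieParams(float(m), float(exp_par.phi_sp[s]), float(exp_par.p_sp[s])),
            )
            for k, m in enumerate(mu)
        )
        assert L[s, i] == pytest.approx(ref, rel=1e-12)

    def test_duplicating_a_site_doubles_its_contribution(self, small_panel):
        data, (tstate, tsharing), _ = small_panel
        L = loglik_matrix(tstate, tsharing, data)
        sl = data.site_slice(0)
        data2 = PanelData(
            species=data.species,
            sites=data.sites + ["copy"],
            window_start=np.append(data.window_start, data.window_start[0]),
            window_len=np.append(data.window_len, data.window_len[0]),
            y=np.concatenate([data.y, data.y[:, sl]], axis=1),
            v=np.concatenate([data.v, data.v[sl]], axis=0),
            x=np.concatenate([data.x, data.x[:1]], axis=0),
        )
        st2 = tstate.copy()
        st2.eps = np.append(tstate.eps, tstate.eps[0])
        st2.delta = np.concatenate([tstate.delta, tstate.delta[:, :1]], axis=1)
        st2.mu0 = np.concatenate([tstate.mu0, tstate.mu0[:, :1]], axis=1)
        assert log_likelihood(st2, tsharing, data2) == pytest.approx(
            L.sum() + L[:, 0].sum(), rel=1e-12
        )


class TestLogPrior:
    def test_out_of_support_returns_minus_inf(self, small_panel, priors):
        data, (tstate, tsharing), _ = small_panel
        st = tstate.copy()
        st.values["phi"] = np.array([6.0, 0.2, 0.3])  # outside U[0, 5]
        assert log_prior(st, tsharing, data, priors) == -math.inf
        st = tstate.copy()
        st.nu[(0, 0)] = +0.01  # positive density dependence
        assert log_prior(st, tsharing, data, priors) == -math.inf
        st = tstate.copy()
        st.mu0[1, 2] = 201.0
        assert log_prior(st, tsharing, data, priors) == -math.inf
        st = tstate.copy()
        st.sigma2_eps = -1.0
        assert log_prior(st, tsharing, data, priors) == -math.inf

    def test_term_by_term_oracle(self, small_panel, priors):
        from scipy import stats

        data, (tstate, tsharing), _ = small_panel
        st = tstate
        expect = 0.0
        var_c = priors.coef_variance
        expect += stats.norm.logpdf(st.alpha, 0, math.sqrt(var_c)).sum()
        for key, part in tsharing.partitions.items():
            vals = st.values[key]
            if key == "phi":
                expect += len(vals) * math.log(1 / 5)
            elif key == "p":
                expect += 0.0
            else:
                expect += stats.norm.logpdf(vals, 0, math.sqrt(var_c)).sum()
        for (l, s), v in st.nu.items():
            if l == s:
                expect += math.log(2) + stats.norm.logpdf(
                    v, 0, math.sqrt(priors.dd_variance)
                )
            else:
                expect += stats.norm.logpdf(v, 0, math.sqrt(var_c))
        expect += st.mu0.size * math.log(1 / 200)
        expect += stats.invgamma.logpdf(st.sigma2_eps, 1e-3, scale=1e-3)
        expect += stats.invgamma.logpdf(st.sigma2_s, 1e-3, scale=1e-3).sum()
        expect += stats.norm.logpdf(st.eps, 0, math.sqrt(st.sigma2_eps)).sum()
        exp_par = st.expanded(tsharing, data)
        mean = st.alpha[:, None] + exp_par.beta_sp @ data.x.T
        expect += stats.norm.logpdf(
            st.delta, mean, np.sqrt(st.sigma2_s)[:, None]
        ).sum()
        assert log_prior(st, tsharing, data, priors) == pytest.approx(expect, rel=1e-10)

    def test_shared_blocks_contribute_one_term_each(self, small_panel, priors):
        data, (tstate, tsharing), _ = small_panel
        pooled = tsharing.copy()
        pooled.partitions["beta_0"] = Partition([[0, 1, 2]])
        st = tstate.copy()
        st.values["beta_0"] = np.array([0.0])
        split = tsharing.copy()
        split.partitions["beta_0"] = Partition([[0], [1], [2]])
        st2 = tstate.copy()
        st2.values["beta_0"] = np.zeros(3)
        from scipy import stats

        one_term = stats.norm.logpdf(0.0, 0, priors.coef_sd)
        diff = log_prior(st2, split, data, priors) - log_prior(st, pooled, data, priors)
        assert diff == pytest.approx(2 * one_term, rel=1e-10)


class TestParameterizationEquivalence:
    def test_centered_equals_uncentered(self, small_panel, priors):
        """The hierarchically-centered joint density equals the uncentered
        one after shifting delta by the linear predictor (Jacobian 1)."""
        data, (tstate, tsharing), _ = small_panel
        rng = np.random.default_rng(3)
        for _ in range(100):
            st = tstate.copy()
            st.alpha = rng.normal(0, 0.05, 3)
            st.eps = rng.normal(0, 0.05, data.n_sites)
            st.delta = rng.normal(0.05, 0.05, (3, data.n_sites))
            st.mu0 = rng.uniform(1, 10, (3, data.n_sites))
            for k in st.values:
                if k == "phi":
                    st.values[k] = rng.uniform(0.1, 0.6, st.values[k].shape)
                elif k == "p":
                    st.values[k] = rng.uniform(1.2, 1.8, st.values[k].shape)
                else:
                    st.values[k] = rng.normal(0, 0.03, st.values[k].shape)
            st.sigma2_eps = rng.uniform(0.001, 0.01)
            st.sigma2_s = rng.uniform(0.001, 0.01, 3)
            lc = log_joint(st, tsharing, data, priors)
            exp_par = st.expanded(tsharing, data)
            un = st.copy()
            un.delta = st.delta - (st.alpha[:, None] + exp_par.beta_sp @ data.x.T)
            lu = log_joint(un, tsharing, data, priors, uncentered=True)
            assert lu == pytest.approx(lc, abs=1e-10)


class TestICC:
    def test_symmetry_and_limits(self):
        assert intraclass_correlation(0.004, 0.004) == pytest.approx(0.5)
        assert intraclass_correlation(0.004, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_arithmetic(self):
        assert intraclass_correlation(0.0043, 0.0005) == pytest.approx(
            0.0043 / 0.0048
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            intraclass_correlation(0.0, 0.1)
        with pytest.raises(ValueError):
            intraclass_correlation(0.1, -0.1)

    def test_vectorized(self):
        out = intraclass_correlation(np.array([0.004, 0.002]), np.array([0.001, 0.002]))
        np.testing.assert_allclose(out, [0.8, 0.5])
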