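"""Coupled evolution, observables, and the spectral-expansion oracle."""

import numpy as np
import pytest

import interflux as ifx
from interflux import fixtures
from interflux.dynamics import (
    PopulationState,
    build_coupled_matrix,
    distribution_x,
    evolve,
    numeric_flux,
    population_share,
    spectral_expansion_oracle,
)
from interflux.networks import NodeNetwork, UndefinedStateError
from interflux.spectral import embed_pair, exact_equilibrium


def single_edge(label=""):
    return NodeNetwork(weights=np.array([[0.0, 1.0], [1.0, 0.0]]), label=label)


class TestBuildCoupledMatrix:
    def test_two_single_edges_pp(self):
        cfg = ifx.ConnectorConfig([(1, 1)], epsilon=0.3)
        sys = build_coupled_matrix(single_edge(), single_edge(), cfg)
        T = sys.matrix
        assert T.shape == (4, 4)
        assert T[1, 3] == T[3, 1] == 0.3
        assert T[0, 1] == T[1, 0] == T[2, 3] == T[3, 2] == 1.0
        assert np.allclose(T, T.T)

    def test_star_pair_cc(self, star_pair):
        sys = build_coupled_matrix(*star_pair, ifx.ConnectorConfig([(0, 0)], 0.1))
        off = sys.matrix[:10, 10:]
        assert off[0, 0] == 0.1
        assert np.count_nonzero(off) == 1

    def test_empty_connector_block_diagonal(self, star_pair):
        sys = build_coupled_matrix(*star_pair, ifx.ConnectorConfig([], 1.0))
        assert not sys.matrix[:10, 10:].any()

    def test_out_of_range_pair_raises(self, star_pair):
        with pytest.raises(ValueError):
            build_coupled_matrix(*star_pair, ifx.ConnectorConfig([(0, 99)], 1.0))


class TestEvolve:
    def test_permutation_dynamics(self):
        """On a single edge, knowledge swaps endpoints each step (M = G)."""
        G = single_edge().weights
        n = np.array([1.0, 0.0])
        np.testing.assert_array_equal(G @ n, [0.0, 1.0])
        np.testing.assert_array_equal(G @ (G @ n), n)

    def test_stochastic_conservation(self, rng):
        """Column-stochastic coupled matrices conserve total population."""
        W = rng.uniform(0.1, 1.0, (8, 8))
        M = W / W.sum(axis=0, keepdims=True)
        net = NodeNetwork(weights=M, directed=True, allow_self_loops=True)
        netB = NodeNetwork(weights=np.zeros((1, 1)))
        n = rng.uniform(0, 1, 8)
        n /= n.sum()
        for _ in range(100):
            n = M @ n
        assert n.sum() == pytest.approx(1.0, abs=1e-12)

    def test_converges_to_exact_equilibrium(self, star_pair):
        """x(t) settles at the Perron-eigenvector equilibrium.

        Stars are exactly bipartite, so a period-2 component of amplitude
        O(eps^2) survives forever; the two-step mean converges cleanly.
        """
        cfg = ifx.ConnectorConfig([(0, 0)], epsilon=0.1)
        sys = build_coupled_matrix(*star_pair, cfg)
        uA, uB = sys.embedded_eigenvectors()
        traj = evolve(sys, uB.copy(), steps=500)
        x_mean = (traj.x[-1] + traj.x[-2]) / 2
        x_eq = exact_equilibrium(sys)
        assert x_mean == pytest.approx(x_eq, rel=1e-3)
        assert traj.x[-1] == pytest.approx(x_eq, rel=0.05)  # oscillation floor

    def test_renormalization_invariance(self, small_ba_pair):
        """x(t) and P_A(t) are invariant to per-step renormalization."""
        cfg = ifx.ConnectorConfig([(0, 0)], epsilon=0.5)
        sys = build_coupled_matrix(*small_ba_pair, cfg)
        n0 = sys.equilibrium_initial_state(2.0)
        a = evolve(sys, n0, steps=60, renormalize=True)
        b = evolve(sys, n0, steps=60, renormalize=False)
        np.testing.assert_allclose(a.x, b.x, atol=1e-10)
        np.testing.assert_allclose(a.p_a, b.p_a, atol=1e-10)

    def test_overflow_guard(self, star_pair):
        sys = build_coupled_matrix(*star_pair, ifx.ConnectorConfig([(0, 0)], 0.1))
        n0 = sys.equilibrium_initial_state(1.0)
        with pytest.raises(OverflowError, match="renormalize"):
            evolve(sys, n0, steps=1000, renormalize=False)


class TestObservables:
    def test_distribution_x_pure_and_mixed(self, star_pair):
        uA, uB = embed_pair(*star_pair)
        assert distribution_x(uA, uA, uB) == 0.0
        assert np.isinf(distribution_x(uB, uA, uB))
        mix = (uA + uB) / np.sqrt(2)
        assert distribution_x(mix, uA, uB) == pytest.approx(1.0, rel=1e-12)

    def test_distribution_x_undefined(self, star_pair):
        uA, uB = embed_pair(*star_pair)
        n = np.zeros_like(uA)
        n[1] = 0.0
        with pytest.raises(UndefinedStateError):
            distribution_x(n, uA, uB)

    def test_population_share(self):
        idx = (np.array([0, 1]), np.array([2]))
        assert population_share(np.array([1.0, 2.0, 3.0]), idx) == (0.5, 0.5)
        assert population_share(np.array([2.0, 3.0, 0.0]), idx) == (1.0, 0.0)

    def test_numeric_flux_signs(self, star_pair):
        """Starting above equilibrium, population flows monotonically B -> A.

        On the exactly bipartite star pair the monotone regime ends when
        |x - x_eq| hits the O(eps^2) period-2 oscillation floor.
        """
        eps = 0.05
        cfg = ifx.ConnectorConfig([(0, 0)], epsilon=eps)
        sys = build_coupled_matrix(*star_pair, cfg)
        traj = evolve(sys, sys.equilibrium_initial_state(2.5), steps=100)
        x_eq = exact_equilibrium(sys)
        for t in range(100):
            if abs(traj.x[t] - x_eq) < eps**2:
                assert t > 5  # a substantial monotone stretch was observed
                break
            assert numeric_flux(traj, t) < 0
        with pytest.raises(ValueError):
            numeric_flux(traj, 100)

    def test_flux_zero_at_equilibrium_start(self, star_pair):
        from interflux.dynamics import equilibrium_state

        cfg = ifx.ConnectorConfig([(0, 0)], epsilon=0.05)
        sys = build_coupled_matrix(*star_pair, cfg)
        traj = evolve(sys, equilibrium_state(sys), steps=50)
        assert np.nanmax(np.abs(traj.flux)) < 1e-8


class TestSpectralExpansionOracle:
    def test_t0_and_t1(self, star_pair):
        cfg = ifx.ConnectorConfig([(0, 0)], epsilon=0.1)
        sys = build_coupled_matrix(*star_pair, cfg)
        n0 = sys.equilibrium_initial_state(1.3)
        n, exact = spectral_expansion_oracle(sys, n0, 0)
        np.testing.assert_array_equal(n, n0)
        n1, _ = spectral_expansion_oracle(sys, n0, 1)
        np.testing.assert_allclose(n1, sys.matrix @ n0, atol=1e-12)

    @pytest.mark.parametrize("t", [10, 50])
    def test_matches_evolution(self, star_pair, t):
        """Two independent code paths for n(t) agree to 1e-8 relative."""
        cfg = ifx.ConnectorConfig([(1, 2)], epsilon=0.2)
        sys = build_coupled_matrix(*star_pair, cfg)
        n0 = sys.equilibrium_initial_state(0.7)
        traj = evolve(sys, n0, steps=t, renormalize=False)
        n_oracle, exact = spectral_expansion_oracle(sys, n0, t)
        assert exact
        err = np.linalg.norm(traj.final_state.n - n_oracle) / np.linalg.norm(n_oracle)
        assert err < 1e-8


class TestMonotonicity:
    def test_flux_always_points_at_equilibrium(self):
        """sign(dx) = sign(x_eq - x) on random scenarios until convergence."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            netA, netB = fixtures.make_scale_free_pair(
                N=25, m=2, seedA=int(rng.integers(2**31)), seedB=int(rng.integers(2**31))
            )
            if netA.eigen().lam1 < netB.eigen().lam1:
                netA, netB = netB, netA
            i = int(rng.integers(netA.n_nodes))
            j = int(rng.integers(netB.n_nodes))
            eps = float(rng.uniform(0.01, 0.3))
            sys = build_coupled_matrix(netA, netB, ifx.ConnectorConfig([(i, j)], eps))
            x_eq = exact_equilibrium(sys)
            x0 = float(rng.uniform(0, 3))
            traj = evolve(sys, sys.equilibrium_initial_state(x0), steps=2000)
            for t in range(len(traj) - 1):
                gap = x_eq - traj.x[t]
                if abs(gap) < 1e-6:
                    break
                dx = traj.x[t + 1] - traj.x[t]
                if abs(dx) > 1e-12:
                    assert np.sign(dx) == np.sign(gap)
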