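"""Directed flow networks: stochastic normalisation, strength, series."""

import numpy as np
import pytest

from interflux import fixtures
from interflux.flows import (
    FlowTable,
    equilibria_series,
    flow_to_transition,
    group_vs_rest,
    stationary_state,
)
from interflux.networks import DegenerateSpectrumError, ReducibleSystemError


def table(entries, labels=None, groups=None):
    entries = np.asarray(entries, dtype=float)
    labels = labels or [f"n{i}" for i in range(entries.shape[0])]
    return FlowTable(entries=entries, node_labels=labels, group_map=groups or {})


class TestFlowToTransition:
    def test_two_node_hand_normalisation(self):
        M = flow_to_transition(table([[0, 2], [1, 0]]))
        np.testing.assert_allclose(M, [[0, 1], [1, 0]])

    def test_columns_sum_to_one(self, rng):
        L = rng.uniform(0.0, 3.0, (7, 7))
        np.fill_diagonal(L, 0.0)
        M = flow_to_transition(table(L))
        np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-12)

    def test_stochastic_leading_eigenvalue(self, rng):
        L = rng.uniform(0.1, 2.0, (5, 5))
        M = flow_to_transition(table(L))
        from interflux.networks import NodeNetwork
        from interflux.spectral import leading_eigenpair

        eig = leading_eigenpair(
            NodeNetwork(weights=M, directed=True, allow_self_loops=True)
        )
        assert eig.lam1 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(eig.u1_left, 1 / np.sqrt(5), atol=1e-8)

    def test_zero_outflow_named(self):
        with pytest.raises(ValueError, match="n1"):
            flow_to_transition(table([[0, 0, 1], [0, 0, 0], [1, 1, 0]]))

    def test_conservation_long_run(self, rng):
        L = rng.uniform(0.1, 2.0, (6, 6))
        M = flow_to_transition(table(L))
        n = rng.uniform(0, 1, 6)
        total = n.sum()
        for _ in range(10_000):
            n = M @ n
        assert abs(n.sum() - total) <= 1e-10 * total


class TestStationaryState:
    def test_permutation_chain_flagged_periodic(self):
        st = stationary_state(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert st.periodic
        np.testing.assert_allclose(st.distribution, [0.5, 0.5], atol=1e-10)

    def test_three_cycle_uniform_periodic(self):
        M = np.roll(np.eye(3), 1, axis=0)
        st = stationary_state(M)
        assert st.periodic
        np.testing.assert_allclose(st.distribution, 1 / 3, atol=1e-10)

    def test_random_chain_two_solvers_agree(self, rng):
        L = rng.uniform(0.1, 1.0, (10, 10))
        M = flow_to_transition(table(L))
        st = stationary_state(M)
        assert not st.periodic
        vals, vecs = np.linalg.eig(M)
        v = np.abs(np.real(vecs[:, np.argmax(vals.real)]))
        np.testing.assert_allclose(st.distribution, v / v.sum(), atol=1e-10)
        # stationarity
        np.testing.assert_allclose(M @ st.distribution, st.distribution, atol=1e-10)

    def test_reducible_reports_classes(self):
        M = np.eye(4)
        with pytest.raises(ReducibleSystemError, match="classes"):
            stationary_state(M)


class TestGroupVsRest:
    def test_block_diagonal_zero_strength(self):
        tabs = fixtures.make_two_group_flow(3, 4, 0.0, 1, seed=0)
        with pytest.raises(ReducibleSystemError):
            group_vs_rest(tabs[0], "A")

    def test_identical_blocks_tie(self):
        intra = np.array([[0.0, 1.0], [1.0, 0.0]])
        E = np.zeros((4, 4))
        E[:2, :2] = intra
        E[2:, 2:] = intra
        E[0, 2] = E[2, 0] = 1e-9  # make irreducible but keep blocks identical
        tb = table(E, labels=["A0", "A1", "B0", "B1"],
                   groups={"A0": "A", "A1": "A", "B0": "B", "B1": "B"})
        with pytest.raises(DegenerateSpectrumError):
            group_vs_rest(tb, "A")

    def test_strength_matches_dense_brute_force(self):
        """The formula agrees with an independent dense evaluation."""
        tb = fixtures.make_two_group_flow(3, 2, 0.2, 1, seed=11)[0]
        res = group_vs_rest(tb, "A")
        M = flow_to_transition(tb)
        g = tb.group_indices("A")
        r = np.setdiff1d(np.arange(5), g)
        Mg, Mr = M[np.ix_(g, g)], M[np.ix_(r, r)]

        def dense_eig(B, left=False):
            vals, vecs = np.linalg.eig(B.T if left else B)
            k = np.argmax(vals.real)
            v = np.abs(np.real(vecs[:, k]))
            return float(vals[k].real), v / np.linalg.norm(v)

        lg, ug = dense_eig(Mg)
        lr, ur = dense_eig(Mr)
        assert lg > lr  # group A built strong by the generator
        _, ugl = dense_eig(Mg, left=True)
        _, url = dense_eig(Mr, left=True)
        w_r = url / (url @ ur)
        V = M[np.ix_(r, g)]
        expected = (w_r @ V @ ug) / (lg - lr)
        assert res.strength == pytest.approx(expected, abs=1e-10)

    def test_symmetric_table_reduces_to_undirected_formula(self, rng):
        """Constant-outflow symmetric tables: directed strength = eps*F/dlam."""
        nA, nB = 4, 3
        intra_A = rng.uniform(0.5, 1.5, (nA, nA))
        intra_A = np.triu(intra_A, 1)
        intra_A += intra_A.T
        intra_B = rng.uniform(0.5, 1.5, (nB, nB))
        intra_B = np.triu(intra_B, 1)
        intra_B += intra_B.T
        eps = 0.05
        E = np.zeros((nA + nB, nA + nB))
        E[:nA, :nA] = intra_A
        E[nA:, nA:] = intra_B
        E[0, nA] = E[nA, 0] = eps  # one symmetric connector pair
        rowsum = E.sum(axis=1)
        c = rowsum.max() + 1.0
        np.fill_diagonal(E, c - rowsum)  # pad with self-flows: constant outflow
        labels = [f"A{i}" for i in range(nA)] + [f"B{j}" for j in range(nB)]
        groups = {lab: lab[0] for lab in labels}
        tb = table(E, labels=labels, groups=groups)
        res = group_vs_rest(tb, "A")

        # undirected route on the scaled blocks (self-loops included)
        from interflux.networks import ConnectorConfig, NodeNetwork
        from interflux.spectral import connection_strength, leading_eigenpair

        netA = NodeNetwork(weights=E[:nA, :nA] / c, allow_self_loops=True)
        netB = NodeNetwork(weights=E[nA:, nA:] / c, allow_self_loops=True)
        eigA, eigB = leading_eigenpair(netA), leading_eigenpair(netB)
        uA, uB = eigA.u1, eigB.u1
        F, eps_F = connection_strength(uA, uB, ConnectorConfig([(0, 0)], eps / c))
        expected = eps_F / abs(eigA.lam1 - eigB.lam1)
        assert res.strength == pytest.approx(expected, abs=1e-10)


class TestEquilibriaSeries:
    def test_needs_three_periods(self):
        tabs = fixtures.make_two_group_flow(3, 2, 0.2, 2, seed=0)
        with pytest.raises(ValueError):
            equilibria_series(tabs, "A")

    def test_constant_series_flagged(self):
        tabs = fixtures.make_two_group_flow(3, 2, 0.2, 4, seed=0, sigma=0.0)
        _, corr, flags = equilibria_series(tabs, "A")
        assert corr == 1.0
        assert flags["constant_series"]

    def test_matches_hand_pearson(self):
        tabs = fixtures.make_two_group_flow(3, 2, 0.2, 4, seed=3, sigma=0.4)
        points, corr, _ = equilibria_series(tabs, "A")
        s = np.array([p.strength for p in points])
        a, b = s[:-1], s[1:]
        expected = ((a - a.mean()) * (b - b.mean())).sum() / (
            np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        assert corr == pytest.approx(expected, rel=1e-12)

    def test_ar1_truth_recovered(self):
        """Ensemble-mean lag-1 correlation recovers the AR coefficient."""
        cs = []
        for k in range(10):
            tabs = fixtures.make_two_group_flow(
                4, 3, 0.3, 50, ar_coefficient=0.9, seed=100 + k
            )
            _, corr, _ = equilibria_series(tabs, "A")
            cs.append(corr + (1 + 4 * corr) / 49)  # small-sample bias correction
        assert np.mean(cs) == pytest.approx(0.9, abs=0.1)


class TestDiagonalCollapse:
    def test_points_collapse_on_diagonal(self):
        """(strength, x) pairs deviate from x = strength only at O(strength^2)."""
        consts = []
        for k, asym in enumerate((0.02, 0.05, 0.1, 0.2)):
            tb = fixtures.make_two_group_flow(4, 3, 0.3, 1, seed=60 + k, asymmetry=asym)[0]
            res = group_vs_rest(tb, "A")
            consts.append(abs(res.x_eq - res.strength) / res.strength**2)
        assert max(consts) < 2.0  # uniformly bounded quadratic constant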