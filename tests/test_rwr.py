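"""Diffusion engine: transition matrix contract, RWR oracle equivalence, aggregation."""

import numpy as np
import pytest

from conftest import make_network

from omicsplex import (
    DrugGeneBipartite,
    RunConfig,
    aggregate_proximity,
    build_mh_network,
    build_multiplex,
    build_similarity_matrix,
    build_transition_matrix,
    layer_contribution,
    random_mh_network,
    rwr_from_seed,
    seed_profile,
    tiny_mh_example,
)

# stationary vector of the tiny fixture (r=0.5), solved once from
# (I - (1-r)H) p = r p_RS with the hand-enumerated H
TINY_STATIONARY = np.array(
    [
        0.323795551222, 0.051420826866, 0.018075118421, 0.001663930723,
        0.323258799376, 0.012855206717, 0.046590060250, 0.006655722893,
        0.215684783532,
    ]
)


def solve_stationary(T, sp, r):
    """Independent linear-system oracle for the stationary distribution."""
    H = T.H.toarray()
    n = H.shape[0]
    return np.linalg.solve(np.eye(n) - (1 - r) * H, r * sp.p_rs)


class TestTransitionMatrix:
    def test_tiny_fixture_matches_hand_enumeration(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam, cfg.weighted)
        expected = np.zeros((9, 9))
        cols = {
            0: {1: 0.25, 4: 0.25, 8: 0.5},   # G1@alpha: drug half, G2 and G1@beta quarter each
            1: {0: 0.25, 2: 0.25, 5: 0.5},   # G2@alpha
            2: {1: 0.5, 6: 0.5},             # G3@alpha
            3: {7: 1.0},                     # G4 isolated in alpha -> all mass to its beta twin
            4: {6: 0.25, 0: 0.25, 8: 0.5},   # G1@beta
            5: {1: 1.0},                     # G2 isolated in beta
            6: {4: 0.25, 7: 0.25, 2: 0.5},   # G3@beta
            7: {6: 0.5, 3: 0.5},             # G4@beta
            8: {0: 0.25, 4: 0.25, 8: 0.5},   # drug D1: targets G1 in both layers + self-loop
        }
        for j, col in cols.items():
            for i, v in col.items():
                expected[i, j] = v
        np.testing.assert_allclose(T.H.toarray(), expected, atol=1e-15)

    @pytest.mark.parametrize("delta", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_columns_stochastic_across_parameter_grid(self, delta, lam):
        rng = np.random.default_rng(hash((delta, lam)) % 2**31)
        for _ in range(3):
            mh = random_mh_network(rng)
            T = build_transition_matrix(mh, delta, lam, weighted=bool(rng.random() < 0.5))
            np.testing.assert_allclose(
                np.asarray(T.H.sum(axis=0)).ravel(), 1.0, atol=1e-12
            )

    def test_isolated_projection_redirects_to_interlayer_twin(self):
        l1 = make_network("l1", ["A", "B"], [("A", "B")])
        l2 = make_network("l2", ["A", "B"], [])
        mh = build_mh_network(build_multiplex([l1, l2]), DrugGeneBipartite(frozenset()))
        T = build_transition_matrix(mh, 0.5, 0.5)
        col = T.H.toarray()[:, T.node_index(("A", 1))]  # A isolated in layer 2
        assert col[T.node_index(("A", 0))] == pytest.approx(1.0)

    def test_fully_isolated_node_becomes_self_loop(self):
        mh = build_mh_network(
            build_multiplex([make_network("l1", ["A"], [])]), DrugGeneBipartite(frozenset())
        )
        T = build_transition_matrix(mh, 0.5, 0.5)
        assert T.H.toarray()[0, 0] == pytest.approx(1.0)

    def test_parameters_out_of_range_rejected(self, tiny):
        mh, _ = tiny
        with pytest.raises(ValueError):
            build_transition_matrix(mh, 1.5, 0.5)
        with pytest.raises(ValueError):
            build_transition_matrix(mh, 0.5, -0.1)


class TestRWR:
    def test_restart_probability_one_returns_restart_vector(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        sp = seed_profile(T, "G2")
        pv = rwr_from_seed(T, sp, r=1.0)
        np.testing.assert_array_equal(pv.p, sp.p_rs)

    def test_two_node_closed_form(self):
        mh = build_mh_network(
            build_multiplex([make_network("l", ["A", "B"], [("A", "B")])]),
            DrugGeneBipartite(frozenset()),
        )
        T = build_transition_matrix(mh, 0.5, 0.5)
        pv = rwr_from_seed(T, seed_profile(T, "A"), r=0.5)
        np.testing.assert_allclose(pv.p, [2 / 3, 1 / 3], atol=1e-9)

    def test_tiny_fixture_reproduces_pinned_stationary_vector(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        pv = rwr_from_seed(T, seed_profile(T, "G1"), cfg.r, cfg.tol, cfg.max_iter)
        assert pv.converged
        np.testing.assert_allclose(pv.p, TINY_STATIONARY, atol=1e-8)
        # and the pinned vector is a genuine fixed point of the recursion
        residual = (1 - cfg.r) * (T.H @ TINY_STATIONARY) + cfg.r * seed_profile(T, "G1").p_rs
        np.testing.assert_allclose(residual, TINY_STATIONARY, atol=1e-10)

    def test_power_iteration_matches_linear_solve_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            mh = random_mh_network(rng)
            T = build_transition_matrix(mh, rng.uniform(0, 1), rng.uniform(0, 1))
            nodes = list(T.genes) + list(T.drugs)
            seed = nodes[int(rng.integers(len(nodes)))]
            sp = seed_profile(T, seed)
            r = rng.uniform(0.1, 0.9)
            pv = rwr_from_seed(T, sp, r, tol=1e-12, max_iter=5000)
            np.testing.assert_allclose(pv.p, solve_stationary(T, sp, r), atol=1e-8)
            assert pv.p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_probability_mass_conserved_each_iterate(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        sp = seed_profile(T, "G3")
        p = sp.p_rs.copy()
        for _ in range(10):
            p = 0.4 * (T.H @ p) + 0.6 * sp.p_rs
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_seed_mass_non_decreasing_as_r_grows(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        sp = seed_profile(T, "G1")
        masses = []
        for r in (0.2, 0.5, 0.8, 0.95):
            pv = rwr_from_seed(T, sp, r)
            agg = aggregate_proximity(pv, T, "sum")
            masses.append(agg[T.genes.index("G1")])
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))

    def test_drug_seed_restarts_at_drug_node(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        sp = seed_profile(T, "D1")
        assert sp.p_rs[T.node_index("D1")] == 1.0


class TestAggregation:
    def make_T(self):
        l1 = make_network("l1", ["A", "B"], [("A", "B")])
        l2 = make_network("l2", ["A", "B"], [])
        mh = build_mh_network(build_multiplex([l1, l2]), DrugGeneBipartite(frozenset()))
        return build_transition_matrix(mh, 0.5, 0.5)

    def test_geometric_mean_of_layer_values(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        from omicsplex.rwr import ProximityVector

        p = np.zeros(9)
        p[T.node_index(("G1", 0))] = 0.1
        p[T.node_index(("G1", 1))] = 0.4
        p[T.node_index("D1")] = 0.5
        agg = aggregate_proximity(ProximityVector("x", p, 1, True), T, "geometric")
        # sqrt(0.1 * 0.4) = 0.2 before rescaling; drug passes through
        assert agg[T.genes.index("G1")] == pytest.approx(0.2 / 0.7)
        assert agg[-1] == pytest.approx(0.5 / 0.7)

    def test_geometric_annihilates_on_any_zero_layer(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        from omicsplex.rwr import ProximityVector

        p = np.zeros(9)
        p[T.node_index(("G2", 0))] = 0.3
        p[T.node_index("D1")] = 0.7
        agg = aggregate_proximity(ProximityVector("x", p, 1, True), T, "geometric")
        assert agg[T.genes.index("G2")] == 0.0

    def test_sum_aggregation_equals_manual_collapse(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        pv = rwr_from_seed(T, seed_profile(T, "G1"), cfg.r)
        agg = aggregate_proximity(pv, T, "sum")
        manual = np.array(
            [pv.p[[T.node_index((g, a)) for a in range(2)]].sum() for g in T.genes]
            + [pv.p[T.node_index("D1")]]
        )
        np.testing.assert_allclose(agg, manual / manual.sum(), atol=1e-12)

    def test_aggregated_vector_sums_to_one(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        pv = rwr_from_seed(T, seed_profile(T, "G3"), 0.7)
        for method in ("geometric", "arithmetic", "sum"):
            assert aggregate_proximity(pv, T, method).sum() == pytest.approx(1.0)

    def test_unknown_method_rejected(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        pv = rwr_from_seed(T, seed_profile(T, "G1"), 0.7)
        with pytest.raises(ValueError):
            aggregate_proximity(pv, T, "harmonic")


class TestSimilarityMatrix:
    def test_dimensions_and_column_sums(self, tiny):
        mh, cfg = tiny
        S = build_similarity_matrix(mh, cfg)
        assert S.values.shape == (5, 5)  # 4 genes + 1 drug
        np.testing.assert_allclose(S.values.sum(axis=0), 1.0, atol=1e-9)
        assert (S.values >= 0).all()

    def test_equals_seed_by_seed_composition(self, tiny):
        mh, cfg = tiny
        S = build_similarity_matrix(mh, cfg)
        T = build_transition_matrix(mh, cfg.delta, cfg.lam, cfg.weighted)
        for node in S.nodes:
            pv = rwr_from_seed(T, seed_profile(T, node), cfg.r, cfg.tol, cfg.max_iter)
            np.testing.assert_allclose(
                S.column(node), aggregate_proximity(pv, T, cfg.aggregation), atol=1e-12
            )

    def test_deterministic_across_reruns(self, tiny):
        mh, cfg = tiny
        a = build_similarity_matrix(mh, cfg)
        b = build_similarity_matrix(mh, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_stable_under_small_parameter_perturbation(self, tiny):
        mh, cfg = tiny
        base = build_similarity_matrix(mh, cfg)
        for ddelta, dlam in ((0.1, 0.0), (-0.1, 0.0), (0.0, 0.1), (0.0, -0.1)):
            cfg2 = RunConfig(
                r=cfg.r, delta=cfg.delta + ddelta, lam=cfg.lam + dlam,
                aggregation=cfg.aggregation,
            )
            pert = build_similarity_matrix(mh, cfg2)
            l1 = np.abs(pert.values - base.values).sum(axis=0)
            assert l1.max() < 0.5  # bounded drift per column under +-0.1 changes

    def test_similarity_round_trip_hdf5(self, tiny, tmp_path):
        from omicsplex.rwr import read_similarity, write_similarity

        mh, cfg = tiny
        S = build_similarity_matrix(mh, cfg)
        write_similarity(S, tmp_path / "s.h5", tmp_path / "nodes.tsv")
        back = read_similarity(tmp_path / "s.h5", tmp_path / "nodes.tsv")
        np.testing.assert_array_equal(back.values, S.values)
        assert [str(n) for n in S.nodes] == back.nodes


class TestLayerContribution:
    def test_fractions_sum_to_one_and_match_renormalization(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        pv = rwr_from_seed(T, seed_profile(T, "G1"), cfg.r)
        frac = layer_contribution(pv, T, "G3")
        assert frac.sum() == pytest.approx(1.0)
        raw = pv.p[[T.node_index(("G3", a)) for a in range(2)]]
        np.testing.assert_allclose(frac, raw / raw.sum(), atol=1e-12)

    def test_equal_layer_values_give_uniform_fractions(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        from omicsplex.rwr import ProximityVector

        p = np.zeros(9)
        p[T.node_index(("G4", 0))] = 0.5
        p[T.node_index(("G4", 1))] = 0.5
        frac = layer_contribution(ProximityVector("x", p, 1, True), T, "G4")
        np.testing.assert_allclose(frac, [0.5, 0.5])

    def test_single_layer_concentration(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        from omicsplex.rwr import ProximityVector

        p = np.zeros(9)
        p[T.node_index(("G4", 1))] = 1.0
        frac = layer_contribution(ProximityVector("x", p, 1, True), T, "G4")
        np.testing.assert_allclose(frac, [0.0, 1.0])

    def test_drug_target_rejected(self, tiny):
        mh, cfg = tiny
        T = build_transition_matrix(mh, cfg.delta, cfg.lam)
        pv = rwr_from_seed(T, seed_profile(T, "G1"), cfg.r)
        with pytest.raises(ValueError, match="gene targets only"):
            layer_contribution(pv, T, "D1")
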