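import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedwalk import (
    CommunitySet,
    Network,
    WalkParams,
    belonging_probabilities,
    conditional_community_probability,
    expand_communities,
    membership_prior,
    stationary_distribution,
    walk_matrix,
)
from seedwalk.expansion import ConvergenceError
from seedwalk.seeding import SeedCommunity

from conftest import clique_edges


def random_walk_instance(rng):
    m = rng.integers(2, 21)
    M = rng.random((m, m))
    np.fill_diagonal(M, 0.0)
    M /= M.sum(axis=1, keepdims=True)
    d = rng.random(m)
    d /= d.sum()
    s0 = rng.random(m)
    s0 /= s0.sum()
    return M, d, s0


class TestStationaryDistribution:
    def test_alpha_one_returns_restart_vector(self):
        rng = np.random.default_rng(0)
        M, d, s0 = random_walk_instance(rng)
        pi = stationary_distribution(M, d, s0, WalkParams(alpha=1.0))
        np.testing.assert_allclose(pi, d, atol=1e-9)

    def test_triangle_uniform(self, triangle):
        M = walk_matrix(triangle, ["a", "b", "c"])
        d = np.full(3, 1 / 3)
        pi = stationary_distribution(M, d, d)
        np.testing.assert_allclose(pi, d, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_linear_solve_oracle(self, seed):
        # oracle: pi solves (I - (1 - alpha) M^T) pi = alpha d directly
        rng = np.random.default_rng(seed)
        M, d, s0 = random_walk_instance(rng)
        params = WalkParams()
        pi = stationary_distribution(M, d, s0, params)
        m = len(d)
        direct = np.linalg.solve(
            np.eye(m) - (1 - params.alpha) * M.T, params.alpha * d
        )
        np.testing.assert_allclose(pi, direct, atol=1e-8)
        assert np.all(pi >= 0)
        assert pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_start_vector_does_not_matter(self):
        rng = np.random.default_rng(3)
        M, d, s0 = random_walk_instance(rng)
        other = np.zeros_like(s0)
        other[0] = 1.0
        np.testing.assert_allclose(
            stationary_distribution(M, d, s0),
            stationary_distribution(M, d, other),
            atol=1e-8,
        )

    def test_nonconvergence_raises(self):
        rng = np.random.default_rng(1)
        M, d, s0 = random_walk_instance(rng)
        with pytest.raises(ConvergenceError, match="residual"):
            stationary_distribution(M, d, s0, WalkParams(tol=1e-16, max_iter=2))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.eye(3), np.ones(2) / 2, np.ones(3) / 3)


class TestWalkParams:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 0.0}, {"alpha": 1.5}, {"tol": 0.0}, {"max_iter": 0}]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            WalkParams(**kwargs)

    def test_defaults(self):
        wp = WalkParams()
        assert wp.alpha == 0.15
        assert wp.tol == 1e-10
        assert wp.max_iter == 1000


class TestConditionalCommunityProbability:
    def test_uniform_two_communities(self):
        V = ["a", "b", "c", "d"]
        cs = CommunitySet([{"a", "b"}, {"c", "d"}])
        out = conditional_community_probability(np.full(4, 0.25), cs, V)
        np.testing.assert_allclose(out, [0.25, 0.25])

    def test_single_community_mean(self):
        V = ["a", "b", "c", "d"]
        cs = CommunitySet([set(V)])
        out = conditional_community_probability(np.full(4, 0.25), cs, V)
        np.testing.assert_allclose(out, [0.25])

    def test_concentrated_mass(self):
        V = ["a", "b", "c", "d"]
        cs = CommunitySet([{"a", "b"}, {"c", "d"}])
        out = conditional_community_probability(
            np.array([0.5, 0.5, 0.0, 0.0]), cs, V
        )
        np.testing.assert_allclose(out, [0.5, 0.0])

    def test_member_missing_from_v(self):
        cs = CommunitySet([{"a", "zz"}])
        with pytest.raises(ValueError, match="zz"):
            conditional_community_probability(np.array([1.0]), cs, ["a"])


class TestMembershipPrior:
    def test_mirror_symmetry(self, two_cliques4):
        # u bridges two mirror-image cliques
        net = Network(
            edges=list(two_cliques4.edges()) + [("u", "a1"), ("u", "b1")]
        )
        cs = CommunitySet([{f"a{i}" for i in range(4)}, {f"b{i}" for i in range(4)}])
        np.testing.assert_allclose(membership_prior(net, "u", cs), [0.5, 0.5])

    def test_zero_similarity_uniform(self):
        net = Network(edges=[("a", "b"), ("c", "d"), ("u", "x")])
        cs = CommunitySet([{"a", "b"}, {"c", "d"}])
        np.testing.assert_allclose(membership_prior(net, "u", cs), [0.5, 0.5])

    def test_hand_computed_path(self):
        # u-a-b path; communities {a}, {b}
        net = Network(edges=[("u", "a"), ("a", "b")])
        cs = CommunitySet([{"a"}, {"b"}])
        # Similar(u,a) = |{u,a}| / |{u,a,b}| = 2/3; Similar(u,b) = 1/3
        expected = np.array([2 / 3, 1 / 3])
        expected /= expected.sum()
        np.testing.assert_allclose(membership_prior(net, "u", cs), expected)

    def test_member_rejected(self, triangle):
        cs = CommunitySet([{"a", "b"}])
        with pytest.raises(ValueError):
            membership_prior(triangle, "a", cs)


class TestBelongingProbabilities:
    def test_single_community_is_certain(self, two_cliques4):
        cs = CommunitySet([{"a0", "a1", "a2"}])
        pt = belonging_probabilities(two_cliques4, "b1", cs)
        np.testing.assert_allclose(pt.pu, [1.0])

    def test_barbell_midpoint_symmetric(self):
        a = [f"a{i}" for i in range(3)]
        b = [f"b{i}" for i in range(3)]
        net = Network(
            edges=clique_edges(a) + clique_edges(b) + [("a0", "m"), ("m", "b0")]
        )
        cs = CommunitySet([set(a), set(b)])
        pt = belonging_probabilities(net, "m", cs)
        np.testing.assert_allclose(pt.pu, [0.5, 0.5], atol=1e-9)

    def test_two_cliques_argmax(self, two_cliques4):
        # u = a1 (removed from its clique); seeds are triangles
        cs = CommunitySet([{"a0", "a2", "a3"}, {"b0", "b1", "b2"}])
        pt = belonging_probabilities(two_cliques4, "a1", cs)
        assert pt.pu[0] > pt.pu[1]
        assert pt.pu.sum() == pytest.approx(1.0)
        assert pt.PC.shape == (2, 2)
        np.testing.assert_allclose(pt.PC.sum(axis=1), 1.0)
        assert pt.PP.sum() == pytest.approx(1.0)

    def test_permutation_equivariance(self, two_cliques4):
        cs = CommunitySet([{"a0", "a2", "a3"}, {"b0", "b1", "b2"}])
        flipped = CommunitySet([{"b0", "b1", "b2"}, {"a0", "a2", "a3"}])
        pu = belonging_probabilities(two_cliques4, "a1", cs).pu
        pu_f = belonging_probabilities(two_cliques4, "a1", flipped).pu
        np.testing.assert_allclose(pu, pu_f[::-1], atol=1e-12)

    def test_assigned_node_rejected(self, two_cliques4):
        cs = CommunitySet([{"a0", "a1", "a2"}])
        with pytest.raises(ValueError):
            belonging_probabilities(two_cliques4, "a1", cs)


def _seed(members, anchor):
    return SeedCommunity(members=frozenset(members), anchor=anchor)


class TestExpandCommunities:
    def test_fully_covered_is_identity(self, triangle):
        cs = CommunitySet([{"a", "b", "c"}])
        out = expand_communities(triangle, cs)
        assert out.communities == [{"a", "b", "c"}]

    @pytest.mark.parametrize("mode", ["assign_unique", "overlapping"])
    def test_two_cliques_recovered(self, two_cliques4, mode):
        seeds = [_seed(["a0", "a1", "a2"], "a0"), _seed(["b0", "b1", "b2"], "b0")]
        out = expand_communities(two_cliques4, seeds, mode=mode)
        assert {frozenset(c) for c in out} == {
            frozenset({"a0", "a1", "a2", "a3"}),
            frozenset({"b0", "b1", "b2", "b3"}),
        }

    def test_deterministic(self, two_cliques5):
        seeds = [_seed(["a0", "a1", "a2"], "a0"), _seed(["b0", "b1", "b2"], "b0")]
        a = expand_communities(two_cliques5, seeds)
        b = expand_communities(two_cliques5, seeds)
        assert a.communities == b.communities

    def test_monotone_one_node_per_round(self, two_cliques5):
        # sizes only grow, and the total grows by one per assignment
        seeds = [_seed(["a0", "a1", "a2"], "a0")]
        out = expand_communities(two_cliques5, seeds, mode="assign_unique")
        assert len(out[0]) == 10  # everything reachable joins the one community

    def test_unreachable_nodes_left_unassigned(self):
        net = Network(edges=[("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")])
        out = expand_communities(net, [_seed(["a", "b", "c"], "a")])
        assert out.members() == {"a", "b", "c"}

    def test_clique_union_respects_boundaries(self):
        cliques = [[f"c{k}_{i}" for i in range(5)] for k in range(3)]
        edges = [e for c in cliques for e in clique_edges(c)]
        net = Network(edges=edges)
        seeds = [_seed(c[:3], c[0]) for c in cliques]
        out = expand_communities(net, seeds, mode="assign_unique")
        assert [set(c) for c in out] == [set(c) for c in cliques]

    def test_bad_mode_rejected(self, triangle):
        with pytest.raises(ValueError):
            expand_communities(triangle, [_seed(["a", "b", "c"], "a")], mode="x")


class TestCommunitySet:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            CommunitySet([])
        with pytest.raises(ValueError):
            CommunitySet([set()])

    def test_members_union(self):
        cs = CommunitySet([{"a", "b"}, {"b", "c"}])
        assert cs.members() == {"a", "b", "c"}
        assert cs.q == 2
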