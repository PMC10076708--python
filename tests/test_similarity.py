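"""Similarity views against hand-worked values and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdgan.data import AssociationMatrix, DiseaseDAG, DiseaseGeneAnnotation, GeneNetwork
from mdgan.similarity import (
    build_heterogeneous_network,
    cosine_similarity,
    disease_functional_similarity,
    disease_semantic_similarity,
    fuse_views,
    gene_functional_score,
    gip_similarity,
    integrated_similarities,
    microbe_functional_similarity,
    semantic_contribution,
)

from conftest import random_association, random_dag

TOL = 1e-12


# ---------------------------------------------------------------- oracles


def gip_oracle(A: np.ndarray) -> np.ndarray:
    """Scalar loop re-evaluation of the GIP kernel definition."""
    n = A.shape[0]
    lam = 1.0 / (sum(float(A[i] @ A[i]) for i in range(n)) / n)
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = A[i] - A[j]
            S[i, j] = math.exp(-lam * float(diff @ diff))
    return S


def sc_oracle(dag: DiseaseDAG, dt: str) -> dict[str, float]:
    """Memo-free recursive semantic contribution."""
    V = dag.ancestors(dt)

    def rec(node):
        if node == dt:
            return 1.0
        return max(0.5 * rec(c) for c in dag.children(node) & V)

    return {node: rec(node) for node in V}


def dss_oracle(dag: DiseaseDAG, di: str, dj: str) -> float:
    sci, scj = sc_oracle(dag, di), sc_oracle(dag, dj)
    shared = set(sci) & set(scj)
    return sum(sci[d] + scj[d] for d in shared) / (sum(sci.values()) + sum(scj.values()))


# ---------------------------------------------------------- hand-worked


class TestGIP:
    def test_identity_association_off_diagonal(self, identity_am):
        """Unit bandwidth on the 2x2 identity pattern gives exp(-2)."""
        S = gip_similarity(identity_am, "disease").S
        assert S[0, 1] == pytest.approx(math.exp(-2), abs=TOL)

    def test_diagonal_is_one(self, small_am):
        for axis in ("disease", "microbe"):
            assert np.all(gip_similarity(small_am, axis).S.diagonal() == 1.0)

    def test_identical_profiles_similarity_one(self):
        am = AssociationMatrix(["d1", "d2"], ["m1", "m2"], np.ones((2, 2)))
        assert gip_similarity(am, "disease").S[0, 1] == pytest.approx(1.0, abs=TOL)

    def test_all_zero_matrix_rejected(self):
        am = AssociationMatrix(["d"], ["m"], np.zeros((1, 1)))
        with pytest.raises(ZeroDivisionError, match="bandwidth"):
            gip_similarity(am, "disease")

    def test_squared_norm_of_binary_rows_equals_row_sum(self, small_am):
        # the l2^2 / l1 coincidence the bandwidth relies on for binary profiles
        A = small_am.A
        np.testing.assert_array_equal((A**2).sum(1), A.sum(1))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 30), st.integers(2, 40))
    def test_matches_loop_oracle_on_random_instances(self, seed, nd, nm):
        am = random_association(np.random.default_rng(seed), nd, nm)
        S = gip_similarity(am, "disease").S
        np.testing.assert_allclose(S, gip_oracle(am.A), atol=TOL, rtol=0)


class TestCosine:
    def test_hand_value(self):
        am = AssociationMatrix(
            ["d1", "d2"], ["m1", "m2", "m3"], np.array([[1, 1, 0], [1, 0, 0]], float)
        )
        assert cosine_similarity(am, "disease").S[0, 1] == pytest.approx(
            1 / math.sqrt(2), abs=TOL
        )

    def test_identical_and_disjoint_profiles(self, small_am):
        S = cosine_similarity(small_am, "disease").S
        assert S[0, 2] == 0.0  # disjoint
        am = AssociationMatrix(["a", "b"], ["m1"], np.ones((2, 1)))
        assert cosine_similarity(am, "disease").S[0, 1] == pytest.approx(1.0, abs=TOL)

    def test_zero_profile_maps_to_zero_even_on_diagonal(self):
        am = AssociationMatrix(["d1", "d2"], ["m1"], np.array([[1.0], [0.0]]))
        S = cosine_similarity(am, "disease").S
        assert S[1, 1] == 0.0 and S[0, 1] == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_adding_shared_association_never_decreases_similarity(self, seed):
        """Cosine monotonicity under a new shared positive."""
        rng = np.random.default_rng(seed)
        am = random_association(rng, 6, 12)
        i, j = 0, 1
        before = cosine_similarity(am, "disease").S[i, j]
        zeros = np.nonzero((am.A[i] == 0) & (am.A[j] == 0))[0]
        if zeros.size == 0:
            return
        col = int(rng.choice(zeros))
        am.A[i, col] = am.A[j, col] = 1.0
        after = cosine_similarity(am, "disease").S[i, j]
        assert after >= before - TOL


class TestGeneFunctionalScore:
    def test_identity_pair_scores_one(self, two_gene_net):
        assert gene_functional_score("g1", "g1", two_gene_net) == 1.0

    def test_minmax_endpoints(self, two_gene_net):
        assert gene_functional_score("g1", "g2", two_gene_net) == pytest.approx(1.0, abs=TOL)
        assert gene_functional_score("g2", "g3", two_gene_net) == pytest.approx(0.0, abs=TOL)

    def test_non_adjacent_pair_scores_zero(self, two_gene_net):
        assert gene_functional_score("g1", "g3", two_gene_net) == 0.0

    def test_degenerate_range_rejected(self):
        net = GeneNetwork({frozenset(("a", "b")): 5.0, frozenset(("b", "c")): 5.0})
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            gene_functional_score("a", "b", net)


class TestDiseaseFunctionalSimilarity:
    def test_equal_gene_sets_score_one(self, two_gene_net):
        ann = DiseaseGeneAnnotation({"d1": frozenset({"g1", "g2"}), "d2": frozenset({"g1", "g2"})})
        S = disease_functional_similarity(ann, two_gene_net, ["d1", "d2"]).S
        assert S[0, 1] == pytest.approx(1.0, abs=TOL)

    def test_max_lls_bridge_scores_one(self, two_gene_net):
        ann = DiseaseGeneAnnotation({"d1": frozenset({"g1"}), "d2": frozenset({"g2"})})
        S = disease_functional_similarity(ann, two_gene_net, ["d1", "d2"]).S
        assert S[0, 1] == pytest.approx(1.0, abs=TOL)

    def test_non_adjacent_gene_sets_score_zero(self, two_gene_net):
        ann = DiseaseGeneAnnotation({"d1": frozenset({"g1"}), "d2": frozenset({"g3"})})
        S = disease_functional_similarity(ann, two_gene_net, ["d1", "d2"]).S
        assert S[0, 1] == 0.0

    def test_unannotated_disease_scores_zero_with_unit_diagonal(self, two_gene_net):
        ann = DiseaseGeneAnnotation({"d1": frozenset({"g1"})})
        with pytest.warns(UserWarning, match="without gene annotation"):
            S = disease_functional_similarity(ann, two_gene_net, ["d1", "dx"]).S
        assert S[0, 1] == 0.0 and S[1, 1] == 1.0


class TestSemantic:
    def test_self_contribution_and_parent_decay(self, sibling_dag):
        sc = semantic_contribution(sibling_dag, "b")
        assert sc["b"] == 1.0 and sc["r"] == 0.5

    def test_chain_with_shortcut_takes_best_path(self, chain_shortcut_dag):
        sc = semantic_contribution(chain_shortcut_dag, "dt")
        assert sc["r"] == pytest.approx(0.5, abs=TOL)
        assert sc["a"] == pytest.approx(0.5, abs=TOL)

    def test_missing_disease_rejected(self, sibling_dag):
        with pytest.raises(KeyError):
            semantic_contribution(sibling_dag, "nope")

    def test_self_similarity_is_one(self, chain_shortcut_dag):
        assert disease_semantic_similarity(chain_shortcut_dag, "dt", "dt") == pytest.approx(
            1.0, abs=TOL
        )

    def test_disjoint_roots_share_nothing(self):
        dag = DiseaseDAG(["r1", "r2", "x", "y"], {("r1", "x"), ("r2", "y")})
        assert disease_semantic_similarity(dag, "x", "y") == 0.0

    def test_sibling_similarity_is_one_third(self, sibling_dag):
        assert disease_semantic_similarity(sibling_dag, "b", "c") == pytest.approx(
            1 / 3, abs=TOL
        )

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 12))
    def test_matches_recursive_oracle_on_random_dags(self, seed, n_nodes):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, n_nodes)
        di, dj = rng.choice(dag.nodes, size=2, replace=False)
        assert semantic_contribution(dag, di) == pytest.approx(sc_oracle(dag, di), abs=TOL)
        assert disease_semantic_similarity(dag, di, dj) == pytest.approx(
            dss_oracle(dag, di, dj), abs=TOL
        )


class TestMicrobeFunctionalSimilarity:
    def test_equal_disease_sets_score_one(self, sibling_dag):
        am = AssociationMatrix(["b", "c"], ["m1", "m2"], np.ones((2, 2)))
        S = microbe_functional_similarity(am, sibling_dag).S
        assert S[0, 1] == pytest.approx(1.0, abs=TOL)

    def test_disjoint_dag_components_score_zero(self):
        dag = DiseaseDAG(["r1", "r2", "x", "y"], {("r1", "x"), ("r2", "y")})
        am = AssociationMatrix(["x", "y"], ["m1", "m2"], np.eye(2))
        assert microbe_functional_similarity(am, dag).S[0, 1] == 0.0

    def test_sibling_diseases_give_one_third(self, sibling_dag):
        am = AssociationMatrix(["b", "c"], ["m1", "m2"], np.eye(2))
        S = microbe_functional_similarity(am, sibling_dag).S
        assert S[0, 1] == pytest.approx(1 / 3, abs=TOL)

    def test_diseases_missing_from_dag_treated_as_isolated(self, sibling_dag):
        am = AssociationMatrix(["b", "zz"], ["m1", "m2"], np.eye(2))
        with pytest.warns(UserWarning, match="absent from DAG"):
            S = microbe_functional_similarity(am, sibling_dag).S
        assert S[0, 1] == 0.0 and S[0, 0] == 1.0

    def test_matches_elementwise_oracle_on_random_instances(self):
        """MFS equals a direct evaluation of the max-match formula."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            dag = random_dag(rng, 8)
            am = random_association(rng, 8, 6)
            am.diseases = list(dag.nodes)
            S = microbe_functional_similarity(am, dag).S
            for i in range(am.nm):
                for j in range(am.nm):
                    Di = [am.diseases[x] for x in np.nonzero(am.A[:, i])[0]]
                    Dj = [am.diseases[x] for x in np.nonzero(am.A[:, j])[0]]
                    if not Di or not Dj:
                        expect = 0.0
                    else:
                        expect = (
                            sum(max(dss_oracle(dag, d, e) for e in Di) for d in Dj)
                            + sum(max(dss_oracle(dag, d, e) for e in Dj) for d in Di)
                        ) / (len(Di) + len(Dj))
                    assert S[i, j] == pytest.approx(expect, abs=TOL)


class TestFusionAndNetwork:
    def test_mean_of_identical_views_is_identity_map(self, small_am):
        g = gip_similarity(small_am, "disease")
        np.testing.assert_allclose(fuse_views(g, g, g).S, g.S, atol=TOL)

    def test_elementwise_mean(self, small_am):
        import copy

        g = gip_similarity(small_am, "disease")
        a, b, c = copy.deepcopy(g), copy.deepcopy(g), copy.deepcopy(g)
        a.S, b.S, c.S = (np.full((3, 3), v) for v in (0.9, 0.6, 0.3))
        assert fuse_views(a, b, c).S[0, 0] == pytest.approx(0.6, abs=TOL)

    def test_subset_fusion_uses_available_views_only(self, small_am):
        g = gip_similarity(small_am, "disease")
        c = cosine_similarity(small_am, "disease")
        np.testing.assert_allclose(fuse_views(g, c).S, (g.S + c.S) / 2, atol=TOL)

    def test_mismatched_ids_rejected(self, small_am, identity_am):
        with pytest.raises(ValueError):
            fuse_views(
                gip_similarity(small_am, "disease"), gip_similarity(identity_am, "disease")
            )

    def test_fused_entries_within_view_envelope(self):
        rng = np.random.default_rng(3)
        am = random_association(rng, 10, 14)
        g, c = gip_similarity(am, "disease"), cosine_similarity(am, "disease")
        fused = fuse_views(g, c).S
        lo, hi = np.minimum(g.S, c.S), np.maximum(g.S, c.S)
        assert np.all(fused >= lo - TOL) and np.all(fused <= hi + TOL)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 30), st.integers(2, 40))
    def test_all_views_symmetric_on_random_matrices(self, seed, nd, nm):
        am = random_association(np.random.default_rng(seed), nd, nm)
        for axis in ("disease", "microbe"):
            for view in (gip_similarity(am, axis), cosine_similarity(am, axis)):
                np.testing.assert_allclose(view.S, view.S.T, atol=TOL, rtol=0)

    def test_block_placement_and_symmetry(self, small_am):
        DS, MS = integrated_similarities(small_am)
        net = build_heterogeneous_network(DS, MS, small_am)
        nd, nm = small_am.nd, small_am.nm
        assert net.Y.shape == (nd + nm, nd + nm)
        np.testing.assert_array_equal(net.Y[:nd, nd:], small_am.A)
        np.testing.assert_array_equal(net.Y[nd:, :nd], small_am.A.T)
        np.testing.assert_allclose(net.Y, net.Y.T, atol=TOL)

    def test_zero_association_block_makes_block_diagonal(self, small_am):
        DS, MS = integrated_similarities(small_am)
        zero = AssociationMatrix(small_am.diseases, small_am.microbes, np.zeros_like(small_am.A))
        net = build_heterogeneous_network(DS, MS, zero)
        assert np.all(net.Y[: small_am.nd, small_am.nd :] == 0)

    def test_dimension_mismatch_rejected(self, small_am, identity_am):
        DS, MS = integrated_similarities(identity_am)
        with pytest.raises(ValueError):
            build_heterogeneous_network(DS, MS, small_am)
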