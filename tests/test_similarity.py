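"""Classical and structure-aware partition-similarity measures."""

import math

import pytest

from filacover import (
    EdgePath,
    FilamentCover,
    FilacoverError,
    contingency_counts,
    edge_distance,
    jaccard_index,
    match_filaments,
    rand_index,
    variation_of_information,
)

from helpers import chain_graph


def labels(mapping):
    return {e: frozenset(ids) for e, ids in mapping.items()}


class TestEdgeDistance:
    def test_shared_node_distance_zero(self):
        g = chain_graph([0.5, 0.5])
        assert edge_distance(g, (0, 1), (1, 2)) == 0.0

    def test_identical_edge_distance_zero(self):
        g = chain_graph([0.5, 0.5])
        assert edge_distance(g, (0, 1), (0, 1)) == 0.0

    def test_chain_separation(self):
        g = chain_graph([0.5, 0.5, 0.5])  # a-b-c-d
        assert edge_distance(g, (0, 1), (2, 3)) == 1.0

    def test_disconnected_pair_is_inf(self):
        from filacover import FilamentGraph

        g = FilamentGraph.from_data(
            {0: (0, 0), 1: (1, 0), 2: (5, 5), 3: (6, 5)},
            [(0, 1, 0.5), (2, 3, 0.5)],
        )
        assert edge_distance(g, (0, 1), (2, 3)) == math.inf


class TestContingency:
    def test_identical_labellings(self):
        g = chain_graph([0.5, 0.5, 0.5])
        a = labels({(0, 1): {0}, (1, 2): {0}, (2, 3): {1}})
        h = contingency_counts(a, a, g, d=math.inf)
        assert h.same_diff == 0 and h.diff_same == 0
        assert h.total == 3

    def test_three_edge_chain_one_vs_singletons_d1(self):
        g = chain_graph([0.5, 0.5, 0.5])
        one = labels({(0, 1): {0}, (1, 2): {0}, (2, 3): {0}})
        sing = labels({(0, 1): {0}, (1, 2): {1}, (2, 3): {2}})
        h = contingency_counts(one, sing, g, d=1)
        assert (h.same_same, h.same_diff, h.diff_same, h.diff_diff) == (0, 2, 0, 0)
        assert rand_index(h) == 0.0 and jaccard_index(h) == 0.0

    def test_d_infinity_counts_all_pairs(self, scene):
        graph, truth = scene
        m = truth.edge_membership()
        h = contingency_counts(m, m, graph, d=math.inf)
        n = graph.n_edges
        assert h.total == n * (n - 1) // 2

    def test_admissible_pairs_monotone_in_d(self, scene):
        graph, truth = scene
        m = truth.edge_membership()
        totals = [contingency_counts(m, m, graph, d).total for d in (1, 2, 4, math.inf)]
        assert totals == sorted(totals)

    def test_large_d_equals_classical(self, scene, scene_cover):
        graph, truth = scene
        a, b = scene_cover.edge_membership(), truth.edge_membership()
        h_inf = contingency_counts(a, b, graph, d=math.inf)
        h_big = contingency_counts(a, b, graph, d=graph.n_nodes + 1)
        assert rand_index(h_big) == rand_index(h_inf)
        assert jaccard_index(h_big) == jaccard_index(h_inf)

    def test_symmetry(self, scene, scene_cover):
        graph, truth = scene
        a, b = scene_cover.edge_membership(), truth.edge_membership()
        for d in (1, math.inf):
            h = contingency_counts(a, b, graph, d)
            hs = contingency_counts(b, a, graph, d)
            assert rand_index(h) == pytest.approx(rand_index(hs))
            assert jaccard_index(h) == pytest.approx(jaccard_index(hs))

    def test_relabelling_invariance(self, rng):
        g = chain_graph([0.5] * 5)
        edges = list(g.edges)
        ids = rng.integers(0, 3, size=len(edges))
        a = labels({e: {int(i)} for e, i in zip(edges, ids)})
        perm = {0: 7, 1: 5, 2: 9}
        b = labels({e: {perm[int(i)]} for e, i in zip(edges, ids)})
        h = contingency_counts(a, b, g, d=1)
        assert rand_index(h) == 1.0 and jaccard_index(h) == 1.0


class TestVariationOfInformation:
    def test_identical_exact_covers_zero(self):
        a = labels({(0, 1): {0}, (1, 2): {0}, (2, 3): {1}})
        assert variation_of_information(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_block_split_closed_form(self):
        # one 4-edge block vs two 2-edge blocks: VI = ln 2
        edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
        a = labels({e: {0} for e in edges})
        b = labels({edges[0]: {0}, edges[1]: {0}, edges[2]: {1}, edges[3]: {1}})
        assert variation_of_information(a, b) == pytest.approx(math.log(2))

    def test_overlapping_cover_rejected(self):
        a = labels({(0, 1): {0, 1}, (1, 2): {1}})
        b = labels({(0, 1): {0}, (1, 2): {1}})
        with pytest.raises(FilacoverError, match="overlapping"):
            variation_of_information(a, b)


class TestMatchFilaments:
    def test_identity(self, scene):
        _, truth = scene
        mapping = match_filaments(truth, truth)
        assert mapping == {i: i for i in range(truth.n_filaments)}

    def test_two_by_two_assignment(self):
        g = chain_graph([0.5] * 6)
        # shared-edge matrix [[3, 1], [0, 2]] -> matching (0,0), (1,1), value 5
        a = FilamentCover((EdgePath((0, 1, 2, 3, 4)), EdgePath((4, 5, 6))))
        b = FilamentCover((EdgePath((0, 1, 2, 3)), EdgePath((3, 4, 5, 6))))
        mapping = match_filaments(a, b)
        assert mapping == {0: 0, 1: 1}

    def test_rectangular_surplus_unmatched(self):
        g = chain_graph([0.5] * 3)
        a = FilamentCover((EdgePath((0, 1, 2, 3)),))
        b = FilamentCover((EdgePath((0, 1)), EdgePath((1, 2)), EdgePath((2, 3))))
        mapping = match_filaments(a, b)
        assert len(mapping) == 1 and 0 in mapping
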