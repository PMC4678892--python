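"""Planted scene generation and the robustness protocols."""

import numpy as np
import pytest

from filacover import (
    CoverOptions,
    SceneParams,
    add_weight_noise,
    contrived_scene,
    edge_removal_curve,
    generate_scene,
    max_deflection_angle,
    noise_robustness_curve,
    remove_random_edges,
)
from filacover.synthetic import assemble_scene


class TestAssembleScene:
    def test_two_crossing_straight_filaments_make_an_x(self, rng):
        # constructive geometry: the crossing splits both segments
        a = np.array([[0.0, 0.0], [2.0, 0.0]])
        b = np.array([[1.0, -1.0], [1.0, 1.0]])
        graph, cover = assemble_scene([a, b], [0.8, 0.5], 0.0, rng)
        assert graph.n_nodes == 5 and graph.n_edges == 4
        assert cover.n_filaments == 2
        assert all(p.n_edges == 2 for p in cover.paths)

    def test_exact_vertex_runs_become_shared_edges(self, rng):
        host = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        over = np.array([[0.3, -0.7], [1.0, 0.0], [2.0, 0.0], [2.7, 0.7]])
        graph, cover = assemble_scene([host, over], [0.8, 0.7], 0.0, rng)
        shared = [e for e, s in cover.edge_membership().items() if len(s) == 2]
        assert len(shared) == 1  # the copied run (1,0)-(2,0)

    def test_single_loop(self, rng):
        m = 9
        ang = 2 * np.pi * np.arange(m + 1) / m
        poly = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        graph, cover = assemble_scene([poly], [0.8], 0.0, rng)
        assert cover.n_filaments == 1 and cover.paths[0].is_closed
        assert graph.n_edges == m


class TestGenerateScene:
    def test_planted_cover_valid_and_angle_bounded(self):
        params = SceneParams(n_filaments=6, p_overlap=0.3, p_loop=0.3, seed=5)
        graph, cover = generate_scene(params)
        cover.validate_against(graph)
        assert set(cover.edge_membership()) == set(graph.edges)
        for p in cover.paths:
            assert max_deflection_angle(p, graph) < params.turn_max_deg

    def test_reproducible_from_seed(self):
        params = SceneParams(seed=9)
        g1, c1 = generate_scene(params)
        g2, c2 = generate_scene(params)
        assert [p.nodes for p in c1.paths] == [p.nodes for p in c2.paths]
        for e in g1.edges:
            assert g1.weight(*e) == g2.weight(*e)

    def test_loop_probability_one_yields_closed_filament(self):
        params = SceneParams(n_filaments=1, p_loop=1.0, seed=2)
        _, cover = generate_scene(params)
        assert cover.paths[0].is_closed

    def test_contrived_scene_features(self, scene):
        graph, truth = scene
        memberships = truth.edge_membership()
        assert any(len(s) > 1 for s in memberships.values())  # overlap
        assert any(p.is_closed for p in truth.paths)  # loop
        # crossing: a node of degree 4 shared by two filaments
        degrees = dict(graph.graph.degree)
        assert max(degrees.values()) >= 4


class TestWeightNoise:
    def test_zero_sd_identity(self, scene):
        graph, _ = scene
        noisy = add_weight_noise(graph, 0.0, seed=1)
        for e in graph.edges:
            assert noisy.weight(*e) == graph.weight(*e)

    def test_topology_and_positions_untouched(self, scene):
        graph, _ = scene
        noisy = add_weight_noise(graph, 0.5, seed=1)
        assert set(noisy.edges) == set(graph.edges)
        for n in graph.graph.nodes:
            assert np.array_equal(noisy.position(n), graph.position(n))

    def test_noise_is_centred(self):
        # CLT check: the mean perturbed weight stays within 3 standard errors
        from filacover import FilamentGraph

        g = FilamentGraph.from_data(
            {0: (0, 0), 1: (1, 0)}, [(0, 1, 0.5)]
        )
        sd = 0.1
        draws = [
            add_weight_noise(g, sd, seed=k).weight(0, 1) for k in range(1000)
        ]
        se = sd * 0.5 / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 0.5) < 3 * se


class TestEdgeRemoval:
    def test_k_zero_identity(self, scene):
        graph, _ = scene
        out = remove_random_edges(graph, 0, seed=0)
        assert set(out.edges) == set(graph.edges)

    def test_edge_count_reduced(self, scene):
        graph, _ = scene
        out = remove_random_edges(graph, 3, seed=0)
        assert out.n_edges == graph.n_edges - 3
        assert out.n_nodes == graph.n_nodes  # isolated nodes retained

    def test_k_out_of_range_rejected(self, scene):
        graph, _ = scene
        with pytest.raises(ValueError):
            remove_random_edges(graph, graph.n_edges, seed=0)

    def test_every_single_edge_variant_reachable(self):
        from filacover import FilamentGraph

        g = FilamentGraph.from_data(
            {0: (0, 0), 1: (1, 0), 2: (2, 0)}, [(0, 1, 0.5), (1, 2, 0.5)]
        )
        removed = {
            tuple(sorted(set(g.edges) - set(remove_random_edges(g, 1, seed=k).edges)))
            for k in range(20)
        }
        assert removed == {((0, 1),), ((1, 2),)}


class TestRobustnessCurves:
    def test_removal_baseline_row(self, scene):
        graph, truth = scene
        tbl = edge_removal_curve(
            graph, truth, CoverOptions(), k_max=2, samples_per_k=2, seed=0
        )
        assert tbl.loc[0, "k"] == 0
        assert 0.0 <= tbl["mean_ji1"].min() <= tbl["mean_ji1"].max() <= 1.0

    def test_noise_zero_level_matches_noiseless(self, scene):
        graph, truth = scene
        tbl = noise_robustness_curve(
            graph, truth, CoverOptions(), sd_levels=(0.0,), n_instances=3, seed=0
        )
        base = noise_robustness_curve(
            graph, truth, CoverOptions(), sd_levels=(0.0,), n_instances=1, seed=99
        )
        assert tbl.loc[0, "mean_ji1"] == base.loc[0, "mean_ji1"]
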