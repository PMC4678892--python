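"""Graph/path/cover data model and GML/CSV round trips."""

import numpy as np
import pytest

from filacover import (
    CoverOptions,
    EdgePath,
    FilamentCover,
    FilamentGraph,
    GMLFormatError,
    GraphValidationError,
    read_gml,
    write_cover_gml,
    write_filament_csv,
)
from filacover.analytics import filament_metrics
from filacover.core_model import read_cover_gml

from helpers import chain_graph

MINIMAL_GML = """graph [
  node [ id 0 x 0.0 y 0.0 ]
  node [ id 1 x 1.0 y 0.0 ]
  edge [ source 0 target 1 weight 0.5 ]
]
"""

GRAPHICS_GML = """graph [
  node [ id 0 graphics [ x 0.0 y 0.0 ] ]
  node [ id 1 graphics [ x 1.0 y 2.0 ] ]
  edge [ source 0 target 1 weight 0.25 ]
]
"""


class TestReadGML:
    def test_minimal_wellformed(self, tmp_path):
        f = tmp_path / "g.gml"
        f.write_text(MINIMAL_GML)
        g = read_gml(f)
        assert g.n_nodes == 2 and g.n_edges == 1
        assert g.weight(0, 1) == 0.5
        assert np.allclose(g.position(1), [1.0, 0.0])

    def test_graphics_block_coordinates(self, tmp_path):
        f = tmp_path / "g.gml"
        f.write_text(GRAPHICS_GML)
        g = read_gml(f)
        assert np.allclose(g.position(1), [1.0, 2.0])

    def test_missing_weight_is_format_error(self, tmp_path):
        f = tmp_path / "g.gml"
        f.write_text(MINIMAL_GML.replace("weight 0.5 ", ""))
        with pytest.raises(GMLFormatError, match="weight"):
            read_gml(f)

    def test_missing_coordinates_is_format_error(self, tmp_path):
        f = tmp_path / "g.gml"
        f.write_text(MINIMAL_GML.replace("x 1.0 y 0.0 ", ""))
        with pytest.raises(GMLFormatError, match="coordinates"):
            read_gml(f)

    def test_self_loop_rejected(self, tmp_path):
        f = tmp_path / "g.gml"
        f.write_text(MINIMAL_GML.replace("source 0 target 1", "source 0 target 0"))
        with pytest.raises(GraphValidationError, match="self-loop"):
            read_gml(f)

    def test_nonpositive_weight_rejected(self, tmp_path):
        f = tmp_path / "g.gml"
        f.write_text(MINIMAL_GML.replace("weight 0.5", "weight -1.0"))
        with pytest.raises(GraphValidationError, match="not positive"):
            read_gml(f)


class TestEdgePath:
    def test_single_edge_and_closed_loop_allowed(self):
        assert EdgePath((0, 1)).n_edges == 1
        loop = EdgePath((0, 1, 2, 0))
        assert loop.is_closed and loop.n_edges == 3

    def test_repeated_edge_rejected(self):
        with pytest.raises(GraphValidationError, match="repeated"):
            EdgePath((0, 1, 0, 1))

    def test_self_loop_step_rejected(self):
        with pytest.raises(GraphValidationError):
            EdgePath((0, 0))


class TestWriteCoverGML:
    def test_overlapping_edge_lists_both_ids_sorted(self, tmp_path):
        g = chain_graph([0.5, 0.5, 0.5])
        # filament 0 covers edges (1,2),(2,3); filament 2 covers (0,1),(1,2)
        cover = FilamentCover((EdgePath((1, 2, 3)), EdgePath((3, 2)),
                               EdgePath((0, 1, 2))))
        out = tmp_path / "c.gml"
        write_cover_gml(g, cover, out)
        text = out.read_text()
        assert 'filaments "0;1;2"' in text or 'filaments "0;1"' in text
        g2, c2 = read_cover_gml(out)
        members = c2.edge_membership()
        assert len(members[(1, 2)]) >= 2

    def test_exact_cover_single_id_per_edge(self, tmp_path, scene):
        from filacover import solve_fcp

        graph, _ = scene
        cover = solve_fcp(graph, CoverOptions(cover="exact"))
        out = tmp_path / "exact.gml"
        write_cover_gml(graph, cover, out)
        _, c2 = read_cover_gml(out)
        assert all(len(s) == 1 for s in c2.edge_membership().values())

    def test_planted_overlap_edges_carry_both_ids(self, tmp_path, scene):
        graph, truth = scene
        out = tmp_path / "truth.gml"
        write_cover_gml(graph, truth, out)
        _, c2 = read_cover_gml(out)
        shared_truth = {e for e, s in truth.edge_membership().items() if len(s) > 1}
        shared_read = {e for e, s in c2.edge_membership().items() if len(s) > 1}
        assert shared_truth and shared_truth == shared_read

    def test_round_trip_preserves_weights_and_positions(self, tmp_path, rng):
        pos = {i: rng.uniform(0, 5, 2) for i in range(11)}
        edges = [(i, i + 1, float(rng.uniform(0.1, 1.0))) for i in range(10)]
        g = FilamentGraph.from_data(pos, edges)
        cover = FilamentCover(tuple(EdgePath((u, v)) for u, v, _ in edges))
        out = tmp_path / "rt.gml"
        write_cover_gml(g, cover, out)
        g2 = read_gml(out)
        assert g2.n_nodes == g.n_nodes and g2.n_edges == g.n_edges
        for u, v, w in edges:
            # 6 significant digits declared print precision
            assert g2.weight(u, v) == pytest.approx(w, rel=1e-5)
        for n in pos:
            assert g2.position(n) == pytest.approx(g.position(n), rel=1e-5, abs=1e-6)


class TestFilamentCSV:
    def test_single_edge_filament_row(self, tmp_path):
        g = chain_graph([0.4], spacing=2.0)
        cover = FilamentCover((EdgePath((0, 1)),))
        rows = filament_metrics(cover, g)
        out = tmp_path / "m.csv"
        write_filament_csv(rows, out)
        lines = out.read_text().strip().split("\n")
        header, row = lines[0], lines[1]
        assert header.startswith("filament_id,n_edges,length_geometric")
        fields = row.split(",")
        assert fields[1] == "1"  # n_edges
        assert float(fields[2]) == pytest.approx(2.0)  # geometric length
        assert float(fields[4]) == pytest.approx(0.4)  # roughness_pair = weight
        assert float(fields[8]) == pytest.approx(1.0)  # convolutedness

    def test_empty_metrics_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_filament_csv([], tmp_path / "m.csv")

    def test_output_byte_stable(self, tmp_path, scene, scene_cover):
        graph, _ = scene
        rows = filament_metrics(scene_cover, graph)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_filament_csv(rows, a, header_comments=["opts"])
        write_filament_csv(rows, b, header_comments=["opts"])
        assert a.read_bytes() == b.read_bytes()
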