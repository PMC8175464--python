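"""Skeleton data model, SWC/JSON round trips, and path decomposition."""

import io
import json
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselmorph.errors import SkeletonFormatError, UnsupportedStructureError
from vesselmorph.io import (SkeletonGraph, SkeletonNode, decompose_paths,
                            read_json_graph, read_swc, write_json_graph,
                            write_swc)

from conftest import build_chain, random_tree_graph


class TestSwcReader:
    def test_two_node_file(self, swc_two_nodes):
        g = read_swc(swc_two_nodes)
        assert g.n_nodes == 2 and g.n_edges == 1
        assert g.radius(1) == 4.0 and g.radius(2) == 4.0
        assert np.allclose(g.position(2), [10, 0, 0])

    def test_comments_only_gives_empty_graph(self):
        g = read_swc(io.StringIO("# header\n\n# another comment\n"))
        assert g.n_nodes == 0 and g.n_edges == 0

    @pytest.mark.parametrize("text, match", [
        ("1 2 0 0 0 4.0 -1\n3 2 0 0 0 -1.0 1\n", "negative radius"),
        ("1 2 0 0 0 4.0 -1\n1 2 1 0 0 4.0 1\n", "duplicate node id"),
        ("1 2 0 0 0 4.0 5\n", "not previously defined"),
        ("1 2 0 0 0 4.0\n", "expected 7 fields"),
    ])
    def test_format_errors_name_the_line(self, text, match):
        with pytest.raises(SkeletonFormatError, match=match) as exc:
            read_swc(io.StringIO(text))
        assert "line" in str(exc.value)

    def test_inline_comments_and_whitespace_tolerated(self):
        g = read_swc(io.StringIO("  1 2 0 0 0 4.0 -1  # soma\n"))
        assert g.n_nodes == 1


class TestSwcWriter:
    def test_two_node_round_trip(self, swc_two_nodes):
        g = read_swc(swc_two_nodes)
        buf = io.StringIO()
        write_swc(g, buf)
        g2 = read_swc(io.StringIO(buf.getvalue()))
        assert g2.n_nodes == 2 and g2.has_edge(1, 2)

    def test_cycle_is_rejected(self):
        g = build_chain([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        g.add_edge(3, 1)
        with pytest.raises(UnsupportedStructureError, match="json"):
            write_swc(g, io.StringIO())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_tree_round_trip_is_isomorphic(self, seed):
        rng = np.random.default_rng(seed)
        g = random_tree_graph(rng, 100)
        buf = io.StringIO()
        write_swc(g, buf)
        g2 = read_swc(io.StringIO(buf.getvalue()))
        assert g2.n_nodes == g.n_nodes
        assert sorted(g2.edges()) == sorted(g.edges())
        for nid in g.node_ids():
            assert np.allclose(g2.position(nid), g.position(nid), atol=1e-4)
            assert g2.radius(nid) == pytest.approx(g.radius(nid), abs=1e-5)


class TestJsonGraph:
    def _triangle(self):
        return json.dumps({
            "nodes": [{"id": i, "x": float(i), "y": 0.0, "z": 0.0, "r": 4.0}
                      for i in (1, 2, 3)],
            "edges": [[1, 2], [2, 3], [3, 1]],
        })

    def test_triangle_has_one_cycle(self):
        g = read_json_graph(io.StringIO(self._triangle()))
        assert g.n_nodes == 3 and g.n_edges == 3
        assert not g.is_forest()

    def test_isolated_nodes_decompose_to_no_paths(self):
        doc = json.dumps({"nodes": [{"id": 1, "x": 0, "y": 0, "z": 0, "r": 1},
                                    {"id": 2, "x": 5, "y": 0, "z": 0, "r": 1}],
                          "edges": []})
        g = read_json_graph(io.StringIO(doc))
        assert g.n_nodes == 2
        assert decompose_paths(g) == []

    def test_self_edge_rejected(self):
        doc = json.dumps({"nodes": [{"id": 1, "x": 0, "y": 0, "z": 0, "r": 1}],
                          "edges": [[1, 1]]})
        with pytest.raises(SkeletonFormatError, match="self-edge"):
            read_json_graph(io.StringIO(doc))

    def test_unknown_edge_id_rejected(self):
        doc = json.dumps({"nodes": [{"id": 1, "x": 0, "y": 0, "z": 0, "r": 1}],
                          "edges": [[1, 9]]})
        with pytest.raises(SkeletonFormatError, match="unknown"):
            read_json_graph(io.StringIO(doc))

    def test_round_trip_preserves_cycles_and_metadata(self):
        g = read_json_graph(io.StringIO(self._triangle()))
        g.metadata["sample_id"] = "S1-22"
        buf = io.StringIO()
        write_json_graph(g, buf)
        g2 = read_json_graph(io.StringIO(buf.getvalue()))
        assert sorted(g2.edges()) == sorted(g.edges())
        assert g2.metadata["sample_id"] == "S1-22"
        for nid in g.node_ids():
            assert np.allclose(g2.position(nid), g.position(nid))


class TestZeroLengthEdges:
    def test_coincident_nodes_are_merged_with_warning(self):
        g = build_chain([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.warns(UserWarning, match="zero-length"):
            merged = g.merge_zero_length_edges()
        assert merged == 1
        assert g.n_nodes == 3 and g.n_edges == 2
        assert g.total_length() == pytest.approx(2.0)


class TestDecomposePaths:
    def test_chain_is_single_path(self):
        g = build_chain(np.column_stack([np.arange(10), np.zeros(10), np.zeros(10)]))
        paths = decompose_paths(g)
        assert len(paths) == 1 and len(paths[0]) == 10 and not paths[0].closed

    def test_y_tree_gives_three_paths_sharing_center(self):
        g = SkeletonGraph()
        g.add_node(SkeletonNode(1, np.zeros(3), 1.0))
        nid = 2
        for arm in range(3):
            prev = 1
            direction = np.eye(3)[arm]
            for k in range(1, 6):
                g.add_node(SkeletonNode(nid, k * direction, 1.0))
                g.add_edge(prev, nid)
                prev = nid
                nid += 1
        paths = decompose_paths(g)
        assert len(paths) == 3
        assert all(len(p) == 6 for p in paths)
        assert all(p.node_ids[0] == 1 for p in paths)

    def test_isolated_cycle_is_closed_path_with_deterministic_start(self):
        n = 8
        theta = 2 * np.pi * np.arange(n) / n
        g = build_chain(np.column_stack([np.cos(theta), np.sin(theta),
                                         np.zeros(n)]))
        g.add_edge(n, 1)
        paths = decompose_paths(g)
        assert len(paths) == 1
        (p,) = paths
        assert p.closed and len(p) == 8
        assert p.node_ids[0] == 1          # lowest id starts the loop
        assert p.node_ids[1] == 2          # oriented toward the lower-id neighbor
        assert Counter(p.edge_list()) == Counter(g.edges())

    def test_lollipop_partitions_edges_exactly_once(self):
        # a tail attached to a loop: the loop endpoints at the junction
        pts = [[float(i), 0, 0] for i in range(4)]
        g = build_chain(pts)
        theta = 2 * np.pi * np.arange(1, 6) / 6
        nid = 5
        prev = 4
        for t in theta:
            g.add_node(SkeletonNode(nid, np.array([3 + np.cos(t) - 1,
                                                   np.sin(t), 0.0]), 4.0))
            g.add_edge(prev, nid)
            prev = nid
            nid += 1
        g.add_edge(prev, 4)  # close the loop back at node 4
        paths = decompose_paths(g)
        edges = [e for p in paths for e in p.edge_list()]
        assert Counter(edges) == Counter(g.edges())
        assert all(g.degree(i) == 2
                   for p in paths for i in p.node_ids[1:-1] if not p.closed)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10**6), n=st.integers(2, 60),
           extra=st.integers(0, 8))
    def test_edge_partition_property_on_random_graphs(self, seed, n, extra):
        """Every edge appears in exactly one path, for trees + random chords."""
        rng = np.random.default_rng(seed)
        g = random_tree_graph(rng, n)
        for _ in range(extra):
            u, v = rng.integers(1, n + 1, size=2)
            if u != v and not g.has_edge(int(u), int(v)):
                g.add_edge(int(u), int(v))
        paths = decompose_paths(g)
        assert Counter(e for p in paths for e in p.edge_list()) == \
            Counter(g.edges())
        total = sum(p.arc_length(g) for p in paths)
        assert total == pytest.approx(g.total_length(), rel=1e-9)
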