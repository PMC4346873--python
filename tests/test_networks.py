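"""Bipartite topology: degree statistics, hubs, overlap, mapping, export."""

import numpy as np
import pytest

from herbnet.networks import (
    build_bipartite,
    degree_summary,
    export_network,
    find_hubs,
    import_network,
    map_targets_to_pathways,
    shared_targets,
    write_node_attributes,
)
from herbnet.synthetic import load_fixture


@pytest.fixture(scope="module")
def it_network():
    edges = [(r.compound_id, r.target_id) for r in load_fixture("it_edges").records]
    return build_bipartite(edges, "ingredients", "targets", name="ingredient-target")


@pytest.fixture(scope="module")
def dt_network():
    return build_bipartite(load_fixture("dt_edges"), "drugs", "targets", name="drug-target")


def random_network(rng, max_left=12, max_right=20):
    n_left = int(rng.integers(1, max_left))
    n_right = int(rng.integers(1, max_right))
    left = [f"L{i}" for i in range(n_left)]
    right = [f"R{i}" for i in range(n_right)]
    edges = {
        (left[int(rng.integers(n_left))], right[int(rng.integers(n_right))])
        for _ in range(int(rng.integers(0, 3 * max(n_left, n_right))))
    }
    return build_bipartite(edges, "left_role", "targets", left_nodes=left, right_nodes=right)


class TestBuild:
    def test_fixture_network_has_54_nodes_82_edges(self, it_network):
        assert len(it_network.left) == 11
        assert len(it_network.right) == 43
        assert len(it_network.edges) == 82

    def test_duplicate_edges_collapse(self):
        net = build_bipartite([("a", "x"), ("a", "x")], "l", "r")
        assert len(net.edges) == 1

    def test_declared_isolated_nodes_kept_with_degree_zero(self):
        net = build_bipartite([], "l", "r", left_nodes=["a"], right_nodes=["x", "y"])
        summary = degree_summary(net)
        assert summary.per_node == {("left", "a"): 0, ("right", "x"): 0, ("right", "y"): 0}

    def test_edge_endpoint_outside_partition_fails(self):
        with pytest.raises(ValueError, match="ghost"):
            build_bipartite(
                [("a", "ghost")], "l", "r", left_nodes=["a"], right_nodes=["x"]
            )


class TestDegreeSummary:
    def test_fixture_means_match_printed_values(self, it_network):
        summary = degree_summary(it_network)
        assert round(summary.mean_degree_all, 2) == 3.04
        assert round(summary.mean_degree_right, 2) == 1.91

    def test_single_edge_network_all_means_one(self):
        summary = degree_summary(build_bipartite([("a", "x")], "l", "r"))
        assert summary.mean_degree_all == 1.0
        assert summary.mean_degree_left == 1.0
        assert summary.mean_degree_right == 1.0

    def test_empty_network_fails(self):
        net = build_bipartite([], "l", "r")
        with pytest.raises(ValueError):
            degree_summary(net)

    def test_handshake_lemma_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            net = random_network(rng)
            summary = degree_summary(net)
            assert sum(summary.per_node.values()) == 2 * len(net.edges)
            # partition consistency
            assert summary.mean_degree_left * len(net.left) == pytest.approx(len(net.edges))
            assert summary.mean_degree_right * len(net.right) == pytest.approx(len(net.edges))


class TestHubs:
    def test_fixture_compound_hubs_match_printed_degrees(self, it_network):
        assert find_hubs(it_network, "left") == [
            ("M_05", 38),
            ("M_14", 15),
            ("M_04", 14),
            ("M_29", 5),
        ]

    def test_star_center_is_unique_hub(self):
        net = build_bipartite([("c", "x"), ("c", "y"), ("c", "z")], "l", "r")
        assert find_hubs(net, "left") == [("c", 3)]
        assert find_hubs(net, "right") == []

    def test_regular_graph_has_no_hubs_under_strict_rule(self):
        edges = [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")]
        net = build_bipartite(edges, "l", "r")
        assert find_hubs(net, "left") == []
        assert find_hubs(net, "right") == []

    def test_multiplier_raises_bar(self, it_network):
        hubs = find_hubs(it_network, "left", multiplier=2.0)  # bar 6.07
        assert hubs == [("M_05", 38), ("M_14", 15), ("M_04", 14)]

    def test_hub_rule_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            net = random_network(rng)
            n_nodes = len(net.left) + len(net.right)
            if not net.edges:
                continue
            mean = 2 * len(net.edges) / n_nodes
            oracle = sorted(
                (
                    (node, net.degree(node, "left"))
                    for node in net.left
                    if net.degree(node, "left") > mean
                ),
                key=lambda item: (-item[1], item[0]),
            )
            assert find_hubs(net, "left") == oracle

    def test_unknown_partition_fails(self, it_network):
        with pytest.raises(ValueError):
            find_hubs(it_network, "middle")


class TestOverlap:
    def test_fixture_overlap_is_the_six_shared_targets(self, it_network, dt_network):
        assert shared_targets(dt_network, it_network) == [
            "ALOX5", "COX1", "COX2", "ICAM1", "PPARD", "PPARG",
        ]

    def test_intersection_symmetry(self, it_network, dt_network):
        assert shared_targets(it_network, dt_network) == shared_targets(
            dt_network, it_network
        )

    def test_disjoint_networks_share_nothing(self):
        a = build_bipartite([("c", "x")], "l", "targets")
        b = build_bipartite([("c", "y")], "l", "targets")
        assert shared_targets(a, b) == []

    def test_identical_networks_share_everything(self, it_network):
        assert shared_targets(it_network, it_network) == sorted(it_network.right)

    def test_network_without_target_partition_fails(self):
        net = build_bipartite([("a", "x")], "l", "r")
        with pytest.raises(ValueError, match="targets"):
            shared_targets(net, net)


class TestPathwayMapping:
    def test_bche_is_unmapped_in_fixture(self, table2):
        genes = [t.gene for t in table2.records]
        edges, unmapped = map_targets_to_pathways(genes, load_fixture("pathways"))
        assert unmapped == ["BCHE"]
        assert len({t for t, _ in edges}) == 42

    def test_membership_count_equals_degree(self):
        table = {"p1": {"T"}, "p2": {"T"}, "p3": {"T", "U"}}
        edges, unmapped = map_targets_to_pathways(["T", "U"], table)
        assert sum(1 for t, _ in edges if t == "T") == 3
        assert not unmapped

    def test_random_membership_matches_table_scan(self):
        rng = np.random.default_rng(3)
        targets = [f"T{i}" for i in range(30)]
        table = {
            f"p{j}": {t for t in targets if rng.random() < 0.3} for j in range(8)
        }
        edges, unmapped = map_targets_to_pathways(targets, table)
        oracle = {
            (t, p) for p, members in table.items() for t in targets if t in members
        }
        assert set(edges) == oracle
        assert set(unmapped) == {
            t for t in targets if not any(t in m for m in table.values())
        }

    def test_empty_table_maps_nothing(self):
        edges, unmapped = map_targets_to_pathways(["T1"], {})
        assert edges == [] and unmapped == ["T1"]


class TestExport:
    def test_sif_single_edge(self, tmp_path):
        net = build_bipartite([("a", "x")], "l", "r")
        path = tmp_path / "net.sif"
        export_network(net, path, "sif")
        assert path.read_text().strip() == "l:a\tl-r\tr:x"

    def test_graphml_counts_for_fixture(self, it_network, tmp_path):
        import networkx as nx

        path = tmp_path / "it.graphml"
        export_network(it_network, path, "graphml")
        graph = nx.read_graphml(path)
        assert graph.number_of_nodes() == 54
        assert graph.number_of_edges() == 82

    @pytest.mark.parametrize("fmt", ["sif", "graphml"])
    def test_round_trip_on_random_networks(self, fmt, tmp_path):
        rng = np.random.default_rng(5)
        for i in range(20):
            net = random_network(rng)
            path = tmp_path / f"net{i}.{fmt}"
            export_network(net, path, fmt)
            back = import_network(path, fmt)
            assert back.edges == net.edges
            assert set(back.left) == set(net.left)
            assert set(back.right) == set(net.right)

    def test_unknown_format_fails(self, it_network, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(it_network, tmp_path / "x", "xml")

    def test_node_attribute_table(self, it_network, tmp_path):
        path = tmp_path / "attrs.tsv"
        write_node_attributes(it_network, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "node\trole\tdegree"
        assert len(lines) == 1 + 54
        assert "ingredients:M_05\tingredients\t38" in lines
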