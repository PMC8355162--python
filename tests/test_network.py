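"""Scored-edge filtering, subnetwork extraction, multi-network merge, roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cardiomir.exceptions import ConfigurationError, InputError
from cardiomir.network import (
    ROLE_DOWN_ANY,
    ROLE_DOWN_TARGET,
    ROLE_OTHER,
    ROLE_UP_ALL,
    CompartmentCatalogue,
    classify_nodes,
    compartmentalize,
    extract_subnetwork,
    filter_edges,
    merge_multinet,
)
from cardiomir.targetome import Targetome


def _edges(rows):
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


class TestFilterEdges:
    def test_cutoff_is_inclusive(self):
        g = filter_edges(_edges([("a", "b", 699), ("a", "c", 700), ("b", "c", 701)]))
        assert {tuple(sorted(e)) for e in g.edges} == {("a", "c"), ("b", "c")}

    def test_duplicate_directions_collapse(self):
        g = filter_edges(_edges([("a", "b", 800), ("b", "a", 900)]))
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["combined_score"] == 900

    def test_empty_edge_list(self):
        g = filter_edges(_edges([]))
        assert g.number_of_nodes() == 0

    def test_self_loops_dropped(self):
        g = filter_edges(_edges([("a", "a", 950)]))
        assert g.number_of_edges() == 0

    def test_namespace_restriction(self):
        g = filter_edges(_edges([("rat1", "mouse1", 900), ("rat1", "rat2", 900)]),
                         allowed_nodes={"rat1", "rat2"})
        assert set(g.edges) == {("rat1", "rat2")}

    def test_cutoff_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_edges(_edges([("a", "b", 500)]), score_cutoff=1500)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(InputError):
            filter_edges(_edges([("a", "b", 1200)]))

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        rows = [(f"n{a}", f"n{b}", int(rng.integers(0, 1001)))
                for a, b in itertools.combinations(range(12), 2)]
        sizes = [filter_edges(_edges(rows), score_cutoff=c).number_of_edges()
                 for c in (0, 200, 400, 600, 800, 1000)]
        assert sizes == sorted(sizes, reverse=True)


class TestExtractSubnetwork:
    def test_empty_node_set(self):
        g = filter_edges(_edges([("a", "b", 900)]))
        assert extract_subnetwork(g, set()).number_of_nodes() == 0

    def test_triangle_induction(self):
        g = filter_edges(_edges([("a", "b", 900), ("b", "c", 900), ("a", "c", 900)]))
        sub = extract_subnetwork(g, {"a", "b"})
        assert set(sub.nodes) == {"a", "b"}
        assert set(sub.edges) == {("a", "b")}

    def test_genes_of_interest_union(self):
        g = filter_edges(_edges([("a", "b", 900), ("a", "d", 900)]))
        sub = extract_subnetwork(g, {"a", "b"}, genes_of_interest={"d"})
        assert ("a", "d") in sub.edges

    def test_isolated_nodes_retained(self):
        g = filter_edges(_edges([("a", "b", 900), ("c", "d", 900)]))
        sub = extract_subnetwork(g, {"a", "b", "c"})
        assert "c" in sub.nodes and sub.degree("c") == 0

    def test_matches_pair_scan_oracle(self):
        """Induced subgraphs equal an exhaustive pair scan on random graphs."""
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = int(rng.integers(5, 51))
            nodes = [f"n{i}" for i in range(n)]
            rows = [(a, b, int(rng.integers(0, 1001)))
                    for a, b in itertools.combinations(nodes, 2)
                    if rng.random() < 0.15]
            g = filter_edges(_edges(rows), score_cutoff=500)
            keep = {v for v in nodes if rng.random() < 0.5}
            sub = extract_subnetwork(g, keep)
            oracle = {
                tuple(sorted((a, b)))
                for a, b in itertools.combinations(sorted(keep & set(g.nodes)), 2)
                if g.has_edge(a, b)
            }
            assert {tuple(sorted(e)) for e in sub.edges} == oracle


class TestMerge:
    def _subnets(self):
        s1 = nx.Graph([("a", "b"), ("b", "c")])
        s2 = nx.Graph([("a", "b")])
        s3 = nx.Graph([("a", "b"), ("c", "d")])
        return {"miR-106b": s1, "miR-93": s2, "miR-25": s3}

    def test_single_subnetwork(self):
        merged = merge_multinet({"miR-25": nx.Graph([("a", "b")])})
        assert merged["a"]["b"]["supporting_mirnas"] == {"miR-25"}

    def test_shared_edge_supported_by_all(self):
        merged = merge_multinet(self._subnets())
        assert merged["a"]["b"]["supporting_mirnas"] == {"miR-106b", "miR-93", "miR-25"}
        assert merged["b"]["c"]["supporting_mirnas"] == {"miR-106b"}

    def test_disjoint_subnetworks(self):
        merged = merge_multinet({"m1": nx.Graph([("a", "b")]), "m2": nx.Graph([("c", "d")])})
        assert merged.number_of_nodes() == 4
        assert all(len(d["supporting_mirnas"]) == 1 for _, _, d in merged.edges(data=True))

    def test_no_edge_invention(self):
        """Every merged edge exists in some input subnetwork."""
        subnets = self._subnets()
        merged = merge_multinet(subnets)
        union = set().union(*({tuple(sorted(e)) for e in s.edges} for s in subnets.values()))
        assert {tuple(sorted(e)) for e in merged.edges} == union

    def test_round_trip_single_mirna(self):
        g = filter_edges(_edges([("a", "b", 900), ("b", "c", 900), ("c", "d", 900)]))
        sub = extract_subnetwork(g, {"a", "b", "c"})
        merged = merge_multinet({"miR-93": sub})
        assert set(merged.edges) == set(sub.edges)
        assert set(merged.nodes) == set(sub.nodes)

    def test_empty_mapping_rejected(self):
        with pytest.raises(InputError):
            merge_multinet({})


class TestRolesAndCompartments:
    def _de(self):
        rows = []
        for mirna in ("miR-106b", "miR-93", "miR-25"):
            rows += [
                {"gene_id": "down25", "mirna": mirna,
                 "de_status": "down" if mirna == "miR-25" else "not_significant"},
                {"gene_id": "upAll", "mirna": mirna, "de_status": "up"},
                {"gene_id": "upTwo", "mirna": mirna,
                 "de_status": "up" if mirna != "miR-25" else "not_significant"},
                {"gene_id": "plain", "mirna": mirna, "de_status": "not_significant"},
            ]
        return pd.DataFrame(rows)

    def _net(self):
        g = nx.Graph()
        g.add_nodes_from(["down25", "upAll", "upTwo", "plain"])
        return g

    def _targetomes(self, predicted):
        return {m: Targetome(mirna=m, predicted_rat_genes=set(p))
                for m, p in predicted.items()}

    def test_down_and_predicted_is_down_target(self):
        t = self._targetomes({"miR-106b": set(), "miR-93": set(), "miR-25": {"down25"}})
        net = classify_nodes(self._net(), self._de(), t)
        assert net.nodes["down25"]["role"] == ROLE_DOWN_TARGET

    def test_down_without_prediction_is_down_any(self):
        t = self._targetomes({"miR-106b": set(), "miR-93": set(), "miR-25": set()})
        net = classify_nodes(self._net(), self._de(), t)
        assert net.nodes["down25"]["role"] == ROLE_DOWN_ANY

    def test_up_in_all_three_is_up_all(self):
        t = self._targetomes({"miR-106b": set(), "miR-93": set(), "miR-25": set()})
        net = classify_nodes(self._net(), self._de(), t)
        assert net.nodes["upAll"]["role"] == ROLE_UP_ALL
        assert net.nodes["upTwo"]["role"] == ROLE_OTHER
        assert net.nodes["plain"]["role"] == ROLE_OTHER

    def test_compartment_multimembership(self):
        net = self._net()
        catalogue = CompartmentCatalogue.from_gene_sets(
            {"cell_division": {"down25", "upAll"}, "hippo_canonical": {"down25"}}
        )
        compartmentalize(net, catalogue)
        assert net.nodes["down25"]["compartments"] == {"cell_division", "hippo_canonical"}
        assert net.nodes["plain"]["compartments"] == set()

    def test_empty_compartment_rejected(self):
        with pytest.raises(InputError):
            CompartmentCatalogue.from_gene_sets({"cell_division": set()})
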