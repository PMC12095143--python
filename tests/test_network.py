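import networkx as nx
import numpy as np
import pytest

from dosagenet import (
    ComponentMap,
    DosageVector,
    build_network,
    intersect_disease_targets,
    ones_vector,
    predict_targets,
    select_key_targets,
    weighted_degree,
)
from dosagenet.network import DISEASE_NODE, nondosage_vector


class TestBuildNetwork:
    def test_all_ones_vector_gives_unit_weights(self, simple_map):
        """Without metabolite sharing, the non-dosage network has weight 1 everywhere."""
        net = build_network(ones_vector(2, ["drugA", "drugB"]), simple_map, {"T1"})
        assert all(d["weight"] == 1.0 for _, _, d in net.edges(data=True))

    def test_single_path_propagation(self):
        maps = ComponentMap({"d": {"m"}}, {"m": {"T"}})
        net = build_network(DosageVector(("d",), (10.0,)), maps, set())
        assert net["d"]["m"]["weight"] == 10.0
        assert net["m"]["T"]["weight"] == 10.0

    def test_shared_metabolite_sums_parent_dosages(self):
        maps = ComponentMap({"a": {"m"}, "b": {"m"}}, {"m": {"T"}})
        vec = DosageVector(("a", "b"), (1.0, 10.0))
        net = build_network(vec, maps, set())
        assert net["m"]["T"]["weight"] == 11.0
        net_max = build_network(vec, maps, set(), propagation="max")
        assert net_max["m"]["T"]["weight"] == 10.0

    def test_disease_edges_only_for_disease_targets(self, simple_map):
        net = build_network(
            ones_vector(2, ["drugA", "drugB"]), simple_map, {"T1", "T3"}
        )
        assert net.has_edge("T1", DISEASE_NODE)
        assert net.has_edge("T3", DISEASE_NODE)
        assert not net.has_edge("T2", DISEASE_NODE)
        assert net["T1"][DISEASE_NODE]["weight"] == 1.0

    def test_unmapped_drug_raises(self, simple_map):
        with pytest.raises(KeyError, match="no metabolite/target data"):
            build_network(ones_vector(1, ["ghost"]), simple_map, set())

    def test_layers_are_adjacent_only(self, simple_map):
        net = build_network(
            DosageVector(("drugA", "drugB"), (1.0, 5.0)), simple_map, {"T1"}
        )
        order = {"drug": 0, "metabolite": 1, "target": 2, "disease": 3}
        for u, v in net.edges():
            lu, lv = net.nodes[u]["layer"], net.nodes[v]["layer"]
            assert abs(order[lu] - order[lv]) == 1


class TestWeightedDegree:
    def test_star_center(self):
        g = nx.star_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert weighted_degree(g, 0) == 4.0

    def test_manual_sum(self):
        g = nx.Graph()
        g.add_edge("m1", "T", weight=1.0)
        g.add_edge("m2", "T", weight=10.0)
        assert weighted_degree(g, "T") == 11.0

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("x")
        assert weighted_degree(g, "x") == 0.0

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            weighted_degree(nx.Graph(), "nope")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_adjacency_row_sums(self, seed):
        """Oracle: weighted degree equals the adjacency-matrix row sum."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        g = nx.gnp_random_graph(n, 0.4, seed=seed)
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.uniform(0.1, 10))
        adj = nx.to_numpy_array(g, nodelist=sorted(g), weight="weight")
        for i, node in enumerate(sorted(g)):
            assert weighted_degree(g, node) == pytest.approx(adj[i].sum())

    def test_unit_weights_equal_plain_degree(self):
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        for node in g:
            assert weighted_degree(g, node) == g.degree(node)


def _degree_network(degrees: dict[str, float]):
    """A network whose target layer has the prescribed weighted degrees."""
    from dosagenet import PrescriptionNetwork

    g = PrescriptionNetwork()
    for i, (t, d) in enumerate(degrees.items()):
        m = f"m{i}"
        g.add_node(m, layer="metabolite")
        g.add_node(t, layer="target")
        g.add_edge(m, t, weight=float(d))
    return g


class TestKeyTargetSelection:
    def test_strictly_above_mean(self):
        pred = select_key_targets(_degree_network({"t1": 3, "t2": 1, "t3": 1, "t4": 1}))
        assert pred.key_targets == {"t1"}  # mean 1.5

    def test_all_equal_yields_empty(self):
        pred = select_key_targets(_degree_network({"t1": 2, "t2": 2, "t3": 2}))
        assert pred.key_targets == set()

    def test_tie_at_mean_excluded(self):
        pred = select_key_targets(_degree_network({"t1": 1, "t2": 2, "t3": 3}))
        assert pred.key_targets == {"t3"}  # mean exactly 2

    def test_weighting_changes_selection_on_same_topology(self):
        """The dosage mechanism: same graph, different weights, different keys."""
        maps = ComponentMap(
            {"a": {"ma"}, "b": {"mb"}},
            {"ma": {"TA", "TC"}, "mb": {"TB", "TC"}},
        )
        flat = select_key_targets(build_network(ones_vector(2, ["a", "b"]), maps, set()))
        dosed = select_key_targets(
            build_network(DosageVector(("a", "b"), (1.0, 10.0)), maps, set())
        )
        assert flat.key_targets == {"TC"}  # degree 2 vs mean 4/3
        assert dosed.key_targets == {"TC", "TB"}  # 11, 10 vs mean 22/3

    def test_no_targets_is_an_error(self):
        maps = ComponentMap({"d": {"m"}}, {"m": set()})
        net = build_network(ones_vector(1, ["d"]), maps, set())
        with pytest.raises(ValueError):
            select_key_targets(net)

    def test_brute_force_mean_comparison(self, chong_he):
        """Oracle: recompute key targets from raw incident-weight sums."""
        from dosagenet.units import standardize

        x = standardize(chong_he.records)
        net = build_network(x, chong_he.maps, chong_he.disease_targets)
        targets = net.nodes_in_layer("target")
        raw = {
            t: sum(d["weight"] for _, _, d in net.edges(t, data=True)) for t in targets
        }
        mean = sum(raw.values()) / len(raw)
        expected = {t for t, d in raw.items() if d > mean}
        assert select_key_targets(net).key_targets == expected


class TestDrugTargets:
    @pytest.mark.parametrize(
        "key,disease,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, {"B", "C"}),
            ({"A"}, {"B"}, set()),
            ({"A", "B"}, {"A", "B", "C"}, {"A", "B"}),
        ],
    )
    def test_intersection(self, key, disease, expected):
        from dosagenet.network import TargetPrediction

        pred = TargetPrediction(key_targets=frozenset(key))
        assert intersect_disease_targets(pred, disease).drug_targets == expected

    def test_containment_invariants(self, chong_he):
        from dosagenet.units import standardize

        x = standardize(chong_he.records)
        pred = predict_targets(x, chong_he.maps, chong_he.disease_targets)
        assert pred.drug_targets <= pred.key_targets
        assert pred.key_targets <= set(pred.degree_table)
        assert pred.drug_targets <= chong_he.disease_targets


def test_nondosage_equals_all_ones_evaluation(chong_he):
    """The non-dosage variant is the weighted pipeline at the all-ones vector."""
    from dosagenet.units import standardize

    x = standardize(chong_he.records)
    y = nondosage_vector(x)
    assert y.values == (1.0,) * len(x)
    p_ones = predict_targets(y, chong_he.maps, chong_he.disease_targets)
    p_again = predict_targets(
        ones_vector(len(x), x.drug_ids), chong_he.maps, chong_he.disease_targets
    )
    assert p_ones.key_targets == p_again.key_targets
    assert p_ones.degree_table == p_again.degree_table
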