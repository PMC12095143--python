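"""Layered prescription networks and target prediction.

The prescription is modeled as a four-layer graph: botanical drugs ->
bioactive metabolites -> protein targets -> disease.  In the non-dosage
variant every edge has weight 1.  In the dosage-weighted variant each
drug->metabolite edge carries the drug's standardized dosage component,
and each metabolite->target edge carries the combined (by default,
summed) standardized dosages of all drugs contributing that metabolite,
so dosage propagates to where targets are ranked.  Targets whose
weighted degree strictly exceeds the average over the target layer are
"key targets"; key targets that are also disease-associated genes are
the prescription's "drug targets".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import networkx as nx

from .units import DosageVector, ones_vector

__all__ = [
    "ComponentMap",
    "PrescriptionNetwork",
    "TargetPrediction",
    "build_network",
    "weighted_degree",
    "select_key_targets",
    "intersect_disease_targets",
    "predict_targets",
]

LAYERS = ("drug", "metabolite", "target", "disease")
DISEASE_NODE = "__disease__"


@dataclass(frozen=True)
class ComponentMap:
    """Drug -> metabolites and metabolite -> targets lookup tables.

    Gene symbols are upper-cased on construction; every metabolite a drug
    mentions is guaranteed a (possibly empty) entry in
    ``metabolite_to_targets``.
    """

    drug_to_metabolites: Mapping[str, frozenset[str]]
    metabolite_to_targets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        d2m = {
            d: frozenset(ms) for d, ms in dict(self.drug_to_metabolites).items()
        }
        m2t = {
            m: frozenset(t.upper() for t in ts)
            for m, ts in dict(self.metabolite_to_targets).items()
        }
        for ms in d2m.values():
            for m in ms:
                m2t.setdefault(m, frozenset())
        object.__setattr__(self, "drug_to_metabolites", d2m)
        object.__setattr__(self, "metabolite_to_targets", m2t)

    def metabolites_of(self, drug_id: str) -> frozenset[str]:
        try:
            return self.drug_to_metabolites[drug_id]
        except KeyError:
            raise KeyError(
                f"drug {drug_id!r} has no metabolite/target data"
            ) from None


class PrescriptionNetwork(nx.Graph):
    """Weighted layered graph; node attribute ``layer`` names the layer."""

    def nodes_in_layer(self, layer: str) -> list:
        return [n for n, d in self.nodes(data=True) if d.get("layer") == layer]


@dataclass
class TargetPrediction:
    """Key targets, drug targets and the target-degree table."""

    key_targets: frozenset[str] = frozenset()
    drug_targets: frozenset[str] = frozenset()
    degree_table: dict[str, float] = field(default_factory=dict)


def build_network(
    dosage_vector: DosageVector,
    maps: ComponentMap,
    disease_targets: Iterable[str],
    propagation: Literal["sum", "max"] = "sum",
) -> PrescriptionNetwork:
    """Assemble the drug-metabolite-target-disease graph.

    Drug-incident edges take the drug's standardized dosage as weight.
    A metabolite contributed by several drugs passes the combination
    (``sum`` by default, optionally ``max``) of their dosages on to its
    target edges.  Targets found in ``disease_targets`` connect to a
    single disease node with weight 1.  With an all-ones dosage vector
    the result is exactly the non-dosage network (every weight 1 under
    either propagation rule).
    """
    if propagation not in ("sum", "max"):
        raise ValueError(f"propagation must be 'sum' or 'max', got {propagation!r}")
    disease = frozenset(t.upper() for t in disease_targets)
    g = PrescriptionNetwork()
    g.add_node(DISEASE_NODE, layer="disease")

    # metabolite weight = combined standardized dosage of its parent drugs
    met_weight: dict[str, float] = {}
    for drug_id in dosage_vector.drug_ids:
        w = dosage_vector.weight_of(drug_id)
        g.add_node(drug_id, layer="drug")
        for met in maps.metabolites_of(drug_id):  # sets: duplicates collapsed
            g.add_node(met, layer="metabolite")
            g.add_edge(drug_id, met, weight=w, layer_pair="drug-metabolite")
            if propagation == "sum":
                met_weight[met] = met_weight.get(met, 0.0) + w
            else:
                met_weight[met] = max(met_weight.get(met, 0.0), w)

    for met, w in met_weight.items():
        for target in maps.metabolite_to_targets[met]:
            g.add_node(target, layer="target")
            g.add_edge(met, target, weight=w, layer_pair="metabolite-target")

    for target in g.nodes_in_layer("target"):
        if target in disease:
            g.add_edge(target, DISEASE_NODE, weight=1.0, layer_pair="target-disease")
    return g


def weighted_degree(network: nx.Graph, node) -> float:
    """Sum of incident edge weights (== plain degree when all weights are 1)."""
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    return float(network.degree(node, weight="weight"))


def select_key_targets(
    network: PrescriptionNetwork,
    averaging: Literal["target-layer", "all-nodes"] = "target-layer",
) -> TargetPrediction:
    """Targets whose weighted degree strictly exceeds the average degree.

    The averaging population defaults to the target layer (key targets
    are chosen among targets); ``all-nodes`` averages over the whole
    graph for sensitivity checks.  Ties at the mean are excluded.
    """
    targets = network.nodes_in_layer("target")
    if not targets:
        raise ValueError("network has no target nodes")
    table = {t: weighted_degree(network, t) for t in targets}
    if averaging == "target-layer":
        pool = list(table.values())
    elif averaging == "all-nodes":
        pool = [weighted_degree(network, n) for n in network.nodes]
    else:
        raise ValueError(f"unknown averaging scope {averaging!r}")
    mean = sum(pool) / len(pool)
    key = frozenset(t for t, d in table.items() if d > mean)
    return TargetPrediction(key_targets=key, degree_table=table)


def intersect_disease_targets(
    prediction: TargetPrediction, disease_targets: Iterable[str]
) -> TargetPrediction:
    """Fill ``drug_targets``: key targets that are disease-associated."""
    disease = frozenset(t.upper() for t in disease_targets)
    prediction.drug_targets = prediction.key_targets & disease
    return prediction


def predict_targets(
    dosage_vector: DosageVector,
    maps: ComponentMap,
    disease_targets: Iterable[str],
    propagation: Literal["sum", "max"] = "sum",
    averaging: Literal["target-layer", "all-nodes"] = "target-layer",
) -> TargetPrediction:
    """Build the network and run the full target-prediction step."""
    disease = frozenset(t.upper() for t in disease_targets)
    net = build_network(dosage_vector, maps, disease, propagation)
    pred = select_key_targets(net, averaging)
    return intersect_disease_targets(pred, disease)


def nondosage_vector(dosage_vector: DosageVector) -> DosageVector:
    """The all-ones vector matching a prescription (non-dosage input)."""
    return ones_vector(len(dosage_vector), dosage_vector.drug_ids)
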