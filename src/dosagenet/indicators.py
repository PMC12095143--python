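"""The four input/output difference indicators and their orchestration.

Input-side indicators compare the standardized dosage vector x against
the all-ones vector y of the non-dosage variant:

* ``dedis``: Euclidean distance ||x - y||; zero iff the dosages are all
  equal.
* ``desd``: sample standard deviation (n-1 denominator) of x; since the
  all-ones vector has SD identically 0, sd(x) is itself the difference.

Both have metabolite-level variants (``compound_dedis``,
``compound_desd``) computed on the metabolite dosage vector, where each
distinct metabolite inherits the summed standardized dosages of its
parent drugs.  The metabolite-level reference is the expansion of the
all-ones drug vector (which is itself non-uniform when a metabolite has
several parent drugs), so equal dosages still yield exactly zero:
``compound_dedis`` is the Euclidean distance between the two metabolite
vectors and ``compound_desd`` the absolute difference of their sample
standard deviations.

Output-side indicators compare what the two network variants predict:

* ``dedt``: 1 - Jaccard similarity between the two drug-target sets;
* ``depy``: 1 - Jaccard similarity between the two enriched-pathway sets.

Both lie in [0, 1]; with equal dosages the two networks coincide and
every indicator is exactly 0.  A positive dedis permits, but does not
force, a change in the outputs (targets can survive a re-weighting), so
dedis is a necessary-not-sufficient signal for output change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .enrichment import GeneSetCollection, enrich
from .network import ComponentMap, nondosage_vector, predict_targets
from .units import DosageRecord, DosageVector, standardize

__all__ = [
    "IndicatorPanel",
    "dedis",
    "desd",
    "set_difference",
    "metabolite_dosage_vector",
    "compare_prescription",
]


@dataclass(frozen=True)
class IndicatorPanel:
    """All six indicators for one prescription.

    ``depy`` is None when no gene-set collection was supplied (pathway
    comparison skipped); all fields are 0 for equal-dosage prescriptions.
    """

    dedis: float
    desd: float
    compound_dedis: float
    compound_desd: float
    dedt: float
    depy: float | None


def dedis(x: DosageVector | Sequence[float], y: DosageVector | Sequence[float]) -> float:
    """Euclidean distance between two dosage vectors of equal length."""
    xv = x.as_array() if isinstance(x, DosageVector) else np.asarray(x, dtype=float)
    yv = y.as_array() if isinstance(y, DosageVector) else np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.shape} vs {yv.shape}")
    return float(np.linalg.norm(xv - yv))


def desd(x: DosageVector | Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) of a dosage vector.

    The non-dosage vector is all ones with SD 0, so sd(x) equals the
    SD difference between the two variants.
    """
    xv = x.as_array() if isinstance(x, DosageVector) else np.asarray(x, dtype=float)
    if xv.size < 2:
        raise ValueError("standard deviation needs at least 2 components")
    return float(np.std(xv, ddof=1))


def set_difference(s1: Iterable, s2: Iterable) -> float:
    """1 - Jaccard similarity of two sets, in [0, 1].

    0 for equal sets (including both empty: identical outputs mean no
    difference), 1 for disjoint non-empty sets.
    """
    a, b = frozenset(s1), frozenset(s2)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def metabolite_dosage_vector(
    dosage_vector: DosageVector, maps: ComponentMap
) -> DosageVector:
    """Expand a drug-level dosage vector to the metabolite level.

    Each distinct metabolite gets one component equal to the summed
    standardized dosages of the drugs that contain it (metabolites shared
    by several drugs are deduplicated, their parents' weights summed).
    Components are ordered lexicographically by metabolite id so the
    compound-level indicators are reproducible.
    """
    weights: dict[str, float] = {}
    for drug_id in dosage_vector.drug_ids:
        w = dosage_vector.weight_of(drug_id)
        for met in maps.metabolites_of(drug_id):
            weights[met] = weights.get(met, 0.0) + w
    if not weights:
        raise ValueError("no metabolites mapped for any drug in the vector")
    mets = sorted(weights)
    return DosageVector(tuple(mets), tuple(weights[m] for m in mets))


def compare_prescription(
    prescription: Sequence[DosageRecord] | DosageVector,
    maps: ComponentMap,
    disease_targets: Iterable[str],
    gene_sets: GeneSetCollection | None = None,
    *,
    p_cutoff: float = 0.05,
    min_genes: int = 10,
    propagation: Literal["sum", "max"] = "sum",
    averaging: Literal["target-layer", "all-nodes"] = "target-layer",
) -> IndicatorPanel:
    """Run both network variants end-to-end and fill the indicator panel.

    ``prescription`` may be raw dosage records (standardized here) or an
    already-standardized vector.  Pathway indicators are skipped (depy
    None) when ``gene_sets`` is None.
    """
    if isinstance(prescription, DosageVector):
        x = prescription
    else:
        x = standardize(prescription)
    y = nondosage_vector(x)
    disease = frozenset(t.upper() for t in disease_targets)

    met_x = metabolite_dosage_vector(x, maps)
    met_y = metabolite_dosage_vector(y, maps)

    pred_plain = predict_targets(y, maps, disease, propagation, averaging)
    pred_dosed = predict_targets(x, maps, disease, propagation, averaging)
    s1, s2 = pred_plain.drug_targets, pred_dosed.drug_targets
    dedt = set_difference(s1, s2)

    depy: float | None = None
    if gene_sets is not None:
        paths1 = {r.pathway_id for r in enrich(s1, gene_sets, p_cutoff, min_genes)}
        paths2 = {r.pathway_id for r in enrich(s2, gene_sets, p_cutoff, min_genes)}
        depy = set_difference(paths1, paths2)

    return IndicatorPanel(
        dedis=dedis(x, y),
        desd=desd(x),
        compound_dedis=dedis(met_x, met_y),
        compound_desd=abs(desd(met_x) - desd(met_y)),
        dedt=dedt,
        depy=depy,
    )
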