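"""Readers and writers for the plain-text dialects the pipeline uses.

* prescriptions: CSV or JSON with fields drug_id, quantity, unit, dynasty
* component maps: two TSV edge lists (drug_id<TAB>metabolite_id and
  metabolite_id<TAB>gene_symbol)
* disease targets: one gene symbol per line
* gene sets: GMT (pathway_id<TAB>description<TAB>gene...)
* outputs: weighted edge-list TSV, indicator-panel TSV, stats JSON
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enrichment import EnrichmentResult, GeneSetCollection
from .indicators import IndicatorPanel
from .network import ComponentMap, PrescriptionNetwork
from .units import DosageRecord

__all__ = [
    "read_prescriptions",
    "write_prescriptions",
    "read_component_map",
    "write_component_map",
    "read_disease_targets",
    "write_disease_targets",
    "read_gmt",
    "write_gmt",
    "write_edge_list",
    "write_indicator_table",
    "write_enrichment_table",
]

PRESCRIPTION_FIELDS = ("drug_id", "quantity", "unit", "dynasty")


def read_prescriptions(path) -> dict[str, list[DosageRecord]]:
    """Read prescriptions from CSV or JSON keyed by prescription_id.

    CSV needs columns prescription_id, drug_id, quantity, unit, dynasty
    (prescription_id optional for single-prescription files).  JSON is a
    mapping prescription_id -> list of record objects.
    """
    path = Path(path)
    out: dict[str, list[DosageRecord]] = {}
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        for pid, recs in raw.items():
            out[pid] = [
                DosageRecord(
                    r["drug_id"], float(r["quantity"]), r["unit"], r["dynasty"]
                )
                for r in recs
            ]
        return out
    df = pd.read_csv(path, dtype=str)
    missing = set(PRESCRIPTION_FIELDS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "prescription_id" not in df.columns:
        df["prescription_id"] = "prescription1"
    for pid, grp in df.groupby("prescription_id", sort=True):
        out[str(pid)] = [
            DosageRecord(
                row.drug_id, float(row.quantity), row.unit, row.dynasty
            )
            for row in grp.itertuples()
        ]
    return out


def write_prescriptions(prescriptions: Mapping[str, Sequence[DosageRecord]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("prescription_id",) + PRESCRIPTION_FIELDS)
        for pid in sorted(prescriptions):
            for r in prescriptions[pid]:
                w.writerow([pid, r.drug_id, repr(float(r.quantity)), r.unit.value, r.dynasty.value])


def read_component_map(drug_metabolite_tsv, metabolite_target_tsv) -> ComponentMap:
    """Assemble a ComponentMap from the two TSV edge lists.

    A metabolite line with an empty gene field declares a metabolite with
    no known targets.  Duplicate edges are collapsed.
    """
    d2m: dict[str, set[str]] = {}
    for line in Path(drug_metabolite_tsv).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        drug, met = line.split("\t")[:2]
        d2m.setdefault(drug, set()).add(met)
    m2t: dict[str, set[str]] = {}
    for line in Path(metabolite_target_tsv).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        met = parts[0]
        m2t.setdefault(met, set())
        if len(parts) > 1 and parts[1]:
            m2t[met].add(parts[1])
    return ComponentMap(d2m, m2t)


def write_component_map(maps: ComponentMap, drug_metabolite_tsv, metabolite_target_tsv) -> None:
    with open(drug_metabolite_tsv, "w") as fh:
        for drug in sorted(maps.drug_to_metabolites):
            for met in sorted(maps.drug_to_metabolites[drug]):
                fh.write(f"{drug}\t{met}\n")
    with open(metabolite_target_tsv, "w") as fh:
        for met in sorted(maps.metabolite_to_targets):
            targets = sorted(maps.metabolite_to_targets[met])
            if not targets:
                fh.write(f"{met}\t\n")  # metabolite with no known targets
            for t in targets:
                fh.write(f"{met}\t{t}\n")


def read_disease_targets(path) -> frozenset[str]:
    """One gene symbol per line; blank lines and # comments skipped."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line.upper())
    return frozenset(genes)


def write_disease_targets(targets: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in sorted(targets)))


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file: id, description, then genes, tab-separated."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs >= 3 fields: {line[:60]!r}")
        pid, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        sets[pid] = (name, frozenset(genes))
    return GeneSetCollection(sets, frozenset(universe or ()))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(collection.sets):
            name, genes = collection.sets[pid]
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


def write_edge_list(network: PrescriptionNetwork, path) -> None:
    """Weighted edge list TSV (source, target, layer_pair, weight)."""
    rows = sorted(
        (str(u), str(v), d.get("layer_pair", ""), d.get("weight", 1.0))
        for u, v, d in network.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("source\ttarget\tlayer_pair\tweight\n")
        for u, v, lp, w in rows:
            fh.write(f"{u}\t{v}\t{lp}\t{w!r}\n")


def write_indicator_table(panels: Mapping[str, tuple[int, IndicatorPanel]], path) -> None:
    """One TSV row per prescription; (n_drugs, panel) keyed by id."""
    cols = ["prescription_id", "n_drugs", "dedis", "desd",
            "compound_dedis", "compound_desd", "dedt", "depy"]
    rows = []
    for pid in sorted(panels):
        n, p = panels[pid]
        rows.append([pid, n, p.dedis, p.desd, p.compound_dedis,
                     p.compound_desd, p.dedt, "" if p.depy is None else p.depy])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tname\toverlap_count\tp_value\tgenes\n")
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.name}\t{r.overlap_count}\t{r.p_value!r}\t"
                + ",".join(sorted(r.overlap_genes)) + "\n"
            )
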