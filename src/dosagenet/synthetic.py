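"""Synthetic fixtures and ensembles emulating the study inputs.

Real analyses of this kind draw on three external resources: a
herb-chemistry database (drug -> bioactive metabolites -> targets), a
disease-gene list, and a pathway annotation.  None is redistributable,
so this module fabricates structurally faithful stand-ins: a small
hand-built worked example (the Chong He powder prescription with a
synthetic component map) and seeded random ensembles at the study's
scale (94 prescriptions by default).  Identifiers are synthetic
(D0001/M0001/G0001) and imply no real biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as dio
from .enrichment import GeneSetCollection
from .network import ComponentMap
from .units import DosageRecord, Dynasty, Unit, validate_prescription

__all__ = [
    "SyntheticConfig",
    "PrescriptionBundle",
    "chong_he_fixture",
    "generate_ensemble",
    "write_bundle",
    "read_bundle",
]


@dataclass(frozen=True)
class PrescriptionBundle:
    """One prescription plus everything needed to analyze it."""

    prescription_id: str
    records: tuple[DosageRecord, ...]
    maps: ComponentMap
    disease_targets: frozenset[str]
    gene_sets: GeneSetCollection | None = None
    # enrichment thresholds appropriate for the bundle's scale
    min_genes: int = 10
    p_cutoff: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(
            self, "disease_targets", frozenset(t.upper() for t in self.disease_targets)
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the ensemble generator.

    Defaults emulate the published study's scale: 94 prescriptions of
    2-12 botanical drugs, dosage ratios spanning up to ~99 (log-uniform,
    so near-uniform and extreme prescriptions both occur), and a fifth
    of prescriptions with exactly equal dosages as null cases.
    """

    n_prescriptions: int = 94
    drugs_per_prescription: tuple[int, int] = (2, 12)
    metabolites_per_drug: tuple[int, int] = (2, 6)
    targets_per_metabolite: tuple[int, int] = (2, 8)
    dosage_ratio_max: float = 99.0
    dosage_ratio_min: float = 1.0
    disease_target_fraction: float = 0.3
    n_pathways: int = 20
    pathway_size: tuple[int, int] = (10, 40)
    null_fraction: float = 0.2
    seed: int = 0
    # "loguniform": every drug's dose ratio sampled independently;
    # "monarch": one chief drug at a sampled ratio, the rest at the base
    # dose; "monarch_fixed_sd": chief drug's dose excess scales with the
    # square root of the drug count so the dosage SD is (up to log-normal
    # noise of scale sd_noise around sd_level) the same for every
    # prescription -- a sensitivity construction in which the SD carries
    # no information about the output change
    dosage_pattern: str = "loguniform"
    sd_level: float = 3.0
    sd_noise: float = 0.02
    # shared "database" dimensions
    n_drugs_pool: int = 40
    n_metabolites_pool: int = 80
    n_genes: int = 300

    def __post_init__(self) -> None:
        for name in ("drugs_per_prescription", "metabolites_per_drug",
                     "targets_per_metabolite", "pathway_size"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or invalid")
        if not (0 < self.disease_target_fraction < 1):
            raise ValueError("disease_target_fraction must be in (0, 1)")
        if not (0 <= self.null_fraction <= 1):
            raise ValueError("null_fraction must be in [0, 1]")
        if not (1.0 <= self.dosage_ratio_min <= self.dosage_ratio_max):
            raise ValueError("need 1 <= dosage_ratio_min <= dosage_ratio_max")
        if self.dosage_pattern not in ("loguniform", "monarch", "monarch_fixed_sd"):
            raise ValueError(f"unknown dosage_pattern {self.dosage_pattern!r}")
        if self.sd_level <= 0 or self.sd_noise < 0:
            raise ValueError("sd_level must be positive and sd_noise nonnegative")
        if self.n_prescriptions < 1:
            raise ValueError("n_prescriptions must be >= 1")
        if self.drugs_per_prescription[1] > self.n_drugs_pool:
            raise ValueError("drug pool smaller than drugs_per_prescription max")
        if self.pathway_size[1] > self.n_genes:
            raise ValueError("pathway_size max exceeds gene universe")


def chong_he_fixture() -> PrescriptionBundle:
    """The Chong He powder worked example with a synthetic component map.

    The prescription is one Fen of Bai Yao Zi, one Fen of Gan Cao and one
    Qian of Xiong Huang (Song-Yuan units), standardizing to [1, 1, 10].
    The component map, disease list and gene sets are hand-built
    (synthetic stand-ins, not database content) so that the dosage
    weighting promotes the high-dose drug's targets: the non-dosage
    variant predicts drug targets {T0, T4} while the weighted variant
    predicts {T0, T2, T3}, sharing the core T0 but adding targets of the
    ten-fold-dosed Xiong Huang.
    """
    records = (
        DosageRecord("BaiYaoZi", 1, Unit.FEN, Dynasty.SONG_YUAN),
        DosageRecord("GanCao", 1, Unit.FEN, Dynasty.SONG_YUAN),
        DosageRecord("XiongHuang", 1, Unit.QIAN, Dynasty.SONG_YUAN),
    )
    maps = ComponentMap(
        drug_to_metabolites={
            "BaiYaoZi": {"MB", "MS"},
            "GanCao": {"MG", "MS"},
            "XiongHuang": {"MX1", "MX2"},
        },
        metabolite_to_targets={
            "MB": {"T0", "T1", "T5"},
            "MG": {"T0", "T1", "T6"},
            "MX1": {"T0", "T2"},
            "MX2": {"T3"},
            "MS": {"T4"},
        },
    )
    disease = frozenset({"T0", "T2", "T3", "T4", "T6"})
    extras = [f"U{i}" for i in range(1, 14)]
    gene_sets = GeneSetCollection({
        "GO:0001": ("T cell immune regulation", frozenset({"T0", "T2", "T3", "U1"})),
        "GO:0002": ("inflammatory response", frozenset({"T0", "T4", "U2", "U3"})),
        "GO:0003": ("transmembrane transport", frozenset({"T4", "T6", "U4", "U5"})),
        "GO:0004": ("response to virus", frozenset({"T0", "T2", "T3", "T4"})),
        "GO:0005": ("background", frozenset({"T1", "T5", *extras})),
    })
    return PrescriptionBundle(
        prescription_id="ChongHe",
        records=records,
        maps=maps,
        disease_targets=disease,
        gene_sets=gene_sets,
        min_genes=1,  # the hand-built collection is tiny
    )


def _sample_database(cfg: SyntheticConfig, rng: np.random.Generator):
    """Shared drug/metabolite/gene 'database' for one ensemble."""
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    mets = [f"M{i:04d}" for i in range(1, cfg.n_metabolites_pool + 1)]
    drugs = [f"D{i:04d}" for i in range(1, cfg.n_drugs_pool + 1)]

    lo, hi = cfg.targets_per_metabolite
    m2t = {
        m: frozenset(
            str(g) for g in rng.choice(genes, size=int(rng.integers(lo, hi + 1)), replace=False)
        )
        for m in mets
    }
    lo, hi = cfg.metabolites_per_drug
    d2m = {
        d: frozenset(
            str(m) for m in rng.choice(mets, size=int(rng.integers(lo, hi + 1)), replace=False)
        )
        for d in drugs
    }
    maps = ComponentMap(d2m, m2t)

    n_disease = max(1, int(round(cfg.disease_target_fraction * cfg.n_genes)))
    disease = frozenset(str(g) for g in rng.choice(genes, size=n_disease, replace=False))

    # pathways biased toward disease genes so over-representation of drug
    # targets (subsets of the disease list) is non-degenerate
    disease_list = sorted(disease)
    other_list = sorted(set(genes) - disease)
    lo, hi = cfg.pathway_size
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(1, cfg.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        n_dis = min(len(disease_list), size // 2)
        chosen = {str(g) for g in rng.choice(disease_list, size=n_dis, replace=False)}
        chosen |= {str(g) for g in rng.choice(other_list, size=size - n_dis, replace=False)}
        sets[f"PTH{i:03d}"] = (f"synthetic pathway {i}", frozenset(chosen))
    leftover = set(genes) - set().union(*(g for _, g in sets.values()))
    if leftover:
        sets["PTH_BG"] = ("background (uncovered genes)", frozenset(leftover))
    gene_sets = GeneSetCollection(sets)
    return maps, disease, gene_sets


def generate_ensemble(config: SyntheticConfig) -> list[PrescriptionBundle]:
    """Seeded ensemble of prescription bundles sharing one database.

    Dosage ratios are log-uniform on [1, dosage_ratio_max]; the first
    ``round(null_fraction * n)`` prescriptions get exactly equal dosages
    (null cases where both network variants coincide).  Output is fully
    deterministic given the seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    maps, disease, gene_sets = _sample_database(cfg, rng)
    pool = sorted(maps.drug_to_metabolites)
    n_null = int(round(cfg.null_fraction * cfg.n_prescriptions))

    bundles: list[PrescriptionBundle] = []
    lo, hi = cfg.drugs_per_prescription
    for i in range(cfg.n_prescriptions):
        n_drugs = int(rng.integers(lo, hi + 1))
        chosen = sorted(str(d) for d in rng.choice(pool, size=n_drugs, replace=False))
        dynasty = Dynasty.SONG_YUAN if rng.integers(2) == 0 else Dynasty.MING_QING
        if i < n_null:
            fen_equiv = np.ones(n_drugs)  # equal-dosage null case
        elif cfg.dosage_pattern == "monarch":
            fen_equiv = np.ones(n_drugs)
            ratio = np.exp(rng.uniform(np.log(cfg.dosage_ratio_min),
                                       np.log(cfg.dosage_ratio_max)))
            fen_equiv[int(rng.integers(n_drugs))] = ratio
        elif cfg.dosage_pattern == "monarch_fixed_sd":
            # sample SD of [r, 1, ..., 1] is (r - 1) / sqrt(n), so this
            # chief ratio pins the SD at ~sd_level for every size n
            fen_equiv = np.ones(n_drugs)
            ratio = 1.0 + cfg.sd_level * np.sqrt(n_drugs) * np.exp(
                rng.normal(0.0, cfg.sd_noise))
            fen_equiv[int(rng.integers(n_drugs))] = ratio
        else:
            fen_equiv = np.exp(
                rng.uniform(np.log(cfg.dosage_ratio_min),
                            np.log(cfg.dosage_ratio_max), size=n_drugs)
            )
        records = []
        for drug, fe in zip(chosen, fen_equiv):
            unit = (Unit.FEN, Unit.QIAN, Unit.LIANG)[int(rng.integers(3))]
            per_unit = {"Fen": 1, "Qian": 10, "Liang": 100}[unit.value]
            records.append(DosageRecord(drug, float(fe) / per_unit, unit, dynasty))
        bundles.append(
            PrescriptionBundle(
                prescription_id=f"RX{i + 1:03d}",
                records=tuple(records),
                maps=maps,
                disease_targets=disease,
                gene_sets=gene_sets,
            )
        )
    return bundles


def write_bundle(bundle: PrescriptionBundle, directory) -> dict[str, Path]:
    """Write a bundle as the five plain-text files the readers accept."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "prescription": directory / "prescription.csv",
        "drug_metabolite": directory / "drug_metabolite.tsv",
        "metabolite_target": directory / "metabolite_target.tsv",
        "disease_targets": directory / "disease_targets.txt",
        "gene_sets": directory / "gene_sets.gmt",
    }
    dio.write_prescriptions({bundle.prescription_id: list(bundle.records)},
                            paths["prescription"])
    dio.write_component_map(bundle.maps, paths["drug_metabolite"],
                            paths["metabolite_target"])
    dio.write_disease_targets(bundle.disease_targets, paths["disease_targets"])
    if bundle.gene_sets is not None:
        dio.write_gmt(bundle.gene_sets, paths["gene_sets"])
    else:
        del paths["gene_sets"]
    return paths


def read_bundle(directory, min_genes: int = 10, p_cutoff: float = 0.05) -> PrescriptionBundle:
    """Read back a directory written by :func:`write_bundle`."""
    directory = Path(directory)
    prescriptions = dio.read_prescriptions(directory / "prescription.csv")
    (pid, records), = prescriptions.items()
    maps = dio.read_component_map(directory / "drug_metabolite.tsv",
                                  directory / "metabolite_target.tsv")
    disease = dio.read_disease_targets(directory / "disease_targets.txt")
    gmt = directory / "gene_sets.gmt"
    gene_sets = dio.read_gmt(gmt) if gmt.exists() else None
    return PrescriptionBundle(pid, tuple(records), maps, disease, gene_sets,
                              min_genes=min_genes, p_cutoff=p_cutoff)


def ensure_valid(bundle: PrescriptionBundle) -> None:
    """Raise if a bundle fails prescription screening."""
    report = validate_prescription(bundle.records, bundle.maps.drug_to_metabolites)
    if not report:
        raise ValueError("; ".join(report.reasons))
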