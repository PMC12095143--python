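"""Dosage records, historical-unit conversion and dosage standardization.

Pre-modern Chinese prescriptions state each botanical drug's dose in
dynastic mass units (Fen, Qian, Liang) whose metric value depends on the
era: one Fen weighed 0.4 g under the Song-Yuan standard and 0.37 g under
the Ming-Qing standard, with 1 Liang = 10 Qian = 100 Fen in both.  After
conversion to grams, the per-drug doses are standardized by dividing by
the minimum dose, producing a dimensionless ratio vector whose smallest
component is exactly 1.  This standardized vector is what the weighted
network consumes; the unweighted (non-dosage) variant corresponds to the
all-ones vector of the same length.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Unit",
    "Dynasty",
    "ConversionTable",
    "DosageRecord",
    "DosageVector",
    "ValidationReport",
    "convert_to_grams",
    "standardize",
    "ones_vector",
    "validate_prescription",
]


class UnitConversionError(ValueError):
    """Raised for non-quantifiable or unknown dosage units."""


class Unit(str, enum.Enum):
    """Quantifiable mass units accepted by the pipeline."""

    FEN = "Fen"
    QIAN = "Qian"
    LIANG = "Liang"
    GRAM = "gram"


class Dynasty(str, enum.Enum):
    """Metric standards for the historical units."""

    SONG_YUAN = "SongYuan"
    MING_QING = "MingQing"


@dataclass(frozen=True)
class ConversionTable:
    """Unit-conversion constants, loadable from a YAML config.

    ``fen_per_unit`` maps each historical unit to its size in Fen and
    ``grams_per_fen`` maps each dynasty to the gram value of one Fen.
    """

    fen_per_unit: Mapping[str, float]
    grams_per_fen: Mapping[str, float]
    version: int = 1

    @classmethod
    def default(cls) -> "ConversionTable":
        """Load the table shipped with the package."""
        ref = importlib.resources.files("dosagenet.data") / "unit_conversion.yaml"
        raw = yaml.safe_load(ref.read_text())
        return cls(
            fen_per_unit=dict(raw["fen_per_unit"]),
            grams_per_fen=dict(raw["grams_per_fen"]),
            version=int(raw.get("version", 1)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ConversionTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            fen_per_unit=dict(raw["fen_per_unit"]),
            grams_per_fen=dict(raw["grams_per_fen"]),
            version=int(raw.get("version", 1)),
        )


_DEFAULT_TABLE: ConversionTable | None = None


def _default_table() -> ConversionTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ConversionTable.default()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class DosageRecord:
    """One botanical drug's dose: a positive quantity of a named unit.

    ``unit`` must be one of the quantifiable units (Fen, Qian, Liang or
    gram); count or volume descriptions such as "50 grains" are rejected
    rather than coerced. ``dynasty`` selects the metric standard and has
    no default because the two standards differ.
    """

    drug_id: str
    quantity: float
    unit: Unit
    dynasty: Dynasty

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")
        if not np.isfinite(self.quantity) or self.quantity <= 0:
            raise ValueError(
                f"quantity must be a positive finite number, got {self.quantity!r}"
            )
        # Accept plain strings but fail loudly on anything outside the enums.
        try:
            object.__setattr__(self, "unit", Unit(self.unit))
        except ValueError:
            raise UnitConversionError(
                f"non-quantifiable or unknown unit {self.unit!r} "
                f"for drug {self.drug_id!r}"
            ) from None
        try:
            object.__setattr__(self, "dynasty", Dynasty(self.dynasty))
        except ValueError:
            raise ValueError(
                f"unknown dynasty {self.dynasty!r} for drug {self.drug_id!r}"
            ) from None


@dataclass(frozen=True)
class DosageVector:
    """Standardized (min-normalized) per-drug weights.

    After :func:`standardize`, every component is >= 1 and the minimum is
    exactly 1.  The dosage-weighted network uses this vector; the
    non-dosage network uses the matching all-ones vector.
    """

    drug_ids: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.drug_ids) != len(self.values):
            raise ValueError("drug_ids and values must have equal length")
        if len(self.drug_ids) != len(set(self.drug_ids)):
            raise ValueError("drug_ids must be unique")
        if any(v <= 0 or not np.isfinite(v) for v in self.values):
            raise ValueError("all dosage components must be positive and finite")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def weight_of(self, drug_id: str) -> float:
        try:
            return self.values[self.drug_ids.index(drug_id)]
        except ValueError:
            raise KeyError(f"drug {drug_id!r} not in dosage vector") from None

    def is_uniform(self) -> bool:
        return len(set(self.values)) == 1


def convert_to_grams(
    record: DosageRecord, table: ConversionTable | None = None
) -> float:
    """Convert one dosage record to grams.

    grams = quantity x (Fen per unit) x (grams per Fen for the dynasty);
    gram-denominated records pass through unchanged.
    """
    table = table or _default_table()
    if record.unit is Unit.GRAM:
        return float(record.quantity)
    try:
        fen = table.fen_per_unit[record.unit.value]
    except KeyError:
        raise UnitConversionError(
            f"unit {record.unit.value!r} missing from conversion table"
        ) from None
    try:
        gpf = table.grams_per_fen[record.dynasty.value]
    except KeyError:
        raise UnitConversionError(
            f"dynasty {record.dynasty.value!r} missing from conversion table"
        ) from None
    return float(record.quantity) * float(fen) * float(gpf)


def standardize(
    records: Sequence[DosageRecord], table: ConversionTable | None = None
) -> DosageVector:
    """Standardize a prescription's doses to a min-1 ratio vector.

    Every dose is converted to grams and divided by the smallest gram
    dose, so the result is scale-invariant: doubling every dose (or
    re-expressing it in a finer unit) leaves the vector unchanged.
    Mixed units are allowed; mixed dynasties are rejected because the
    gram value of a Fen differs between standards.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot standardize an empty prescription")
    dynasties = {r.dynasty for r in records}
    if len(dynasties) > 1:
        raise ValueError(
            f"mixed dynasties within one prescription: "
            f"{sorted(d.value for d in dynasties)}"
        )
    ids = [r.drug_id for r in records]
    grams = np.array([convert_to_grams(r, table) for r in records], dtype=float)
    if np.any(grams <= 0):
        raise ValueError("all converted masses must be positive")
    return DosageVector(tuple(ids), tuple(grams / grams.min()))


def ones_vector(n: int, drug_ids: Sequence[str] | None = None) -> DosageVector:
    """The all-ones dosage vector of length ``n`` (the non-dosage input)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if drug_ids is None:
        drug_ids = tuple(f"drug{i + 1}" for i in range(n))
    else:
        drug_ids = tuple(drug_ids)
        if len(drug_ids) != n:
            raise ValueError("drug_ids length must equal n")
    return DosageVector(drug_ids, (1.0,) * n)


@dataclass
class ValidationReport:
    """Structured pass/fail result of prescription screening."""

    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_prescription(
    records: Iterable[object],
    drug_to_metabolites: Mapping[str, set] | None = None,
) -> ValidationReport:
    """Screen a prescription against the two exclusion rules.

    A prescription fails if (1) any drug's dose uses a non-quantifiable
    unit, or (2) any drug has no bioactive-metabolite/target data in the
    supplied map.  Records may be :class:`DosageRecord` instances or raw
    ``(drug_id, quantity, unit, dynasty)``-like mappings; raw records
    with bad units are reported, not raised.
    """
    reasons: list[str] = []
    parsed: list[DosageRecord] = []
    for rec in records:
        if isinstance(rec, DosageRecord):
            parsed.append(rec)
            continue
        if isinstance(rec, Mapping):
            kwargs = dict(rec)
        else:  # tuple-like
            kwargs = dict(
                zip(("drug_id", "quantity", "unit", "dynasty"), rec)
            )
        try:
            parsed.append(DosageRecord(**kwargs))
        except UnitConversionError:
            reasons.append(
                f"drug {kwargs.get('drug_id')!r}: non-quantifiable unit "
                f"{kwargs.get('unit')!r}"
            )
        except (TypeError, ValueError) as exc:
            reasons.append(f"drug {kwargs.get('drug_id')!r}: {exc}")
    if not parsed and not reasons:
        reasons.append("empty prescription")
    if drug_to_metabolites is not None:
        for rec in parsed:
            if not drug_to_metabolites.get(rec.drug_id):
                reasons.append(
                    f"drug {rec.drug_id!r}: no metabolite/target data"
                )
    return ValidationReport(passed=not reasons, reasons=reasons)
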