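"""Quantify drug-target mechanisms of action into per-drug treatment vectors."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .model_builder import FILTERED, SystemModel, canonical_gene

__all__ = [
    "MechanismTable",
    "DrugProfile",
    "TreatmentVector",
    "quantify_drug_action",
    "build_treatment_vector",
    "DEFAULT_DRUG_MIN_CONFIDENCE",
    "SET_LABELS",
]

logger = logging.getLogger(__name__)

#: Minimum drug-interaction confidence (0-1000 scale) for score-bearing rows.
DEFAULT_DRUG_MIN_CONFIDENCE = 800.0

SET_LABELS = ("D1", "D2", "D3", "unlabeled")


@dataclass
class MechanismTable:
    """Mechanism-of-action label -> signed action value, with a fallback.

    The default table ships with the package; unlisted labels quantify to
    ``fallback`` (0, the catch-all for "other terms").
    """

    mapping: dict[str, float]
    fallback: float = 0.0

    def __post_init__(self) -> None:
        self.mapping = {k.strip().casefold(): float(v) for k, v in self.mapping.items()}
        bad = {k: v for k, v in self.mapping.items() if not -1 <= v <= 1}
        if bad:
            raise ValueError(f"mechanism values outside [-1, 1]: {bad}")

    def value(self, mechanism: str) -> float:
        return self.mapping.get(mechanism.strip().casefold(), self.fallback)

    def __len__(self) -> int:
        return len(self.mapping)

    @classmethod
    def from_tsv(cls, path: str | Path, fallback: float = 0.0) -> "MechanismTable":
        mapping: dict[str, float] = {}
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            if reader.fieldnames is None or {"mechanism", "value"} - set(reader.fieldnames):
                raise ValueError(f"mechanism table {path} needs columns mechanism, value")
            for row in reader:
                mapping[row["mechanism"]] = float(row["value"])
        return cls(mapping=mapping, fallback=fallback)

    @classmethod
    def default(cls) -> "MechanismTable":
        ref = resources.files("decost").joinpath("data/mechanism_table.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class DrugProfile:
    """A drug, its evaluation-set label, and its (gene, mechanism, confidence) targets."""

    drug: str
    set_label: str
    targets: tuple[tuple[str, str, float | None], ...]

    def __post_init__(self) -> None:
        if not self.drug or not self.drug.strip():
            raise ValueError("drug name must be non-empty")
        if self.set_label not in SET_LABELS:
            raise ValueError(
                f"set label {self.set_label!r} not in {SET_LABELS} for drug {self.drug!r}"
            )
        object.__setattr__(self, "targets", tuple(self.targets))


@dataclass
class TreatmentVector:
    """Quantified drug-action vector aligned to a model's gene order."""

    drug: str
    u_d: np.ndarray
    n_targets_in_model: int
    n_targets_outside_model: int = 0
    set_label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.u_d = np.asarray(self.u_d, dtype=float)
        if not np.all(np.isfinite(self.u_d)):
            raise ValueError(f"treatment vector for {self.drug!r} has non-finite entries")


def quantify_drug_action(
    mechanism: str,
    confidence: float | None = None,
    table: MechanismTable | None = None,
    min_confidence: float = DEFAULT_DRUG_MIN_CONFIDENCE,
) -> float | object:
    """Look up a mechanism's action value, or FILTERED on low confidence.

    The confidence filter only applies to rows that carry a score (curated
    drug-bank style rows come without one and always pass).
    """
    if confidence is not None and confidence < min_confidence:
        return FILTERED
    if table is None:
        table = MechanismTable.default()
    return table.value(mechanism)


def build_treatment_vector(
    profile: DrugProfile,
    model: SystemModel,
    table: MechanismTable | None = None,
    aggregation: str = "sum",
    min_confidence: float = DEFAULT_DRUG_MIN_CONFIDENCE,
) -> TreatmentVector:
    """Aggregate a drug's quantified target actions onto the model genes.

    Multiple surviving interactions on one gene combine by ``sum`` (default,
    lets opposing mechanisms cancel) or ``mean``.  Targets outside the model
    are counted, not an error.
    """
    if aggregation not in ("sum", "mean"):
        raise ValueError(f"aggregation must be 'sum' or 'mean', got {aggregation!r}")
    if table is None:
        table = MechanismTable.default()
    totals = np.zeros(model.n_genes)
    counts = np.zeros(model.n_genes, dtype=int)
    outside = 0
    for gene, mechanism, confidence in profile.targets:
        value = quantify_drug_action(mechanism, confidence, table, min_confidence)
        if value is FILTERED:
            continue
        i = model.index.get(canonical_gene(gene))
        if i is None:
            outside += 1
            continue
        totals[i] += value
        counts[i] += 1
    if aggregation == "mean":
        nonzero = counts > 0
        totals[nonzero] /= counts[nonzero]
    return TreatmentVector(
        drug=profile.drug,
        u_d=totals,
        n_targets_in_model=int(counts.sum()),
        n_targets_outside_model=outside,
        set_label=profile.set_label,
    )
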