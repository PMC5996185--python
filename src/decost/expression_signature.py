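"""Discretize a differential-expression top-table into {-1, 0, +1} states."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .model_builder import SystemModel, canonical_gene

__all__ = [
    "ExpressionRecord",
    "ExpressionSignature",
    "AlignedSignature",
    "discretize_expression",
    "align_signature",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ExpressionRecord:
    """One row of a limma-style top-table: gene, logFC, adjusted p-value."""

    gene: str
    logFC: float
    adj_p: float

    def __post_init__(self) -> None:
        if not self.gene or not self.gene.strip():
            raise ValueError("expression record gene must be non-empty")
        if not math.isfinite(self.logFC):
            raise ValueError(f"non-finite logFC for gene {self.gene!r}")
        if not 0 <= self.adj_p <= 1:
            raise ValueError(f"adj_p {self.adj_p!r} outside [0, 1] for {self.gene!r}")


@dataclass
class ExpressionSignature:
    """Per-gene discretized dysregulation state, keyed by canonical gene id."""

    values: dict[str, int]
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.values.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"signature values outside {{-1, 0, +1}}: {bad}")

    def __len__(self) -> int:
        return len(self.values)


class AlignedSignature(NamedTuple):
    """Initial-condition vector for a model plus match bookkeeping."""

    x0: np.ndarray
    n_matched: int
    n_unmatched: int


def discretize_expression(
    records: Iterable[ExpressionRecord], alpha: float = DEFAULT_ALPHA
) -> ExpressionSignature:
    """Threshold adjusted p-values and keep the sign of logFC.

    Genes with ``adj_p > alpha`` map to 0; significant genes map to the sign
    of their logFC (0 if logFC is exactly 0).  The boundary ``adj_p == alpha``
    is kept as significant.  A gene appearing on several rows (multiple
    probes) is resolved by its smallest adjusted p-value.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    best: dict[str, ExpressionRecord] = {}
    for rec in records:
        key = canonical_gene(rec.gene)
        if key not in best or rec.adj_p < best[key].adj_p:
            best[key] = rec
    values = {}
    for key, rec in best.items():
        if rec.adj_p > alpha:
            values[key] = 0
        else:
            values[key] = int(np.sign(rec.logFC))
    return ExpressionSignature(values=values, alpha=alpha)


def align_signature(signature: ExpressionSignature, model: SystemModel) -> AlignedSignature:
    """Project the signature onto the model's gene order as x(0).

    Genes absent from the signature contribute 0; signature genes absent from
    the model are counted as unmatched.
    """
    x0 = np.zeros(model.n_genes)
    matched = 0
    for gene, value in signature.values.items():
        i = model.index.get(gene)
        if i is not None:
            x0[i] = value
            matched += 1
    unmatched = len(signature.values) - matched
    if unmatched:
        logger.info("%d signature genes not present in the model", unmatched)
    return AlignedSignature(x0=x0, n_matched=matched, n_unmatched=unmatched)
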