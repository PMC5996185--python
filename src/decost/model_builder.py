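"""Build the signed-interaction system model.

A table of directed, mechanism-labelled gene-gene interactions is quantified
into a raw adjacency matrix (activation ``+1``, inhibition ``-1``, everything
else ``0``; parallel edges summed then clipped to ``[-1, 1]``) and then
normalized by the largest eigenvalue magnitude so that the discrete-time
linear dynamics ``x(t) = A x(t-1) + u(t-1)`` cannot diverge under zero
control.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FILTERED",
    "InteractionRecord",
    "SystemModel",
    "EmptyModelError",
    "quantify_interaction",
    "build_adjacency",
    "normalize_dynamics",
    "canonical_gene",
]

logger = logging.getLogger(__name__)

#: Mechanism labels that are meaningful but carry no signed effect.
NEUTRAL_MECHANISMS = frozenset(
    {"expression", "catalysis", "ptmod", "binding", "reaction", "other"}
)

#: Default minimum interaction confidence on the 0-1000 scale.
DEFAULT_MIN_CONFIDENCE = 500.0

#: Eigenvalue magnitudes below this are treated as an exactly-nilpotent matrix.
SPECTRAL_TOL = 1e-12


class _Filtered:
    """Sentinel returned when an interaction fails its confidence filter."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "FILTERED"

    def __bool__(self) -> bool:
        return False


FILTERED = _Filtered()


class EmptyModelError(ValueError):
    """No interaction survives the confidence filter."""


def canonical_gene(gene: str) -> str:
    """Whitespace-trimmed, case-folded form used for all identifier matching."""
    return gene.strip().casefold()


@dataclass(frozen=True)
class InteractionRecord:
    """One signed, directed gene->gene edge with mechanism and confidence."""

    source: str
    target: str
    mechanism: str
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not self.source or not self.source.strip():
            raise ValueError("interaction source must be a non-empty string")
        if not self.target or not self.target.strip():
            raise ValueError("interaction target must be a non-empty string")
        if self.confidence is not None and not 0 <= self.confidence <= 1000:
            raise ValueError(
                f"confidence {self.confidence!r} outside [0, 1000] "
                f"for edge {self.source}->{self.target}"
            )


@dataclass
class SystemModel:
    """Gene index plus raw and normalized dynamics matrices.

    ``layout='incoming'`` (the default) stores entry ``(i, j)`` as the effect
    of gene ``j`` ON gene ``i``, so that ``dynamics @ x`` propagates influence
    along the directed edges.  ``layout='paper-literal'`` stores the
    transpose, i.e. entry ``(i, j)`` is the effect of gene ``i`` on ``j``.
    """

    genes: list[str]
    raw_adjacency: np.ndarray
    dynamics: np.ndarray | None = None
    normalization: float | None = None
    layout: str = "incoming"
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene list contains duplicates")
        n = len(self.genes)
        self.raw_adjacency = np.asarray(self.raw_adjacency, dtype=float)
        if self.raw_adjacency.shape != (n, n):
            raise ValueError(
                f"raw_adjacency shape {self.raw_adjacency.shape} != ({n}, {n})"
            )
        if self.dynamics is not None:
            self.dynamics = np.asarray(self.dynamics, dtype=float)
            if self.dynamics.shape != (n, n):
                raise ValueError("dynamics matrix shape mismatch")
        self.index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def save(self, directory: str | Path) -> None:
        """Serialize as genes.txt / raw_adjacency.tsv / dynamics.tsv / meta.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "genes.txt").write_text("\n".join(self.genes) + "\n")
        np.savetxt(directory / "raw_adjacency.tsv", self.raw_adjacency, delimiter="\t")
        if self.dynamics is not None:
            np.savetxt(directory / "dynamics.tsv", self.dynamics, delimiter="\t")
        meta = {
            "n_genes": self.n_genes,
            "normalization": self.normalization,
            "layout": self.layout,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "SystemModel":
        directory = Path(directory)
        genes = (directory / "genes.txt").read_text().split()
        raw = np.loadtxt(directory / "raw_adjacency.tsv", delimiter="\t", ndmin=2)
        meta = json.loads((directory / "meta.json").read_text())
        dynamics = None
        dyn_path = directory / "dynamics.tsv"
        if dyn_path.exists():
            dynamics = np.loadtxt(dyn_path, delimiter="\t", ndmin=2)
        return cls(
            genes=genes,
            raw_adjacency=raw,
            dynamics=dynamics,
            normalization=meta.get("normalization"),
            layout=meta.get("layout", "incoming"),
        )


def quantify_interaction(
    mechanism: str,
    confidence: float | None = None,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> float | _Filtered:
    """Map a mechanism label to its signed value, or FILTERED.

    Returns ``FILTERED`` when a confidence score is present and below
    ``min_confidence``; otherwise ``+1`` for activation, ``-1`` for
    inhibition and ``0`` for every other label (case-insensitive).  Unknown
    labels map to ``0`` with a logged warning.  Edges without a confidence
    score (curated-pathway edges) always pass the filter.
    """
    if confidence is not None and confidence < min_confidence:
        return FILTERED
    label = mechanism.strip().casefold()
    if label == "activation":
        return 1.0
    if label == "inhibition":
        return -1.0
    if label not in NEUTRAL_MECHANISMS:
        logger.warning("unknown interaction mechanism %r quantified as 0", mechanism)
    return 0.0


def build_adjacency(
    records: Iterable[InteractionRecord],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    layout: str = "incoming",
) -> SystemModel:
    """Quantify interactions into the raw adjacency matrix.

    The gene index is the sorted union of sources and targets of all
    surviving (unfiltered) records; parallel edges between one ordered pair
    are summed and the total clipped to ``[-1, 1]``.
    """
    if layout not in ("incoming", "paper-literal"):
        raise ValueError(f"unknown adjacency layout {layout!r}")
    surviving: list[tuple[str, str, float]] = []
    n_filtered = 0
    for rec in records:
        value = quantify_interaction(rec.mechanism, rec.confidence, min_confidence)
        if value is FILTERED:
            n_filtered += 1
            continue
        surviving.append((canonical_gene(rec.source), canonical_gene(rec.target), value))
    if not surviving:
        raise EmptyModelError(
            f"no interactions survive the confidence filter "
            f"(min_confidence={min_confidence}, filtered={n_filtered})"
        )
    genes = sorted({g for s, t, _ in surviving for g in (s, t)})
    index = {g: i for i, g in enumerate(genes)}
    matrix = np.zeros((len(genes), len(genes)))
    for source, target, value in surviving:
        if layout == "incoming":
            matrix[index[target], index[source]] += value
        else:
            matrix[index[source], index[target]] += value
    np.clip(matrix, -1.0, 1.0, out=matrix)
    logger.info(
        "built %d-gene model from %d interactions (%d filtered)",
        len(genes), len(surviving), n_filtered,
    )
    return SystemModel(genes=genes, raw_adjacency=matrix, layout=layout)


def normalize_dynamics(model: SystemModel, stability_margin: float = 0.0) -> SystemModel:
    """Divide the raw adjacency by its largest eigenvalue magnitude.

    The divisor is ``|lambda| * (1 + stability_margin)`` where ``lambda`` is
    the eigenvalue of largest magnitude; the magnitude (not the possibly
    complex eigenvalue itself) keeps the dynamics matrix real.  A matrix
    whose spectrum is numerically zero (e.g. nilpotent) is left unchanged
    and the normalization recorded as 0.
    """
    raw = model.raw_adjacency
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw adjacency contains non-finite entries")
    if stability_margin < 0:
        raise ValueError("stability_margin must be >= 0")
    radius = float(np.max(np.abs(np.linalg.eigvals(raw)))) if raw.size else 0.0
    if radius > SPECTRAL_TOL:
        divisor = radius * (1.0 + stability_margin)
        model.dynamics = raw / divisor
        model.normalization = divisor
    else:
        model.dynamics = raw.copy()
        model.normalization = 0.0
    return model
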