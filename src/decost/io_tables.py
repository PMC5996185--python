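"""Table readers/writers, run configuration and the end-to-end pipeline.

All tables are UTF-8, header-bearing, tab-delimited by default with comma
auto-detection.  Interaction tables may also arrive as simple interaction
format (``.sif``), where the relation token is taken as the mechanism.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .drug_treatment import (
    DEFAULT_DRUG_MIN_CONFIDENCE,
    DrugProfile,
    MechanismTable,
    SET_LABELS,
    TreatmentVector,
    build_treatment_vector,
)
from .expression_signature import (
    DEFAULT_ALPHA,
    ExpressionRecord,
    ExpressionSignature,
    align_signature,
    discretize_expression,
)
from .lqr_control import (
    DEFAULT_MAX_ITER,
    DEFAULT_SIGN_TOL,
    DEFAULT_TOL,
    HypoTreatment,
    RiccatiSolution,
    hypo_treatment,
    solve_dare,
)
from .model_builder import (
    DEFAULT_MIN_CONFIDENCE,
    InteractionRecord,
    SystemModel,
    build_adjacency,
    normalize_dynamics,
)
from .scoring_eval import RocResult, TherapeuticScore, rank_drugs, roc_auc, therapeutic_score

__all__ = [
    "RunConfig",
    "PipelineError",
    "PipelineResult",
    "TableReadResult",
    "read_interaction_table",
    "read_expression_table",
    "read_drug_table",
    "write_signature_tsv",
    "read_signature_tsv",
    "write_hypo_tsv",
    "write_scores_tsv",
    "write_roc_json",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

# accepted header aliases, all matched case-insensitively
_GENE_ALIASES = ("gene", "gene.symbol", "gene_symbol", "symbol", "id")
_LOGFC_ALIASES = ("logfc", "log_fc")
_ADJP_ALIASES = ("adj.p.val", "adj_p", "adj_p_val", "adjusted_p", "padj")


class TableReadResult(NamedTuple):
    records: list
    n_rows: int
    n_skipped: int


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run; serialized into every output."""

    interactions: str | None = None
    expression: str | None = None
    drugs: str | None = None
    out_dir: str = "decost_out"
    alpha: float = DEFAULT_ALPHA
    min_ppi_confidence: float = DEFAULT_MIN_CONFIDENCE
    min_drug_confidence: float = DEFAULT_DRUG_MIN_CONFIDENCE
    stability_margin: float = 0.0
    sign_tol: float = DEFAULT_SIGN_TOL
    solver_tol: float = DEFAULT_TOL
    solver_max_iter: int = DEFAULT_MAX_ITER
    aggregation: str = "sum"
    abs_numerator: bool = False
    undefined_as_zero: bool = False
    adjacency_layout: str = "incoming"
    mechanism_table: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("min_ppi_confidence", "min_drug_confidence"):
            value = getattr(self, name)
            if not 0 <= value <= 1000:
                raise ValueError(f"{name} must be in [0, 1000], got {value}")
        if self.stability_margin < 0:
            raise ValueError("stability_margin must be >= 0")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError("aggregation must be 'sum' or 'mean'")
        if self.adjacency_layout not in ("incoming", "paper-literal"):
            raise ValueError("adjacency_layout must be 'incoming' or 'paper-literal'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON key-value config file; keyword overrides win."""
        data = json.loads(Path(path).read_text())
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, sniffing tab vs comma, with casefolded headers."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    df.columns = [str(c).strip().casefold() for c in df.columns]
    return df


def _pick_column(df: pd.DataFrame, aliases: tuple[str, ...], path, required: bool = True):
    for alias in aliases:
        if alias in df.columns:
            return alias
    if required:
        raise ValueError(
            f"missing required column (one of {aliases}) in {path}; found {list(df.columns)}"
        )
    return None


def _parse_confidence(raw) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text or text.lower() in ("na", "nan", "none"):
        return None
    return float(text)


def read_interaction_table(path: str | Path) -> TableReadResult:
    """Read interactions from TSV/CSV (source, target, mechanism[, confidence]) or SIF."""
    path = Path(path)
    if path.suffix.lower() == ".sif":
        return _read_sif(path)
    df = _read_table(path)
    source_col = _pick_column(df, ("source",), path)
    target_col = _pick_column(df, ("target",), path)
    mech_col = _pick_column(df, ("mechanism",), path)
    conf_col = _pick_column(df, ("confidence",), path, required=False)
    records, skipped = [], 0
    for _, row in df.iterrows():
        try:
            records.append(
                InteractionRecord(
                    source=str(row[source_col]),
                    target=str(row[target_col]),
                    mechanism=str(row[mech_col]),
                    confidence=_parse_confidence(row[conf_col]) if conf_col else None,
                )
            )
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping malformed interaction row: %s", exc)
    logger.info("%s: %d interactions read, %d rows skipped", path, len(records), skipped)
    return TableReadResult(records, len(df), skipped)


def _read_sif(path: Path) -> TableReadResult:
    records, n_rows, skipped = [], 0, 0
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        n_rows += 1
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            skipped += 1
            continue
        source, mechanism, *targets = parts
        for target in targets:
            try:
                records.append(
                    InteractionRecord(source=source, target=target, mechanism=mechanism)
                )
            except ValueError:
                skipped += 1
    return TableReadResult(records, n_rows, skipped)


def read_expression_table(path: str | Path) -> TableReadResult:
    """Read a top-table with columns gene / logFC / adj.P.Val (aliases accepted)."""
    path = Path(path)
    df = _read_table(path)
    gene_col = _pick_column(df, _GENE_ALIASES, path)
    logfc_col = _pick_column(df, _LOGFC_ALIASES, path)
    adjp_col = _pick_column(df, _ADJP_ALIASES, path)
    records, skipped = [], 0
    for _, row in df.iterrows():
        try:
            records.append(
                ExpressionRecord(
                    gene=str(row[gene_col]),
                    logFC=float(row[logfc_col]),
                    adj_p=float(row[adjp_col]),
                )
            )
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping malformed expression row: %s", exc)
    logger.info("%s: %d expression rows read, %d skipped", path, len(records), skipped)
    return TableReadResult(records, len(df), skipped)


def read_drug_table(path: str | Path) -> TableReadResult:
    """Read drug-target rows (drug, set_label, gene, mechanism[, confidence]) into profiles."""
    path = Path(path)
    df = _read_table(path)
    drug_col = _pick_column(df, ("drug",), path)
    label_col = _pick_column(df, ("set_label", "set", "label"), path)
    gene_col = _pick_column(df, ("gene", "target"), path)
    mech_col = _pick_column(df, ("mechanism",), path)
    conf_col = _pick_column(df, ("confidence",), path, required=False)
    grouped: dict[str, dict] = {}
    skipped = 0
    for _, row in df.iterrows():
        try:
            drug = str(row[drug_col]).strip()
            label = str(row[label_col]).strip()
            if label not in SET_LABELS:
                raise ValueError(
                    f"unknown drug set label {label!r} for drug {drug!r}; "
                    f"allowed labels are {SET_LABELS}"
                )
            gene = str(row[gene_col])
            if not drug or not gene.strip():
                raise ValueError("drug and gene must be non-empty")
            confidence = _parse_confidence(row[conf_col]) if conf_col else None
            entry = grouped.setdefault(drug, {"label": label, "targets": []})
            if entry["label"] != label:
                raise ValueError(f"drug {drug!r} has conflicting set labels")
            entry["targets"].append((gene, str(row[mech_col]), confidence))
        except ValueError as exc:
            if "set label" in str(exc) or "conflicting" in str(exc):
                raise
            skipped += 1
            logger.warning("skipping malformed drug row: %s", exc)
    profiles = [
        DrugProfile(drug=name, set_label=entry["label"], targets=tuple(entry["targets"]))
        for name, entry in grouped.items()
    ]
    logger.info("%s: %d drugs read from %d rows, %d skipped", path, len(profiles), len(df), skipped)
    return TableReadResult(profiles, len(df), skipped)


def write_interaction_tsv(records: list[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("source\ttarget\tmechanism\tconfidence\n")
        for rec in records:
            conf = "" if rec.confidence is None else f"{rec.confidence:g}"
            handle.write(f"{rec.source}\t{rec.target}\t{rec.mechanism}\t{conf}\n")


def write_expression_tsv(records: list[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene\tlogFC\tadj.P.Val\n")
        for rec in records:
            handle.write(f"{rec.gene}\t{rec.logFC:.6g}\t{rec.adj_p:.6g}\n")


def write_drug_tsv(profiles: list[DrugProfile], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("drug\tset_label\tgene\tmechanism\tconfidence\n")
        for profile in profiles:
            for gene, mechanism, confidence in profile.targets:
                conf = "" if confidence is None else f"{confidence:g}"
                handle.write(
                    f"{profile.drug}\t{profile.set_label}\t{gene}\t{mechanism}\t{conf}\n"
                )


def write_signature_tsv(signature: ExpressionSignature, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene\tstate\n")
        for gene in sorted(signature.values):
            handle.write(f"{gene}\t{signature.values[gene]}\n")


def read_signature_tsv(path: str | Path, alpha: float = DEFAULT_ALPHA) -> ExpressionSignature:
    df = _read_table(path)
    values = {
        str(row["gene"]).strip().casefold(): int(row["state"]) for _, row in df.iterrows()
    }
    return ExpressionSignature(values=values, alpha=alpha)


def write_hypo_tsv(treatment: HypoTreatment, model: SystemModel, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene\tu0\tsign\n")
        for gene, u, s in zip(model.genes, treatment.u0, treatment.sign_pattern):
            handle.write(f"{gene}\t{u:.12g}\t{int(s)}\n")


def write_scores_tsv(scores: list[TherapeuticScore], path: str | Path,
                     undefined_as_zero: bool = False) -> None:
    with open(path, "w") as handle:
        handle.write("drug\tset_label\tn_targets_in_model\tnumerator\tdenominator\tT_d\n")
        for score in scores:
            if score.t_d is not None:
                t_d = f"{score.t_d:.12g}"
            else:
                t_d = "0" if undefined_as_zero else "NA"
            handle.write(
                f"{score.drug}\t{score.set_label}\t{score.n_targets_in_model}\t"
                f"{score.numerator:.12g}\t{score.denominator:.12g}\t{t_d}\n"
            )


def write_roc_json(roc: RocResult, path: str | Path) -> None:
    payload = {
        "auc": roc.auc,
        "n_positive": roc.n_positive,
        "n_negative": roc.n_negative,
        "curve": [list(point) for point in roc.curve],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class PipelineResult:
    model: SystemModel
    signature: ExpressionSignature
    riccati: RiccatiSolution
    treatment: HypoTreatment
    scores: list[TherapeuticScore]
    roc: RocResult | None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute model building, signature, control, scoring and evaluation.

    Writes scores.tsv, hypo.tsv, signature.tsv, roc.json (when both D1 and
    D2 drugs are present), the serialized model, meta.json with solver
    diagnostics, and the resolved config for provenance.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json() + "\n")

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    interactions = stage(
        "read_tables", lambda: read_interaction_table(config.interactions).records
    )
    expression = stage(
        "read_tables", lambda: read_expression_table(config.expression).records
    )
    profiles = stage("read_tables", lambda: read_drug_table(config.drugs).records)

    def build():
        model = build_adjacency(
            interactions, config.min_ppi_confidence, layout=config.adjacency_layout
        )
        return normalize_dynamics(model, config.stability_margin)

    model = stage("model_builder", build)
    signature = stage(
        "expression_signature", lambda: discretize_expression(expression, config.alpha)
    )
    aligned = stage("expression_signature", lambda: align_signature(signature, model))
    riccati = stage(
        "lqr_control",
        lambda: solve_dare(model.dynamics, config.solver_tol, config.solver_max_iter),
    )
    treatment = stage(
        "lqr_control",
        lambda: hypo_treatment(riccati.P, model.dynamics, aligned.x0, config.sign_tol),
    )

    table = (
        MechanismTable.from_tsv(config.mechanism_table)
        if config.mechanism_table
        else MechanismTable.default()
    )

    def score_all():
        if not profiles:
            raise ValueError("no drugs to score (empty drug table)")
        scores = []
        for profile in profiles:
            vector = build_treatment_vector(
                profile, model, table, config.aggregation, config.min_drug_confidence
            )
            scores.append(
                therapeutic_score(vector, treatment.sign_pattern, config.abs_numerator)
            )
        return rank_drugs(scores)

    scores = stage("scoring_eval", score_all)

    roc = None
    has_d1 = any(s.set_label == "D1" and s.is_defined for s in scores)
    has_d2 = any(s.set_label == "D2" and s.is_defined for s in scores)
    if has_d1 and has_d2:
        roc = stage("scoring_eval", lambda: roc_auc(scores))
    else:
        logger.warning("skipping ROC: need defined scores in both D1 and D2")

    model.save(out_dir / "model")
    write_signature_tsv(signature, out_dir / "signature.tsv")
    write_hypo_tsv(treatment, model, out_dir / "hypo.tsv")
    write_scores_tsv(scores, out_dir / "scores.tsv", config.undefined_as_zero)
    if roc is not None:
        write_roc_json(roc, out_dir / "roc.json")
    meta = {
        "n_genes": model.n_genes,
        "normalization": model.normalization,
        "adjacency_layout": model.layout,
        "signature_genes": len(signature),
        "signature_matched": aligned.n_matched,
        "signature_unmatched": aligned.n_unmatched,
        "riccati_residual": riccati.residual,
        "riccati_iterations": riccati.iterations,
        "closed_loop_radius": riccati.closed_loop_radius,
        "n_drugs_scored": len(scores),
        "roc_auc": None if roc is None else roc.auc,
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return PipelineResult(
        model=model,
        signature=signature,
        riccati=riccati,
        treatment=treatment,
        scores=scores,
        roc=roc,
    )
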