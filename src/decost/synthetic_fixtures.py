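"""Synthetic scenarios with planted ground truth.

Generates a random signed network, a planted {-1, 0, +1} disease signature
emitted through a realistic top-table dialect, and drug panels whose "good"
members agree with the LQR control's sign pattern and whose "bad" members
oppose it, so the whole pipeline and its ranking can be tested offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drug_treatment import DrugProfile
from .expression_signature import (
    ExpressionRecord,
    ExpressionSignature,
    align_signature,
    discretize_expression,
)
from .lqr_control import hypo_treatment, solve_dare
from .model_builder import (
    InteractionRecord,
    SystemModel,
    build_adjacency,
    normalize_dynamics,
)

__all__ = [
    "ScenarioParams",
    "SyntheticScenario",
    "generate_network",
    "generate_expression_records",
    "generate_signature",
    "generate_drug_panel",
    "generate_scenario",
]

# label pool for "random" drugs; spans +1 / -1 / 0 quantifications
_RANDOM_MECHANISMS = (
    "Agonist", "Inhibitor", "Binder", "Stimulator", "Antagonist",
    "Ligand", "Activator", "Suppressor", "Modulator", "Potentiator",
)


@dataclass(frozen=True)
class ScenarioParams:
    n_genes: int = 100
    density: float = 0.05
    inhibition_fraction: float = 0.3
    n_dysregulated: int = 20
    n_good: int = 10
    n_bad: int = 10
    n_random: int = 0
    targets_per_drug: int = 5
    noise_rate: float = 0.0


@dataclass
class SyntheticScenario:
    """One fully generated scenario; same seed and params regenerate it exactly."""

    params: ScenarioParams
    seed: int
    interactions: list[InteractionRecord]
    model: SystemModel
    expression: list[ExpressionRecord]
    signature: ExpressionSignature
    drugs: list[DrugProfile]


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(
    n_genes: int,
    density: float,
    inhibition_fraction: float,
    seed: int | np.random.Generator,
) -> list[InteractionRecord]:
    """Directed Erdos-Renyi edge set with a given inhibition probability.

    Every ordered pair of distinct genes is an edge with probability
    ``density``; each edge is labelled ``inhibition`` with probability
    ``inhibition_fraction`` and ``activation`` otherwise.  No duplicate
    ordered pairs are produced.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if not 0 <= inhibition_fraction <= 1:
        raise ValueError("inhibition_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_genes):
        for j in range(n_genes):
            if i == j:
                continue
            if rng.random() < density:
                mech = "inhibition" if rng.random() < inhibition_fraction else "activation"
                records.append(
                    InteractionRecord(source=_gene_name(i), target=_gene_name(j), mechanism=mech)
                )
    return records


def generate_expression_records(
    model: SystemModel,
    n_dysregulated: int,
    seed: int | np.random.Generator,
) -> list[ExpressionRecord]:
    """Top-table rows whose discretization plants ±1 on a random gene subset.

    Dysregulated genes get a significant adjusted p-value (< 0.05) and a
    logFC whose sign is the planted state; every other model gene gets an
    insignificant p-value, so the planted signature survives discretization
    exactly.
    """
    if not 1 <= n_dysregulated <= model.n_genes:
        raise ValueError("n_dysregulated must be in [1, n_genes]")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(model.n_genes, size=n_dysregulated, replace=False).tolist())
    records = []
    for i, gene in enumerate(model.genes):
        if i in chosen:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            magnitude = rng.uniform(0.5, 3.0)
            records.append(
                ExpressionRecord(gene=gene, logFC=sign * magnitude, adj_p=rng.uniform(1e-6, 0.04))
            )
        else:
            records.append(
                ExpressionRecord(gene=gene, logFC=rng.uniform(-3, 3), adj_p=rng.uniform(0.06, 1.0))
            )
    return records


def generate_signature(
    model: SystemModel,
    n_dysregulated: int,
    seed: int | np.random.Generator,
) -> tuple[ExpressionSignature, list[ExpressionRecord]]:
    """Planted signature plus the top-table rows it was discretized from."""
    records = generate_expression_records(model, n_dysregulated, seed)
    return discretize_expression(records), records


def generate_drug_panel(
    model: SystemModel,
    signature: ExpressionSignature,
    params: ScenarioParams,
    seed: int | np.random.Generator,
    plant_against: str = "control",
) -> list[DrugProfile]:
    """Drug panels with planted labels.

    "good" drugs target genes where the reference sign pattern is nonzero,
    with a mechanism quantifying to that sign; "bad" drugs use the opposing
    mechanism; "random" drugs draw uniform targets and mechanisms.  With
    ``plant_against='control'`` (default) the reference is the sign of the
    optimal LQR control; ``'signature'`` plants against the (negated) disease
    state itself, the simpler signature-reversal baseline.  ``noise_rate``
    flips each good/bad mechanism choice independently.
    """
    if plant_against not in ("control", "signature"):
        raise ValueError("plant_against must be 'control' or 'signature'")
    rng = np.random.default_rng(seed)
    x0 = align_signature(signature, model).x0
    if plant_against == "control":
        if model.dynamics is None:
            model = normalize_dynamics(model)
        solution = solve_dare(model.dynamics)
        reference = hypo_treatment(solution.P, model.dynamics, x0).sign_pattern
    else:
        reference = -x0
    nonzero = np.flatnonzero(reference)
    if nonzero.size == 0:
        raise ValueError("reference sign pattern is identically zero; nothing to plant")

    def planted(name: str, label: str, flip: bool) -> DrugProfile:
        k = min(params.targets_per_drug, nonzero.size)
        picks = rng.choice(nonzero, size=k, replace=False)
        targets = []
        for i in picks:
            want = reference[i] if not flip else -reference[i]
            if rng.random() < params.noise_rate:
                want = -want
            mech = "Agonist" if want > 0 else "Inhibitor"
            targets.append((model.genes[i], mech, None))
        return DrugProfile(drug=name, set_label=label, targets=tuple(targets))

    drugs = []
    for d in range(params.n_good):
        drugs.append(planted(f"good_{d:03d}", "D1", flip=False))
    for d in range(params.n_bad):
        drugs.append(planted(f"bad_{d:03d}", "D2", flip=True))
    for d in range(params.n_random):
        picks = rng.choice(model.n_genes, size=min(params.targets_per_drug, model.n_genes), replace=False)
        targets = tuple(
            (model.genes[i], _RANDOM_MECHANISMS[rng.integers(len(_RANDOM_MECHANISMS))], None)
            for i in picks
        )
        drugs.append(DrugProfile(drug=f"rnd_{d:03d}", set_label="D3", targets=targets))
    return drugs


def generate_scenario(params: ScenarioParams, seed: int) -> SyntheticScenario:
    """Generate network, signature and drug panel from one fanned-out seed."""
    streams = np.random.SeedSequence(seed).spawn(3)
    interactions = generate_network(
        params.n_genes, params.density, params.inhibition_fraction,
        np.random.default_rng(streams[0]),
    )
    model = normalize_dynamics(build_adjacency(interactions))
    signature, expression = generate_signature(
        model, min(params.n_dysregulated, model.n_genes), np.random.default_rng(streams[1])
    )
    drugs = generate_drug_panel(model, signature, params, np.random.default_rng(streams[2]))
    return SyntheticScenario(
        params=params,
        seed=seed,
        interactions=interactions,
        model=model,
        expression=expression,
        signature=signature,
        drugs=drugs,
    )
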