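# decost

Rank candidate drugs for a disease by treating its dysregulated expression
signature as the initial condition of a discrete-time linear system over a
signed gene-interaction network, computing the optimal linear-quadratic
regulator (LQR) control that would stabilize the signature back to
equilibrium, and scoring each drug by how well its quantified target-action
vector matches that optimal control's sign pattern.

## How it works

1. **Model building** (`decost.model_builder`) — a table of directed,
   mechanism-labelled gene–gene interactions (activation → +1,
   inhibition → −1, everything else → 0, with a confidence filter at 500 on
   a 0–1000 scale) is assembled into a signed adjacency matrix, then divided
   by its largest eigenvalue magnitude so the open-loop dynamics
   `x(t) = A x(t−1) + u(t−1)` cannot diverge.
2. **Expression signature** (`decost.expression_signature`) — a limma/GEO2R
   style top-table is discretized to {−1, 0, +1}: genes with adjusted
   p-value above 0.05 become 0, the rest take the sign of their logFC.
3. **LQR control** (`decost.lqr_control`) — the algebraic Riccati equation
   (identity state/control costs and control matrix) is solved by fixed-point
   iteration; the optimal first control
   `u(0) = −(I+P)⁻¹ P A x(0)` is the per-gene intervention the drugs are
   scored against.
4. **Drug treatment** (`decost.drug_treatment`) — drug–target mechanisms of
   action are quantified via a packaged 37-label table (e.g. Agonist → 1,
   Antagonist → −1, Adduct → 0.5), filtered at confidence 800 when a score
   is present, and aggregated into per-drug vectors on the model's genes.
5. **Scoring & evaluation** (`decost.scoring_eval`) — each drug gets
   `T_d = Σ u_d·sign(u0) / Σ |u_d|·|sign(u0)|` in [−1, 1] (UNDEFINED when the
   drug touches no controlled gene), drugs are ranked, and approved (D1) vs
   withdrawn (D2) sets are separated by an all-pairs Mann–Whitney ROC/AUC.
6. **Synthetic fixtures** (`decost.synthetic_fixtures`) — seeded scenarios
   with planted good/bad/random drug panels so the entire pipeline is
   testable without any external data.

## CLI

```sh
# generate a synthetic scenario, then run the full pipeline on it
decost simulate --n 100 --density 0.05 --seed 42 --out data/
decost run --interactions data/interactions.tsv \
           --expression data/expression.tsv \
           --drugs data/drugs.tsv --out results/

# or step by step
decost build-model --interactions data/interactions.tsv --out model/
decost signature --expression data/expression.tsv --out signature.tsv
decost control --model model/ --signature signature.tsv --out hypo.tsv --diagnostics
decost score --model model/ --signature signature.tsv --drugs data/drugs.tsv --out scores.tsv
decost evaluate --scores scores.tsv --out roc.json
```

Every output directory of `decost run` contains the resolved configuration
(`config.json`) and solver diagnostics (`meta.json`) for provenance.
`decost run --config file.json` reads any flag from a JSON key-value file;
command-line flags override it.

Input dialects: interaction tables are TSV/CSV with columns
`source, target, mechanism[, confidence]` (SIF also accepted); expression
tables need `gene`/`Gene.symbol`, `logFC` and `adj.P.Val`; drug tables need
`drug, set_label, gene, mechanism[, confidence]` with set labels from
{D1, D2, D3, unlabeled}.

Notable flags: `--adjacency-layout {incoming,paper-literal}` switches the
edge-orientation convention, `--stability-margin` enforces strict (rather
than marginal) open-loop stability, `--abs-numerator` uses the
absolute-value score variant, and `--undefined-as-zero` writes undefined
scores as 0 instead of NA.

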