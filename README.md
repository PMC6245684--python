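# grnlogic

Exhaustive visibility and ambiguity analysis for logic-based (Boolean)
gene-regulatory-network inference from perturbation experiments.

A target gene regulated by `k` factors hides a k-input Boolean function. This
package quantifies how identifiable that function is from knock-down (`D`)
and over-expression (`O`) experiments, optionally strengthened by
cis-element and protein–protein-interaction (PPI) evidence, and identifies
the function from real or simulated perturbation records.

## What it computes

- **Search spaces** — all k-input Boolean functions in which every input is
  effective (10 / 218 / 64,594 for k = 2 / 3 / 4), cross-checked against an
  inclusion–exclusion closed form.
- **Single-perturbation state diagrams (SPSDs)** — one node per regulator
  state, one edge per single perturbation, with per-edge visibility under
  three integration modes: transcriptome only (`tx`), transcriptome + PPI
  (`ppi`), transcriptome + cis-elements (+PPI) (`cis-ppi`). Export to DOT,
  GraphML or JSON.
- **Visibility statistics** — the probability that a perturbation's effect
  is observable (P_v), and per-state / overall full-visibility probabilities
  (P_fv,s and P_fv), exactly (rational arithmetic) over the whole search
  space.
- **Ambiguity statistics** — the number of candidate functions consistent
  with an experiment's observations (N_cmn), and the unambiguity
  probability P_ua for single- and multi-step experiments, where multi-step
  analysis minimises ambiguity over all perturbation paths.
- **Identification** — candidate-regulator proposal from cis/PPI evidence
  and truth-table identification from perturbation records, including a
  seeded experiment simulator; reproduces the yeast GAL4/GAL80 → SWI5
  worked example.

## Command line

```bash
# P_ua for a single-step DO experiment with full cis(+PPI) knowledge, k=2
grnlogic analyze ambiguity --k 2 --regime DO --integration cis-ppi --steps 1

# visibility sweep to CSV
grnlogic analyze visibility --k 3 --regime D --integration ppi --out vis.csv

# ratio tables (integration gain, DO-over-D) for k = 2..4
grnlogic analyze tables --k 2 --k 3 --out tables.json

# state diagram of one function as graphviz DOT (dashed = invisible)
grnlogic build --k 2 --function 4 --regime DO --integration tx --format dot

# identify a target's Boolean function from records + evidence
grnlogic identify --records tests/data/gal_records.tsv --k 2 \
    --condition glucose --cis tests/data/gal_cis.tsv \
    --ppi tests/data/gal_ppi.tsv --target SWI5

# seeded synthetic experiment
grnlogic simulate --k 3 --function 22 --wild-type 3 --regime DO \
    --steps 2 --seed 1 --dropout 0.1
```

A YAML config mirroring the flags can be passed with `--config`; explicit
flags win.

## Conventions

- State number `s` encodes the regulator tuple with RF1 as the most
  significant bit (state 2 at k=2 means RF1=1, RF2=0).
- Function index `b` is the decimal value of the output column with state 0
  as the most significant bit (`F_8^2` has outputs 1,0,0,0).
- Knock-down edges always descend in state number; over-expression edges
  ascend. Knock-down-only experiments exhaust after at most k steps.
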