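# netreg

Upstream-regulator inference on signed, directed molecular-interaction
networks. Given a network with typed nodes (ligand / receptor / kinase /
transcription factor / generic), a paired lesional vs. non-lesional
expression matrix, and a small protein panel, the pipeline identifies the
transcription factors and membrane receptors most likely to drive the
observed overexpression:

1. **diffexpr** — per-sample median normalization, paired t-test on
   per-pair log2 differences, Benjamini–Hochberg FDR; genes with fold
   change > 2.5 and q < 0.01 form the transcriptomics list of interest.
2. **overconnectivity** — hypergeometric enrichment of a candidate's
   direct interactions with the list of interest
   (r = links into the set, R = degree, n = summed set degrees,
   N = total interactions).
3. **hidden_nodes** — enrichment on *transcription-activation shortest
   paths*: minimal-hop directed paths whose last edge is a
   transcription-regulation edge out of a TF and whose inhibition count
   has even parity (net-activating). Candidates over-represented on the
   paths bound for the list of interest are significant hidden regulators.
4. **rank_aggregation** — the two rankings per data type are combined into
   one list of size k (default 20) by minimizing summed weighted Spearman
   footrule distance with a genetic algorithm.
5. **subnetworks** — per-receptor shortest-path networks (receptor → the
   TFs directly regulating the set → their targets) and greedy TF
   expansion networks (default 50 nodes), each scored by hypergeometric
   node enrichment and sorted.
6. **integration_pipeline** — aggregated TF lists for the transcriptomics
   and proteomics sets are intersected into the common-TF set (topped up
   with seeds of the best expansion networks); receptors significant by
   the path statistic (p < 0.05) are then kept only if their gene or a
   ligand is overexpressed (> 2.5-fold) and they can reach a common TF,
   and classified as receptor-only / ligand-only / both.
7. **synthetic_data** — class-respecting preferential-attachment networks
   with a planted all-activating ligand→receptor→kinase→TF→target cascade
   and paired log-normal expression with planted fold changes, plus full
   ground truth for recovery testing.

## CLI

```bash
# generate a synthetic input bundle with ground truth
netreg simulate --out sim/ --seed 1

# run the full pipeline from a YAML config
netreg run --config config.yaml
```

A minimal `config.yaml`:

```yaml
network_edges: sim/network_edges.tsv
network_nodes: sim/network_nodes.tsv
expression: sim/expression.tsv
pairs: sim/pairs.tsv
protein_sets: sim/protein_panel.gmt
out_dir: results/
seed: 1
```

Individual stages are exposed as subcommands (`netreg de`,
`netreg overconnect`, `netreg hidden`, `netreg aggregate`,
`netreg networks`, `netreg receptors`); see `netreg COMMAND --help`.

File formats are plain TSV with headers (edge list:
`source target effect mechanism`; node attributes: `node class`), GMT for
gene sets, and TSV reports. Reports are byte-identical across runs with
the same config and seed.

## Acceptance

The acceptance surface is property- and simulation-based (exact
hypergeometric oracles, brute-force path enumeration, permutation nulls,
GA-vs-exhaustive optima, planted-regulator recovery); it lives in
`tests/test_acceptance.py`. The report generator

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end smoke and writes the (empty) numeric-target report:
there are no numeric targets, because reference values for this method
family are tied to proprietary curated interactomes and cannot be
recomputed offline.
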