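# epocflow

Desk-scale pipeline for inferring the prokaryotic sister clade of
eukaryotic gene families (EPOCs: eukaryotic–prokaryotic orthologous
clusters).  Given a gene tree, its amino-acid alignment and a taxonomy
table, the pipeline

1. curates the tree (log-normal branch-length outlier removal at the
   99.5% quantile, weighted midpoint rooting),
2. detects taxonomic clades with a *soft-LCA* score
   (purity × scope), applying validity rules (≥ 3 sequences / purity
   > 0.8 for prokaryotes, ≥ 5 / > 0.8 for eukaryotes) and discarding
   paraphyletic families (> 3 valid eukaryotic clades),
3. enumerates up to 12 candidate prokaryotic sisters per eukaryotic
   clade by topological distance, regrafts the eukaryotic clade as
   sister to each candidate, re-optimizes branch lengths under
   LG(+G4) with a Felsenstein pruning engine, and ranks the candidate
   topologies with expected likelihood weights (ELW) estimated by RELL
   site resampling,
4. extracts stem lengths (SL) and normalized stem lengths
   (NSL = SL / median eukaryotic root-to-leaf distance), with bootstrap
   CDFs and two-sided Mann–Whitney comparisons,
5. filters associations into a core set (annotation, LECA-spanning
   eukaryotic clades, 0.4 < ELW < 0.99 with the stated
   oxidative-phosphorylation exception) and aggregates ELW into
   per-category aELW tables,
6. optionally superclusters a profile-similarity graph (greedy set
   cover) and partitions trees via 2-D embedding + density clustering.

A seeded synthetic gene-family generator (`epocflow.synthetic`)
replaces the external sequence databases: it builds trees with known
donor clades, evolves alignments under the same substitution models
used for inference, and can inject HGT leaves and long-branch outliers,
so every stage is testable offline with known ground truth.

## Layout

| module | contents |
|---|---|
| `epocflow.synthetic` | `SimConfig`, tree/alignment simulation, HGT & outlier injection, family-set serialization |
| `epocflow.msa` | alignment I/O, Shannon column information, trimming, taxonomy-aware prune-and-align reduction |
| `epocflow.trees` | outlier pruning, weighted midpoint rooting, soft-LCA scan, clade validity, topological distance |
| `epocflow.substitution` | LG / Poisson models (PAML dat dialect), discrete gamma rates |
| `epocflow.likelihood` | per-site log-likelihoods, branch-length optimization, gamma-shape grid estimation |
| `epocflow.elw` | candidate enumeration, constraint topologies, RELL ELW, per-clade sister assignment |
| `epocflow.stems` | SL / NSL, bootstrap CDFs, exact & asymptotic Mann–Whitney |
| `epocflow.filters` | soft-core pangenome rule, core-set & strict-subset filters, aELW tables |
| `epocflow.annealing` | greedy set cover, tree partitioning (classical MDS + HDBSCAN) |
| `epocflow.pipeline` / `epocflow.cli` | per-family orchestration and the `epocflow` command |

## CLI

```sh
epocflow simulate --config sim.json --n-families 10 --out-dir epocs/
epocflow run --epoc-dir epocs/ --out-dir results/ [--config run.json]
epocflow aggregate --elw results/elw.tsv --ontology cats.tsv --out aelw.tsv
```

`sim.json` holds `SimConfig` fields (`n_prok_classes`, `donor_label`,
`stem_length`, `n_sites`, `gamma_alpha`, `seed`, ...); `run.json` holds
`RunConfig` fields (`model_name`, `gamma_alpha` — null to estimate on a
grid, `k_candidates`, `rell_replicates`, `seed`, thresholds).  Outputs
are TSV tables (`elw.tsv`, `stems.tsv`), a JSONL discard log with
machine-readable reason codes and a JSON run manifest.

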