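# trapline

A pipeline for analysing trapped-bait interaction proteomics and its
downstream functional readouts:

* **`tables_io`** — validated readers/writers for protein-identification
  tables (TSV/CSV, dialect-mapped so e.g. Proteome Discoverer exports work),
  GMT gene-set collections, weighted edge lists (unit or 0–1000 integer
  score scales), long-format FRAP traces and dose-pair viability grids.
* **`interactome_core`** — the filtering cascade (single-peptide removal;
  removal of proteins identified with more than 2 unique peptides in a
  negative-control sample), replicate aggregation, the pseudocounted
  trap/reference PSM enrichment ratio (reference absent or zero → divide
  by 1), dual-criterion prioritization (PSM ratio and MS score), and an
  accession-level outer join contrasting two baits.
* **`network_gsea`** — hit-interaction network at a confidence cutoff
  (default 0.7, singletons removed) and one-sided Fisher's exact gene-set
  over-representation with inclusive −log10(p) filtering (1.3 ↔ p = 0.05).
* **`frap_kinetics`** — photobleaching-trace normalization (pre-bleach = 1,
  post-bleach = 0), deterministic profiled least-squares fits of the
  one-site binding recovery model `Y(t) = ymax·t/(t_half + t)`, and the
  extra-sum-of-squares F-test for shared vs per-group half-times.
* **`combo_response`** — vehicle-normalized surviving fractions and Bliss
  independence scoring (expected effect `E_A + E_B − E_A·E_B`, excess over
  it, mean over combination cells).
* **`synthetic_data`** — seeded generators for all of the above with
  ground-truth labels (spiked interactors over a Poisson background, bead
  binders in the control, noisy saturating recovery curves, multiplicative
  dose-response surfaces with an optional supra-additive bonus).
* **`cli_pipeline`** — the `trapline` command-line tool and the end-to-end
  `run_pipeline` orchestration with a YAML config and a run manifest.

## Command line

```bash
# write a complete synthetic experiment (identification tables, control,
# edges, gene sets, FRAP traces, viability grid, ground truth)
trapline simulate --seed 1 --out toy/

# full interactome cascade from a config file
trapline run-all --config config.yaml --outdir out/

# individual stages
trapline filter   --table toy/trap_rep1.tsv --control toy/control.tsv --out filtered.tsv
trapline enrich   --trap toy/trap_rep1.tsv --trap toy/trap_rep2.tsv \
                  --ref toy/ref_rep1.tsv --ref toy/ref_rep2.tsv \
                  --control toy/control.tsv --out enrichment.tsv
trapline network  --hits hits.txt --edges toy/edges.tsv --out-prefix net
trapline gsea     --hits hits.txt --gene-sets toy/gene_sets.gmt --out gsea.tsv
trapline frap     --traces toy/frap_traces.tsv --traces-b other.tsv --out frap.json
trapline synergy  --grid toy/viability.tsv --out-prefix syn
```

`run-all` reads a YAML file whose keys mirror `cli_pipeline.PipelineConfig`
(`trap_paths`, `ref_paths`, `control_path`, `edges_path`, `gene_sets_path`,
`max_control_unique`, `min_ratio`, `min_score`, `strategy`,
`network_cutoff`, `neg_log10_threshold`, `flag_mode`, …).  Every artifact is
written to the output directory together with `manifest.json` recording
per-stage row counts.

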