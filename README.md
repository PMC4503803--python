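# cortexreg

Age-dependent co-expression modules and their transcription-factor master
regulators in cortex transcriptomes.

## The problem

Bulk transcriptomes of postmortem human frontal cortex carry a microglia
gene signature whose summary expression declines across the adult life
span.  Identifying that signature — and the transcription factors (TFs)
that regulate it — requires a chain of network statistics:

1. **Co-expression module detection** (`cortexreg.coexpr`): Pearson
   correlation → soft-threshold adjacency `|r|^β` (β picked by the
   scale-free topology fit index) → topological overlap matrix
   `TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` → average-linkage
   tree → branch cut → eigengene merging at height 0.25.  A module is
   *age-dependent* when its eigengene (first PC of the module submatrix)
   correlates with age at a more significant p-value than with every
   tissue-quality confounder (RIN, pH, PMI), validated within strata of
   matched confounder values.
2. **Regulon inference** (`cortexreg.minet`): a mutual-information network
   (Gaussian-kernel MI on copula-transformed pairs; fast binned estimator
   for all-pairs work), thresholded at a null p-value of 10⁻⁷ via
   exponential tail extrapolation, pruned by the data-processing
   inequality (tolerance 0.1) with TF-target protection, optionally
   aggregated over 100 bootstrap rounds.  A TF's regulon is its adjacency
   list.
3. **Master regulators** (`cortexreg.mrscan`): one-sided Fisher's exact
   test of each regulon against the module, Bonferroni-corrected over the
   TFs in the network; replication summarized across datasets.
4. **Corroboration**: empirical marker-panel enrichment against random
   gene sets (`cortexreg.markers`), ChIP-peak overlap with strand-aware
   basal regulatory domains (5 kb upstream / 1 kb downstream of the TSS)
   by randomization within a workspace (`cortexreg.regdom`), and
   protein-interaction connectivity under within-degree node-label
   permutation (`cortexreg.ppinet`).

Because the original cohort data live in controlled repositories, the
package ships a synthetic-study generator (`cortexreg.synthio`) that
plants every signal with known ground truth — a latent age-tracking module
eigengene, driver-TF regulons, marker panels, enriched peaks, and a PPI
clique — so each stage is verified by parameter recovery.  See
`docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the full pipeline on a generated study (400 genes, 150 samples,
60-gene planted module with eigengene–age correlation −0.4, 5 driver TFs
among 20):

```bash
cortexreg run --config examples/demo.yaml
```

with `examples/demo.yaml`:

```yaml
outdir: demo_out
seed: 11
bootstrap_rounds: 0
B_enrich: 500
nsim_overlap: 500
perms_ppi: 500
powers: [6]          # fixed soft power; histogram-based selection needs genome scale
simulate:
  n_genes: 400
  n_samples: 150
  n_module_genes: 60
  regulon_size: 10
  n_ppi_nodes: 400
  marker_panel_size: 50
  marker_overlap: 25
  off_panel_sizes: [15]
  n_peaks: 100
  seed: 0
```

The run prints

```
report written to demo_out/report.json
age module: 65 genes; MRs: ['TF001', 'TF002', 'TF003', 'TF005', 'TF004']
```

and `demo_out/report.md` summarizes every stage:

```
## Age-dependent module
- soft power: 6
- modules detected: 16
- selected (age rule): [1]
- age module id 1 with 65 genes

## Master regulators
- TFs tested: 20
- flagged: TF001, TF002, TF003, TF005, TF004

## Marker enrichment
- off_cell_1: observed 0, null median 2.0, fold 0, p 1
- target_cell: observed 26, null median 8.0, fold 3.25, p 0.002

## Peak / regulatory-domain overlap
- observed 28963 bp vs expected 5492.4 bp (fold 5.27), p 0.002, q 0.002

## PPI connectivity
- 10 direct edges among 5 connected seeds (mean direct degree 4.00)
- network p-values: {'n_direct_edges': 0.00399..., ...}
```

Reading this: the tree cut found 16 modules and exactly one passed the age
rule — a 65-gene module that recovers the planted 60-gene block (it
contains the module plus a handful of correlated TFs).  All five planted
driver TFs, and nothing else, were flagged as master regulators.  The
planted 50-gene marker panel hits 26 of the module's genes against a null
median of 8 (3.25-fold, empirical p = 0.002, the floor for 500 draws);
ChIP-style peaks overlap the module's basal regulatory domains 5.3-fold
above the workspace-randomization null; and the flagged TFs arrive fully
interconnected in the protein network (10 direct edges among 5 seeds,
permutation p ≈ 0.004).  Rerunning with the same seed reproduces every
output byte for byte.

Each stage is also a library call (`coexpr.detect_modules`,
`minet.build_mi_network`, `mrscan.identify_master_regulators`, …) and a
subcommand (`cortexreg simulate|coexpr|minet|mrscan|markers|regdom|ppinet`)
for use on your own TSV/BED inputs.

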