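outdir: demo_out
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
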