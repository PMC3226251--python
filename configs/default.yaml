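# Default pipeline configuration for `assaynet` (synthetic study).
# Any key omitted here falls back to the built-in default; CLI flags
# (--seed, --out) override config keys.
#
# To run on real data instead, replace the synthetic block with:
#   inputs:
#     activity: path/to/activity.tsv        # assay_id <TAB> compound_id
#     assay_meta: path/to/assays.tsv        # assay_id <TAB> assay_type <TAB> target_symbol
#     ppi: path/to/ppi_edges.tsv            # symbol <TAB> symbol
#     markers:
#       essential: path/to/essential.txt    # one gene symbol per line
#       drug_targets: path/to/drug_targets.txt
#       disease_genes: path/to/disease_genes.txt
#       bioassay_targets: path/to/bioassay_targets.txt

synthetic:
  n_proteins: 2000        # interactome size
  attach_m: 3             # preferential-attachment edges per new protein
  n_essential: 60         # degree-biased essential genes
  n_drug_targets: 130     # uniform approved-drug targets
  n_disease: 170          # uniform disease genes
  n_bioassay_targets: 60  # planted screen targets
  proximity_rho: 5.0      # odds multiplier within distance 1 of an essential gene (1 = null)
  n_assays: 60
  n_compounds: 600
  n_clusters: 6           # activity-table community structure
  p_in: 0.30              # P(active) within a cluster
  p_out: 0.005            # P(active) across clusters
  target_based_frac: 0.52 # fraction of assays that are target-based
  rng_seed: 0

projection:
  min_jaccard: 0.10       # "share at least 10% active compounds"
  drop_isolates: false

enrichment:
  n_random: 1000          # randomised-control trials
  rng_seed: 0

prioritize:
  bin_width: 0.5          # d-hat-essential bin size
  min_degree: 17          # minimum interactome degree for a candidate
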