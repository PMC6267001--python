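# Default study-design cohort: 15 children + 15 teens, 3 sites, 2 timepoints.
seed: 7
out_dir: results
n_perm: 999
sites: [underarm, neck, head]
strata: [youth, children, teens]
simulate:
  n_children: 15
  n_teens: 15
  n_taxa: 30
  n_gene_families: 80
thresholds:
  taxon_abundance: 1.0   # percent, mean in either age group
  gene_rpk: 10.0
  pathway_coverage: 0.3
  q: 0.1
  rho: 0.2
  min_hits: 2            # of the six (stratum, test) comparisons
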