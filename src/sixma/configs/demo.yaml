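# Small demo pipeline run: two 250 kb contigs, reduced permutation count.
seed: 7
outdir: results/demo
sim:
  genome:
    contigs: [[sim2L, 250000], [sim3R, 250000]]
    genes_per_contig: 25
thresholds:
  prm_min: 70.0
  concordance: 10.0
  coverage_lo: 0.5
  coverage_hi: 1.5
  control_prm_max: 30.0
enrichment:
  n_perm: 1000
  mode: exclusive
conservation:
  d: 100
expression:
  statistic: max
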