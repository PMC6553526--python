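# Shared configuration for the numbered analysis scripts.
# Default-scale synthetic study: two 400 kb contigs, 40 genes each,
# ~96,000 candidate A/T positions, the study's 10,000 permutation draws.
seed: 1
outdir: results/study
enrichment:
  n_perm: 10000
  mode: exclusive
conservation:
  d: 100
expression:
  statistic: max
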