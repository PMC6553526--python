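# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic study does and does not establish.

## Coordinate model

All internal coordinates are 0-based half-open. GFF3 (1-based closed) and
BED (0-based half-open) convert at the I/O boundary only. Positions are
strand-resolved — a T on the + strand marks a candidate methylated A on the
− strand — but site identity is `(contig, pos)`: an A/+ record and a T/+
record at one coordinate are the same site, and all overlap/conservation
comparisons ignore strand. Per gene, the isoform with the greatest summed
exon length defines the feature intervals; ties break on the
lexicographically smallest transcript id so results are deterministic.
Introns are the gaps between that isoform's consecutive exons; the upstream
window is the 1,000 bp 5′ of its TSS (configurable), clipped at contig
edges but not at neighbouring genes.

## The calling cascade

Thresholds (all inclusive, because the rules are phrased as "at least" /
"within"): PRM ≥ 70% in replicate 1; |PRM₁ − PRM₂| ≤ 10 points; PRM ≥ 70%
in the control-comparison (`sample_compare`) set; coverage within
[0.5µ, 1.5µ] of each dataset's own genomic mean, applied independently per
dataset before merging. A position must be present in all three
coverage-filtered tables to be called (an intersection cannot keep a
position absent from one input). Control positions mirror the cascade with
PRM ≤ `control_prm_max` (default 30%, the complement of the 70% rule; the
construction is "analogous", so the exact cutoff is exposed as a knob) and
must *not* be flagged by the control comparison — which also makes
site/control disjointness hold for any threshold combination, since a
position cannot be simultaneously flagged and unflagged.

## Statistics

- **Empirical permutation p** is the raw tail count k/n_perm, not
  (k+1)/(n+1): a statistic beyond every permutation is reported as the
  bound "< 1/n_perm" (e.g. "< 0.0001" at 10,000 draws), never as 0.
  Enrichment uses the ≥ tail, depletion the mirrored ≤ tail; both are
  always computed.
- **Wilcoxon rank-sum** enumerates all group assignments exactly (valid
  under ties via average ranks) when the pooled size is ≤ 12, and otherwise
  uses the tie-corrected normal approximation without continuity
  correction; `method="exact"` forces scipy's no-ties enumeration for
  larger samples. Default sidedness is two-sided.
- **Hypergeometric overlap** is the upper tail P(X ≥ k) for a size-n_b draw
  against n_a marked elements among `pop`. The population ("universe") for
  conservation tests is a modelling choice — the package defaults to the
  count of candidate A/T positions eligible in both datasets and records
  the value used in every report.
- **Spearman rho** uses average ranks and refuses constant input rather
  than returning NaN.

The permutation null samples |sites| positions without replacement per
draw, independently across draws, from one seeded generator
(random-key partial sort, O(|controls|) per draw). No multiple-testing
correction is applied across the eight categories; both raw tails are
reported.

## Synthetic study design

The generator emulates the structure of a two-replicate PCR-free + one
PCR-control nanopore experiment on a compact genome. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| contigs | 2 × 400 kb | large enough for ~96k candidate positions and stable category counts, small enough for seconds-scale runs |
| genes/contig, exons/gene | 40, 4 | every gene has introns and UTRs; genes cover ~25% of the genome |
| candidate A/T density | 0.12 of bases | keeps tables light while giving every category ≥ ~1k candidates |
| base methylation rate | 0.005 per candidate | sparse enough that gene bodies split into site-bearing and site-free groups, as in real data |
| category multipliers | intron 3×, 3′ UTR 2×, upstream 2×, simple repeat 2×, 5′ UTR 1×, CDS 0.5×, intergenic 0.5×, TE 0.3× | plants the enrichment/depletion directions the pipeline is meant to detect |
| PRM distributions | Beta, mean 0.85 (conc 40) methylated; mean 0.05 (conc 120) unmethylated, scaled ×100 | well-separated but overlapping tails |
| replicate noise sd | 3.0 points (Gaussian, clipped to [0,100]) | calibrated so the default study lands the replicate Spearman rho in the moderate band (≈0.5–0.6) |
| coverage | NB(mean 30, size 300); 1% outliers split between 3× and 0.2× mean | the ±50% coverage filter removes a real (~3%) but small fraction |
| second strain | p_exact 0.16, p_near 0.74 within ±100 bp, background 2×10⁻⁵/bp | region-level conservation stronger than base-level |
| tissues | 12 columns, log-normal(σ=0.6) around 1; one random tissue ×8 for modified genes; 20% of genes score-less | single-tissue-dominant expression with incomplete score coverage |
| signal differences | folded normal, mean 3.0 (methylated) vs 0.5, sd 1.0 | clear separation at called vs control positions |

One master seed drives named per-operation streams
(`SeedSequence(seed, spawn_key)`), so every artifact is bit-reproducible
and stages are individually re-runnable; the pipeline additionally derives
fixed per-stage child seeds from its config seed.

**What the simulation does not model:** read-level data and basecalling
error, sequence composition (positions are abstract A/T coordinates, so no
motif structure), strand-biased methylation, spatial autocorrelation of
methylation beyond category membership, between-replicate coverage
correlation, and assembly errors in the block map (the simulated map is
exact and fully covering). Passing tests therefore demonstrate correctness
of the filtering, resampling and interval machinery under a faithful noise
model — not calling accuracy on real flowcell data.

## Problem sizes used in the tests

Test and acceptance runs use the default two-contig 800 kb study (~96k
candidate positions, ~400 planted sites, ~90k controls) or smaller;
permutation calibration uses 200 replicate null datasets of 2,000
pseudo-sites at 1,000 permutations — pseudo-site sets of a few thousand
keep per-category counts away from small-count discreteness, mirroring the
scale of a genome-wide call set. The pseudo-sites are drawn from the same
control pool the test resamples from, which makes the permutation null
exact by construction.

## Known limitations

- The gene-membership test uses gene bodies only; a site in an upstream
  window credits the category but not the gene. Promoter-level gene
  assignment would need a distance rule the interface does not currently
  expose.
- `within_distance_fraction` is not invariant under liftover when nearby
  sites straddle a block boundary (distances are preserved only within
  blocks); exact-overlap fractions are invariant.
- The per-gene tissue-specificity reduction defaults to the maximum score
  (it captures "strongly expressed in one tissue"); mean and tau are
  selectable, and conclusions can differ for genes with broad moderate
  expression.
- Empirical p-values at n_perm draws have resolution 1/n_perm; p-value
  comparisons tighter than that need more permutations, at linear cost.
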