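#!/usr/bin/env python
"""Gene-level characterization: which genes carry sites, whether they are
more tissue-specific (rank-sum on the max tissue enrichment score), and
whether the raw signal deviation is larger at sites than controls."""

from pathlib import Path

from sixma.pipeline import run_pipeline

CONFIG = Path(__file__).with_name("config.yaml")

if __name__ == "__main__":
    report = run_pipeline(CONFIG, stages=("express",))
    ex = report["stages"]["express"]
    spec = ex["tissue_specificity"]
    sig = ex["signal_difference"]
    print(f"genes with >=1 site: {ex['n_genes_with_sites']}")
    print(f"tissue specificity (max score), modified vs not: "
          f"medians {spec['median_modified']:.2f} / {spec['median_unmodified']:.2f}, "
          f"Wilcoxon p = {spec['p']:.2e} "
          f"(n = {spec['n_modified']} / {spec['n_unmodified']})")
    print(f"|signal difference| at sites vs controls: "
          f"medians {sig['median_site_diff']:.2f} / {sig['median_control_diff']:.2f}, "
          f"Wilcoxon p = {sig['p']:.2e}")
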