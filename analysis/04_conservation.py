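#!/usr/bin/env python
"""Between-strain conservation: lift the second strain's calls back through
the alignment block map, measure exact and within-100bp overlap fractions
with hypergeometric significance, and overlap with gain-of-methylation
regions."""

from pathlib import Path

from sixma.pipeline import run_pipeline

CONFIG = Path(__file__).with_name("config.yaml")

if __name__ == "__main__":
    report = run_pipeline(CONFIG, stages=("conserve",))
    cons = report["stages"]["conserve"]
    fwd = cons["query_vs_strain2"]
    print(f"universe (eligible A/T positions): {cons['universe']:,}")
    print(f"sites with exact strain-2 match : {fwd['exact_fraction']:.1%} "
          f"(hypergeometric p = {fwd['hypergeom_p']:.2e})")
    print(f"sites within {fwd['d']} bp of a match : {fwd['within_d_fraction']:.1%}")
    gain = cons["gain_regions"]
    print(f"sites in gain regions           : {gain['overlap_fraction']:.1%} "
          f"(p = {gain['hypergeom_p']:.2e})")
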