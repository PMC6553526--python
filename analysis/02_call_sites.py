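#!/usr/bin/env python
"""Run the filtering cascade: coverage filter, 70% PRM threshold, +/-10
point replicate concordance, control-comparison intersection — yielding the
high-confidence site set and the confident-unmethylated control set."""

from pathlib import Path

from sixma.pipeline import run_pipeline

CONFIG = Path(__file__).with_name("config.yaml")

if __name__ == "__main__":
    report = run_pipeline(CONFIG, stages=("call",))
    call = report["stages"]["call"]
    print("cascade counts:")
    for stage, n in call["cascade"].items():
        print(f"  {stage:28s} {n:>8,}")
    print(f"high-confidence sites : {call['n_sites']:,}")
    print(f"control positions     : {call['n_controls']:,}")
    print(f"replicate Spearman rho: {call['replicate_spearman_rho']:.3f}")
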