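"""The filtering cascade that turns three per-position PRM tables into a
high-confidence methylated site set and a mirrored confident-unmethylated
control set.

A site is called when, after per-dataset coverage filtering, its PRM is at
least ``prm_min`` (default 70%) in replicate 1, replicated within
``concordance`` percentage points (default 10) in replicate 2, and flagged
at ``prm_min`` by the control-comparison (sample_compare) call set. Controls
mirror the cascade: PRM at most ``control_prm_max`` in replicate 1,
concordant in replicate 2, and NOT flagged by the control comparison — so
the two sets are disjoint on every input. All thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SiteSet
from .stats import spearman_rho


@dataclass(frozen=True)
class CallingThresholds:
    prm_min: float = 70.0
    concordance: float = 10.0
    coverage_lo: float = 0.5
    coverage_hi: float = 1.5
    control_prm_max: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.prm_min <= 100:
            raise ValueError("prm_min must be in [0, 100]")
        if self.coverage_lo >= self.coverage_hi:
            raise ValueError("coverage_lo must be < coverage_hi")


def coverage_filter(
    table: pd.DataFrame, lo: float = 0.5, hi: float = 1.5
) -> pd.DataFrame:
    """Keep rows whose coverage lies within [lo*mu, hi*mu] of that dataset's
    genomic mean coverage mu (bounds inclusive)."""
    if len(table) == 0:
        raise ValueError("cannot coverage-filter an empty table")
    mu = float(table["coverage"].mean())
    cov = table["coverage"].to_numpy()
    keep = (cov >= lo * mu) & (cov <= hi * mu)
    return table.loc[keep].reset_index(drop=True)


def _merge_three(
    rep1: pd.DataFrame, rep2: pd.DataFrame, sample_compare: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join the three tables on (contig, pos); presence in all three is
    required for any call."""
    keys = ["contig", "pos"]
    m = rep1.merge(
        rep2[keys + ["prm"]], on=keys, suffixes=("_1", "_2")
    ).merge(sample_compare[keys + ["prm"]].rename(columns={"prm": "prm_sc"}), on=keys)
    return m.rename(columns={"prm_1": "prm1", "prm_2": "prm2"})


def call_high_confidence(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    sample_compare: pd.DataFrame,
    thresholds: CallingThresholds = CallingThresholds(),
) -> SiteSet:
    """Run the cascade on three (already coverage-filtered) tables."""
    m = _merge_three(rep1, rep2, sample_compare)
    t = thresholds
    keep = (
        (m["prm1"] >= t.prm_min)
        & ((m["prm1"] - m["prm2"]).abs() <= t.concordance)
        & (m["prm_sc"] >= t.prm_min)
    )
    m = m.loc[keep]
    return SiteSet.from_records(
        m["contig"], m["pos"], m["strand"], names=m["prm1"].round(3),
        scores=m["prm2"].round(3),
    )


def call_unmodified_controls(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    sample_compare: pd.DataFrame,
    thresholds: CallingThresholds = CallingThresholds(),
) -> SiteSet:
    """Confident-unmethylated A/T positions, the matched-control universe for
    the permutation test."""
    m = _merge_three(rep1, rep2, sample_compare)
    t = thresholds
    keep = (
        (m["prm1"] <= t.control_prm_max)
        & ((m["prm1"] - m["prm2"]).abs() <= t.concordance)
        & (m["prm_sc"] < t.prm_min)  # not flagged by the control comparison
    )
    m = m.loc[keep]
    return SiteSet.from_records(m["contig"], m["pos"], m["strand"])


def cascade_counts(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    sample_compare: pd.DataFrame,
    thresholds: CallingThresholds = CallingThresholds(),
) -> dict[str, int]:
    """Stage-by-stage position counts (raw -> coverage filter -> PRM threshold
    -> replicate concordance -> control-comparison intersection), for the run
    report. Tables here are the raw, unfiltered inputs."""
    t = thresholds
    f1 = coverage_filter(rep1, t.coverage_lo, t.coverage_hi)
    f2 = coverage_filter(rep2, t.coverage_lo, t.coverage_hi)
    fsc = coverage_filter(sample_compare, t.coverage_lo, t.coverage_hi)
    m = _merge_three(f1, f2, fsc)
    prm_pass = m["prm1"] >= t.prm_min
    concordant = prm_pass & ((m["prm1"] - m["prm2"]).abs() <= t.concordance)
    final = concordant & (m["prm_sc"] >= t.prm_min)
    return {
        "input_rep1": int(len(rep1)),
        "after_coverage_rep1": int(len(f1)),
        "after_coverage_all_three": int(len(m)),
        "after_prm_threshold": int(prm_pass.sum()),
        "after_concordance": int(concordant.sum()),
        "high_confidence": int(final.sum()),
    }


def replicate_correlation(rep1: pd.DataFrame, rep2: pd.DataFrame) -> float:
    """Spearman rho of PRM over positions present in both replicates."""
    m = rep1.merge(rep2, on=["contig", "pos"], suffixes=("_1", "_2"))
    if len(m) < 2:
        raise ValueError("need at least 2 shared positions")
    return spearman_rho(m["prm_1"].to_numpy(), m["prm_2"].to_numpy())
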