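"""Gene-level views of the called sites: which genes carry them, whether
those genes are more tissue-specific in their expression, and whether the
raw signal-level deviation is larger at called than at control positions.

Gene membership uses the gene body only (TSS to transcription end of the
selected isoform, introns included); sites in the upstream window are
credited in feature enrichment but do not make a gene "modified" here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import AnnotationSet, SiteSet
from .stats import wilcoxon_rank_sum

SPECIFICITY_STATISTICS = ("max", "mean", "tau")


def genes_with_sites(sites: SiteSet, ann: AnnotationSet) -> set[str]:
    """Gene ids whose body span contains at least one site."""
    contigs = sites.df["contig"].to_numpy(dtype=object)
    positions = sites.df["pos"].to_numpy()
    hits: set[str] = set()
    for gene_id, span in ann.genes.items():
        pos = positions[contigs == span.contig]
        if len(pos) and np.any((pos >= span.start) & (pos < span.end)):
            hits.add(gene_id)
    return hits


def specificity_statistic(
    scores: pd.DataFrame, gene: str, statistic: str = "max"
) -> float | None:
    """Per-gene tissue-specificity summary of the enrichment-score row.

    ``max`` (default) captures "strongly expressed in a single tissue";
    ``mean`` averages across tissues; ``tau`` is the classical
    tissue-specificity index in [0, 1]. Genes absent from the table return
    None and are excluded from group comparisons.
    """
    if gene not in scores.index:
        return None
    row = scores.loc[gene].to_numpy(dtype=float)
    return _reduce(row, statistic)


def _reduce(row: np.ndarray, statistic: str) -> float:
    if statistic == "max":
        return float(row.max())
    if statistic == "mean":
        return float(row.mean())
    if statistic == "tau":
        top = row.max()
        if top <= 0:
            return 0.0
        return float(np.sum(1.0 - row / top) / (len(row) - 1))
    raise ValueError(f"statistic must be one of {SPECIFICITY_STATISTICS}")


def compare_specificity(
    scores: pd.DataFrame,
    modified_genes: set[str],
    all_genes: set[str],
    statistic: str = "max",
    alternative: str = "two-sided",
) -> dict:
    """Rank-sum comparison of the per-gene specificity statistic between
    modified and unmodified genes; genes without scores are dropped from
    both groups symmetrically."""
    scored = set(scores.index)
    mod = sorted((modified_genes & all_genes) & scored)
    unmod = sorted((all_genes - modified_genes) & scored)
    if not mod or not unmod:
        raise ValueError("both gene groups must be non-empty after score filtering")
    vals = scores.to_numpy(dtype=float)
    lookup = {g: i for i, g in enumerate(scores.index)}
    x = np.array([_reduce(vals[lookup[g]], statistic) for g in mod])
    y = np.array([_reduce(vals[lookup[g]], statistic) for g in unmod])
    stat, p = wilcoxon_rank_sum(x, y, alternative=alternative)
    return {
        "statistic": stat,
        "p": p,
        "n_modified": len(mod),
        "n_unmodified": len(unmod),
        "median_modified": float(np.median(x)),
        "median_unmodified": float(np.median(y)),
        "specificity_statistic": statistic,
    }


def compare_signal_difference(
    signal_table: pd.DataFrame,
    sites: SiteSet,
    controls: SiteSet,
    alternative: str = "two-sided",
) -> dict:
    """Rank-sum comparison of |signal-level difference| between called-site
    positions and control positions."""
    keys = list(zip(signal_table["contig"], signal_table["pos"].astype(int)))
    values = signal_table["signal_diff"].to_numpy(dtype=float)
    in_sites = np.fromiter((k in sites for k in keys), dtype=bool, count=len(keys))
    in_controls = np.fromiter((k in controls for k in keys), dtype=bool, count=len(keys))
    x = values[in_sites]
    y = values[in_controls & ~in_sites]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both position groups must be non-empty")
    stat, p = wilcoxon_rank_sum(x, y, alternative=alternative)
    return {
        "statistic": stat,
        "p": p,
        "n_sites": int(len(x)),
        "n_controls": int(len(y)),
        "median_site_diff": float(np.median(x)),
        "median_control_diff": float(np.median(y)),
    }


def plot_specificity_heatmap(scores: pd.DataFrame, genes: set[str], path) -> None:
    """Optional heatmap of tissue scores for site-bearing genes (needs
    matplotlib; not part of the tested contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = scores.loc[sorted(genes & set(scores.index))]
    order = np.argsort(sub.to_numpy().argmax(axis=1))
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(np.log1p(sub.to_numpy()[order]), aspect="auto", cmap="viridis")
    ax.set_xticks(range(sub.shape[1]))
    ax.set_xticklabels(sub.columns, rotation=90, fontsize=6)
    ax.set_ylabel(f"{sub.shape[0]} site-bearing genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
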