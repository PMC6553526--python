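"""Feature-category assignment, overlap counting, the matched-control
permutation enrichment test, and per-window density summaries.

The null model resamples position sets of the observed size, without
replacement, from the confident-unmethylated control positions — not from
the genome at large — so base-composition and callability confounding are
matched by construction. Both empirical tails (enrichment and depletion)
are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AnnotationSet, GenomePosition, SiteSet
from .stats import EmpiricalP, empirical_p

#: Exclusive assignment order: repeat classes first so the doughnut partition
#: is well defined; intergenic is the complement and always matches last.
DEFAULT_PRECEDENCE = (
    "TE",
    "simple_repeat",
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "upstream1kb",
    "intergenic",
)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed_count: int
    perm_mean: float
    perm_sd: float
    p_enrich: EmpiricalP
    p_deplete: EmpiricalP
    n_perm: int


def assign_category(
    p: GenomePosition,
    ann: AnnotationSet,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> str:
    """Exclusive category of a single position: first match in precedence
    order, intergenic as the complement. Unknown contigs raise."""
    if ann.contig_lengths and p.contig not in ann.contig_lengths:
        raise KeyError(f"unknown contig {p.contig!r}")
    for category in precedence:
        if category == "intergenic":
            continue
        if ann.overlapping(p.contig, p.pos, category):
            return category
    return "intergenic"


def assign_categories(
    contigs: np.ndarray,
    positions: np.ndarray,
    ann: AnnotationSet,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> np.ndarray:
    """Vectorized exclusive assignment for many positions at once."""
    contigs = np.asarray(contigs, dtype=object)
    positions = np.asarray(positions)
    if ann.contig_lengths:
        unknown = set(pd.unique(contigs)) - set(ann.contig_lengths)
        if unknown:
            raise KeyError(f"unknown contigs {sorted(unknown)}")
    out = np.full(len(positions), "intergenic", dtype=object)
    unassigned = np.ones(len(positions), dtype=bool)
    for category in precedence:
        if category == "intergenic":
            continue
        hit = ann.membership(category, contigs, positions) & unassigned
        out[hit] = category
        unassigned &= ~hit
    return out


def _site_arrays(sites: SiteSet) -> tuple[np.ndarray, np.ndarray]:
    return sites.df["contig"].to_numpy(dtype=object), sites.df["pos"].to_numpy()


def count_overlaps(
    sites: SiteSet,
    ann: AnnotationSet,
    mode: str = "exclusive",
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> dict[str, int]:
    """Per-category site counts.

    ``exclusive`` assigns each site one category (counts sum to |sites|);
    ``multi`` counts a site once per overlapped category (intergenic then
    means "in no annotated feature").
    """
    contigs, positions = _site_arrays(sites)
    counts = {c: 0 for c in precedence}
    if mode == "exclusive":
        labels = assign_categories(contigs, positions, ann, precedence)
        for c, n in zip(*np.unique(labels, return_counts=True)):
            counts[str(c)] = int(n)
    elif mode == "multi":
        in_any = np.zeros(len(positions), dtype=bool)
        for category in precedence:
            if category == "intergenic":
                continue
            member = ann.membership(category, contigs, positions)
            counts[category] = int(member.sum())
            in_any |= member
        if "intergenic" in counts:
            counts["intergenic"] = int((~in_any).sum())
    else:
        raise ValueError("mode must be 'exclusive' or 'multi'")
    return counts


def permutation_enrichment(
    sites: SiteSet,
    controls: SiteSet,
    ann: AnnotationSet,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "exclusive",
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> dict[str, EnrichmentResult]:
    """Matched-control permutation test of per-category overlap counts.

    Each of ``n_perm`` permutations draws |sites| control positions without
    replacement, counts category overlaps in the same mode as the observed
    set, and the empirical p for each category is the fraction of permuted
    counts >= (enrichment) or <= (depletion) the observed count.
    """
    n_sites, n_controls = len(sites), len(controls)
    if n_controls < n_sites:
        raise ValueError(
            f"need at least as many controls ({n_controls}) as sites ({n_sites})"
        )
    observed = count_overlaps(sites, ann, mode, precedence)
    cats = list(precedence)
    cat_index = {c: i for i, c in enumerate(cats)}

    ctg, pos = _site_arrays(controls)
    if mode == "exclusive":
        labels = assign_categories(ctg, pos, ann, precedence)
        codes = np.array([cat_index[c] for c in labels], dtype=np.int64)
        member = None
    else:
        member = np.zeros((n_controls, len(cats)), dtype=np.int64)
        in_any = np.zeros(n_controls, dtype=bool)
        for c in cats:
            if c == "intergenic":
                continue
            col = ann.membership(c, ctg, pos)
            member[:, cat_index[c]] = col
            in_any |= col
        if "intergenic" in cat_index:
            member[:, cat_index["intergenic"]] = ~in_any
        codes = None

    rng = np.random.default_rng(seed)
    perm_counts = np.empty((n_perm, len(cats)), dtype=np.int64)
    for i in range(n_perm):
        # sample-without-replacement via random keys; O(n_controls) per draw
        idx = np.argpartition(rng.random(n_controls), n_sites - 1)[:n_sites]
        if codes is not None:
            perm_counts[i] = np.bincount(codes[idx], minlength=len(cats))
        else:
            perm_counts[i] = member[idx].sum(axis=0)

    out: dict[str, EnrichmentResult] = {}
    for c in cats:
        col = perm_counts[:, cat_index[c]]
        obs = observed[c]
        out[c] = EnrichmentResult(
            category=c,
            observed_count=int(obs),
            perm_mean=float(col.mean()),
            perm_sd=float(col.std(ddof=0)),
            p_enrich=empirical_p(obs, col, "ge"),
            p_deplete=empirical_p(obs, col, "le"),
            n_perm=n_perm,
        )
    return out


def enrichment_table(results: dict[str, EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for c, r in results.items():
        rows.append(
            {
                "category": c,
                "observed": r.observed_count,
                "perm_mean": r.perm_mean,
                "perm_sd": r.perm_sd,
                "p_enrich": r.p_enrich.p,
                "p_enrich_report": r.p_enrich.p_report,
                "p_deplete": r.p_deplete.p,
                "p_deplete_report": r.p_deplete.p_report,
                "n_perm": r.n_perm,
            }
        )
    return pd.DataFrame(rows)


def density_per_window(
    sites: SiteSet,
    contig_lengths: dict[str, int],
    window: int = 100_000,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Tile contigs with fixed windows and report site density.

    Returns (per-contig mean sites per 100 kb, per-window track). The last
    partial window's density is scaled by its actual length.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    means: dict[str, float] = {}
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        pos = sites.positions(contig)
        edges = np.arange(0, length + window, window)
        edges[-1] = min(edges[-1], length)
        if edges[-1] <= edges[-2]:
            edges = edges[:-1]
        counts, _ = np.histogram(pos, bins=edges)
        for i, n in enumerate(counts):
            w_len = edges[i + 1] - edges[i]
            rows.append(
                {
                    "contig": contig,
                    "start": int(edges[i]),
                    "end": int(edges[i + 1]),
                    "count": int(n),
                    "per_100kb": float(n) * 100_000 / w_len,
                }
            )
        means[contig] = float(len(pos)) * 100_000 / length
    return means, pd.DataFrame(rows)
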