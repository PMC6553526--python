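"""Between-strain site conservation and overlap with externally defined
regions (e.g. gain-of-methylation intervals from a demethylase mutant).

Matching is coordinate-level: strand is ignored, identity is (contig, pos).
The hypergeometric universe — the number of positions eligible to be called
in both data sets — is an explicit argument because it is a modelling
choice; the report records the value used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import Interval, SiteSet, read_bed_intervals
from .stats import hypergeom_overlap_p


def read_regions(path) -> list[Interval]:
    """Read an externally defined region BED (e.g. gain-of-methylation)."""
    return read_bed_intervals(path, "region")


@dataclass(frozen=True)
class ConservationReport:
    n_query: int
    n_subject: int
    exact_count: int
    exact_fraction: float
    within_d_fraction: float
    d: int
    universe: int
    hypergeom_p: float

    def __post_init__(self) -> None:
        if not 0 <= self.exact_fraction <= self.within_d_fraction <= 1:
            raise ValueError("need 0 <= exact_fraction <= within_d_fraction <= 1")


def exact_overlap_count(query: SiteSet, subject: SiteSet) -> int:
    return sum(1 for key in query if key in subject)


def exact_overlap_fraction(query: SiteSet, subject: SiteSet) -> float:
    """Fraction of query positions whose (contig, pos) is also in subject."""
    if len(query) == 0:
        raise ValueError("query set is empty")
    return exact_overlap_count(query, subject) / len(query)


def within_distance_fraction(query: SiteSet, subject: SiteSet, d: int = 100) -> float:
    """Fraction of query positions with a subject position within d bp on the
    same contig (exact matches count; d=0 reduces to exact overlap)."""
    if d < 0:
        raise ValueError("d must be >= 0")
    if len(query) == 0:
        raise ValueError("query set is empty")
    n_near = 0
    for contig in query.contigs:
        q = query.positions(contig)
        s = subject.positions(contig)
        if len(s) == 0:
            continue
        idx = np.searchsorted(s, q)
        left = np.where(idx > 0, q - s[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(
            idx < len(s), s[np.minimum(idx, len(s) - 1)] - q, np.iinfo(np.int64).max
        )
        n_near += int(np.sum(np.minimum(left, right) <= d))
    return n_near / len(query)


def site_overlap_test(
    query: SiteSet, subject: SiteSet, universe: int, d: int = 100
) -> ConservationReport:
    """Exact-overlap hypergeometric test plus both conservation fractions.

    ``universe`` is the number of positions eligible for calling in both
    strains; it must be at least |query ∪ subject|.
    """
    k = exact_overlap_count(query, subject)
    n_union = len(query) + len(subject) - k
    if universe < n_union:
        raise ValueError(
            f"universe ({universe}) smaller than |query ∪ subject| ({n_union})"
        )
    return ConservationReport(
        n_query=len(query),
        n_subject=len(subject),
        exact_count=k,
        exact_fraction=exact_overlap_fraction(query, subject),
        within_d_fraction=within_distance_fraction(query, subject, d),
        d=d,
        universe=universe,
        hypergeom_p=hypergeom_overlap_p(universe, len(subject), len(query), k),
    )


def sites_in_regions(sites: SiteSet, regions: Iterable[Interval]) -> int:
    """Count sites falling inside any region (union semantics)."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        per_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    count = 0
    for contig, ivs in per_contig.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        starts_a, ends_a = np.asarray(starts), np.asarray(ends)
        pos = sites.positions(contig)
        if len(pos) == 0:
            continue
        idx = np.searchsorted(starts_a, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] = pos[ok] < ends_a[idx[ok]]
        count += int(ok.sum())
    return count


def region_overlap_test(
    sites: SiteSet,
    regions: Sequence[Interval],
    universe: "int | SiteSet",
    n_in_regions: int | None = None,
) -> tuple[int, float, float]:
    """Overlap of sites with a region set: (count, fraction, hypergeometric p).

    ``universe`` is either the number of eligible positions (then
    ``n_in_regions`` — how many of them fall inside the regions — must be
    given) or a SiteSet of eligible positions from which both are computed.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("region set is empty")
    if len(sites) == 0:
        raise ValueError("site set is empty")
    if isinstance(universe, SiteSet):
        n_universe = len(universe)
        n_marked = sites_in_regions(universe, regions)
    else:
        n_universe = int(universe)
        if n_in_regions is None:
            raise ValueError("n_in_regions is required when universe is an integer")
        n_marked = int(n_in_regions)
    k = sites_in_regions(sites, regions)
    p = hypergeom_overlap_p(n_universe, n_marked, len(sites), k)
    return k, k / len(sites), p
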