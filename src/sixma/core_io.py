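"""Core data types, file I/O and coordinate utilities.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
GFF3 (1-based, closed) and BED (0-based, half-open) are converted at the
read/write boundary, so no other module ever reasons about conventions.

Positions are strand-resolved — a T on the + strand marks a candidate
methylated A on the − strand — but site identity is ``(contig, pos)`` only:
overlap queries and set comparisons ignore strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Closed vocabulary of exclusive feature categories (precedence order is
#: owned by :mod:`sixma.feature_enrichment`; ``gene`` spans are kept separately).
CATEGORIES = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "upstream1kb",
    "intergenic",
    "simple_repeat",
    "TE",
    "gene",
    # generic label for externally supplied interval sets (e.g. gain-of-6mA
    # regions); never part of the exclusive feature partition
    "region",
)

POSITION_TABLE_COLUMNS = ("contig", "pos", "strand", "base", "coverage", "prm")

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomePosition:
    """A single-base genomic position (0-based) with strand."""

    contig: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"position must be >= 0, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class Interval:
    """A typed genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    category: str
    strand: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"interval must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Transcript:
    """One isoform: ordered exons plus optional CDS/UTR sub-features."""

    id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in transcript {self.id}")
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    transcripts: tuple[Transcript, ...]


def select_longest_isoform(transcripts: Sequence[Transcript]) -> Transcript:
    """Pick the isoform with the greatest summed exon length.

    Ties are broken by the lexicographically smallest transcript id so the
    choice is deterministic.
    """
    if not transcripts:
        raise ValueError("no transcripts to select from")
    return min(transcripts, key=lambda t: (-t.exonic_length, t.id))


class AnnotationSet:
    """Typed genomic intervals, queryable by point.

    Intervals within a category may overlap (nested TEs, repeats inside
    genes); membership queries work on the merged union per category.
    """

    def __init__(
        self,
        intervals: Iterable[Interval] = (),
        contig_lengths: Mapping[str, int] | None = None,
        source: str = "unknown",
    ) -> None:
        self.contig_lengths: dict[str, int] = dict(contig_lengths or {})
        self.source = source
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._by_category: dict[str, list[Interval]] = {c: [] for c in CATEGORIES}
        self.genes: dict[str, Interval] = {}
        self.gene_models: list[GeneModel] = []
        self._merged_cache: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: Interval) -> None:
        if self.contig_lengths and iv.contig not in self.contig_lengths:
            raise KeyError(f"interval on unknown contig {iv.contig!r}")
        if self.contig_lengths and iv.end > self.contig_lengths[iv.contig]:
            raise ValueError(
                f"interval [{iv.start},{iv.end}) exceeds contig {iv.contig} length"
            )
        self._by_category[iv.category].append(iv)
        self._trees.setdefault((iv.contig, iv.category), IntervalTree()).addi(
            iv.start, iv.end, iv
        )
        if iv.category == "gene" and iv.name is not None:
            self.genes[iv.name] = iv
        self._merged_cache.pop(iv.category, None)

    def intervals(self, category: str | None = None) -> list[Interval]:
        if category is None:
            return [iv for c in CATEGORIES for iv in self._by_category[c]]
        return list(self._by_category[category])

    def overlapping(self, contig: str, pos: int, category: str) -> list[Interval]:
        """Intervals of ``category`` containing ``pos`` (O(log n) tree query)."""
        tree = self._trees.get((contig, category))
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]

    def categories_at(self, contig: str, pos: int) -> set[str]:
        if self.contig_lengths and contig not in self.contig_lengths:
            raise KeyError(f"unknown contig {contig!r}")
        return {
            c
            for c in CATEGORIES
            if c not in ("intergenic", "gene") and self.overlapping(contig, pos, c)
        }

    # -- vectorized membership -------------------------------------------------

    def _merged(self, category: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Merged (union) interval arrays per contig for fast membership."""
        cached = self._merged_cache.get(category)
        if cached is not None:
            return cached
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in self._by_category[category]:
            per_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, ivs in per_contig.items():
            ivs.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in ivs:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            merged[contig] = (np.asarray(starts), np.asarray(ends))
        self._merged_cache[category] = merged
        return merged

    def membership(
        self, category: str, contigs: np.ndarray, positions: np.ndarray
    ) -> np.ndarray:
        """Boolean vector: does each (contig, position) fall in ``category``."""
        contigs = np.asarray(contigs)
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=bool)
        merged = self._merged(category)
        for contig in pd.unique(contigs):
            mask = contigs == contig
            arrs = merged.get(contig)
            if arrs is None:
                continue
            starts, ends = arrs
            pos = positions[mask]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            ok[ok] = pos[ok] < ends[idx[ok]]
            out[mask] = ok
        return out


# -- position tables -----------------------------------------------------------


def read_position_table(path: str | Path) -> pd.DataFrame:
    """Read a per-position modification table.

    Expected TSV header: ``contig  pos  strand  base  coverage  prm`` with
    0-based positions, base in {A, T} and prm (percent reads modified) in
    [0, 100]. Row order is preserved. Malformed rows raise ``ValueError``
    naming the offending line.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pandas message carries the line number
        raise ValueError(f"malformed row in {path}: {exc}") from exc
    if list(df.columns) != list(POSITION_TABLE_COLUMNS):
        raise ValueError(
            f"{path}: expected columns {POSITION_TABLE_COLUMNS}, got {tuple(df.columns)}"
        )

    def _bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path} line {line}: {what}")

    _bad((df == "").any(axis=1), "missing field")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    _bad(pos.isna() | (pos < 0) | (pos % 1 != 0), "pos must be a non-negative integer")
    _bad(~df["strand"].isin(STRANDS), "strand must be + or -")
    _bad(~df["base"].isin(("A", "T")), "base must be A or T")
    cov = pd.to_numeric(df["coverage"], errors="coerce")
    _bad(cov.isna() | (cov < 0) | (cov % 1 != 0), "coverage must be a non-negative integer")
    prm = pd.to_numeric(df["prm"], errors="coerce")
    _bad(prm.isna() | (prm < 0) | (prm > 100), "prm must be in [0, 100]")

    return pd.DataFrame(
        {
            "contig": df["contig"].to_numpy(),
            "pos": pos.astype(np.int64).to_numpy(),
            "strand": df["strand"].to_numpy(),
            "base": df["base"].to_numpy(),
            "coverage": cov.astype(np.int64).to_numpy(),
            "prm": prm.astype(float).to_numpy(),
        }
    )


def write_position_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(POSITION_TABLE_COLUMNS),
              float_format="%.6g")


# -- site sets -----------------------------------------------------------------


class SiteSet:
    """A strand-aware set of single-base positions; identity is (contig, pos).

    Backed by a DataFrame (``contig``, ``pos`` plus optional ``strand``,
    ``name``, ``score`` carried through to BED6 output) and per-contig sorted
    position arrays for fast neighbourhood queries.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        df = df.drop_duplicates(subset=["contig", "pos"]).sort_values(
            ["contig", "pos"], kind="mergesort"
        )
        self.df = df.reset_index(drop=True)
        self._by_contig: dict[str, np.ndarray] = {
            str(contig): np.asarray(sub["pos"], dtype=np.int64)
            for contig, sub in self.df.groupby("contig", sort=True)
        }
        self._index = frozenset(zip(self.df["contig"], self.df["pos"].astype(int)))

    @classmethod
    def from_records(
        cls,
        contigs: Sequence[str],
        positions: Sequence[int],
        strands: Sequence[str] | None = None,
        names: Sequence | None = None,
        scores: Sequence | None = None,
    ) -> "SiteSet":
        data = {"contig": list(contigs), "pos": list(positions)}
        if strands is not None:
            data["strand"] = list(strands)
        if names is not None:
            data["name"] = list(names)
        if scores is not None:
            data["score"] = list(scores)
        return cls(pd.DataFrame(data))

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, key: tuple[str, int]) -> bool:
        contig, pos = key
        return (contig, int(pos)) in self._index

    def __iter__(self):
        return iter(self._index)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._by_contig)

    def positions(self, contig: str) -> np.ndarray:
        return self._by_contig.get(contig, np.empty(0, dtype=np.int64))

    def to_bed(self, path: str | Path) -> None:
        """Write BED6 (one-base intervals); name/score default to '.'/0."""
        df = self.df
        bed = pd.DataFrame(
            {
                "contig": df["contig"],
                "start": df["pos"],
                "end": df["pos"] + 1,
                "name": df["name"] if "name" in df else ".",
                "score": df["score"] if "score" in df else 0,
                "strand": df["strand"] if "strand" in df else "+",
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")

    @classmethod
    def read_bed(cls, path: str | Path) -> "SiteSet":
        df = _read_bed_df(path)
        data = {"contig": df["contig"], "pos": df["start"]}
        for col in ("name", "score", "strand"):
            if col in df:
                data[col] = df[col]
        return cls(pd.DataFrame(data))

    def lift(self, lomap: "LiftoverMap") -> tuple["SiteSet", int]:
        """Map every site through ``lomap``; returns (lifted set, n unmapped)."""
        rows = []
        n_unmapped = 0
        strands = self.df["strand"] if "strand" in self.df else pd.Series(
            ["+"] * len(self.df)
        )
        for (_, row), strand in zip(self.df.iterrows(), strands):
            q = lomap.map_position(
                GenomePosition(str(row["contig"]), int(row["pos"]), str(strand))
            )
            if q is None:
                n_unmapped += 1
            else:
                rows.append((q.contig, q.pos, q.strand))
        if rows:
            contigs, positions, strands_out = zip(*rows)
        else:
            contigs, positions, strands_out = (), (), ()
        return SiteSet.from_records(contigs, positions, strands_out), n_unmapped


def _read_bed_df(path: str | Path) -> pd.DataFrame:
    names = ["contig", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_bed_intervals(
    path: str | Path,
    category: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[Interval]:
    """Read BED4/BED6 intervals (0-based half-open) into typed Intervals."""
    df = _read_bed_df(path)
    out = []
    for i, row in df.iterrows():
        contig = str(row["contig"])
        if contig_lengths is not None and contig not in contig_lengths:
            raise ValueError(f"{path} line {i + 1}: unknown contig {contig!r}")
        out.append(
            Interval(
                contig,
                int(row["start"]),
                int(row["end"]),
                category,
                strand=str(row["strand"]) if "strand" in df else None,
                name=str(row["name"]) if "name" in df else None,
            )
        )
    return out


def write_bed_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            strand = iv.strand if iv.strand is not None else "+"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


# -- GFF3 ----------------------------------------------------------------------


def write_gff3(
    gene_models: Iterable[GeneModel],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features, converting to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(contig_lengths):
            fh.write(f"##sequence-region {contig} 1 {contig_lengths[contig]}\n")

        def row(contig, ftype, start, end, strand, attrs):
            fh.write(
                f"{contig}\tsixma\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )

        for gm in gene_models:
            spans = [t.span for t in gm.transcripts]
            g0, g1 = min(s for s, _ in spans), max(e for _, e in spans)
            row(gm.contig, "gene", g0, g1, gm.strand, f"ID={gm.gene_id}")
            for t in gm.transcripts:
                s, e = t.span
                row(gm.contig, "mRNA", s, e, t.strand, f"ID={t.id};Parent={gm.gene_id}")
                for ftype, segs in (
                    ("exon", t.exons),
                    ("CDS", t.cds),
                    ("five_prime_UTR", t.utr5),
                    ("three_prime_UTR", t.utr3),
                ):
                    for s, e in segs:
                        row(gm.contig, ftype, s, e, t.strand, f"Parent={t.id}")


def read_gene_models(path: str | Path) -> tuple[list[GeneModel], dict[str, int]]:
    """Parse a GFF3 file into gene models plus contig lengths.

    Contig lengths come from ``##sequence-region`` pragmas; files without
    them yield an empty length map (downstream clipping then only applies
    at zero).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    contig_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 3:
            contig_lengths[parts[1]] = int(parts[3]) if len(parts) > 3 else int(parts[2])

    def _segs(parent, ftype) -> tuple[tuple[int, int], ...]:
        segs = []
        for f in db.children(parent, featuretype=ftype, order_by="start"):
            if f.end < f.start:
                raise ValueError(f"{path}: feature with end < start at {f.seqid}:{f.start}")
            segs.append((f.start - 1, f.end))  # to 0-based half-open
        return tuple(segs)

    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.end < gene.start:
            raise ValueError(f"{path}: gene with end < start: {gene.id}")
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = _segs(mrna, "exon")
            if not exons:
                span = (mrna.start - 1, mrna.end)
                exons = (span,)
            transcripts.append(
                Transcript(
                    id=mrna.id,
                    gene_id=gene.id,
                    contig=gene.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=_segs(mrna, "CDS"),
                    utr5=_segs(mrna, "five_prime_UTR"),
                    utr3=_segs(mrna, "three_prime_UTR"),
                )
            )
        if transcripts:
            models.append(
                GeneModel(gene.id, gene.seqid, gene.strand, tuple(transcripts))
            )
    return models, contig_lengths


def build_annotation_set(
    gene_models: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    repeats: Iterable[Interval] = (),
    tes: Iterable[Interval] = (),
    upstream: int = 1000,
    source: str = "unknown",
) -> AnnotationSet:
    """Assemble the exclusive-category annotation from gene models + repeat BEDs.

    Per gene, the longest isoform (summed exon length) defines CDS/UTR/intron
    intervals, the gene span, and the strand-aware ``upstream`` window 5' of
    the TSS, clipped at contig edges.
    """
    ann = AnnotationSet(contig_lengths=contig_lengths, source=source)
    for gm in gene_models:
        t = select_longest_isoform(gm.transcripts)
        s, e = t.span
        ann.add(Interval(t.contig, s, e, "gene", strand=t.strand, name=gm.gene_id))
        for seg in t.cds:
            ann.add(Interval(t.contig, *seg, category="CDS", strand=t.strand))
        for seg in t.utr5:
            ann.add(Interval(t.contig, *seg, category="five_prime_UTR", strand=t.strand))
        for seg in t.utr3:
            ann.add(Interval(t.contig, *seg, category="three_prime_UTR", strand=t.strand))
        for seg in t.introns():
            ann.add(Interval(t.contig, *seg, category="intron", strand=t.strand))
        if t.strand == "+":
            u0, u1 = s - upstream, s
        else:
            u0, u1 = e, e + upstream
        u0 = max(u0, 0)
        if t.contig in contig_lengths:
            u1 = min(u1, contig_lengths[t.contig])
        if u0 < u1:
            ann.add(Interval(t.contig, u0, u1, "upstream1kb", strand=t.strand))
    for iv in repeats:
        ann.add(replace(iv, category="simple_repeat"))
    for iv in tes:
        ann.add(replace(iv, category="TE"))
    ann.gene_models = list(gene_models)
    return ann


def read_annotations(
    gff_path: str | Path,
    repeat_bed: str | Path | None = None,
    te_bed: str | Path | None = None,
    upstream: int = 1000,
) -> AnnotationSet:
    """Read GFF3 + repeat/TE BEDs into a uniform 0-based AnnotationSet."""
    models, contig_lengths = read_gene_models(gff_path)
    lengths_or_none = contig_lengths if contig_lengths else None
    repeats = (
        read_bed_intervals(repeat_bed, "simple_repeat", lengths_or_none)
        if repeat_bed
        else []
    )
    tes = read_bed_intervals(te_bed, "TE", lengths_or_none) if te_bed else []
    return build_annotation_set(
        models, contig_lengths, repeats, tes, upstream=upstream, source=str(gff_path)
    )


# -- liftover ------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentBlock:
    """One collinear alignment block; src and tgt spans have equal length."""

    src_contig: str
    src_start: int
    src_end: int
    tgt_contig: str
    tgt_start: int
    tgt_end: int
    orientation: str  # "same" or "flipped"

    def __post_init__(self) -> None:
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise ValueError("alignment block src/tgt lengths differ")
        if self.src_start < 0 or self.src_start >= self.src_end:
            raise ValueError("invalid src span")
        if self.orientation not in ("same", "flipped"):
            raise ValueError(f"orientation must be same|flipped, got {self.orientation!r}")


class LiftoverMap:
    """Ordered collinear blocks mapping positions one-to-one between assemblies."""

    def __init__(self, blocks: Iterable[AlignmentBlock]) -> None:
        per_contig: dict[str, list[AlignmentBlock]] = {}
        for b in blocks:
            per_contig.setdefault(b.src_contig, []).append(b)
        self._blocks: dict[str, list[AlignmentBlock]] = {}
        self._starts: dict[str, list[int]] = {}
        for contig, bs in per_contig.items():
            bs.sort(key=lambda b: b.src_start)
            for b0, b1 in zip(bs, bs[1:]):
                if b1.src_start < b0.src_end:
                    raise ValueError(
                        f"blocks overlap on source contig {contig} at {b1.src_start}"
                    )
            self._blocks[contig] = bs
            self._starts[contig] = [b.src_start for b in bs]

    @property
    def blocks(self) -> list[AlignmentBlock]:
        return [b for contig in sorted(self._blocks) for b in self._blocks[contig]]

    def map_position(self, p: GenomePosition) -> GenomePosition | None:
        """Map a position; returns None when no block covers it."""
        starts = self._starts.get(p.contig)
        if not starts:
            return None
        i = bisect.bisect_right(starts, p.pos) - 1
        if i < 0:
            return None
        b = self._blocks[p.contig][i]
        if p.pos >= b.src_end:
            return None
        off = p.pos - b.src_start
        if b.orientation == "same":
            return GenomePosition(b.tgt_contig, b.tgt_start + off, p.strand)
        flipped = "-" if p.strand == "+" else "+"
        return GenomePosition(b.tgt_contig, b.tgt_end - 1 - off, flipped)

    def inverted(self) -> "LiftoverMap":
        """The inverse map (valid because blocks are one-to-one)."""
        return LiftoverMap(
            AlignmentBlock(
                b.tgt_contig,
                b.tgt_start,
                b.tgt_end,
                b.src_contig,
                b.src_start,
                b.src_end,
                b.orientation,
            )
            for b in self.blocks
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "src_contig\tsrc_start\tsrc_end\ttgt_contig\ttgt_start\ttgt_end\torientation\n"
            )
            for b in self.blocks:
                fh.write(
                    f"{b.src_contig}\t{b.src_start}\t{b.src_end}\t"
                    f"{b.tgt_contig}\t{b.tgt_start}\t{b.tgt_end}\t{b.orientation}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LiftoverMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            AlignmentBlock(
                str(r.src_contig),
                int(r.src_start),
                int(r.src_end),
                str(r.tgt_contig),
                int(r.tgt_start),
                int(r.tgt_end),
                str(r.orientation),
            )
            for r in df.itertuples()
        )
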