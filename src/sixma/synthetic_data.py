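"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the study design end to end: a compact annotated
genome, per-position percent-reads-modified (PRM) tables for two PCR-free
replicates plus a control-comparison call set, a second strain's site set, a
cross-assembly alignment block map, externally defined gain-of-methylation
regions, per-position signal-level differences, and a per-gene tissue
enrichment-score matrix. Methylated and unmethylated positions draw PRM from
well-separated Beta distributions; replicate disagreement is additive
Gaussian noise on the percent scale; coverage is negative-binomial with a
small planted outlier fraction so the coverage filter has work to do.

One seed governs everything: each operation derives its generator from the
config seed and a fixed stream index, so outputs are bit-reproducible and
stages remain individually reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    AlignmentBlock,
    AnnotationSet,
    GeneModel,
    Interval,
    LiftoverMap,
    SiteSet,
    Transcript,
    build_annotation_set,
)

# Fixed per-operation RNG stream indices (determinism contract).
_STREAMS = {
    "genome": 0,
    "tables": 1,
    "strain2": 2,
    "tissue": 3,
    "signal": 4,
    "liftover": 5,
    "gain": 6,
}


def derive_rng(seed: int, stream: str | int) -> np.random.Generator:
    """Child generator for one named stream of a single master seed."""
    key = _STREAMS[stream] if isinstance(stream, str) else int(stream)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass
class GenomeConfig:
    contigs: tuple[tuple[str, int], ...] = (("sim2L", 400_000), ("sim3R", 400_000))
    genes_per_contig: int = 40
    exons_per_gene: int = 4
    exon_len: tuple[int, int] = (180, 450)
    intron_len: tuple[int, int] = (60, 400)
    utr5_len: int = 100
    utr3_len: int = 150
    intergenic_gap: tuple[int, int] = (1_200, 4_000)
    repeats_per_100kb: float = 25.0
    repeat_len: tuple[int, int] = (30, 200)
    tes_per_100kb: float = 6.0
    te_len: tuple[int, int] = (400, 2_000)


@dataclass
class MethylationConfig:
    #: fraction of genome bases emitted as candidate A/T positions in the tables
    at_fraction: float = 0.12
    #: per-candidate-position probability of planted methylation (before
    #: multipliers); sparse enough that gene bodies split into site-bearing
    #: and site-free groups, as in real data
    base_rate: float = 0.005
    multipliers: dict = field(
        default_factory=lambda: {
            "CDS": 0.5,
            "five_prime_UTR": 1.0,
            "three_prime_UTR": 2.0,
            "intron": 3.0,
            "upstream1kb": 2.0,
            "intergenic": 0.5,
            "simple_repeat": 2.0,
            "TE": 0.3,
        }
    )
    prm_meth_mean: float = 0.85
    prm_meth_conc: float = 40.0
    prm_unmeth_mean: float = 0.05
    prm_unmeth_conc: float = 120.0
    #: replicate/control PRM noise sd in percentage points; calibrated so the
    #: default config lands the replicate Spearman rho near the mid-0.5s
    replicate_noise_sd: float = 3.0


@dataclass
class CoverageConfig:
    mean: float = 30.0
    #: negative-binomial size parameter; 0 means constant coverage
    nb_size: float = 300.0
    #: fraction of positions drawn as coverage outliers, split evenly between
    #: 3x and 0.2x the mean, to exercise the +/-50% coverage filter
    outlier_fraction: float = 0.01


@dataclass
class Strain2Config:
    p_exact: float = 0.16
    p_near: float = 0.74
    max_shift: int = 100
    #: background call rate per bp of genome
    background_rate: float = 2e-5


@dataclass
class TissueConfig:
    n_tissues: int = 12
    #: multiplier applied to one random tissue of each modified gene
    fold: float = 8.0
    lognorm_sigma: float = 0.6
    #: genes with no score row at all (score table availability is incomplete)
    missing_fraction: float = 0.2


@dataclass
class SignalConfig:
    mu_mod: float = 3.0
    mu_unmod: float = 0.5
    sd: float = 1.0


@dataclass
class GainRegionConfig:
    per_100kb: float = 4.0
    length: tuple[int, int] = (500, 3_000)
    #: probability a region is centred near a planted site rather than uniform
    p_near_site: float = 0.5


@dataclass
class LiftoverSimConfig:
    blocks_per_contig: int = 8
    flip_fraction: float = 0.25
    max_target_gap: int = 500


@dataclass
class SimConfig:
    """All knobs for one synthetic study; a single seed drives every stream."""

    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    methylation: MethylationConfig = field(default_factory=MethylationConfig)
    coverage: CoverageConfig = field(default_factory=CoverageConfig)
    strain2: Strain2Config = field(default_factory=Strain2Config)
    tissue: TissueConfig = field(default_factory=TissueConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    gain: GainRegionConfig = field(default_factory=GainRegionConfig)
    liftover: LiftoverSimConfig = field(default_factory=LiftoverSimConfig)

    def __post_init__(self) -> None:
        s2 = self.strain2
        if not (0 <= s2.p_exact <= 1 and 0 <= s2.p_near <= 1):
            raise ValueError("strain2 probabilities must be in [0, 1]")
        if s2.p_exact + s2.p_near > 1 + 1e-12:
            raise ValueError("p_exact + p_near must be <= 1")
        if any(m <= 0 for m in self.methylation.multipliers.values()):
            raise ValueError("category multipliers must be > 0")
        if not 0 <= self.coverage.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome"]["contigs"] = [list(c) for c in self.genome.contigs]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        sections = {
            "genome": GenomeConfig,
            "methylation": MethylationConfig,
            "coverage": CoverageConfig,
            "strain2": Strain2Config,
            "tissue": TissueConfig,
            "signal": SignalConfig,
            "gain": GainRegionConfig,
            "liftover": LiftoverSimConfig,
        }
        kwargs: dict = {"seed": int(d.get("seed", 0))}
        for name, klass in sections.items():
            sub = dict(d.get(name, {}))
            if name == "genome" and "contigs" in sub:
                sub["contigs"] = tuple((str(c), int(n)) for c, n in sub["contigs"])
            for key in ("exon_len", "intron_len", "intergenic_gap", "repeat_len",
                        "te_len", "length"):
                if key in sub and isinstance(sub[key], (list, tuple)):
                    sub[key] = tuple(int(v) for v in sub[key])
            kwargs[name] = klass(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# -- genome --------------------------------------------------------------------


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[AnnotationSet, dict[str, int]]:
    """Lay out non-overlapping genes plus independently placed repeats/TEs.

    Genes are placed left to right with random intergenic gaps; repeats and
    TEs land uniformly and may overlap genes, so exclusive category
    precedence is exercised. Raises when a contig cannot host the requested
    gene count.
    """
    rng = rng if rng is not None else derive_rng(cfg.seed, "genome")
    g = cfg.genome
    contig_lengths = {name: int(length) for name, length in g.contigs}
    gene_models: list[GeneModel] = []
    repeats: list[Interval] = []
    tes: list[Interval] = []
    for contig, length in g.contigs:
        cursor = 1_000 + int(rng.integers(*g.intergenic_gap))
        for i in range(g.genes_per_contig):
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = max(1, int(g.exons_per_gene))
            exon_lens = rng.integers(g.exon_len[0], g.exon_len[1] + 1, n_exons)
            intron_lens = rng.integers(g.intron_len[0], g.intron_len[1] + 1,
                                       max(0, n_exons - 1))
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + 1_000 > length:
                raise ValueError(
                    f"contig {contig} ({length} bp) too small for "
                    f"{g.genes_per_contig} genes"
                )
            exons = []
            p = cursor
            for j in range(n_exons):
                exons.append((p, p + int(exon_lens[j])))
                p += int(exon_lens[j])
                if j < n_exons - 1:
                    p += int(intron_lens[j])
            exons_t = tuple(exons)
            gene_id = f"{contig}_g{i:03d}"
            first, last = exons_t[0], exons_t[-1]
            if strand == "+":
                utr5 = ((first[0], min(first[0] + g.utr5_len, first[1])),)
                utr3 = ((max(last[1] - g.utr3_len, last[0]), last[1]),)
            else:
                utr5 = ((max(last[1] - g.utr5_len, last[0]), last[1]),)
                utr3 = ((first[0], min(first[0] + g.utr3_len, first[1])),)
            blocked = set(utr5) | set(utr3)
            cds = []
            for s, e in exons_t:
                lo, hi = s, e
                for us, ue in sorted(blocked):
                    if us <= lo < ue:
                        lo = ue
                    if us < hi <= ue:
                        hi = us
                if lo < hi:
                    cds.append((lo, hi))
            transcript = Transcript(
                id=f"{gene_id}.t1", gene_id=gene_id, contig=contig, strand=strand,
                exons=exons_t, cds=tuple(cds), utr5=utr5, utr3=utr3,
            )
            gene_models.append(GeneModel(gene_id, contig, strand, (transcript,)))
            cursor += span + int(rng.integers(*g.intergenic_gap))

        for kind, per_100kb, len_range, out in (
            ("rep", g.repeats_per_100kb, g.repeat_len, repeats),
            ("te", g.tes_per_100kb, g.te_len, tes),
        ):
            n = int(round(per_100kb * length / 100_000))
            starts = np.sort(rng.integers(0, length - len_range[1], n))
            lens = rng.integers(len_range[0], len_range[1] + 1, n)
            category = "simple_repeat" if kind == "rep" else "TE"
            for k in range(n):
                out.append(
                    Interval(contig, int(starts[k]), int(starts[k] + lens[k]),
                             category, name=f"{contig}_{kind}{k:04d}")
                )
    return (
        build_annotation_set(gene_models, contig_lengths, repeats, tes,
                             source="simulated"),
        contig_lengths,
    )


# -- position tables -----------------------------------------------------------


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def _coverage(cov: CoverageConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cov.nb_size <= 0:
        values = np.full(n, int(round(cov.mean)), dtype=np.int64)
    else:
        p = cov.nb_size / (cov.nb_size + cov.mean)
        values = rng.negative_binomial(cov.nb_size, p, n).astype(np.int64)
    if cov.outlier_fraction > 0:
        u = rng.random(n)
        hi = u < cov.outlier_fraction / 2
        lo = (u >= cov.outlier_fraction / 2) & (u < cov.outlier_fraction)
        values[hi] = int(round(3.0 * cov.mean))
        values[lo] = max(1, int(round(0.2 * cov.mean)))
    return values


def simulate_position_tables(
    cfg: SimConfig,
    annotation: AnnotationSet,
    rng: np.random.Generator | None = None,
    precedence: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw candidate A/T positions and emit (rep1, rep2, sample_compare, truth).

    Methylation is planted per position with probability
    ``base_rate * multiplier(category)``; PRM is Beta-distributed per label,
    scaled to [0, 100]; replicate 2 and the control-comparison set add
    independent Gaussian noise to replicate 1's PRM; coverage is drawn
    independently per dataset. The truth table carries the planted label and
    the category of every emitted position.
    """
    from .feature_enrichment import DEFAULT_PRECEDENCE, assign_categories

    rng = rng if rng is not None else derive_rng(cfg.seed, "tables")
    m = cfg.methylation
    precedence = tuple(precedence) if precedence is not None else DEFAULT_PRECEDENCE

    contigs_all: list[np.ndarray] = []
    pos_all: list[np.ndarray] = []
    for contig in sorted(annotation.contig_lengths):
        length = annotation.contig_lengths[contig]
        n = int(round(length * m.at_fraction))
        pos = np.sort(rng.choice(length, size=n, replace=False)).astype(np.int64)
        pos_all.append(pos)
        contigs_all.append(np.full(n, contig, dtype=object))
    contig_arr = np.concatenate(contigs_all)
    pos_arr = np.concatenate(pos_all)
    n = len(pos_arr)

    base = np.where(rng.random(n) < 0.5, "A", "T")
    strand = np.where(base == "A", "+", "-")  # T on + strand == A on - strand

    category = assign_categories(contig_arr, pos_arr, annotation, precedence)
    p_meth = np.array(
        [min(1.0, m.base_rate * m.multipliers.get(c, 1.0)) for c in category]
    )
    methylated = rng.random(n) < p_meth

    prm1 = np.empty(n)
    a_m, b_m = _beta_params(m.prm_meth_mean, m.prm_meth_conc)
    a_u, b_u = _beta_params(m.prm_unmeth_mean, m.prm_unmeth_conc)
    prm1[methylated] = rng.beta(a_m, b_m, int(methylated.sum())) * 100.0
    prm1[~methylated] = rng.beta(a_u, b_u, int((~methylated).sum())) * 100.0

    def _noisy(base_prm: np.ndarray) -> np.ndarray:
        if m.replicate_noise_sd == 0:
            return base_prm.copy()
        return np.clip(base_prm + rng.normal(0.0, m.replicate_noise_sd, n), 0.0, 100.0)

    prm2 = _noisy(prm1)
    prm_sc = _noisy(prm1)

    def _table(prm: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": contig_arr,
                "pos": pos_arr,
                "strand": strand,
                "base": base,
                "coverage": _coverage(cfg.coverage, n, rng),
                "prm": prm,
            }
        )

    rep1, rep2, sc = _table(prm1), _table(prm2), _table(prm_sc)
    truth = pd.DataFrame(
        {
            "contig": contig_arr,
            "pos": pos_arr,
            "strand": strand,
            "base": base,
            "category": category,
            "methylated": methylated,
        }
    )
    return rep1, rep2, sc, truth


def truth_sites(truth: pd.DataFrame) -> SiteSet:
    """The planted methylated positions as a SiteSet."""
    sub = truth[truth["methylated"]]
    return SiteSet.from_records(sub["contig"], sub["pos"], sub["strand"])


# -- second strain -------------------------------------------------------------


def simulate_second_strain(
    truth: SiteSet | pd.DataFrame,
    cfg: SimConfig,
    contig_lengths: Mapping[str, int],
    rng: np.random.Generator | None = None,
) -> SiteSet:
    """A second strain's call set: each true site kept exactly (p_exact),
    shifted uniformly within +/-max_shift (p_near), or dropped; plus Poisson
    background calls at ``background_rate`` per bp."""
    rng = rng if rng is not None else derive_rng(cfg.seed, "strain2")
    s2 = cfg.strain2
    if isinstance(truth, pd.DataFrame):
        truth = truth_sites(truth)
    contigs: list[str] = []
    positions: list[int] = []
    for contig in truth.contigs:
        pos = truth.positions(contig)
        u = rng.random(len(pos))
        exact = u < s2.p_exact
        near = (u >= s2.p_exact) & (u < s2.p_exact + s2.p_near)
        keep_exact = pos[exact]
        shifts = rng.integers(1, s2.max_shift + 1, int(near.sum()))
        signs = np.where(rng.random(int(near.sum())) < 0.5, -1, 1)
        length = contig_lengths.get(contig)
        shifted = pos[near] + signs * shifts
        shifted = np.clip(shifted, 0, (length - 1) if length else None)
        for p in np.concatenate([keep_exact, shifted]):
            contigs.append(contig)
            positions.append(int(p))
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        n_bg = rng.poisson(s2.background_rate * length)
        for p in rng.integers(0, length, n_bg):
            contigs.append(contig)
            positions.append(int(p))
    return SiteSet.from_records(contigs, positions)


# -- tissue scores -------------------------------------------------------------

TISSUE_NAMES = (
    "brain", "head", "thoracic_ganglion", "midgut", "hindgut", "malpighian_tubule",
    "ovary", "testis", "accessory_gland", "salivary_gland", "fat_body", "larval_cns",
)


def simulate_tissue_scores(
    genes: Sequence[str],
    modified_flags: Sequence[bool],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene tissue enrichment scores (tissue vs whole-organism ratio).

    Baseline scores are log-normal around 1 in every tissue; each modified
    gene has one randomly chosen tissue's score multiplied by the planted
    fold, emulating tissue-restricted expression. A random
    ``missing_fraction`` of genes is dropped to mimic incomplete score
    availability.
    """
    rng = rng if rng is not None else derive_rng(cfg.seed, "tissue")
    t = cfg.tissue
    genes = list(genes)
    flags = np.asarray(list(modified_flags), dtype=bool)
    if len(genes) != len(flags):
        raise ValueError("genes and modified_flags must have equal length")
    n = len(genes)
    tissues = list(TISSUE_NAMES[: t.n_tissues])
    if t.n_tissues > len(TISSUE_NAMES):
        tissues += [f"tissue_{i:02d}" for i in range(len(TISSUE_NAMES), t.n_tissues)]
    scores = np.exp(rng.normal(0.0, t.lognorm_sigma, size=(n, t.n_tissues)))
    chosen = rng.integers(0, t.n_tissues, n)
    rows = np.flatnonzero(flags)
    scores[rows, chosen[rows]] *= t.fold
    df = pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=tissues)
    if t.missing_fraction > 0 and n > 0:
        keep = rng.random(n) >= t.missing_fraction
        df = df.loc[keep]
    return df


# -- signal-level differences --------------------------------------------------


def simulate_signal_differences(
    truth: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-position |signal-level difference| between the PCR-free and control
    libraries: folded-normal draws with a larger mean at methylated positions."""
    rng = rng if rng is not None else derive_rng(cfg.seed, "signal")
    s = cfg.signal
    meth = truth["methylated"].to_numpy(dtype=bool)
    mu = np.where(meth, s.mu_mod, s.mu_unmod)
    diff = np.abs(rng.normal(mu, s.sd)) if s.sd > 0 else np.abs(mu.astype(float))
    return pd.DataFrame(
        {"contig": truth["contig"], "pos": truth["pos"], "signal_diff": diff}
    )


# -- gain-of-methylation regions ----------------------------------------------


def simulate_gain_regions(
    truth: SiteSet | pd.DataFrame,
    cfg: SimConfig,
    contig_lengths: Mapping[str, int],
    rng: np.random.Generator | None = None,
) -> list[Interval]:
    """Externally-defined gain-of-methylation regions: some centred near
    planted sites (overlap signal), the rest uniform."""
    rng = rng if rng is not None else derive_rng(cfg.seed, "gain")
    g = cfg.gain
    if isinstance(truth, pd.DataFrame):
        truth = truth_sites(truth)
    out: list[Interval] = []
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        n = int(round(g.per_100kb * length / 100_000))
        site_pos = truth.positions(contig)
        for k in range(n):
            size = int(rng.integers(g.length[0], g.length[1] + 1))
            if len(site_pos) and rng.random() < g.p_near_site:
                centre = int(rng.choice(site_pos))
                start = centre - size // 2
            else:
                start = int(rng.integers(0, max(1, length - size)))
            start = max(0, min(start, length - size))
            out.append(
                Interval(contig, start, start + size, "region",
                         name=f"gain_{contig}_{k:03d}")
            )
    return out


# -- cross-assembly map --------------------------------------------------------


def simulate_liftover_map(
    contig_lengths: Mapping[str, int],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> LiftoverMap:
    """A block map to a fictitious second assembly: each contig is cut into
    collinear blocks with small target-side gaps and a fraction of flipped
    orientations; the source is fully covered, so every position maps."""
    rng = rng if rng is not None else derive_rng(cfg.seed, "liftover")
    lc = cfg.liftover
    blocks: list[AlignmentBlock] = []
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        n_blocks = max(1, lc.blocks_per_contig)
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_blocks - 1, replace=False))
        bounds = [0, *cuts.tolist(), length]
        tgt_cursor = int(rng.integers(0, lc.max_target_gap + 1))
        for i in range(n_blocks):
            s, e = bounds[i], bounds[i + 1]
            size = e - s
            orientation = "flipped" if rng.random() < lc.flip_fraction else "same"
            blocks.append(
                AlignmentBlock(contig, s, e, f"alt_{contig}", tgt_cursor,
                               tgt_cursor + size, orientation)
            )
            tgt_cursor += size + int(rng.integers(0, lc.max_target_gap + 1))
    return LiftoverMap(blocks)
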