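"""The generator: determinism, construction invariants, planted rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import noiseless_cfg
from sixma import synthetic_data as sd
from sixma.core_io import SiteSet


class TestGenomeConstruction:
    def test_gene_count_and_intron_presence(self, genome, default_cfg):
        ann, lengths = genome
        g = default_cfg.genome
        assert len(ann.genes) == g.genes_per_contig * len(g.contigs)
        for gm in ann.gene_models:
            assert len(gm.transcripts[0].introns()) >= 1  # exons_per_gene >= 2

    def test_genes_do_not_overlap(self, genome):
        ann, _ = genome
        spans = sorted(
            (iv.contig, iv.start, iv.end) for iv in ann.genes.values()
        )
        for (c0, s0, e0), (c1, s1, e1) in zip(spans, spans[1:]):
            assert c0 != c1 or e0 <= s1

    def test_zero_genes_leaves_repeats_and_intergenic(self):
        cfg = sd.SimConfig(
            seed=5, genome=sd.GenomeConfig(contigs=(("c1", 50_000),), genes_per_contig=0)
        )
        ann, _ = sd.simulate_genome(cfg)
        assert len(ann.genes) == 0
        assert len(ann.intervals("simple_repeat")) > 0

    def test_contig_too_small_errors(self):
        cfg = sd.SimConfig(
            seed=5, genome=sd.GenomeConfig(contigs=(("c1", 5_000),), genes_per_contig=50)
        )
        with pytest.raises(ValueError, match="too small"):
            sd.simulate_genome(cfg)

    def test_same_seed_identical_annotation(self, default_cfg):
        a1, _ = sd.simulate_genome(default_cfg)
        a2, _ = sd.simulate_genome(default_cfg)
        s1 = [(gm.gene_id, gm.transcripts[0].exons) for gm in a1.gene_models]
        s2 = [(gm.gene_id, gm.transcripts[0].exons) for gm in a2.gene_models]
        assert s1 == s2


class TestPositionTables:
    def test_same_seed_identical_tables(self, default_cfg, genome):
        ann, _ = genome
        r1a, r2a, sca, ta = sd.simulate_position_tables(default_cfg, ann)
        r1b, r2b, scb, tb = sd.simulate_position_tables(default_cfg, ann)
        pd.testing.assert_frame_equal(r1a, r1b)
        pd.testing.assert_frame_equal(r2a, r2b)
        pd.testing.assert_frame_equal(sca, scb)
        pd.testing.assert_frame_equal(ta, tb)

    def test_prm_bounds_and_shared_positions(self, tables):
        rep1, rep2, scmp, truth = tables
        for t in (rep1, rep2, scmp):
            assert t["prm"].between(0, 100).all()
            assert (t["pos"].to_numpy() == truth["pos"].to_numpy()).all()

    def test_planted_separation(self, tables):
        rep1, _, _, truth = tables
        meth = truth["methylated"].to_numpy()
        assert rep1.loc[meth, "prm"].mean() > 80
        assert rep1.loc[~meth, "prm"].mean() < 10

    def test_uniform_multipliers_give_uniform_rates(self, default_cfg):
        cfg = sd.SimConfig(
            seed=21,
            genome=default_cfg.genome,
            methylation=sd.MethylationConfig(
                base_rate=0.05,
                multipliers={k: 1.0 for k in default_cfg.methylation.multipliers},
            ),
        )
        ann, _ = sd.simulate_genome(cfg)
        _, _, _, truth = sd.simulate_position_tables(cfg, ann)
        for category, sub in truth.groupby("category"):
            n, k = len(sub), int(sub["methylated"].sum())
            if n < 500:
                continue
            lo, hi = sps.binom.interval(0.999, n, 0.05)
            assert lo <= k <= hi, f"{category}: {k}/{n} outside binomial CI"

    def test_coverage_outliers_present(self, tables, default_cfg):
        rep1 = tables[0]
        mean = default_cfg.coverage.mean
        assert (rep1["coverage"] == round(3 * mean)).sum() > 0
        assert (rep1["coverage"] == round(0.2 * mean)).sum() > 0

    def test_constant_coverage_when_dispersion_zero(self):
        cfg = noiseless_cfg()
        ann, _ = sd.simulate_genome(cfg)
        rep1, rep2, scmp, _ = sd.simulate_position_tables(cfg, ann)
        assert rep1["coverage"].nunique() == 1
        np.testing.assert_array_equal(rep1["prm"], rep2["prm"])
        np.testing.assert_array_equal(rep1["prm"], scmp["prm"])


class TestSecondStrain:
    def _truth(self, n=2000, spacing=400):
        return SiteSet.from_records(["c1"] * n, np.arange(n) * spacing + 100)

    def test_exact_copy_when_p_exact_one(self):
        cfg = sd.SimConfig(
            seed=2, strain2=sd.Strain2Config(p_exact=1.0, p_near=0.0, background_rate=0.0)
        )
        truth = self._truth()
        s2 = sd.simulate_second_strain(truth, cfg, {"c1": 10_000_000})
        assert set(s2) == set(truth)

    def test_empty_but_for_background_when_all_dropped(self):
        cfg = sd.SimConfig(
            seed=2, strain2=sd.Strain2Config(p_exact=0.0, p_near=0.0, background_rate=0.0)
        )
        s2 = sd.simulate_second_strain(self._truth(), cfg, {"c1": 10_000_000})
        assert len(s2) == 0

    def test_shifts_stay_within_max_shift(self):
        cfg = sd.SimConfig(
            seed=4,
            strain2=sd.Strain2Config(p_exact=0.0, p_near=1.0, max_shift=100,
                                     background_rate=0.0),
        )
        truth = self._truth()
        s2 = sd.simulate_second_strain(truth, cfg, {"c1": 10_000_000})
        t_pos = truth.positions("c1")
        for p in s2.positions("c1"):
            d = np.abs(t_pos - p).min()
            assert 1 <= d <= 100


class TestTissueScores:
    def test_modified_genes_get_one_boosted_tissue(self):
        cfg = sd.SimConfig(
            seed=6, tissue=sd.TissueConfig(fold=10.0, missing_fraction=0.0)
        )
        genes = [f"g{i}" for i in range(300)]
        flags = [i < 150 for i in range(300)]
        scores = sd.simulate_tissue_scores(genes, flags, cfg)
        max_mod = scores.loc[[g for g, f in zip(genes, flags) if f]].max(axis=1)
        # log-normal tail bound: the boosted tissue alone exceeds 5 with
        # probability Phi(ln(fold/5)/sigma)
        sigma = cfg.tissue.lognorm_sigma
        p_boost = sps.norm.cdf(np.log(10.0 / 5.0) / sigma)
        assert (max_mod > 5).mean() >= p_boost - 0.05
        unmod_max = scores.loc[[g for g, f in zip(genes, flags) if not f]].max(axis=1)
        assert (max_mod > 5).mean() > (unmod_max > 5).mean() + 0.3

    def test_missing_fraction_drops_rows(self):
        cfg = sd.SimConfig(seed=6, tissue=sd.TissueConfig(missing_fraction=0.5))
        scores = sd.simulate_tissue_scores([f"g{i}" for i in range(400)], [False] * 400, cfg)
        assert 120 < len(scores) < 280

    def test_twelve_tissue_columns(self):
        cfg = sd.SimConfig(seed=6)
        scores = sd.simulate_tissue_scores(["g0"], [True], cfg)
        assert scores.shape[1] == 12


class TestSignalDifferences:
    def test_zero_sd_makes_groups_constant(self):
        cfg = sd.SimConfig(seed=8, signal=sd.SignalConfig(sd=0.0))
        truth = pd.DataFrame(
            {"contig": ["c1"] * 4, "pos": [1, 2, 3, 4],
             "methylated": [True, True, False, False]}
        )
        diff = sd.simulate_signal_differences(truth, cfg)
        assert diff["signal_diff"].iloc[0] == diff["signal_diff"].iloc[1]
        assert diff["signal_diff"].iloc[0] > diff["signal_diff"].iloc[2]


class TestConfig:
    def test_yaml_round_trip(self, tmp_path, default_cfg):
        path = tmp_path / "cfg.yaml"
        default_cfg.to_yaml(path)
        back = sd.SimConfig.from_yaml(path)
        assert back == default_cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(strain2=sd.Strain2Config(p_exact=0.7, p_near=0.7)),
            dict(coverage=sd.CoverageConfig(outlier_fraction=1.5)),
            dict(methylation=sd.MethylationConfig(multipliers={"CDS": -1.0})),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.SimConfig(seed=0, **kwargs)
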