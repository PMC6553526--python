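"""End-to-end orchestration: simulate → call → enrich → conserve → express.

Each stage is a plain function that reads and writes named files in the run
directory, so stages can be re-run standalone on the artifacts the previous
stage left behind. A single master seed is fanned out to fixed per-stage
child seeds; re-running the same config is byte-identical.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import expression_specificity as express
from . import feature_enrichment as fe
from . import site_calling as sc
from . import synthetic_data as sd
from .core_io import (
    LiftoverMap,
    SiteSet,
    read_annotations,
    read_position_table,
    write_bed_intervals,
    write_gff3,
    write_position_table,
)

FILES = {
    "annotation": "annotation.gff3",
    "repeats": "repeats.bed",
    "tes": "tes.bed",
    "rep1": "rep1.tsv",
    "rep2": "rep2.tsv",
    "sample_compare": "sample_compare.tsv",
    "truth": "truth.tsv",
    "strain2": "strain2_sites.bed",
    "liftover": "liftover.tsv",
    "gain": "gain_regions.bed",
    "tissue": "tissue_scores.tsv",
    "signal": "signal_diff.tsv",
    "sites": "sites.bed",
    "controls": "controls.bed",
    "calling": "calling_report.json",
    "enrichment": "enrichment.tsv",
    "density": "density.bedgraph",
    "enrich_report": "enrichment_report.json",
    "conservation": "conservation_report.json",
    "genes": "genes_with_sites.txt",
    "expression": "expression_report.json",
    "run_report": "run_report.json",
}

STAGE_OUTPUTS = {
    "simulate": ("annotation", "repeats", "tes", "rep1", "rep2", "sample_compare",
                 "truth", "strain2", "liftover", "gain", "tissue", "signal"),
    "call": ("sites", "controls", "calling"),
    "enrich": ("enrichment", "density", "enrich_report"),
    "conserve": ("conservation",),
    "express": ("genes", "expression"),
}

STAGE_ORDER = ("simulate", "call", "enrich", "conserve", "express")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = {"simulate": 0, "call": 1, "enrich": 2, "conserve": 3, "express": 4}[stage]
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(1000 + idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _package_version() -> str:
    try:
        return version("sixma")
    except PackageNotFoundError:
        return "unknown"


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(config: "str | Path | Mapping") -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    for section in ("seed", "outdir"):
        if section not in cfg:
            raise ValueError(f"config is missing required section {section!r}")
    cfg.setdefault("sim", {})
    cfg.setdefault("thresholds", {})
    cfg.setdefault("enrichment", {})
    cfg.setdefault("conservation", {})
    cfg.setdefault("expression", {})
    return cfg


def _sim_config(cfg: Mapping) -> sd.SimConfig:
    sim = dict(cfg.get("sim", {}))
    sim["seed"] = child_seed(int(cfg["seed"]), "simulate")
    return sd.SimConfig.from_dict(sim)


def _thresholds(cfg: Mapping) -> sc.CallingThresholds:
    return sc.CallingThresholds(**cfg.get("thresholds", {}))


# -- stages --------------------------------------------------------------------


def stage_simulate(cfg: Mapping, outdir: Path) -> dict:
    sim = _sim_config(cfg)
    ann, contig_lengths = sd.simulate_genome(sim)
    write_gff3(ann.gene_models, contig_lengths, outdir / FILES["annotation"])
    write_bed_intervals(ann.intervals("simple_repeat"), outdir / FILES["repeats"])
    write_bed_intervals(ann.intervals("TE"), outdir / FILES["tes"])

    rep1, rep2, scmp, truth = sd.simulate_position_tables(sim, ann)
    for key, table in (("rep1", rep1), ("rep2", rep2), ("sample_compare", scmp)):
        write_position_table(table, outdir / FILES[key])
    truth.to_csv(outdir / FILES["truth"], sep="\t", index=False)

    planted = sd.truth_sites(truth)
    lomap = sd.simulate_liftover_map(contig_lengths, sim)
    lomap.to_tsv(outdir / FILES["liftover"])
    strain2 = sd.simulate_second_strain(planted, sim, contig_lengths)
    strain2_alt, n_unmapped = strain2.lift(lomap)
    strain2_alt.to_bed(outdir / FILES["strain2"])

    write_bed_intervals(
        sd.simulate_gain_regions(planted, sim, contig_lengths), outdir / FILES["gain"]
    )

    modified_genes = express.genes_with_sites(planted, ann)
    all_genes = sorted(ann.genes)
    scores = sd.simulate_tissue_scores(
        all_genes, [g in modified_genes for g in all_genes], sim
    )
    scores.reset_index().to_csv(outdir / FILES["tissue"], sep="\t", index=False,
                                float_format="%.6g")

    sd.simulate_signal_differences(truth, sim).to_csv(
        outdir / FILES["signal"], sep="\t", index=False, float_format="%.6g"
    )
    return {
        "n_candidate_positions": int(len(truth)),
        "n_planted_sites": int(len(planted)),
        "n_strain2_calls": int(len(strain2)),
        "n_strain2_unmapped": int(n_unmapped),
        "n_genes": len(all_genes),
        "n_modified_genes": len(modified_genes),
    }


def stage_call(cfg: Mapping, outdir: Path) -> dict:
    thr = _thresholds(cfg)
    rep1 = read_position_table(outdir / FILES["rep1"])
    rep2 = read_position_table(outdir / FILES["rep2"])
    scmp = read_position_table(outdir / FILES["sample_compare"])
    counts = sc.cascade_counts(rep1, rep2, scmp, thr)
    f1 = sc.coverage_filter(rep1, thr.coverage_lo, thr.coverage_hi)
    f2 = sc.coverage_filter(rep2, thr.coverage_lo, thr.coverage_hi)
    fsc = sc.coverage_filter(scmp, thr.coverage_lo, thr.coverage_hi)
    sites = sc.call_high_confidence(f1, f2, fsc, thr)
    controls = sc.call_unmodified_controls(f1, f2, fsc, thr)
    sites.to_bed(outdir / FILES["sites"])
    controls.to_bed(outdir / FILES["controls"])
    rho = sc.replicate_correlation(rep1, rep2)
    report = {
        "cascade": counts,
        "n_sites": len(sites),
        "n_controls": len(controls),
        "replicate_spearman_rho": round(rho, 6),
        "thresholds": {
            "prm_min": thr.prm_min,
            "concordance": thr.concordance,
            "coverage_lo": thr.coverage_lo,
            "coverage_hi": thr.coverage_hi,
            "control_prm_max": thr.control_prm_max,
        },
    }
    _write_json(report, outdir / FILES["calling"])
    return report


def stage_enrich(cfg: Mapping, outdir: Path) -> dict:
    enr = cfg.get("enrichment", {})
    n_perm = int(enr.get("n_perm", 10_000))
    mode = enr.get("mode", "exclusive")
    precedence = tuple(enr.get("precedence", fe.DEFAULT_PRECEDENCE))
    ann = read_annotations(
        outdir / FILES["annotation"], outdir / FILES["repeats"], outdir / FILES["tes"]
    )
    sites = SiteSet.read_bed(outdir / FILES["sites"])
    controls = SiteSet.read_bed(outdir / FILES["controls"])
    results = fe.permutation_enrichment(
        sites, controls, ann, n_perm=n_perm,
        seed=child_seed(int(cfg["seed"]), "enrich"), mode=mode, precedence=precedence,
    )
    fe.enrichment_table(results).to_csv(
        outdir / FILES["enrichment"], sep="\t", index=False, float_format="%.6g"
    )
    means, track = fe.density_per_window(sites, ann.contig_lengths)
    track[["contig", "start", "end", "per_100kb"]].to_csv(
        outdir / FILES["density"], sep="\t", index=False, header=False,
        float_format="%.6g",
    )
    report = {
        "n_perm": n_perm,
        "mode": mode,
        "mean_sites_per_100kb": {c: round(v, 4) for c, v in means.items()},
        "categories": {
            c: {
                "observed": r.observed_count,
                "perm_mean": round(r.perm_mean, 4),
                "p_enrich": r.p_enrich.p_report,
                "p_deplete": r.p_deplete.p_report,
            }
            for c, r in results.items()
        },
    }
    _write_json(report, outdir / FILES["enrich_report"])
    return report


def stage_conserve(cfg: Mapping, outdir: Path) -> dict:
    d = int(cfg.get("conservation", {}).get("d", 100))
    sites = SiteSet.read_bed(outdir / FILES["sites"])
    strain2_alt = SiteSet.read_bed(outdir / FILES["strain2"])
    lomap = LiftoverMap.read_tsv(outdir / FILES["liftover"])
    strain2, n_unmapped = strain2_alt.lift(lomap.inverted())
    truth = pd.read_csv(outdir / FILES["truth"], sep="\t")
    eligible = SiteSet.from_records(truth["contig"], truth["pos"])
    universe = len(eligible)
    fwd = cons.site_overlap_test(sites, strain2, universe, d=d)
    rev = cons.site_overlap_test(strain2, sites, universe, d=d)
    gain = cons.read_regions(outdir / FILES["gain"])
    g_count, g_frac, g_p = cons.region_overlap_test(sites, gain, eligible)
    report = {
        "universe": universe,
        "n_strain2_unmapped": n_unmapped,
        "query_vs_strain2": _conservation_dict(fwd),
        "strain2_vs_query": _conservation_dict(rev),
        "gain_regions": {
            "n_regions": len(gain),
            "overlap_count": g_count,
            "overlap_fraction": round(g_frac, 6),
            "hypergeom_p": g_p,
        },
    }
    _write_json(report, outdir / FILES["conservation"])
    return report


def _conservation_dict(r: cons.ConservationReport) -> dict:
    return {
        "n_query": r.n_query,
        "n_subject": r.n_subject,
        "exact_count": r.exact_count,
        "exact_fraction": round(r.exact_fraction, 6),
        "within_d_fraction": round(r.within_d_fraction, 6),
        "d": r.d,
        "hypergeom_p": r.hypergeom_p,
    }


def stage_express(cfg: Mapping, outdir: Path) -> dict:
    opts = cfg.get("expression", {})
    statistic = opts.get("statistic", "max")
    ann = read_annotations(
        outdir / FILES["annotation"], outdir / FILES["repeats"], outdir / FILES["tes"]
    )
    sites = SiteSet.read_bed(outdir / FILES["sites"])
    controls = SiteSet.read_bed(outdir / FILES["controls"])
    genes = express.genes_with_sites(sites, ann)
    with open(outdir / FILES["genes"], "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
    scores = pd.read_csv(outdir / FILES["tissue"], sep="\t").set_index("gene")
    spec = express.compare_specificity(
        scores, genes, set(ann.genes), statistic=statistic
    )
    signal = pd.read_csv(outdir / FILES["signal"], sep="\t")
    sig = express.compare_signal_difference(signal, sites, controls)
    report = {
        "n_genes_with_sites": len(genes),
        "tissue_specificity": {k: _jsonable(v) for k, v in spec.items()},
        "signal_difference": {k: _jsonable(v) for k, v in sig.items()},
    }
    _write_json(report, outdir / FILES["expression"])
    return report


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "call": stage_call,
    "enrich": stage_enrich,
    "conserve": stage_conserve,
    "express": stage_express,
}


def run_pipeline(
    config: "str | Path | Mapping",
    stages: Sequence[str] = STAGE_ORDER,
    resume: bool = False,
) -> dict:
    """Run the requested stages in order and write the run report.

    With ``resume=True`` a stage whose output files all exist is skipped;
    otherwise every requested stage recomputes and overwrites.
    """
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": int(cfg["seed"]),
        "version": _package_version(),
        "stages": {},
    }
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        outputs = [outdir / FILES[k] for k in STAGE_OUTPUTS[stage]]
        if resume and all(p.exists() for p in outputs):
            report["stages"][stage] = {"skipped": True}
            continue
        try:
            report["stages"][stage] = STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    _write_json(report, outdir / FILES["run_report"])
    return report
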