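"""sixma: calling and characterizing high-confidence DNA 6mA sites from
per-position nanopore modification-fraction tables.

The package turns two PCR-free replicate tables plus a control-comparison
call set into a high-confidence methylated site set via a replicate
concordance cascade, then characterizes the sites: matched-control
permutation enrichment over genomic feature categories, between-strain
conservation, overlap with externally defined regions, and
tissue-specificity of the genes carrying the sites. A seeded synthetic-data
generator with planted ground truth stands in for raw nanopore data.
"""

from . import (
    conservation,
    core_io,
    expression_specificity,
    feature_enrichment,
    pipeline,
    site_calling,
    stats,
    synthetic_data,
)
from .core_io import (
    AnnotationSet,
    GenomePosition,
    Interval,
    LiftoverMap,
    SiteSet,
)
from .site_calling import CallingThresholds
from .synthetic_data import SimConfig

__version__ = "0.1.0"

__all__ = [
    "AnnotationSet",
    "CallingThresholds",
    "GenomePosition",
    "Interval",
    "LiftoverMap",
    "SimConfig",
    "SiteSet",
    "conservation",
    "core_io",
    "expression_specificity",
    "feature_enrichment",
    "pipeline",
    "site_calling",
    "stats",
    "synthetic_data",
]


def demo_config_path() -> str:
    """Path to the bundled small demo pipeline config."""
    from importlib.resources import files

    return str(files("sixma") / "configs" / "demo.yaml")
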